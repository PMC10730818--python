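"""Superfamily-graph data splitting and the plDDT/PAE disorder proxy.

Shows why chains sharing a homologous superfamily can never straddle the
train/test split, and how predicted-model confidence fields label NDRs.
"""

import numpy as np

from domseg import ndr_proxy, sample_corpus, superfamily_split
from domseg.baselines import AnnotationTable

# Chains c1 and c3 share superfamily A; c1 also contains B, so {A, B} form
# one graph component and the three chains can never be separated from it.
table = AnnotationTable([
    ("c1", "d1", "A", "1-100"), ("c1", "d2", "B", "101-190"),
    ("c2", "d3", "C", "1-120"), ("c3", "d4", "A", "1-95"),
    ("c4", "d5", "D", "1-80"), ("c5", "d6", "E", "1-150"),
])
train_ids, test_ids, components = superfamily_split(table, holdout_rate=0.5,
                                                    seed=0)
print("components:", [sorted(c) for c in components])
print("train:", train_ids, " test:", test_ids)

fx = sample_corpus(1, seed=2)[0]
mask = ndr_proxy(fx.quality)
print(f"{fx.name}: proxy flags {mask.sum()} NDRs of {len(mask)} residues; "
      f"agrees with ground truth: {np.array_equal(mask, fx.dmap.labels == 0)}")

# The proxy marks a residue as a non-domain residue when its plDDT is below
# 60 AND its PAE row is near-constant (std < 0.4) - the signature of a
# disordered region in a predicted model.
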