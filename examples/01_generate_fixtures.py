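"""Generate a small synthetic multi-domain corpus and inspect one target.

Each fixture is a protein-like CA trace: compact self-avoiding-walk domains,
extended linkers/tails (non-domain residues, NDRs), ground-truth labels, and
plDDT/PAE confidence fields whose statistics match the NDR proxy.
"""

import numpy as np

from domseg import ndr_proxy, sample_corpus

fixtures = sample_corpus(5, seed=0)
for fx in fixtures:
    n = len(fx.chain)
    ndr_frac = float(np.mean(fx.dmap.labels == 0))
    proxy_ok = np.array_equal(ndr_proxy(fx.quality), fx.dmap.labels == 0)
    print(f"{fx.name}: {n} residues, {fx.dmap.ndom} domains, "
          f"{ndr_frac:.0%} NDR, proxy recovers truth: {proxy_ok}")

# The printed lines show chain length, how many compact domains the walk
# placed, the fraction of disordered (label 0) residues, and that the
# plDDT/PAE-based NDR proxy reproduces the generator's ground truth exactly.
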