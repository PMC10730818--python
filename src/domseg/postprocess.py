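"""Deterministic clean-up of raw per-residue domain labels.

Two rules applied after the network's argmax assignment:

* :func:`clean_domain_map` — coalesce every domain with fewer than 30
  residues, and every contiguous segment with fewer than 10 residues, into
  the preceding domain (iterated N-to-C until a fixed point).
* :func:`split_disjoint` — at full-chain inference, split residues sharing
  one label into separate domains when the minimum CA-CA distance between
  their spatial clusters exceeds 10 Angstrom, via connected components of
  the label-restricted contact map.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .structio import DistanceMap, DomainMap

DEFAULT_MIN_DOMAIN = 30
DEFAULT_MIN_SEGMENT = 10
DEFAULT_CONTACT_THRESH = 10.0  # Angstrom; "greater than 10 A" splits


def _segments(labels: np.ndarray):
    """Maximal runs of constant label: list of [label, start, end) triples."""
    segs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segs.append([int(labels[start]), start, i])
            start = i
    return segs


def clean_domain_map(dmap: DomainMap, min_domain: int = DEFAULT_MIN_DOMAIN,
                     min_segment: int = DEFAULT_MIN_SEGMENT) -> DomainMap:
    """Coalesce undersized domains and segments into the preceding domain.

    A "segment" is a maximal contiguous run of one label; a "domain" is all
    residues sharing one nonzero label.  Sweeping N-to-C, the first
    violation found is resolved: an undersized domain (total size below
    ``min_domain``) coalesces as a whole, every one of its segments taking
    the label of its nearest preceding nonzero segment with a different
    label (a segment with no predecessor takes the following one's label);
    an undersized segment (run shorter than ``min_segment``) is relabelled
    the same way on its own.  NDR (label 0) segments are transparent: never
    merged into, never consumed.  Sweeps repeat until a fixed point, since
    one merge can push a neighbour domain below threshold; a revisited state
    (possible only when label-0 gaps isolate a short stretch) stops the
    iteration.  A chain whose only nonzero label is undersized is kept as a
    single domain.
    """
    labels = dmap.labels.copy()
    seen = set()
    while True:
        key = labels.tobytes()
        if key in seen:  # a state revisit means no further progress is possible
            break
        seen.add(key)
        segs = _segments(labels)
        totals = {}
        for lab, s, e in segs:
            if lab > 0:
                totals[lab] = totals.get(lab, 0) + (e - s)

        def target_for(k, lab):
            for j in range(k - 1, -1, -1):
                if segs[j][0] > 0 and segs[j][0] != lab:
                    return segs[j][0]
            for j in range(k + 1, len(segs)):  # first segment: use the following
                if segs[j][0] > 0 and segs[j][0] != lab:
                    return segs[j][0]
            return None

        victim = None
        for k, (lab, s, e) in enumerate(segs):
            if lab > 0 and ((e - s) < min_segment or totals[lab] < min_domain):
                victim = (k, lab, s, e)
                break
        if victim is None:
            break
        k, lab, s, e = victim
        if totals[lab] < min_domain:
            # the whole undersized domain coalesces at once; per-segment
            # targets are resolved on the pre-merge segmentation
            moves = [(s2, e2, target_for(k2, lab)) for k2, (l2, s2, e2)
                     in enumerate(segs) if l2 == lab]
            for s2, e2, tgt in moves:
                if tgt is not None:
                    labels[s2:e2] = tgt
        else:
            tgt = target_for(k, lab)
            if tgt is None:
                break  # sole nonzero label on the chain: keep it
            labels[s:e] = tgt
    return DomainMap(labels=labels, mask=dmap.mask.copy())


def split_disjoint(dmap: DomainMap, dist: DistanceMap,
                   contact_thresh: float = DEFAULT_CONTACT_THRESH) -> DomainMap:
    """Split same-label residue sets that are spatially disconnected.

    Adjacency: same nonzero label AND CA-CA distance <= ``contact_thresh``.
    Each connected component over nonzero-labelled residues gets a fresh
    unique label; label 0 is untouched.  Never merges — the output partition
    refines the input one.
    """
    lab = dmap.labels
    nz = np.flatnonzero(lab > 0)
    if len(nz) == 0:
        return dmap.copy()
    sub = dist.values[np.ix_(nz, nz)]
    same = lab[nz][:, None] == lab[nz][None, :]
    adj = csr_matrix(same & (sub <= contact_thresh))
    n_comp, comp = connected_components(adj, directed=False)
    out = np.zeros_like(lab)
    # components numbered by order of first residue for determinism
    order = {}
    for pos, c in zip(nz, comp):
        if c not in order:
            order[c] = len(order) + 1
        out[pos] = order[c]
    return DomainMap(labels=out, mask=dmap.mask.copy())


def apply_ndr_mask(dmap: DomainMap, ndr_mask: np.ndarray) -> DomainMap:
    """Zero out the labels of residues flagged as NDR."""
    ndr_mask = np.asarray(ndr_mask, dtype=bool)
    if len(ndr_mask) != len(dmap):
        raise ValueError("NDR mask length != domain map length")
    labels = dmap.labels.copy()
    labels[ndr_mask] = 0
    return DomainMap(labels=labels, mask=dmap.mask.copy())


def relabel_consecutive(dmap: DomainMap) -> DomainMap:
    """Relabel nonzero labels to 1..ndom by order of first residue."""
    labels = dmap.labels.copy()
    mapping = {}
    for lab in labels:
        if lab > 0 and lab not in mapping:
            mapping[lab] = len(mapping) + 1
    out = np.array([mapping.get(l, 0) for l in labels], dtype=int)
    return DomainMap(labels=out, mask=dmap.mask.copy())
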