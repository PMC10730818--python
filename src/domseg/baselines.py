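"""Random segmentation baselines, dataset splitting and the NDR proxy.

* Domain-Guess-by-Size (DGS) count estimate: one domain per ~125 residues.
* Random equal / unequal / assigned baselines at the DGS count.
* plDDT/PAE proxy labelling of non-domain residues (NDRs) on predicted
  models: plDDT < 60 AND near-constant PAE row (population std of the
  off-diagonal row entries < 0.4).
* Homologous-superfamily adjacency-graph train/test split that forbids any
  superfamily from straddling the split, with ~1-in-20 component holdout.
* A greedy k-mer identity filter standing in for external redundancy
  clustering at 99% sequence identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .structio import DomainMap

DGS_RESIDUES_PER_DOMAIN = 125.0
PLDDT_THRESH = 60.0
PAE_STD_THRESH = 0.4
HOLDOUT_RATE = 1.0 / 20.0
IDENTITY_THRESHOLD = 0.99


@dataclass
class QualityFields:
    """Per-residue model confidence (plDDT, 0-100) and an NxN PAE map (A)."""

    plddt: np.ndarray
    pae: np.ndarray

    def __post_init__(self):
        self.plddt = np.asarray(self.plddt, dtype=float)
        self.pae = np.asarray(self.pae, dtype=float)
        n = len(self.plddt)
        if self.pae.shape != (n, n):
            raise ValueError("PAE shape inconsistent with plDDT length")


def ndr_proxy(q: QualityFields, plddt_thresh: float = PLDDT_THRESH,
              pae_std_thresh: float = PAE_STD_THRESH) -> np.ndarray:
    """Boolean NDR mask: low confidence AND near-constant aligned error.

    A residue is an NDR when its plDDT is strictly below ``plddt_thresh``
    and the population standard deviation of its PAE row — excluding the
    structurally-zero self term — is strictly below ``pae_std_thresh``.
    Disordered residues in predicted models show uniformly high aligned
    error against every other residue, hence the near-constant row.
    """
    n = len(q.plddt)
    off = ~np.eye(n, dtype=bool)
    row_std = np.array([q.pae[i][off[i]].std() for i in range(n)])
    return (q.plddt < plddt_thresh) & (row_std < pae_std_thresh)


def dgs_domain_count(n_residues: int) -> int:
    """Domain-Guess-by-Size: max(1, round(n / 125))."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    return max(1, int(np.floor(n_residues / DGS_RESIDUES_PER_DOMAIN + 0.5)))


def random_baseline(n_residues: int, mode: str, seed: int, ndom: int = None) -> DomainMap:
    """Random segmentations at the DGS domain count.

    ``equal``  — contiguous segments of floor(n/ndom), remainder on the last;
    ``unequal``— ndom-1 distinct internal cut points drawn uniformly;
    ``assigned`` — every residue's label drawn uniformly from 1..ndom.
    """
    if ndom is None:
        ndom = dgs_domain_count(n_residues)
    if ndom > n_residues:
        raise ValueError("more domains than residues")
    rng = np.random.default_rng(seed)
    labels = np.zeros(n_residues, dtype=int)
    if mode == "equal":
        size = n_residues // ndom
        for d in range(ndom):
            end = (d + 1) * size if d < ndom - 1 else n_residues
            labels[d * size:end] = d + 1
    elif mode == "unequal":
        cuts = np.sort(rng.choice(np.arange(1, n_residues), size=ndom - 1, replace=False))
        bounds = np.concatenate([[0], cuts, [n_residues]])
        for d in range(ndom):
            labels[bounds[d]:bounds[d + 1]] = d + 1
    elif mode == "assigned":
        labels = rng.integers(1, ndom + 1, size=n_residues)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DomainMap(labels=labels)


@dataclass
class AnnotationTable:
    """Rows of (chain_id, domain_id, superfamily_id, segment spec)."""

    rows: list

    @classmethod
    def from_tsv(cls, path):
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                chain_id, domain_id, sf, spec = line.split("\t")
                rows.append((chain_id, domain_id, sf, spec))
        return cls(rows)


def superfamily_split(table: AnnotationTable, holdout_rate: float = HOLDOUT_RATE,
                      seed: int = 0):
    """Train/test split over the superfamily adjacency graph.

    Superfamilies are graph nodes; an edge joins two superfamilies whenever
    one chain contains domains from both.  The largest connected component
    goes to training; each remaining component is independently held out
    with probability ``holdout_rate``.  Chains travel with their component,
    so no superfamily ever appears on both sides.
    """
    g = nx.Graph()
    chains = {}
    for chain_id, _dom, sf, _spec in table.rows:
        g.add_node(sf)
        chains.setdefault(chain_id, set()).add(sf)
    for sfs in chains.values():
        sfs = sorted(sfs)
        for i in range(len(sfs)):
            for j in range(i + 1, len(sfs)):
                g.add_edge(sfs[i], sfs[j])
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: (-len(c), c))  # largest first, deterministic
    rng = np.random.default_rng(seed)
    test_sfs = set()
    for comp in components[1:]:
        if rng.random() < holdout_rate:
            test_sfs.update(comp)
    train_ids, test_ids = [], []
    for chain_id in sorted(chains):
        if chains[chain_id] & test_sfs:
            test_ids.append(chain_id)
        else:
            train_ids.append(chain_id)
    return train_ids, test_ids, components


def _kmers(seq: str, k: int = 5):
    return {seq[i:i + k] for i in range(len(seq) - k + 1)} if len(seq) >= k else {seq}


def identity_filter(sequences, threshold: float = IDENTITY_THRESHOLD, k: int = 5):
    """Greedy redundancy filter by k-mer containment identity.

    ``sequences`` is a mapping id -> sequence.  Sequences are visited in
    input order; one becomes a new representative unless its estimated
    identity to an existing representative exceeds ``threshold``.  Identity
    between two sequences is estimated as shared k-mers over the smaller
    k-mer set.
    """
    reps = []
    rep_kmers = []
    for sid, seq in sequences.items():
        ks = _kmers(seq, k)
        redundant = False
        for rk in rep_kmers:
            ident = len(ks & rk) / max(min(len(ks), len(rk)), 1)
            if ident > threshold:
                redundant = True
                break
        if not redundant:
            reps.append(sid)
            rep_kmers.append(ks)
    return reps
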