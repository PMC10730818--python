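"""Backbone structure input and domain annotations.

Reads protein backbones from PDB files (N, CA, C atoms per residue), builds
the per-residue rigid frames and CA distance maps that feed the network, and
parses CATH-style — possibly discontinuous — domain segment strings into
per-residue label vectors.

Conventions: internal arrays are 0-based; annotation ranges are 1-based,
author-numbered and inclusive at both ends.  Residue label 0 is reserved for
non-domain residues (NDRs); domains are numbered 1..k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN_AA = "X"  # maps to the all-zero one-hot vector
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}


class ChainNotFoundError(ValueError):
    pass


class ChainTooShortError(ValueError):
    pass


class DegenerateFrameError(ValueError):
    pass


class SegmentSpecError(ValueError):
    pass


@dataclass
class ProteinChain:
    """Sequence plus index-aligned backbone coordinates for one chain."""

    id: str
    sequence: str
    coords_N: np.ndarray   # [N, 3] in Angstrom
    coords_CA: np.ndarray  # [N, 3]
    coords_C: np.ndarray   # [N, 3]
    author_numbering: np.ndarray  # [N] ints

    def __post_init__(self):
        n = len(self.sequence)
        self.coords_N = np.asarray(self.coords_N, dtype=float).reshape(n, 3)
        self.coords_CA = np.asarray(self.coords_CA, dtype=float).reshape(n, 3)
        self.coords_C = np.asarray(self.coords_C, dtype=float).reshape(n, 3)
        self.author_numbering = np.asarray(self.author_numbering, dtype=int).reshape(n)
        if n < 2:
            raise ChainTooShortError(f"chain too short: {n} residues")
        for arr in (self.coords_N, self.coords_CA, self.coords_C):
            if np.isnan(arr).any():
                raise ValueError("NaN coordinates after parsing")

    def __len__(self) -> int:
        return len(self.sequence)

    def one_hot(self) -> np.ndarray:
        """[N, 20] one-hot sequence; unknown residues are all-zero rows."""
        oh = np.zeros((len(self), len(AA_ALPHABET)))
        for i, aa in enumerate(self.sequence):
            j = _AA_INDEX.get(aa)
            if j is not None:
                oh[i, j] = 1.0
        return oh


@dataclass
class BackboneFrames:
    rotations: np.ndarray     # [N, 3, 3], each orthonormal with det +1
    translations: np.ndarray  # [N, 3] == CA coordinates


@dataclass
class DistanceMap:
    values: np.ndarray  # [N, N] symmetric CA-CA distances


@dataclass
class DomainMap:
    """Per-residue integer domain labels; 0 = NDR, 1..k = domains.

    ``mask`` flags residues excluded from supervision (the CATH "holding
    pen" of unfinalised domains).
    """

    labels: np.ndarray
    mask: np.ndarray = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if (self.labels < 0).any():
            raise ValueError("labels must be >= 0")
        if self.mask is None:
            self.mask = np.zeros(len(self.labels), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.mask) != len(self.labels):
            raise ValueError("mask length != labels length")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def ndom(self) -> int:
        return len(set(self.labels[self.labels > 0]))

    def copy(self) -> "DomainMap":
        return DomainMap(self.labels.copy(), self.mask.copy())


# --------------------------------------------------------------- PDB parsing


def parse_pdb_backbone(path, chain_id: str) -> ProteinChain:
    """Read one chain's backbone from a PDB file.

    Keeps the first model and first altloc; residues missing any of N, CA, C
    are dropped so that frames are always well defined.
    """
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ChainNotFoundError(f"chain not found: {chain_id!r} in {path}")
    model = st[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise ChainNotFoundError(f"chain not found: {chain_id!r} in {path}")

    seq, n_xyz, ca_xyz, c_xyz, numbers = [], [], [], [], []
    for res in chain:
        atoms = {}
        for atom in res:
            if atom.name in ("N", "CA", "C") and atom.name not in atoms:
                atoms[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        if len(atoms) < 3:
            continue
        one = gemmi.find_tabulated_residue(res.name)
        letter = one.one_letter_code.upper() if one else UNKNOWN_AA
        if letter not in _AA_INDEX:
            letter = UNKNOWN_AA
        seq.append(letter)
        n_xyz.append(atoms["N"])
        ca_xyz.append(atoms["CA"])
        c_xyz.append(atoms["C"])
        numbers.append(res.seqid.num)

    if len(seq) < 2:
        raise ChainTooShortError(
            f"chain too short: {len(seq)} complete residues in chain {chain_id!r}")
    return ProteinChain(
        id=chain_id, sequence="".join(seq),
        coords_N=np.array(n_xyz), coords_CA=np.array(ca_xyz), coords_C=np.array(c_xyz),
        author_numbering=np.array(numbers),
    )


# ------------------------------------------------------------------- frames


def build_frames(chain: ProteinChain) -> BackboneFrames:
    """Per-residue rigid frames via Gram-Schmidt on the N-CA-C atoms.

    With v1 = C - CA and v2 = N - CA: e1 = v1/|v1|,
    e2 = normalise(v2 - (e1.v2) e1), e3 = e1 x e2; the rotation has columns
    (e1, e2, e3) and the translation is the CA position.
    """
    v1 = chain.coords_C - chain.coords_CA
    v2 = chain.coords_N - chain.coords_CA
    n1 = np.linalg.norm(v1, axis=1, keepdims=True)
    if (n1 < 1e-8).any():
        raise DegenerateFrameError("degenerate frame: zero C-CA vector")
    e1 = v1 / n1
    proj = (e1 * v2).sum(axis=1, keepdims=True)
    u2 = v2 - proj * e1
    n2 = np.linalg.norm(u2, axis=1, keepdims=True)
    if (n2 < 1e-8).any():
        bad = int(np.argmax(n2[:, 0] < 1e-8))
        raise DegenerateFrameError(f"degenerate frame at residue {bad}: collinear N/CA/C")
    e2 = u2 / n2
    e3 = np.cross(e1, e2)
    rot = np.stack([e1, e2, e3], axis=-1)  # columns are e1, e2, e3
    return BackboneFrames(rotations=rot, translations=chain.coords_CA.copy())


def pairwise_ca_distances(chain: ProteinChain) -> DistanceMap:
    diff = chain.coords_CA[:, None, :] - chain.coords_CA[None, :, :]
    return DistanceMap(values=np.sqrt((diff ** 2).sum(axis=-1)))


# -------------------------------------------------------------- annotations


def _parse_ranges(txt: str):
    out = []
    for part in txt.split(","):
        part = part.strip()
        if not part:
            continue
        lo, sep, hi = part.partition("-")
        try:
            lo_i = int(lo)
            hi_i = int(hi) if sep else lo_i
        except ValueError as exc:
            raise SegmentSpecError(f"bad range {part!r}") from exc
        if hi_i < lo_i:
            raise SegmentSpecError(f"bad range {part!r}: end before start")
        out.append((lo_i, hi_i))
    return out


def parse_domain_segments(spec: str, chain: ProteinChain) -> DomainMap:
    """Expand a segment string into a per-residue DomainMap.

    Format: domains separated by ';', each a comma list of inclusive
    author-numbered ranges, e.g. ``"1-50,120-170;51-119"``.  An optional
    trailing ``|mask:...`` entry lists holding-pen ranges to exclude from
    supervision.
    """
    spec = spec.strip()
    mask_ranges = []
    if "|" in spec:
        spec, _, tail = spec.partition("|")
        tail = tail.strip()
        if not tail.startswith("mask:"):
            raise SegmentSpecError(f"unrecognised trailer {tail!r}")
        mask_ranges = _parse_ranges(tail[len("mask:"):])

    author = chain.author_numbering
    index_of = {num: i for i, num in enumerate(author)}
    labels = np.zeros(len(chain), dtype=int)
    for dom_idx, entry in enumerate(s for s in spec.split(";") if s.strip()):
        for lo, hi in _parse_ranges(entry):
            for num in range(lo, hi + 1):
                i = index_of.get(num)
                if i is None:
                    raise SegmentSpecError(
                        f"range out of bounds: residue {num} not in chain")
                if labels[i] != 0:
                    raise SegmentSpecError(
                        f"conflicting assignment at residue {num}")
                labels[i] = dom_idx + 1
    mask = np.zeros(len(chain), dtype=bool)
    for lo, hi in mask_ranges:
        for num in range(lo, hi + 1):
            i = index_of.get(num)
            if i is None:
                raise SegmentSpecError(f"range out of bounds: residue {num} not in chain")
            mask[i] = True
    return DomainMap(labels=labels, mask=mask)


def serialize_domain_segments(dmap: DomainMap, chain: ProteinChain) -> str:
    """Inverse of :func:`parse_domain_segments` (labels only, plus mask)."""
    author = chain.author_numbering
    entries = []
    for label in sorted(set(dmap.labels[dmap.labels > 0]),
                        key=lambda l: int(np.argmax(dmap.labels == l))):
        idx = np.flatnonzero(dmap.labels == label)
        entries.append(_runs_to_text(author[idx]))
    txt = ";".join(entries)
    if dmap.mask.any():
        txt += "|mask:" + _runs_to_text(author[np.flatnonzero(dmap.mask)])
    return txt


def _runs_to_text(nums: np.ndarray) -> str:
    runs = []
    start = prev = int(nums[0])
    for n in nums[1:]:
        n = int(n)
        if n == prev + 1:
            prev = n
            continue
        runs.append((start, prev))
        start = prev = n
    runs.append((start, prev))
    return ",".join(f"{a}-{b}" if a != b else f"{a}" for a, b in runs)


def domain_map_to_affinity(dmap: DomainMap):
    """Ground-truth co-membership matrix and pair-exclusion flags.

    A[i, j] = 1 iff residues i and j carry the same nonzero label.  Pairs
    touching a masked (holding-pen) or label-0 residue are flagged excluded
    so the affinity objective never sees them.
    """
    lab = dmap.labels
    A = ((lab[:, None] == lab[None, :]) & (lab[:, None] > 0)).astype(float)
    bad = (lab == 0) | dmap.mask
    excluded = bad[:, None] | bad[None, :]
    return A, excluded
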