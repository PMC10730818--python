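"""Synthetic multi-domain backbone fixtures.

Generates protein-like CA traces in which each domain is a compact
self-avoiding walk confined to a sphere, linkers and terminal tails are
extended walks (the non-domain residues, NDRs), and optional discontinuous
domains wrap a spatially separate insert domain in sequence.  Alongside the
coordinates it emits ground-truth domain maps and per-residue plDDT / PAE
confidence fields whose statistics are matched to the NDR proxy (low plDDT
and near-constant high PAE rows for NDRs), so proxy labelling recovers the
ground truth exactly.

These fixtures capture the geometric premise of domain segmentation — high
intra-domain versus inter-domain contact density, CA-CA virtual bonds of
~3.8 A — but not protein chemistry: there is no secondary structure, no
Ramachandran statistics, and sequences are random.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .baselines import QualityFields
from .structio import AA_ALPHABET, DomainMap, ProteinChain, serialize_domain_segments

CA_STEP_LO, CA_STEP_HI = 3.72, 3.88  # virtual CA-CA bond length band, A
CLASH_DIST = 3.6
RADIUS_COEFF = 2.5  # sphere radius = 2.5 * size^(1/3) A


@dataclass
class DomainSpecEntry:
    size: int
    center: np.ndarray
    # if set, the domain is discontinuous: parts interleave with the next
    # domain in sequence (part0, next domain, part1, ...)
    discontinuous_parts: list = None


@dataclass
class FixtureSpec:
    domains: list            # list[DomainSpecEntry]
    linker_lengths: list     # NDR linkers between consecutive sequence blocks
    n_term_len: int = 0
    c_term_len: int = 0
    noise_scale: float = 0.1
    seed: int = 0


@dataclass
class Fixture:
    chain: ProteinChain
    dmap: DomainMap
    quality: QualityFields
    name: str = "synthetic"


def _blocks_from_spec(spec: FixtureSpec):
    """Sequence blocks of (label, length, center-or-None). None = NDR."""
    blocks = []
    if spec.n_term_len > 0:
        blocks.append((0, spec.n_term_len, None))
    linkers = list(spec.linker_lengths)
    i = 0
    doms = spec.domains
    while i < len(doms):
        d = doms[i]
        label = i + 1
        if d.discontinuous_parts and i + 1 < len(doms):
            parts = d.discontinuous_parts
            insert = doms[i + 1]
            blocks.append((label, parts[0], d.center))
            blocks.append((i + 2, insert.size, insert.center))
            blocks.append((label, sum(parts[1:]), d.center))
            i += 2
        else:
            blocks.append((label, d.size, d.center))
            i += 1
        if i < len(doms):
            length = linkers.pop(0) if linkers else 12
            blocks.append((0, length, None))
    if spec.c_term_len > 0:
        blocks.append((0, spec.c_term_len, None))
    return blocks


def _walk(blocks, rng: np.random.Generator) -> np.ndarray:
    """Generate CA coordinates block by block as one continuous walk."""
    coords = []
    domain_points = {}  # label -> list of indices, for clash checks

    first_center = next(c for _, _, c in blocks if c is not None)
    if blocks[0][2] is None:  # chain starts with a tail: begin away from it
        direction = _rand_unit(rng)
        start = first_center + direction * (blocks[0][1] * 2.4 + 12.0)
    else:
        start = first_center + _rand_unit(rng) * (RADIUS_COEFF * blocks[0][1] ** (1 / 3))
    pos = np.asarray(start, dtype=float)
    coords.append(pos.copy())
    heading = _rand_unit(rng)

    for b_idx, (label, length, center) in enumerate(blocks):
        remaining = length - (1 if b_idx == 0 else 0)
        if center is None:
            # extended walk; linkers aim at the next domain's sphere
            target = None
            for lab2, len2, c2 in blocks[b_idx + 1:]:
                if c2 is not None:
                    target = (c2, RADIUS_COEFF * len2 ** (1 / 3))
                    break
            for _ in range(remaining):
                if target is not None:
                    to_t = target[0] - pos
                    dist = np.linalg.norm(to_t)
                    if dist > target[1]:
                        heading = _norm(0.75 * to_t / dist + 0.25 * _rand_unit(rng))
                    else:
                        heading = _norm(heading + 0.4 * _rand_unit(rng))
                else:
                    heading = _norm(heading + 0.25 * _rand_unit(rng))
                pos = pos + heading * rng.uniform(CA_STEP_LO, CA_STEP_HI)
                coords.append(pos.copy())
        else:
            radius = RADIUS_COEFF * length ** (1 / 3)
            own = domain_points.setdefault(label, [])
            for _ in range(remaining):
                step = rng.uniform(CA_STEP_LO, CA_STEP_HI)
                to_c = center - pos
                dist_c = np.linalg.norm(to_c)
                if dist_c > radius:
                    direction = _norm(to_c / max(dist_c, 1e-9) + 0.25 * _rand_unit(rng))
                    pos = pos + direction * step
                else:
                    placed = False
                    for _try in range(60):
                        cand = pos + _rand_unit(rng) * step
                        if np.linalg.norm(cand - center) > radius:
                            continue
                        if own and np.min(np.linalg.norm(
                                np.asarray(coords)[own] - cand, axis=1)) < CLASH_DIST:
                            continue
                        pos = cand
                        placed = True
                        break
                    if not placed:  # fall back: drift toward centre
                        pos = pos + _norm(to_c / max(dist_c, 1e-9)
                                          + 0.6 * _rand_unit(rng)) * step
                coords.append(pos.copy())
                own.append(len(coords) - 1)
        if b_idx == 0:
            # first residue belongs to this block too
            domain_points.setdefault(label, []) if center is not None else None
    return np.asarray(coords)


def _rand_unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _norm(v):
    return v / max(np.linalg.norm(v), 1e-12)


def _place_backbone(ca: np.ndarray):
    """Ideal-geometry N and C atoms around each CA (fixed lengths/angles)."""
    n = len(ca)
    d = np.zeros_like(ca)
    d[:-1] = ca[1:] - ca[:-1]
    d[-1] = ca[-1] - ca[-2]
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    ref = np.tile(np.array([0.0, 0.0, 1.0]), (n, 1))
    p = np.cross(d, ref)
    small = np.linalg.norm(p, axis=1) < 1e-6
    if small.any():
        p[small] = np.cross(d[small], np.array([1.0, 0.0, 0.0]))
    p = p / np.linalg.norm(p, axis=1, keepdims=True)
    q = np.cross(d, p)
    nb = -0.5 * d + 0.866 * p
    cb = 0.5 * d + 0.866 * q
    coords_N = ca + 1.46 * nb / np.linalg.norm(nb, axis=1, keepdims=True)
    coords_C = ca + 1.52 * cb / np.linalg.norm(cb, axis=1, keepdims=True)
    return coords_N, coords_C


def _quality_fields(labels: np.ndarray, rng: np.random.Generator) -> QualityFields:
    n = len(labels)
    ndr = labels == 0
    plddt = np.where(ndr, rng.uniform(30, 55, size=n), rng.uniform(75, 95, size=n))
    pae = rng.uniform(2.0, 22.0, size=(n, n))  # variable rows for domain residues
    for i in np.flatnonzero(ndr):
        # near-constant high aligned error: the disorder signature
        pae[i, :] = rng.uniform(24, 30) + rng.normal(0, 0.05, size=n)
    np.fill_diagonal(pae, 0.0)
    return QualityFields(plddt=plddt, pae=np.abs(pae))


def make_chain(spec: FixtureSpec, name: str = "synthetic"):
    """Build one fixture: (ProteinChain, DomainMap, QualityFields)."""
    rng = np.random.default_rng(spec.seed)
    blocks = _blocks_from_spec(spec)
    labels = np.concatenate([np.full(length, label, dtype=int)
                             for label, length, _ in blocks])
    ca = _walk(blocks, rng)
    assert len(ca) == len(labels)
    coords_N, coords_C = _place_backbone(ca)
    seq = "".join(rng.choice(list(AA_ALPHABET), size=len(labels)))
    chain = ProteinChain(
        id=name, sequence=seq, coords_N=coords_N, coords_CA=ca, coords_C=coords_C,
        author_numbering=np.arange(1, len(labels) + 1),
    )
    centers = {label: c for label, _len, c in blocks if c is not None}
    for a, b in zip(centers, list(centers)[1:]):
        ra = RADIUS_COEFF * np.sum(labels == a) ** (1 / 3)
        rb = RADIUS_COEFF * np.sum(labels == b) ** (1 / 3)
        if np.linalg.norm(centers[a] - centers[b]) < ra + rb:
            import warnings
            warnings.warn(f"domain overlap between {a} and {b}")
    return chain, DomainMap(labels=labels), _quality_fields(labels, rng)


def make_discontinuous(seed: int = 0, part: int = 50, insert: int = 60,
                       separation: float = 40.0) -> Fixture:
    """A two-domain fixture whose first domain wraps the second in sequence.

    Ground-truth labels are [1]*part, [2]*insert, [1]*part; both label-1
    stretches share one centre and therefore one compact region in space.
    """
    c1 = np.zeros(3)
    c2 = np.array([separation, 0.0, 0.0])
    spec = FixtureSpec(
        domains=[
            DomainSpecEntry(size=2 * part, center=c1, discontinuous_parts=[part, part]),
            DomainSpecEntry(size=insert, center=c2),
        ],
        linker_lengths=[], seed=seed,
    )
    chain, dmap, quality = make_chain(spec, name=f"disc{seed}")
    return Fixture(chain=chain, dmap=dmap, quality=quality, name=f"disc{seed}")


@dataclass
class CorpusProfile:
    """Difficulty profile for a fixture corpus."""

    ndom_choices: tuple = (1, 2, 3)
    ndom_weights: tuple = (0.2, 0.4, 0.4)  # multi-domain emphasis
    domain_size: tuple = (90, 150)         # residues, CATH-like
    ndr_frac: tuple = (0.0, 0.3)           # of total chain length
    p_discontinuous: float = 0.2
    linker_len: tuple = (8, 20)


def sample_fixture(profile: CorpusProfile, seed: int, name: str = None) -> Fixture:
    rng = np.random.default_rng(seed)
    ndom = int(rng.choice(profile.ndom_choices, p=np.asarray(profile.ndom_weights)
                          / np.sum(profile.ndom_weights)))
    sizes = rng.integers(profile.domain_size[0], profile.domain_size[1] + 1, size=ndom)
    linkers = [int(rng.integers(*profile.linker_len)) for _ in range(max(0, ndom - 1))]
    total_dom = int(sizes.sum())
    frac = rng.uniform(*profile.ndr_frac)
    total_ndr = int(frac / max(1 - frac, 1e-9) * total_dom)
    tail_budget = max(0, total_ndr - sum(linkers))
    n_tail = int(rng.integers(0, tail_budget + 1))
    c_tail = tail_budget - n_tail

    centers = [np.zeros(3)]
    for i in range(1, ndom):
        r_prev = RADIUS_COEFF * sizes[i - 1] ** (1 / 3)
        r_here = RADIUS_COEFF * sizes[i] ** (1 / 3)
        gap = float(np.clip(0.55 * (linkers[i - 1] if i - 1 < len(linkers) else 12)
                            * 3.8, 8.0, 40.0))
        centers.append(centers[-1] + _rand_unit(rng) * (r_prev + r_here + gap))

    domains = [DomainSpecEntry(size=int(s), center=c) for s, c in zip(sizes, centers)]
    if ndom >= 2 and rng.random() < profile.p_discontinuous:
        # split the first domain around the second
        half = int(sizes[0]) // 2
        domains[0].discontinuous_parts = [half, int(sizes[0]) - half]
        linkers = linkers[1:] if len(linkers) > 1 else []
    spec = FixtureSpec(domains=domains, linker_lengths=linkers,
                       n_term_len=n_tail, c_term_len=c_tail,
                       seed=int(rng.integers(0, 2 ** 31 - 1)))
    chain, dmap, quality = make_chain(spec, name=name or f"synth{seed:05d}")
    return Fixture(chain=chain, dmap=dmap, quality=quality, name=name or f"synth{seed:05d}")


def sample_corpus(n: int, profile: CorpusProfile = None, seed: int = 0):
    """Reproducible list of fixtures; target i uses sub-seed seed*100000+i."""
    profile = profile or CorpusProfile()
    return [sample_fixture(profile, seed=(seed * 100_000 + i) % (2 ** 31 - 1),
                           name=f"synth{seed:03d}_{i:04d}") for i in range(n)]


# ------------------------------------------------------------------ file I/O


def write_pdb(chain: ProteinChain, dmap: DomainMap, path):
    st = gemmi.Structure()
    st.name = chain.id
    model = gemmi.Model("1")
    ch = gemmi.Chain("A")
    three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
        "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
        "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
        "W": "TRP", "Y": "TYR",
    }
    for i in range(len(chain)):
        res = gemmi.Residue()
        res.name = three.get(chain.sequence[i], "ALA")
        res.seqid = gemmi.SeqId(int(chain.author_numbering[i]), " ")
        for atom_name, xyz, elem in (("N", chain.coords_N[i], "N"),
                                     ("CA", chain.coords_CA[i], "C"),
                                     ("C", chain.coords_C[i], "C")):
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = gemmi.Element(elem)
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            atom.b_iso = float(dmap.labels[i])
            res.add_atom(atom)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_fixture_set(n_targets: int, out_dir, profile: CorpusProfile = None,
                      seed: int = 0):
    """Write a reproducible corpus of PDB + truth TSV + quality JSON files.

    Returns the manifest path.  Manifest columns: name, pdb, truth_tsv,
    quality_json, n_res, ndom, ndr_frac, segments.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fixtures = sample_corpus(n_targets, profile=profile, seed=seed)
    rows = []
    for fx in fixtures:
        pdb = out_dir / f"{fx.name}.pdb"
        truth = out_dir / f"{fx.name}_truth.tsv"
        qjson = out_dir / f"{fx.name}_quality.json"
        write_pdb(fx.chain, fx.dmap, pdb)
        with open(truth, "w") as fh:
            fh.write("# residue\tauthor_num\tlabel\tndr_flag\n")
            for i in range(len(fx.chain)):
                fh.write(f"{i}\t{fx.chain.author_numbering[i]}\t"
                         f"{fx.dmap.labels[i]}\t{int(fx.dmap.labels[i] == 0)}\n")
        with open(qjson, "w") as fh:
            json.dump({"plddt": fx.quality.plddt.round(2).tolist(),
                       "pae": fx.quality.pae.round(2).tolist()}, fh)
        ndr_frac = float(np.mean(fx.dmap.labels == 0))
        rows.append((fx.name, pdb.name, truth.name, qjson.name, len(fx.chain),
                     fx.dmap.ndom, f"{ndr_frac:.3f}",
                     serialize_domain_segments(fx.dmap, fx.chain)))
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("# name\tpdb\ttruth_tsv\tquality_json\tn_res\tndom\tndr_frac\tsegments\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return manifest
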