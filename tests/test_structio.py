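"""Structure parsing, frame construction and annotation handling."""

import numpy as np
import pytest

from domseg.structio import (ChainNotFoundError, ChainTooShortError,
                             DegenerateFrameError, DomainMap, ProteinChain,
                             SegmentSpecError, build_frames,
                             domain_map_to_affinity, pairwise_ca_distances,
                             parse_domain_segments, parse_pdb_backbone,
                             serialize_domain_segments)
from domseg.synthgen import sample_corpus, write_pdb

from conftest import make_test_chain, random_rigid, transform_chain

PDB_THREE_RESIDUES = """\
ATOM      1  N   ALA A   1       0.000   1.460   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       1.520   0.000   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       3.800   1.460   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      6  C   GLY A   2       5.320   0.000   0.000  1.00  0.00           C
ATOM      7  N   SER A   3       7.600   1.460   0.000  1.00  0.00           N
ATOM      8  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
ATOM      9  C   SER A   3       9.120   0.000   0.000  1.00  0.00           C
END
"""


class TestParsePdb:
    def test_write_then_read_round_trip(self, tmp_path):
        fx = sample_corpus(1, seed=7)[0]
        path = tmp_path / "fx.pdb"
        write_pdb(fx.chain, fx.dmap, path)
        chain = parse_pdb_backbone(path, "A")
        assert len(chain) == len(fx.chain)
        assert chain.sequence == fx.chain.sequence
        np.testing.assert_allclose(chain.coords_CA, fx.chain.coords_CA, atol=1e-3)
        np.testing.assert_array_equal(chain.author_numbering,
                                      fx.chain.author_numbering)

    def test_three_residue_fixture(self, tmp_path):
        path = tmp_path / "tiny.pdb"
        path.write_text(PDB_THREE_RESIDUES)
        chain = parse_pdb_backbone(path, "A")
        assert len(chain) == 3
        assert chain.sequence == "AGS"
        np.testing.assert_allclose(chain.coords_CA[1], [3.8, 0, 0], atol=1e-3)

    def test_incomplete_residue_dropped(self, tmp_path):
        # residue 2 loses its C atom -> only 2 residues survive
        lines = [l for l in PDB_THREE_RESIDUES.splitlines()
                 if not (l.startswith("ATOM") and " C " in l and " GLY " in l)]
        path = tmp_path / "gap.pdb"
        path.write_text("\n".join(lines) + "\n")
        chain = parse_pdb_backbone(path, "A")
        assert len(chain) == 2
        assert chain.sequence == "AS"

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(ChainNotFoundError):
            parse_pdb_backbone(path, "A")

    def test_missing_chain_raises(self, tmp_path):
        path = tmp_path / "tiny.pdb"
        path.write_text(PDB_THREE_RESIDUES)
        with pytest.raises(ChainNotFoundError):
            parse_pdb_backbone(path, "B")

    def test_too_short_raises(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text("\n".join(PDB_THREE_RESIDUES.splitlines()[:3]) + "\nEND\n")
        with pytest.raises(ChainTooShortError):
            parse_pdb_backbone(path, "A")


class TestFrames:
    def test_canonical_placement_gives_identity(self):
        chain = ProteinChain("c", "AA",
                             coords_N=[[0, 1, 0], [3.8, 1, 0]],
                             coords_CA=[[0, 0, 0], [3.8, 0, 0]],
                             coords_C=[[1, 0, 0], [4.8, 0, 0]],
                             author_numbering=[1, 2])
        frames = build_frames(chain)
        np.testing.assert_allclose(frames.rotations[0], np.eye(3), atol=1e-12)
        np.testing.assert_allclose(frames.translations[0], [0, 0, 0])

    @pytest.mark.parametrize("seed", range(10))
    def test_equivariance_under_rigid_motion(self, seed):
        chain = make_test_chain(20, seed=seed)
        R0, t0 = random_rigid(seed + 100)
        moved = transform_chain(chain, R0, t0)
        f1 = build_frames(chain)
        f2 = build_frames(moved)
        np.testing.assert_allclose(f2.rotations, R0 @ f1.rotations, atol=1e-9)
        np.testing.assert_allclose(f2.translations, f1.translations @ R0.T + t0,
                                   atol=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_orthonormal_with_unit_determinant(self, seed):
        frames = build_frames(make_test_chain(30, seed=seed))
        R = frames.rotations
        np.testing.assert_allclose(np.einsum("nij,nik->njk", R, R),
                                   np.broadcast_to(np.eye(3), R.shape), atol=1e-6)
        np.testing.assert_allclose(np.linalg.det(R), 1.0, atol=1e-6)

    def test_translations_equal_ca(self):
        chain = make_test_chain(15, seed=3)
        assert np.array_equal(build_frames(chain).translations, chain.coords_CA)

    def test_collinear_backbone_raises(self):
        chain = ProteinChain("c", "AA",
                             coords_N=[[2, 0, 0], [5.8, 1, 0]],
                             coords_CA=[[0, 0, 0], [3.8, 0, 0]],
                             coords_C=[[1, 0, 0], [4.8, 0, 0]],
                             author_numbering=[1, 2])
        with pytest.raises(DegenerateFrameError):
            build_frames(chain)


class TestDistances:
    def test_three_four_five(self):
        chain = ProteinChain("c", "AA",
                             coords_N=[[0, 1, 0], [3, 5, 0]],
                             coords_CA=[[0, 0, 0], [3, 4, 0]],
                             coords_C=[[1, 0, 0], [4, 4, 0]],
                             author_numbering=[1, 2])
        d = pairwise_ca_distances(chain).values
        assert d[0, 1] == pytest.approx(5.0)
        assert d[1, 0] == pytest.approx(5.0)
        assert d[0, 0] == 0.0

    def test_symmetric_zero_diagonal_and_rigid_invariant(self):
        chain = make_test_chain(25, seed=0)
        d = pairwise_ca_distances(chain).values
        np.testing.assert_allclose(d, d.T, atol=1e-6)
        np.testing.assert_allclose(np.diag(d), 0.0)
        R0, t0 = random_rigid(0)
        d2 = pairwise_ca_distances(transform_chain(chain, R0, t0)).values
        np.testing.assert_allclose(d, d2, atol=1e-6)


class TestSegments:
    def _chain(self, n=170):
        return make_test_chain(n, seed=1)

    def test_discontinuous_two_domains(self):
        dmap = parse_domain_segments("1-50,120-170;51-119", self._chain(170))
        labels = dmap.labels
        assert (labels[0:50] == 1).all()
        assert (labels[119:170] == 1).all()
        assert (labels[50:119] == 2).all()
        assert (labels > 0).all()

    def test_single_domain(self):
        dmap = parse_domain_segments("1-170", self._chain(170))
        assert (dmap.labels == 1).all()

    def test_overlap_raises(self):
        with pytest.raises(SegmentSpecError, match="conflicting"):
            parse_domain_segments("1-50;40-60", self._chain(170))

    def test_out_of_bounds_raises(self):
        with pytest.raises(SegmentSpecError, match="out of bounds"):
            parse_domain_segments("1-200", self._chain(170))

    def test_mask_trailer(self):
        dmap = parse_domain_segments("1-50|mask:60-70", self._chain(170))
        assert dmap.mask[59:70].all()
        assert dmap.mask.sum() == 11

    @pytest.mark.parametrize("spec", ["1-50,120-170;51-119", "1-170",
                                      "10-40;50-90|mask:100-120"])
    def test_serialize_round_trip(self, spec):
        chain = self._chain(170)
        dmap = parse_domain_segments(spec, chain)
        again = parse_domain_segments(serialize_domain_segments(dmap, chain), chain)
        np.testing.assert_array_equal(dmap.labels, again.labels)
        np.testing.assert_array_equal(dmap.mask, again.mask)


def brute_force_affinity(dmap: DomainMap):
    n = len(dmap)
    A = np.zeros((n, n))
    excl = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            li, lj = dmap.labels[i], dmap.labels[j]
            if li == lj and li > 0:
                A[i, j] = 1.0
            if li == 0 or lj == 0 or dmap.mask[i] or dmap.mask[j]:
                excl[i, j] = True
    return A, excl


class TestAffinity:
    def test_block_structure(self):
        A, _ = domain_map_to_affinity(DomainMap([1, 1, 2, 2]))
        expected = np.array([[1, 1, 0, 0], [1, 1, 0, 0],
                             [0, 0, 1, 1], [0, 0, 1, 1]], dtype=float)
        np.testing.assert_array_equal(A, expected)

    def test_discontinuous_co_membership(self):
        A, _ = domain_map_to_affinity(DomainMap([1, 2, 1]))
        assert A[0, 2] == 1.0

    def test_exhaustive_against_brute_force(self):
        # all label vectors of length <= 12 would be huge; sample densely
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(2, 13))
            labels = rng.integers(0, 5, size=n)
            mask = rng.random(n) < 0.2
            dmap = DomainMap(labels, mask)
            A, excl = domain_map_to_affinity(dmap)
            A2, excl2 = brute_force_affinity(dmap)
            np.testing.assert_array_equal(A, A2)
            np.testing.assert_array_equal(excl, excl2)

    def test_relabel_invariance(self):
        base = DomainMap([1, 1, 2, 2, 0, 2])
        relabeled = DomainMap([7, 7, 3, 3, 0, 3])
        np.testing.assert_array_equal(domain_map_to_affinity(base)[0],
                                      domain_map_to_affinity(relabeled)[0])
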