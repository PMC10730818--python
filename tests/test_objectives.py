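"""Losses, stage weighting, cropping, distillation and the training loop."""

import numpy as np
import pytest

from domseg.baselines import QualityFields
from domseg.netcore import ModelConfig, SegmentationNetwork
from domseg.nn.autograd import Tensor
from domseg.objectives import (DivergenceError, NoSupervisedPairsError,
                               TrainConfig, TrainTarget, achieved_iou_per_predicted,
                               affinity_loss, composite_loss, crop_window,
                               distill_labels, ndr_loss, piou_loss, target_loss,
                               train)
from domseg.structio import DomainMap, domain_map_to_affinity
from domseg.synthgen import DomainSpecEntry, FixtureSpec, make_chain

from conftest import make_test_chain


def brute_force_affinity_loss(probs, labels, mask):
    """Double-loop pairwise BCE oracle."""
    n = len(labels)
    total, count = 0.0, 0
    eps = 1e-9
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] == 0 or labels[j] == 0 or mask[i] or mask[j]:
                continue
            p = float(np.dot(probs[i], probs[j]))
            a = 1.0 if labels[i] == labels[j] else 0.0
            total += -(a * np.log(p + eps) + (1 - a) * np.log(1 - p + eps))
            count += 1
    return total / count


def rows_one_hot(labels, k):
    probs = np.zeros((len(labels), k))
    for i, l in enumerate(labels):
        probs[i, l % k] = 1.0
    return probs


class TestAffinityLoss:
    def test_perfect_prediction_near_zero(self):
        dmap = DomainMap([1, 1, 2, 2])
        A, excl = domain_map_to_affinity(dmap)
        probs = Tensor(rows_one_hot(dmap.labels, 4))
        assert float(affinity_loss(probs, A, excl).data) <= 1e-6

    def test_uniform_probs_closed_form(self):
        # same-domain pair at P = 1/20: -ln(0.05); different: -ln(0.95)
        k = 20
        dmap = DomainMap([1, 1, 2])
        A, excl = domain_map_to_affinity(dmap)
        probs = Tensor(np.full((3, k), 1.0 / k))
        got = float(affinity_loss(probs, A, excl).data)
        expected = (-np.log(1 / k) + 2 * -np.log(1 - 1 / k)) / 3
        assert got == pytest.approx(expected, abs=1e-6)
        assert -np.log(1 / k) == pytest.approx(2.9957, abs=1e-4)
        assert -np.log(1 - 1 / k) == pytest.approx(0.0513, abs=1e-4)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        labels = rng.integers(0, 4, size=n)
        mask = rng.random(n) < 0.15
        if not _has_pairs(labels, mask):
            return
        probs = rng.dirichlet(np.ones(6), size=n)
        dmap = DomainMap(labels, mask)
        A, excl = domain_map_to_affinity(dmap)
        got = float(affinity_loss(Tensor(probs), A, excl).data)
        assert got == pytest.approx(brute_force_affinity_loss(probs, labels, mask),
                                    abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_label_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(1, 5, size=20)
        probs = Tensor(rng.dirichlet(np.ones(6), size=20))
        perm = rng.permutation(np.arange(1, 6))
        relabeled = np.array([perm[l - 1] for l in labels])
        A1, e1 = domain_map_to_affinity(DomainMap(labels))
        A2, e2 = domain_map_to_affinity(DomainMap(relabeled))
        assert float(affinity_loss(probs, A1, e1).data) == float(
            affinity_loss(probs, A2, e2).data)

    def test_masked_residue_has_zero_gradient(self):
        rng = np.random.default_rng(0)
        labels = np.array([1, 1, 2, 2, 2])
        mask = np.array([False, False, False, False, True])
        probs = rng.dirichlet(np.ones(4), size=5)
        dmap = DomainMap(labels, mask)
        A, excl = domain_map_to_affinity(dmap)
        base = float(affinity_loss(Tensor(probs), A, excl).data)
        probs2 = probs.copy()
        probs2[4] = rng.dirichlet(np.ones(4))
        assert float(affinity_loss(Tensor(probs2), A, excl).data) == base
        # and the analytic gradient at the masked row is exactly zero
        t = Tensor(probs, requires_grad=True)
        affinity_loss(t, A, excl).backward()
        np.testing.assert_array_equal(t.grad[4], 0.0)

    def test_all_pairs_excluded_raises(self):
        dmap = DomainMap([0, 0, 1])
        A, excl = domain_map_to_affinity(dmap)
        with pytest.raises(NoSupervisedPairsError):
            affinity_loss(Tensor(np.full((3, 4), 0.25)), A, excl)


def _has_pairs(labels, mask):
    ok = (labels > 0) & ~mask
    return ok.sum() >= 2


class TestNdrLoss:
    def test_confident_correct_is_zero(self):
        labels = np.array([0, 1, 1])
        logits = np.array([[30.0, -30.0], [-30.0, 30.0], [-30.0, 30.0]])
        assert float(ndr_loss(Tensor(logits), labels).data) == pytest.approx(0.0,
                                                                             abs=1e-10)

    def test_uniform_logits_give_ln2(self):
        labels = np.array([0, 1, 0, 1])
        assert float(ndr_loss(Tensor(np.zeros((4, 2))), labels).data) == \
            pytest.approx(np.log(2), abs=1e-12)

    def test_all_masked_raises(self):
        with pytest.raises(NoSupervisedPairsError):
            ndr_loss(Tensor(np.zeros((3, 2))), np.array([0, 1, 1]),
                     np.ones(3, bool))


class TestPiouLoss:
    def test_exact_match_zero(self):
        pred = {1: Tensor(np.array(0.7))}
        assert float(piou_loss(pred, {1: 0.7}).data) == pytest.approx(0.0)

    def test_half_vs_one_quarter(self):
        pred = {1: Tensor(np.array(0.5))}
        assert float(piou_loss(pred, {1: 1.0}).data) == pytest.approx(0.25)

    def test_empty_domains_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert float(piou_loss({}, {}).data) == 0.0


class TestCompositeLoss:
    def _components(self, v=1.0):
        return {k: Tensor(np.array(v)) for k in
                ("affinity_encoder", "affinity_decoder", "ndr_ce", "piou_reg")}

    def test_initial_unit_weights(self):
        assert float(composite_loss(self._components(), "initial").data) == 4.0

    def test_finetune_doubles_affinity(self):
        assert float(composite_loss(self._components(), "finetune").data) == 6.0

    def test_afdb_ndr_is_ndr_only(self):
        comps = self._components()
        comps["ndr_ce"] = Tensor(np.array(0.37))
        assert float(composite_loss(comps, "afdb_ndr").data) == pytest.approx(0.37)

    def test_afdb_scale(self):
        from domseg.objectives import model_scale_afdb
        assert float(model_scale_afdb(Tensor(np.array(5.0))).data) == \
            pytest.approx(1.0)

    def test_unknown_stage_raises(self):
        with pytest.raises(ValueError):
            composite_loss(self._components(), "warmup")


class TestCropWindow:
    def _target(self, n, seed=0):
        chain = make_test_chain(n, seed=seed)
        rng = np.random.default_rng(seed)
        labels = np.repeat(rng.integers(1, 4, size=max(1, n // 50 + 1)), 50)[:n]
        pae = rng.uniform(0, 30, size=(n, n))
        return TrainTarget(chain=chain, dmap=DomainMap(labels),
                           quality=QualityFields(plddt=rng.uniform(0, 100, n),
                                                 pae=pae))

    def test_short_chain_uncropped(self):
        t = self._target(400)
        out = crop_window(t, 512, np.random.default_rng(0))
        assert len(out.chain) == 400

    def test_long_chain_offset_reproducible_and_in_range(self):
        t = self._target(600)
        starts = set()
        for _ in range(5):
            out = crop_window(t, 512, np.random.default_rng(0))
            start = int(np.flatnonzero(
                t.chain.author_numbering == out.chain.author_numbering[0])[0])
            starts.add(start)
            assert 0 <= start <= 88
        assert len(starts) == 1  # same rng state, same window

    def test_affinity_of_crop_is_submatrix(self):
        t = self._target(600)
        rng = np.random.default_rng(1)
        out = crop_window(t, 512, rng)
        start = int(np.flatnonzero(
            t.chain.author_numbering == out.chain.author_numbering[0])[0])
        A_full, _ = domain_map_to_affinity(t.dmap)
        A_crop, _ = domain_map_to_affinity(out.dmap)
        np.testing.assert_array_equal(
            A_crop, A_full[start:start + 512, start:start + 512])
        # quality fields slice consistently too
        np.testing.assert_array_equal(out.quality.pae,
                                      t.quality.pae[start:start + 512,
                                                    start:start + 512])


class TestDistillLabels:
    def _result(self, labels):
        from domseg.netcore import SegmentationResult
        dmap = DomainMap(labels)
        return SegmentationResult(domain_map=dmap,
                                  ndr_mask=dmap.labels == 0,
                                  piou_per_domain={}, ndom=dmap.ndom)

    def test_stray_segment_removed(self):
        labels = np.r_[np.ones(50, int), np.full(5, 2), np.ones(50, int)]
        out = distill_labels(self._result(labels))
        assert (out.labels == 1).all()

    def test_clean_prediction_unchanged(self):
        labels = np.r_[np.ones(60, int), np.full(60, 2)]
        out = distill_labels(self._result(labels))
        np.testing.assert_array_equal(out.labels, labels)

    def test_undersized_domain_absent(self):
        labels = np.r_[np.ones(50, int), np.full(20, 2), np.full(50, 3)]
        out = distill_labels(self._result(labels))
        assert 2 not in out.labels


class TestAchievedIou:
    def test_perfect_and_half(self):
        truth = DomainMap(np.r_[np.ones(50, int), np.full(50, 2)])
        pred = DomainMap(np.r_[np.ones(50, int), np.full(50, 2)])
        assert achieved_iou_per_predicted(pred, truth) == {1: 1.0, 2: 1.0}
        pred2 = DomainMap(np.ones(100, int))
        assert achieved_iou_per_predicted(pred2, truth) == {1: 0.5}


@pytest.fixture(scope="module")
def overfit_target():
    spec = FixtureSpec(domains=[DomainSpecEntry(40, np.zeros(3)),
                                DomainSpecEntry(40, np.array([35.0, 0, 0]))],
                       linker_lengths=[10], seed=0)
    chain, dmap, _ = make_chain(spec)
    return TrainTarget(chain=chain, dmap=dmap)


class TestTrainLoop:
    def test_overfit_single_target_reduces_affinity_loss(self, overfit_target):
        model = SegmentationNetwork(ModelConfig.tiny(seed=0))
        cfg = TrainConfig(lr=3e-3, crop_len=192, accum_steps=2, seed=0)
        report0, _ = target_loss(model, overfit_target, "initial",
                                 with_piou=False)
        hist = train(model, [overfit_target], cfg, stage="initial",
                     epochs=200, max_updates=200, with_piou=False)
        initial_aff = report0.affinity_decoder
        final_aff = hist[-1].affinity_decoder
        assert final_aff < 0.1 * initial_aff

    def test_afdb_ndr_stage_freezes_everything_but_ndr_head(self, overfit_target):
        model = SegmentationNetwork(ModelConfig.tiny(seed=1))
        before = model.state_dict()
        cfg = TrainConfig(lr=1e-2, crop_len=192, accum_steps=1, seed=0)
        train(model, [overfit_target], cfg, stage="afdb_ndr", epochs=1,
              max_updates=4)
        after = model.state_dict()
        changed = {k for k in before if not np.array_equal(before[k], after[k])}
        assert changed  # the NDR head did move
        assert all(k.startswith("decoder.ndr_head") for k in changed)

    def test_same_seed_identical_history(self, overfit_target):
        histories = []
        for _ in range(2):
            model = SegmentationNetwork(ModelConfig.tiny(seed=2))
            cfg = TrainConfig(lr=1e-3, crop_len=96, accum_steps=2, seed=7)
            hist = train(model, [overfit_target], cfg, stage="initial",
                         epochs=6, max_updates=6, with_piou=False)
            histories.append([r.total for r in hist])
        assert histories[0] == histories[1]

    def test_stage_weighting_applied_in_reports(self, overfit_target):
        model = SegmentationNetwork(ModelConfig.tiny(seed=3))
        r_init, t_init = target_loss(model, overfit_target, "initial",
                                     with_piou=False)
        r_ft, t_ft = target_loss(model, overfit_target, "finetune",
                                 with_piou=False)
        assert float(t_ft.data) == pytest.approx(
            2 * r_ft.affinity_encoder + 2 * r_ft.affinity_decoder + r_ft.ndr_ce,
            abs=1e-9)
        assert float(t_init.data) == pytest.approx(
            r_init.affinity_encoder + r_init.affinity_decoder + r_init.ndr_ce,
            abs=1e-9)
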