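"""Evidential cascade: opinions, entropy, losses, routing, classifier heads."""

import numpy as np
import pytest

import mccm
from mccm.cascade import (
    ClassifierConfig,
    EasyClassifier,
    HardClassifier,
    dirichlet_pdf,
    masked_cross_entropy,
    masked_dirichlet_loss,
)
from mccm.nn import Tensor


class TestOpinions:
    def test_negative_logits_clip_to_uniform(self):
        op = mccm.opinion_from_logits([-1.0, -2.0, -3.0])
        assert np.allclose(op.alpha, 1.0)
        assert np.allclose(op.expectation, 1 / 3)
        assert op.strength == pytest.approx(3.0)

    def test_confident_opinion_worked_example(self):
        """alpha [14.10, 1.33, 1.21] -> S 16.64, p ~ [0.8474, 0.0799, 0.0727]."""
        op = mccm.opinion_from_logits([13.10, 0.33, 0.21])
        assert op.strength == pytest.approx(16.64)
        assert np.allclose(op.expectation, [0.8474, 0.0799, 0.0727], atol=1e-4)
        assert op.entropy == pytest.approx(0.7688, abs=1e-4)

    def test_ambiguous_opinion_worked_example(self):
        op = mccm.opinion_from_logits([1.24, 0.82, 0.78])
        assert op.strength == pytest.approx(5.84)
        assert np.allclose(op.expectation, [0.3836, 0.3116, 0.3048], atol=1e-4)
        assert op.entropy == pytest.approx(1.5769, abs=1e-4)

    def test_confident_entropy_below_ambiguous(self):
        confident = mccm.opinion_from_logits([13.10, 0.33, 0.21])
        ambiguous = mccm.opinion_from_logits([1.24, 0.82, 0.78])
        assert confident.entropy < ambiguous.entropy

    def test_expectation_strictly_positive_simplex(self):
        rng = np.random.default_rng(0)
        op = mccm.opinion_from_logits(rng.normal(scale=5, size=(100, 8)))
        assert np.all(op.expectation > 0)
        assert np.allclose(op.expectation.sum(axis=-1), 1.0, atol=1e-10)
        assert np.all(op.alpha >= 1.0)

    def test_nonfinite_logits_rejected(self):
        with pytest.raises(ValueError):
            mccm.opinion_from_logits([np.inf, 0.0])


class TestInformationEntropy:
    def test_extremes(self):
        assert mccm.information_entropy([1.0, 0.0, 0.0]) == pytest.approx(0.0)
        assert mccm.information_entropy(np.full(3, 1 / 3)) == pytest.approx(np.log2(3))
        assert mccm.information_entropy(np.full(8, 1 / 8)) == pytest.approx(3.0)

    def test_sharpening_never_increases_entropy(self):
        """Mixing toward uniform (the reverse of sharpening) raises H."""
        rng = np.random.default_rng(1)
        p = rng.dirichlet(np.ones(8))
        u = np.full(8, 1 / 8)
        hs = [mccm.information_entropy((1 - t) * p + t * u) for t in np.linspace(0, 1, 9)]
        assert np.all(np.diff(hs) >= -1e-12)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            mccm.information_entropy([-0.1, 1.1])


class TestDirichletLoss:
    def test_hand_value_uniform_opinion(self):
        """y=[1,0,0], alpha=[1,1,1]: (2/3)^2 + 2(1/3)^2 + 3*(2/9)/4 = 5/6."""
        op = mccm.opinion_from_logits([-1.0, -1.0, -1.0])
        assert mccm.dirichlet_loss([1.0, 0.0, 0.0], op) == pytest.approx(5 / 6)

    def test_vanishes_for_confident_correct_opinion(self):
        op = mccm.opinion_from_logits([1e6, 0.0, 0.0])
        assert mccm.dirichlet_loss([1.0, 0.0, 0.0], op) == pytest.approx(0.0, abs=1e-5)

    def test_strictly_decreases_in_true_class_evidence(self):
        y = np.array([1.0, 0.0, 0.0])
        losses = [mccm.dirichlet_loss(y, mccm.opinion_from_logits([e, 0.5, 0.5]))
                  for e in [0.0, 1.0, 2.0, 4.0, 8.0, 16.0]]
        assert np.all(np.diff(losses) < 0)

    @pytest.mark.parametrize("alpha,cls", [([1.0, 1.0, 1.0], 0),
                                           ([5.0, 2.0, 1.5], 1),
                                           ([0.5, 9.0, 3.0, 1.0], 2)])
    def test_matches_monte_carlo_expected_brier(self, alpha, cls):
        """The loss equals E_{p~Dir(alpha)} sum (y-p)^2 within 3 SE."""
        alpha = np.maximum(np.asarray(alpha), 1.0)
        rng = np.random.default_rng(7)
        samples = rng.dirichlet(alpha, size=100_000)
        y = np.zeros(len(alpha))
        y[cls] = 1.0
        draws = ((y - samples) ** 2).sum(axis=1)
        mc, se = draws.mean(), draws.std(ddof=1) / np.sqrt(len(draws))
        op = mccm.DirichletOpinion(alpha=alpha, strength=alpha.sum(),
                                   expectation=alpha / alpha.sum(),
                                   entropy=mccm.information_entropy(alpha / alpha.sum()))
        assert mccm.dirichlet_loss(y, op) == pytest.approx(mc, abs=3 * se)

    def test_tensor_version_agrees_with_numpy(self):
        rng = np.random.default_rng(3)
        logits = rng.normal(scale=3, size=(4, 5, 8))
        y = np.zeros((4, 5, 8))
        y[..., 2] = 1.0
        w = np.ones((4, 5))
        t = masked_dirichlet_loss(Tensor(logits), y, w)
        op = mccm.opinion_from_logits(logits.reshape(-1, 8))
        assert float(t.data) == pytest.approx(mccm.dirichlet_loss(y.reshape(-1, 8), op))


class TestDirichletPdf:
    @pytest.mark.parametrize("alpha", [[1.0, 1.0, 1.0], [2.0, 3.0, 1.5],
                                       [14.1, 1.33, 1.21]])
    def test_integrates_to_one_on_simplex(self, alpha):
        """Numeric quadrature over the Z=3 simplex, tolerance 1e-3."""
        from scipy.integrate import dblquad

        total, _ = dblquad(
            lambda p2, p1: dirichlet_pdf([p1, p2, 1 - p1 - p2], alpha),
            0.0, 1.0, 0.0, lambda p1: 1.0 - p1)
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_cross_checks_scipy(self):
        from scipy.stats import dirichlet as sp_dirichlet

        alpha = [2.2, 1.4, 3.0]
        p = [0.2, 0.3, 0.5]
        assert dirichlet_pdf(p, alpha) == pytest.approx(sp_dirichlet.pdf(p[:2], alpha))


class TestCrossEntropy:
    def test_uniform_logits_eight_classes(self):
        y = np.zeros(8)
        y[3] = 1.0
        assert mccm.cross_entropy(y, np.zeros(8)) == pytest.approx(np.log(8))

    def test_hand_two_class_value(self):
        assert mccm.cross_entropy([1.0, 0.0], [1.0, 0.0]) == pytest.approx(0.31326, abs=1e-5)

    def test_large_margin_drives_loss_to_zero(self):
        assert mccm.cross_entropy([1.0, 0.0], [50.0, 0.0]) == pytest.approx(0.0, abs=1e-12)

    def test_tensor_version_agrees_with_numpy(self):
        rng = np.random.default_rng(5)
        logits = rng.normal(size=(3, 4, 8))
        y = np.zeros((3, 4, 8))
        y[..., 1] = 1.0
        w = np.ones((3, 4))
        t = masked_cross_entropy(Tensor(logits), y, w)
        assert float(t.data) == pytest.approx(mccm.cross_entropy(y, logits))


def _opinions_with_entropy(entropies):
    """Build opinions whose entropy array is exactly the given values and
    whose argmax is class 0 (entropy is injected for routing tests)."""
    n = len(entropies)
    p = np.tile([0.6, 0.3, 0.1], (n, 1))
    return mccm.DirichletOpinion(alpha=p * 10, strength=np.full(n, 10.0),
                                 expectation=p, entropy=np.asarray(entropies, float))


class TestRouting:
    def test_hand_example_median_threshold(self):
        """Entropies [0.2,0.4,0.9,1.4], correctness [T,T,F,T], per=50 ->
        threshold 0.65; easy residues are the first two."""
        ops = _opinions_with_entropy([0.2, 0.4, 0.9, 1.4])
        labels = np.array([0, 0, 1, 0])  # argmax is 0 everywhere -> third wrong
        cfg = mccm.RoutingConfig(mode="evidential", per=50.0)
        dec = mccm.route(ops, labels, cfg, phase="train")
        assert dec.threshold_value == pytest.approx(0.65)
        assert dec.assignment.tolist() == [True, True, False, False]

    def test_percentile_zero_routes_everything_hard(self):
        ops = _opinions_with_entropy([0.2, 0.4, 0.9])
        cfg = mccm.RoutingConfig(mode="evidential", per=0.0)
        dec = mccm.route(ops, np.zeros(3, dtype=int), cfg, phase="train")
        assert not dec.assignment.any()

    def test_label_mode_all_correct_all_easy(self):
        ops = _opinions_with_entropy([0.2, 0.4, 0.9])
        cfg = mccm.RoutingConfig(mode="label")
        dec = mccm.route(ops, np.zeros(3, dtype=int), cfg, phase="train")
        assert dec.assignment.all()

    def test_partition_covers_all_residues(self):
        rng = np.random.default_rng(11)
        ops = mccm.opinion_from_logits(rng.normal(scale=3, size=(200, 8)))
        labels = rng.integers(0, 8, 200)
        for mode in ("label", "evidential", "confidence"):
            dec = mccm.route(ops, labels, mccm.RoutingConfig(mode=mode), phase="train")
            assert dec.assignment.shape == (200,)
            assert np.array_equal(dec.easy | dec.hard, np.ones(200, dtype=bool))
            assert not (dec.easy & dec.hard).any()

    def test_evidential_test_phase_is_label_free(self):
        ops = _opinions_with_entropy([0.2, 0.9])
        cfg = mccm.RoutingConfig(mode="evidential")
        dec = mccm.route(ops, None, cfg, phase="test", frozen_threshold=0.5)
        assert dec.assignment.tolist() == [True, False]

    def test_evidential_test_phase_requires_threshold(self):
        ops = _opinions_with_entropy([0.2])
        with pytest.raises(ValueError):
            mccm.route(ops, None, mccm.RoutingConfig(mode="evidential"), phase="test")

    def test_missing_labels_rejected_when_required(self):
        ops = _opinions_with_entropy([0.2])
        with pytest.raises(ValueError):
            mccm.route(ops, None, mccm.RoutingConfig(mode="label"), phase="test")
        with pytest.raises(ValueError):
            mccm.route(ops, None, mccm.RoutingConfig(mode="evidential"), phase="train")

    def test_confidence_mode_exits_when_confident(self):
        ops = _opinions_with_entropy([0.5, 0.5])
        cfg = mccm.RoutingConfig(mode="confidence", confidence_threshold=0.9)
        dec = mccm.route(ops, np.array([0, 0]), cfg, phase="train",
                         confidence=np.array([0.95, 0.5]))
        assert dec.assignment.tolist() == [True, False]
        # test phase ignores labels entirely
        dec = mccm.route(ops, None, cfg, phase="test", confidence=np.array([0.95, 0.5]))
        assert dec.assignment.tolist() == [True, False]


class TestLossAssembly:
    def test_total_is_component_sum(self):
        lb = mccm.total_loss(1.0, 0.5, 2.0, 0.25, beta=1.0)
        assert lb.total == pytest.approx(3.75)

    def test_beta_zero_reduces_to_cross_entropy_sum(self):
        lb = mccm.total_loss(1.0, 0.5, 2.0, 0.25, beta=0.0)
        assert lb.total == pytest.approx(3.0)

    def test_no_hard_residues(self):
        lb = mccm.total_loss(1.2, 0.4, 0.0, 0.0, beta=1.0)
        assert lb.total == pytest.approx(lb.easy_only)

    def test_hard_routed_contribution_never_below_easy_only(self):
        """A hard-routed residue accumulates both heads' losses, so its
        total contribution is at least its easy-only contribution."""
        rng = np.random.default_rng(13)
        easy_logits = rng.normal(size=(1, 6, 8))
        hard_logits = rng.normal(size=(1, 6, 8))
        y = np.zeros((1, 6, 8))
        y[0, np.arange(6), rng.integers(0, 8, 6)] = 1.0
        w = np.ones((1, 6))
        for t in range(6):
            sel = np.zeros((1, 6))
            sel[0, t] = 1.0
            easy_part = float(masked_cross_entropy(Tensor(easy_logits), y, sel).data) \
                + float(masked_dirichlet_loss(Tensor(easy_logits), y, sel).data)
            hard_part = float(masked_cross_entropy(Tensor(hard_logits), y, sel).data) \
                + float(masked_dirichlet_loss(Tensor(hard_logits), y, sel).data)
            assert easy_part + hard_part >= easy_part


class TestClassifierHeads:
    def test_easy_head_is_single_affine_map(self):
        rng = np.random.default_rng(0)
        head = EasyClassifier(rng, 12, 8)
        head.linear.W.data[:] = 0.0
        head.linear.b.data[:] = 0.0
        out = head(Tensor(np.ones((1, 4, 12))))
        assert np.allclose(out.data, 0.0)
        assert out.data.shape == (1, 4, 8)

    def test_hard_head_layer_widths(self):
        rng = np.random.default_rng(0)
        head = HardClassifier(rng, 30, ClassifierConfig(n_classes=8, mlp_hidden=(512, 1024)))
        dims = [l.W.data.shape for l in head.mlp.layers] + [head.mlp.out.W.data.shape]
        assert dims == [(30, 512), (512, 1024), (1024, 8)]

    def test_hard_head_deterministic_in_eval_mode(self):
        rng = np.random.default_rng(1)
        head = HardClassifier(rng, 10, ClassifierConfig(n_classes=3, mlp_hidden=(8, 8)))
        head.eval()
        x = Tensor(np.random.default_rng(2).normal(size=(1, 5, 10)))
        assert np.array_equal(head(x).data, head(x).data)
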