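"""Manifold estimation, participation ratio, SNR terms and error prediction."""

import numpy as np
import pytest
from scipy import integrate

from simplerpm.geometry import (
    DegenerateManifoldError,
    ManifoldStats,
    closed_form_snr,
    estimate_manifold,
    gaussian_tail,
    layerwise_report,
    normalized_overlap,
    pair_snr,
    subspace_alignment,
    summarize_layerwise,
)
from simplerpm.simulate import (
    GaussianManifold,
    planted_pair,
    sample_trial_triples,
    spectrum_with_participation_ratio,
)
from simplerpm.trials import evaluate_arrays


def _isotropic_stats(n, radius=1.0, centroid=None):
    return ManifoldStats(
        centroid=np.zeros(n) if centroid is None else centroid,
        axes=np.eye(n),
        radii=np.full(n, radius),
    )


class TestManifoldStats:
    def test_flat_spectrum_participation_ratio_equals_n(self):
        assert _isotropic_stats(17).participation_ratio == pytest.approx(17.0)

    def test_participation_ratio_closed_form_4_1(self):
        stats = ManifoldStats(
            centroid=np.zeros(3), axes=np.eye(3), radii=np.sqrt(np.array([4.0, 1.0, 0.0]))
        )
        assert stats.participation_ratio == pytest.approx(25 / 17)

    def test_estimate_recovers_known_covariance(self, rng):
        n, m = 50, 2000
        r2 = spectrum_with_participation_ratio(n, 12.0, total=3.0)
        man = GaussianManifold(centroid=rng.standard_normal(n), axes=np.eye(n), radii=np.sqrt(r2))
        stats = estimate_manifold(man.sample(m, rng))
        assert np.allclose(stats.centroid, man.centroid, atol=0.15)
        # leading radii within 5% of ground truth
        top = np.sqrt(r2[:10])
        assert np.all(np.abs(stats.radii[:10] - top) / top < 0.05)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            estimate_manifold(np.ones((1, 4)))
        with pytest.raises(DegenerateManifoldError):
            estimate_manifold(np.ones((5, 4)))


class TestGaussianTail:
    def test_half_at_zero_and_symmetry(self):
        assert gaussian_tail(0.0) == pytest.approx(0.5)
        for x in (0.3, 1.7, 2.5):
            assert gaussian_tail(-x) == pytest.approx(1 - gaussian_tail(x))

    def test_matches_quadrature_oracle_at_one(self):
        oracle, _ = integrate.quad(lambda t: np.exp(-t * t / 2) / np.sqrt(2 * np.pi), 1, np.inf)
        assert gaussian_tail(1.0) == pytest.approx(oracle, abs=1e-10)
        assert gaussian_tail(1.0) == pytest.approx(0.15866, abs=5e-6)

    def test_strictly_decreasing(self):
        xs = np.linspace(-4, 4, 41)
        assert np.all(np.diff(gaussian_tail(xs)) < 0)


class TestPairSnr:
    def test_identical_manifolds_are_chance(self):
        a = _isotropic_stats(20)
        pg = pair_snr(a, a)
        assert pg.signal == 0.0 and pg.bias == 0.0
        assert pg.snr == pytest.approx(0.0, abs=1e-6)
        assert pg.predicted_error == pytest.approx(0.5, abs=1e-6)

    def test_far_separated_manifolds_error_to_zero(self):
        a = _isotropic_stats(20)
        b = _isotropic_stats(20, centroid=np.full(20, 50.0))
        pg = pair_snr(a, b)
        assert pg.predicted_error < 1e-6
        assert pg.snr > 4

    def test_asymmetry_bias_flips(self):
        a = _isotropic_stats(10, radius=1.0)
        b = ManifoldStats(np.ones(10), np.eye(10), np.full(10, 2.0))
        ab, ba = pair_snr(a, b), pair_snr(b, a)
        assert ab.bias == pytest.approx(3.0)      # Rb^2/Ra^2 - 1 = 4 - 1
        assert ba.bias == pytest.approx(-0.75)    # 1/4 - 1
        assert ab.snr != ba.snr

    def test_zero_reference_radius_errors(self):
        a = ManifoldStats(np.zeros(4), np.eye(4), np.zeros(4))
        with pytest.raises(DegenerateManifoldError):
            pair_snr(a, _isotropic_stats(4))

    def test_exact_and_dominant_agree_at_high_dimensionality(self, rng):
        a, b = planted_pair(80, signal=1.0, dim=60.0, overlap="none", rng=rng)
        exact = pair_snr(a.stats(), b.stats(), method="exact")
        dom = pair_snr(a.stats(), b.stats(), method="dominant")
        assert exact.snr == pytest.approx(dom.snr, rel=0.05)
        assert exact.snr_dominant == dom.snr

    def test_prediction_matches_simulation_on_one_hard_geometry(self, rng):
        """Low-dimensional manifolds: exact predictor still tracks simulation."""
        a, b = planted_pair(60, signal=1.0, dim=5.0, overlap="high", rng=rng)
        s, c, i = sample_trial_triples(a, b, 5000, rng)
        emp, _ = evaluate_arrays(s, c, i)
        pg = pair_snr(a.stats(), b.stats())
        assert abs(pg.predicted_error - emp) <= 3 * np.sqrt(emp * (1 - emp) / 5000)

    def test_rotation_invariance_of_all_terms(self, rng):
        X = rng.standard_normal((200, 12)) * np.linspace(2, 0.1, 12)
        Y = rng.standard_normal((200, 12)) + 1.0
        Q, _ = np.linalg.qr(rng.standard_normal((12, 12)))
        pg1 = pair_snr(estimate_manifold(X), estimate_manifold(Y))
        pg2 = pair_snr(estimate_manifold(X @ Q), estimate_manifold(Y @ Q))
        for attr in ("signal", "bias", "inv_dimensionality", "overlap_a", "overlap_b",
                     "cross_overlap", "snr_dominant", "predicted_error"):
            assert getattr(pg1, attr) == pytest.approx(getattr(pg2, attr), rel=1e-6, abs=1e-9)


class TestNormalizedOverlap:
    def test_orthogonal_signal_gives_zero(self):
        a = ManifoldStats(np.zeros(3), np.eye(3)[:1], np.array([1.0]))
        b = ManifoldStats(np.array([0.0, 0.0, 2.0]), np.eye(3)[:1], np.array([1.0]))
        pg = pair_snr(a, b, method="dominant")
        assert normalized_overlap(pg) == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance(self):
        a = ManifoldStats(np.zeros(3), np.eye(3)[:2], np.array([1.0, 0.5]))
        b = ManifoldStats(np.array([1.0, 1.0, 0.0]), np.eye(3)[1:3], np.array([1.0, 0.4]))
        a2 = ManifoldStats(a.centroid * 2, a.axes, a.radii * 2)
        b2 = ManifoldStats(b.centroid * 2, b.axes, b.radii * 2)
        assert normalized_overlap(pair_snr(a, b)) == pytest.approx(
            normalized_overlap(pair_snr(a2, b2))
        )

    def test_aligned_one_dimensional_manifolds_maximal_over_rotations(self):
        """Rotating a 1-D manifold away from the signal direction lowers overlap."""
        gap = np.array([2.0, 0.0, 0.0])
        b = ManifoldStats(gap, np.eye(3)[:1], np.array([0.8]))
        values = []
        for theta in np.linspace(0, np.pi / 2, 7):
            axis = np.array([[np.cos(theta), np.sin(theta), 0.0]])
            a = ManifoldStats(np.zeros(3), axis, np.array([1.0]))
            values.append(normalized_overlap(pair_snr(a, b, method="dominant")))
        assert np.argmax(values) == 0
        assert np.all(np.diff(values) < 0)

    def test_zero_signal_errors(self):
        a = _isotropic_stats(4)
        with pytest.raises(ValueError):
            normalized_overlap(pair_snr(a, a))


class TestSubspaceAlignment:
    def test_containment_and_orthogonality(self, rng):
        train = rng.standard_normal((100, 10))
        train[:, 5:] = 0.0
        inside = rng.standard_normal((30, 10))
        inside[:, 5:] = 0.0
        outside = np.zeros((30, 10))
        outside[:, 5:] = rng.standard_normal((30, 5))
        assert subspace_alignment(inside, train, k=5) == pytest.approx(1.0)
        # train mean is ~0 but not exactly; allow its tiny leakage
        assert subspace_alignment(outside, train - train.mean(0), k=5) == pytest.approx(0.0, abs=1e-12)

    def test_planted_variance_ratio(self, rng):
        n, k = 60, 35
        basis = np.linalg.qr(rng.standard_normal((n, n)))[0]
        shared, ortho = basis[:, :k], basis[:, k:]
        rho = 0.7
        train = rng.standard_normal((4000, k)) @ shared.T
        held = (  # total energy rho inside the shared subspace, 1-rho outside
            np.sqrt(rho / k) * rng.standard_normal((4000, k)) @ shared.T
            + np.sqrt((1 - rho) / (n - k)) * rng.standard_normal((4000, n - k)) @ ortho.T
        )
        assert subspace_alignment(held, train, k=k) == pytest.approx(rho, abs=0.03)

    def test_k_exceeding_rank_errors(self, rng):
        train = rng.standard_normal((10, 40))  # rank <= 9 after centering
        with pytest.raises(ValueError, match="rank"):
            subspace_alignment(rng.standard_normal((5, 40)), train, k=20)


class _FakeRow:
    """Representation-space stand-in for a rendered row."""

    def __init__(self, rule, vec):
        self.rule = rule
        self.vec = vec


class TestLayerwise:
    def test_monotone_signal_gives_monotone_error(self, rng):
        from simplerpm.dataset import sample_splits
        from simplerpm.rules import rule_by_id

        (split,) = sample_splits(1, rng)
        layers = {}
        rows_by_rule = {}
        manifolds = {}
        for signal, layer in zip((0.5, 2.0, 8.0), ("early", "mid", "late")):
            layer_rows = {}
            for rid in split.heldout_rules:
                rule_rng = np.random.default_rng(1000 + rid)
                man = GaussianManifold(
                    centroid=np.sqrt(signal) * rule_rng.standard_normal(30) / np.sqrt(30),
                    axes=np.eye(30),
                    radii=np.sqrt(spectrum_with_participation_ratio(30, 10.0)),
                )
                layer_rows[rid] = man.sample(60, rng)
            manifolds[layer] = layer_rows
            layers[layer] = lambda row, _l=layer: manifolds[_l][row.rule.rule_id][row.idx]

        rows_by_rule = {}
        for rid in split.heldout_rules:
            rule = rule_by_id(rid)
            rows = []
            for i in range(60):
                r = _FakeRow(rule, None)
                r.idx = i
                rows.append(r)
            rows_by_rule[rid] = rows

        report = layerwise_report(
            layers, rows_by_rule, split, n_trials=120, projection_dim=None, rng=rng
        )
        summary = summarize_layerwise(report)
        errors = summary["error_mean"].to_numpy()
        assert np.all(np.diff(errors) < 0)
        preds = summary["predicted_error_mean"].to_numpy()
        assert np.allclose(errors, preds, atol=0.06)
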