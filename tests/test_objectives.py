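"""Loss functions: values, analytic gradients, and consistency with the geometry module."""

import numpy as np
import pytest

from simplerpm.geometry import ManifoldStats, closed_form_snr
from simplerpm.objectives import (
    EpisodeBatch,
    LinearHead,
    batch_pair_snrs,
    cross_entropy,
    prototypical_loss,
    snr_loss,
)


@pytest.fixture
def episode(rng):
    Z = rng.standard_normal((15, 6)) + np.repeat(rng.standard_normal((3, 6)) * 2, 5, axis=0)
    labels = np.repeat([0, 1, 2], 5)
    return EpisodeBatch(Z, labels)


def _numeric_grad(fn, Z, eps=1e-6):
    g = np.zeros_like(Z)
    for i in range(Z.shape[0]):
        for j in range(Z.shape[1]):
            Zp, Zm = Z.copy(), Z.copy()
            Zp[i, j] += eps
            Zm[i, j] -= eps
            g[i, j] = (fn(Zp) - fn(Zm)) / (2 * eps)
    return g


class TestEpisodeBatch:
    def test_needs_two_rules_and_two_rows(self, rng):
        with pytest.raises(ValueError):
            EpisodeBatch(rng.standard_normal((4, 3)), np.zeros(4, dtype=int))
        with pytest.raises(ValueError):
            EpisodeBatch(rng.standard_normal((3, 3)), np.array([0, 1, 1]))


class TestSnrLoss:
    def test_collapsed_rules_give_unit_loss(self):
        """All rules at one point: zero signal, SNR 0, exp(0) = 1 per pair."""
        Z = np.zeros((12, 4))
        loss, _, mean_snr = snr_loss(EpisodeBatch(Z, np.repeat([0, 1, 2], 4)), ridge=1e-6)
        assert loss == pytest.approx(1.0)
        assert mean_snr == pytest.approx(0.0)

    def test_separated_clusters_drive_loss_to_zero(self, rng):
        Z = rng.standard_normal((20, 5)) * 0.01 + np.repeat(
            np.array([[0.0] * 5, [50.0] * 5]), 10, axis=0
        )
        loss, _, mean_snr = snr_loss(EpisodeBatch(Z, np.repeat([0, 1], 10)))
        assert loss < 1e-6 and mean_snr > 10

    def test_analytic_gradient_matches_finite_differences(self, episode):
        _, grad, _ = snr_loss(episode)
        num = _numeric_grad(lambda Z: snr_loss(EpisodeBatch(Z, episode.labels), return_grad=False)[0], episode.reps)
        assert np.abs(grad - num).max() <= 1e-6 * max(1.0, np.abs(num).max())

    def test_consistent_with_geometry_module(self, episode):
        """Within-batch SNRs equal closed-form SNRs of the ridged biased-covariance manifolds."""
        ridge = 1e-6
        snrs = batch_pair_snrs(episode.reps, episode.labels, ridge=ridge)
        stats = {}
        for r in np.unique(episode.labels):
            Zr = episode.reps[episode.labels == r]
            S = np.cov(Zr.T, bias=True) + ridge * np.eye(Zr.shape[1])
            w, V = np.linalg.eigh(S)
            order = np.argsort(w)[::-1]
            stats[r] = ManifoldStats(
                centroid=Zr.mean(0), axes=V.T[order], radii=np.sqrt(np.clip(w[order], 0, None))
            )
        for (a, b), snr in snrs.items():
            assert snr == pytest.approx(closed_form_snr(stats[a], stats[b]), rel=1e-9)
        loss, _, _ = snr_loss(episode, ridge=ridge, return_grad=False)
        assert loss == pytest.approx(np.mean([np.exp(-s) for s in snrs.values()]))


class TestCrossEntropy:
    def test_uniform_logits_equal_log_35(self):
        loss, _ = cross_entropy(np.zeros((8, 35)), np.arange(8) % 35)
        assert loss == pytest.approx(np.log(35))

    def test_confident_correct_logits_drive_loss_to_zero(self):
        labels = np.array([0, 1, 2])
        onehot = np.eye(3)[labels]
        for scale, bound in ((10, 1e-3), (100, 1e-20)):
            loss, _ = cross_entropy(scale * onehot, labels)
            assert loss < bound

    def test_random_guessing_error_is_34_over_35(self, rng):
        """A label-independent guesser errs at the 34/35 = 0.97 chance level."""
        head = LinearHead(4, 35, seed=0)
        Z = np.zeros((40_000, 4))  # constant reps: prediction independent of labels
        labels = rng.integers(0, 35, size=40_000)
        err = head.error_rate(Z, labels)
        assert abs(err - 34 / 35) <= 3 * np.sqrt((34 / 35) * (1 / 35) / 40_000)

    def test_label_outside_split_errors(self):
        with pytest.raises(ValueError, match="split"):
            cross_entropy(np.zeros((2, 35)), np.array([0, 35]))

    def test_gradient_matches_finite_differences(self, rng):
        Z = rng.standard_normal((6, 4))
        labels = np.array([0, 1, 2, 0, 1, 2])
        head = LinearHead(4, 3, seed=1)
        _, dZ = head.forward(Z, labels)
        num = _numeric_grad(lambda z: head.forward(z, labels)[0], Z)
        assert np.allclose(dZ, num, atol=1e-7)


class TestPrototypicalLoss:
    def test_query_at_own_prototype_others_far(self):
        Z = np.array([[0.0, 0], [0, 0], [100, 0], [100, 0], [0, 100], [0, 100]])
        loss, _ = prototypical_loss(EpisodeBatch(Z, np.repeat([0, 1, 2], 2)), n_support=1)
        assert loss < 1e-9

    def test_identical_prototypes_give_log_m(self, rng):
        m = 4
        Z = np.zeros((3 * m, 5))
        Z[np.arange(0, 3 * m, 3)] = 0.0  # support rows all identical
        Z[[i for i in range(3 * m) if i % 3]] = rng.standard_normal((2 * m, 5))
        loss, _ = prototypical_loss(EpisodeBatch(Z, np.repeat(np.arange(m), 3)), n_support=1)
        assert loss == pytest.approx(np.log(m))

    def test_no_query_rows_errors(self, rng):
        Z = rng.standard_normal((4, 3))
        with pytest.raises(ValueError, match="query"):
            prototypical_loss(EpisodeBatch(Z, np.repeat([0, 1], 2)), n_support=2)

    def test_gradient_matches_finite_differences(self, episode):
        _, grad = prototypical_loss(episode, n_support=2)
        num = _numeric_grad(
            lambda Z: prototypical_loss(EpisodeBatch(Z, episode.labels), 2, return_grad=False)[0],
            episode.reps,
        )
        assert np.abs(grad - num).max() <= 1e-6 * max(1.0, np.abs(num).max())
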