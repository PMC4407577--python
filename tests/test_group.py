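"""Random-effects model selection, family inference and BMA."""

import numpy as np
import pytest
from scipy.special import digamma
from scipy.stats import beta as beta_dist

import emodcm as e
from emodcm.group import EvidenceMatrix, bma, summarize_bma
from emodcm.inversion import InversionResult
from emodcm.model_space import build_family_partition


def evidence(F):
    F = np.atleast_2d(np.asarray(F, dtype=float))
    return EvidenceMatrix(F=F, subjects=tuple(range(F.shape[0])),
                          model_ids=tuple(range(1, F.shape[1] + 1)))


class TestRfxBms:
    def test_symmetric_two_models(self):
        res = e.rfx_bms(evidence([[0.0, 0.0]]), n_samples=100_000, seed=0)
        assert np.allclose(res.alpha, [1.5, 1.5])
        assert np.allclose(res.expected, [0.5, 0.5])
        assert res.exceedance == pytest.approx([0.5, 0.5], abs=0.01)

    def test_decisive_single_subject(self):
        """With one subject and a 1000-nat evidence gap the Dirichlet is
        Beta(2, 1): exceedance P(p1 > 1/2) = 1 - (1/2)^2 = 3/4."""
        res = e.rfx_bms(evidence([[1000.0, 0.0]]), n_samples=1_000_000, seed=1)
        assert np.allclose(res.alpha, [2.0, 1.0], atol=1e-6)
        closed_form = 1.0 - beta_dist(2, 1).cdf(0.5)
        assert res.exceedance[0] == pytest.approx(closed_form, abs=0.01)

    def test_shift_invariance(self):
        F = np.array([[3.0, 1.0, 0.5], [0.0, 2.0, 1.0]])
        r1 = e.rfx_bms(evidence(F), n_samples=10_000, seed=2)
        r2 = e.rfx_bms(evidence(F + np.array([[100.0], [-50.0]])),
                       n_samples=10_000, seed=2)
        assert np.allclose(r1.alpha, r2.alpha, atol=1e-10)

    def test_fixed_point_self_consistency(self):
        """At convergence the assignments satisfy
        g_nm ∝ exp(F_nm + ψ(α_m) − ψ(Σα)) and α = α0 + Σ_n g_nm."""
        F = np.array([[2.0, 0.0, -1.0], [1.0, 1.5, 0.0]])
        res = e.rfx_bms(evidence(F), n_samples=10_000, seed=3)
        logu = F + digamma(res.alpha) - digamma(res.alpha.sum())
        g = np.exp(logu - logu.max(axis=1, keepdims=True))
        g /= g.sum(axis=1, keepdims=True)
        assert np.allclose(g, res.g, atol=1e-3)
        assert np.allclose(res.alpha, 1.0 + g.sum(axis=0), atol=1e-3)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            evidence([[np.inf, 0.0]])


class TestExceedance:
    def test_symmetry(self):
        assert e.exceedance_probabilities([1.0, 1.0], 200_000, seed=0) \
            == pytest.approx([0.5, 0.5], abs=0.01)
        xp3 = e.exceedance_probabilities([1.0, 1.0, 1.0], 300_000, seed=1)
        assert xp3 == pytest.approx([1 / 3] * 3, abs=0.01)

    def test_beta_closed_form(self):
        xp = e.exceedance_probabilities([2.0, 1.0], 1_000_000, seed=2)
        assert xp[0] == pytest.approx(0.75, abs=0.01)

    def test_sums_to_one(self):
        xp = e.exceedance_probabilities([3.0, 2.0, 4.0, 1.0], 100_000, seed=3)
        assert xp.sum() == pytest.approx(1.0, abs=1e-2)

    def test_seeded_reproducibility(self):
        a = e.exceedance_probabilities([2.0, 3.0], 50_000, seed=9)
        b = e.exceedance_probabilities([2.0, 3.0], 50_000, seed=9)
        assert np.array_equal(a, b)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            e.exceedance_probabilities([0.0, 1.0], 1000, seed=0)


class TestFamilyInference:
    @staticmethod
    def two_singleton_partition():
        models = [e.enumerate_bottom_up()[0],
                  e.enumerate_top_down(start_id=2)[0]]
        return build_family_partition(models)

    def test_singleton_families_equal_evidence(self):
        part = self.two_singleton_partition()
        ev = evidence([[0.0, 0.0], [0.0, 0.0]])
        res = e.family_inference(ev, part, n_samples=200_000, seed=0)
        assert res.exceedance == pytest.approx([0.5, 0.5], abs=0.02)

    def test_overwhelming_bu_evidence(self):
        """18 subjects each giving every BU model a 10-nat advantage
        produce near-certain BU family exceedance."""
        models = e.enumerate_bottom_up()[:4] + e.enumerate_top_down(start_id=5)[:4]
        part = build_family_partition(models)
        F = np.zeros((18, 8))
        F[:, :4] = 10.0
        ev = EvidenceMatrix(F=F, subjects=tuple(range(18)),
                            model_ids=tuple(m.model_id for m in models))
        res = e.family_inference(ev, part, n_samples=200_000, seed=1)
        assert res.winner == "BU"
        assert res.exceedance[res.labels.index("BU")] > 0.99

    def test_single_family_certain(self):
        models = e.enumerate_bottom_up()[:3]
        part = build_family_partition(models)
        ev = evidence([[1.0, 0.0, 2.0]])
        res = e.family_inference(ev, part, n_samples=10_000, seed=2)
        assert res.exceedance == pytest.approx([1.0])

    def test_uniform_family_prior_mass(self):
        """alpha0 gives each family equal prior mass despite unequal size."""
        models = e.build_model_space()  # 31 + 15
        part = build_family_partition(models)
        F = np.zeros((2, 46))
        ev = EvidenceMatrix(F=F, subjects=(0, 1),
                            model_ids=tuple(m.model_id for m in models))
        res = e.family_inference(ev, part, n_samples=10_000, seed=3)
        bu, td = res.labels.index("BU"), res.labels.index("TD")
        assert res.expected[bu] == pytest.approx(res.expected[td], abs=0.01)

    def test_partition_must_cover(self):
        part = self.two_singleton_partition()
        ev = evidence([[0.0, 0.0, 0.0]])
        ev.model_ids = (1, 2, 99)
        with pytest.raises(ValueError, match="cover"):
            e.family_inference(ev, part, n_samples=1000, seed=0)


def point_posterior(names, mean, var=0.0):
    mean = np.asarray(mean, dtype=float)
    cov = np.eye(len(mean)) * var
    return InversionResult(mean=mean, cov=cov, free_energy=0.0, iterations=1,
                           converged=True, names=tuple(names))


class TestBma:
    def test_degenerate_single_model_family(self):
        models = [e.enumerate_bottom_up()[0], e.enumerate_top_down(start_id=2)[0]]
        part = build_family_partition(models)
        ev = evidence([[5.0, 0.0]])
        rfx = e.rfx_bms(ev, n_samples=10_000, seed=0)
        names = [("A", 5, 0), ("C", 0, 0)]
        post = {(0, 1): point_posterior(names, [0.8, 0.3], var=1e-12),
                (0, 2): point_posterior(names, [0.0, 0.0], var=1e-12)}
        res = bma(rfx, post, part, "BU", n_samples=4000, seed=1)
        assert res.subject_means[0, 0] == pytest.approx(0.8, abs=0.02)
        assert res.subject_means[0, 1] == pytest.approx(0.3, abs=0.02)

    def test_mixture_expectation(self):
        """Parameter free only in model 1 (mean 1, var 0) under a
        50/50 model posterior averages to 1/2."""
        models = e.enumerate_bottom_up()[:2]
        part = build_family_partition(models)
        ev = evidence([[0.0, 0.0]])
        rfx = e.rfx_bms(ev, n_samples=10_000, seed=0)
        post = {(0, 1): point_posterior([("B", 5, 0, 1)], [1.0], var=1e-14),
                (0, 2): point_posterior([("A", 5, 0)], [0.4], var=1e-14)}
        res = bma(rfx, post, part, "BU", n_samples=40_000, seed=2)
        k = res.parameters.index("B:negative:IOG->OFC")
        assert res.subject_means[0, k] == pytest.approx(0.5, abs=0.02)

    def test_absent_parameter_is_exact_zero(self):
        models = e.enumerate_bottom_up()[:2]
        part = build_family_partition(models)
        rfx = e.rfx_bms(evidence([[0.0, 0.0]]), n_samples=10_000, seed=0)
        post = {(0, 1): point_posterior([("A", 5, 0)], [0.5], var=1e-14),
                (0, 2): point_posterior([("A", 5, 0)], [0.5], var=1e-14)}
        res = bma(rfx, post, part, "BU", n_samples=1000, seed=3)
        assert res.parameters == ("A:IOG->OFC",)

    def test_empty_family_rejected(self):
        models = e.enumerate_bottom_up()[:2]
        part = build_family_partition(models)
        rfx = e.rfx_bms(evidence([[0.0, 0.0]]), n_samples=10_000, seed=0)
        with pytest.raises(ValueError, match="empty winning family"):
            bma(rfx, {}, part, "TD", n_samples=100, seed=0)

    def test_seeded_reproducibility(self):
        models = e.enumerate_bottom_up()[:2]
        part = build_family_partition(models)
        rfx = e.rfx_bms(evidence([[1.0, 0.0]]), n_samples=10_000, seed=0)
        post = {(0, 1): point_posterior([("A", 5, 0)], [0.5], var=0.01),
                (0, 2): point_posterior([("A", 5, 0)], [0.2], var=0.01)}
        a = bma(rfx, post, part, "BU", n_samples=500, seed=7)
        b = bma(rfx, post, part, "BU", n_samples=500, seed=7)
        assert np.array_equal(a.subject_means, b.subject_means)


class TestSummaries:
    def test_single_subject_degenerate_quantiles(self):
        res = e.BMAResult(parameters=("A:IOG->OFC",),
                          subject_means=np.array([[0.3]]),
                          subjects=(0,), n_samples=100)
        s = summarize_bma(res)
        assert s["median"].iloc[0] == s["q25"].iloc[0] == s["q75"].iloc[0] == 0.3

    def test_symmetric_median(self):
        res = e.BMAResult(parameters=("x",),
                          subject_means=np.array([[-1.0], [0.0], [1.0]]),
                          subjects=(0, 1, 2), n_samples=1)
        assert summarize_bma(res)["median"].iloc[0] == 0.0

    def test_linear_interpolation_quantiles(self):
        res = e.BMAResult(parameters=("x",),
                          subject_means=np.array([[1.0], [2.0], [3.0], [4.0]]),
                          subjects=(0, 1, 2, 3), n_samples=1)
        s = summarize_bma(res)
        assert s["q25"].iloc[0] == pytest.approx(1.75)
        assert s["q75"].iloc[0] == pytest.approx(3.25)
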