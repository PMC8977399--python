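"""Standard, weighted, and sNB-constrained logistic recalibration."""

import numpy as np
import pytest
from scipy.special import expit, logit

from snbrecal import (
    CohortData,
    DecisionPolicy,
    RecalModel,
    apply_recal,
    fit_constrained,
    fit_standard,
    fit_weighted,
    recalibrated_snb,
    snb_at_cutpoint,
    snb_curve,
)
from snbrecal.recalibrate import _neg_loglik_and_grad


def grid_oracle(z, y, w, a0_range, a1_range, step):
    """Brute-force maximizer of the weighted log-likelihood over a grid."""
    a0s = np.arange(*a0_range, step)
    a1s = np.arange(*a1_range, step)
    A0, A1 = np.meshgrid(a0s, a1s, indexing="ij")
    eta = A0[..., None] + A1[..., None] * z
    ll = np.sum(w * (y * eta - np.logaddexp(0.0, eta)), axis=-1)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return a0s[i], a1s[j], ll[i, j] / z.size


def _calibrated(n, seed, shift=0.0):
    """y ~ Bernoulli(p) with score s = expit(logit(p) + shift)."""
    rng = np.random.default_rng(seed)
    p = rng.beta(2, 4, n)
    y = rng.binomial(1, p)
    s = expit(logit(p) + shift)
    return CohortData(y, s)


class TestApplyRecal:
    def test_identity_map(self):
        s = np.linspace(0.05, 0.95, 11)
        model = RecalModel(alpha0=0.0, alpha1=1.0)
        assert np.allclose(apply_recal(model, s), s)

    def test_composition_is_affine_on_logit_scale(self):
        s = np.linspace(0.05, 0.95, 11)
        inner = RecalModel(alpha0=0.4, alpha1=1.3)
        outer = RecalModel(alpha0=-0.2, alpha1=0.7)
        composed = RecalModel(
            alpha0=outer.alpha0 + outer.alpha1 * inner.alpha0,
            alpha1=outer.alpha1 * inner.alpha1,
        )
        assert np.allclose(
            apply_recal(outer, apply_recal(inner, s)), apply_recal(composed, s)
        )

    def test_published_style_coefficients(self):
        # an intercept-dominated map evaluated at s = 0.5
        model = RecalModel(alpha0=-0.911, alpha1=0.856)
        assert apply_recal(model, np.array([0.5]))[0] == pytest.approx(
            expit(-0.911)
        )

    def test_rank_preservation_and_range(self):
        rng = np.random.default_rng(0)
        s = np.sort(rng.uniform(0.001, 0.999, 200))
        for a0, a1 in [(-2, 0.3), (1.5, 2.7), (0, 0.01)]:
            out = apply_recal(RecalModel(alpha0=a0, alpha1=a1), s)
            assert ((out > 0) & (out < 1)).all()
            assert (np.diff(out) >= 0).all()

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            RecalModel(alpha0=0.0, alpha1=0.0)


class TestFitStandard:
    def test_recovers_identity_on_calibrated_data(self):
        data = _calibrated(50_000, 1)
        model = fit_standard(data)
        # asymptotic SEs from the logistic information matrix
        se = _wald_se(data, model)
        assert abs(model.alpha0 - 0.0) < 3 * se[0]
        assert abs(model.alpha1 - 1.0) < 3 * se[1]
        assert model.converged

    def test_inverts_systematic_logit_shift(self):
        data = _calibrated(50_000, 2, shift=1.0)
        model = fit_standard(data)
        assert model.alpha0 == pytest.approx(-1.0, abs=0.08)
        assert model.alpha1 == pytest.approx(1.0, abs=0.08)

    def test_constant_outcome_fails(self):
        data = CohortData(np.ones(30), np.linspace(0.1, 0.9, 30))
        with pytest.raises(ValueError):
            fit_standard(data)

    def test_complete_separation_flagged(self, separated_cohort):
        assert not fit_standard(separated_cohort).converged


def _wald_se(data, model):
    z = logit(data.s)
    p = expit(model.alpha0 + model.alpha1 * z)
    v = p * (1 - p)
    info = np.array([[v.sum(), (v * z).sum()], [(v * z).sum(), (v * z * z).sum()]])
    return np.sqrt(np.diag(np.linalg.inv(info)))


class TestFitWeighted:
    def test_unit_weights_match_standard(self, calibrated_midsize):
        std = fit_standard(calibrated_midsize)
        wgt = fit_weighted(calibrated_midsize, np.ones(calibrated_midsize.n))
        assert wgt.alpha0 == pytest.approx(std.alpha0, abs=1e-6)
        assert wgt.alpha1 == pytest.approx(std.alpha1, abs=1e-6)
        assert wgt.effective_sample_proportion == 1.0

    def test_matches_grid_oracle(self):
        rng = np.random.default_rng(3)
        n = 40
        data = CohortData(rng.integers(0, 2, n), rng.uniform(0.05, 0.95, n))
        w = rng.uniform(0.2, 1.0, n)
        model = fit_weighted(data, w)
        z = logit(data.s)
        a0_star, a1_star, ll_star = grid_oracle(
            z, data.y.astype(float), w, (-3, 3), (0.01, 3), 0.01
        )
        ll_fit = -_neg_loglik_and_grad(
            (model.alpha0, model.alpha1), z, data.y.astype(float), w
        )[0]
        assert model.alpha0 == pytest.approx(a0_star, abs=0.01)
        assert model.alpha1 == pytest.approx(a1_star, abs=0.01)
        assert ll_fit >= ll_star - 1e-10

    def test_matches_statsmodels_glm(self, calibrated_midsize):
        """Independent cross-check of the weighted optimum."""
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        w = rng.uniform(0.3, 1.0, calibrated_midsize.n)
        model = fit_weighted(calibrated_midsize, w)
        z = logit(calibrated_midsize.s)
        glm = sm.GLM(
            calibrated_midsize.y.astype(float),
            sm.add_constant(z),
            family=sm.families.Binomial(),
            freq_weights=w,
        ).fit()
        assert model.alpha0 == pytest.approx(glm.params[0], abs=1e-4)
        assert model.alpha1 == pytest.approx(glm.params[1], abs=1e-4)

    def test_zero_weight_subjects_do_not_matter(self):
        rng = np.random.default_rng(5)
        n = 200
        s = rng.uniform(0.05, 0.95, n)
        y = rng.binomial(1, s)
        w = np.where((s > 0.2) & (s < 0.6), 1.0, 0.0)
        data = CohortData(y, s)
        model_a = fit_weighted(data, w)
        y2 = y.copy()
        flip = w == 0.0
        y2[flip] = 1 - y2[flip]
        if y2.sum() in (0, n):
            pytest.skip("degenerate flip")
        model_b = fit_weighted(CohortData(y2, s), w)
        assert model_a.alpha0 == pytest.approx(model_b.alpha0, abs=1e-6)
        assert model_a.alpha1 == pytest.approx(model_b.alpha1, abs=1e-6)

    def test_tiny_effective_sample_rejected(self, calibrated_midsize):
        w = np.zeros(calibrated_midsize.n)
        w[:5] = 1.0
        with pytest.raises(ValueError, match="10"):
            fit_weighted(calibrated_midsize, w)


class TestFitConstrained:
    def test_returns_standard_when_feasible(self):
        # large calibrated cohort: the standard fit is essentially the
        # identity, which is sNB-optimal, hence feasible
        data = _calibrated(20_000, 6)
        policy = DecisionPolicy(R=0.3)
        std = fit_standard(data)
        con = fit_constrained(data, policy)
        if recalibrated_snb(std, data, policy) >= con.constraint_bound:
            assert con.alpha0 == std.alpha0
            assert con.alpha1 == std.alpha1
        assert con.method == "constrained"

    def test_feasibility_postcondition(self):
        rng = np.random.default_rng(8)
        for seed in range(3):
            n = 400
            p = np.random.default_rng(seed).beta(2, 5, n)
            y = np.random.default_rng(seed + 100).binomial(1, p)
            s = expit(logit(p) - 0.8)  # miscalibrated
            data = CohortData(y, s)
            policy = DecisionPolicy(R=0.3)
            con = fit_constrained(data, policy)
            assert (
                recalibrated_snb(con, data, policy)
                >= con.constraint_bound - 1e-9
            )
            assert con.alpha1 > 0

    def test_matches_feasible_grid_oracle(self):
        rng = np.random.default_rng(9)
        n = 60
        p = rng.beta(2, 4, n)
        data = CohortData(rng.binomial(1, p), expit(logit(p) - 1.0))
        policy = DecisionPolicy(R=0.3)
        con = fit_constrained(data, policy)
        bound = con.constraint_bound

        z = logit(data.s)
        y = data.y.astype(float)
        a0s = np.arange(-3, 3, 0.01)
        a1s = np.arange(0.01, 3, 0.01)
        best_ll = -np.inf
        for a0 in a0s:
            eta = a0 + a1s[:, None] * z
            ll = np.sum(y * eta - np.logaddexp(0.0, eta), axis=1) / n
            for k in np.argsort(ll)[::-1]:
                m = RecalModel(alpha0=float(a0), alpha1=float(a1s[k]))
                if recalibrated_snb(m, data, policy) >= bound - 1e-12:
                    best_ll = max(best_ll, ll[k])
                    break
        ll_fit = -_neg_loglik_and_grad((con.alpha0, con.alpha1), z, y, np.ones(n))[0]
        assert ll_fit >= best_ll - 1e-2

    def test_likelihood_ordering(self):
        data = _calibrated(1000, 10, shift=-1.2)
        policy = DecisionPolicy(R=0.3)
        std = fit_standard(data)
        con = fit_constrained(data, policy)
        z = logit(data.s)
        y = data.y.astype(float)
        w = np.ones(data.n)
        ll = lambda m: -_neg_loglik_and_grad((m.alpha0, m.alpha1), z, y, w)[0]
        assert ll(std) >= ll(con) - 1e-10
        if not np.isclose(con.alpha0, std.alpha0):
            # standard was infeasible: constrained must buy sNB
            assert recalibrated_snb(con, data, policy) >= recalibrated_snb(
                std, data, policy
            )


class TestPluginConsistency:
    def test_plugin_snb_equals_curve_at_induced_cutpoint(self):
        """The plug-in sNB of a recalibrated model equals the original
        score's sNB curve at the model's induced cutpoint."""
        rng = np.random.default_rng(12)
        n = 300
        data = CohortData(rng.integers(0, 2, n), rng.uniform(0.02, 0.98, n))
        policy = DecisionPolicy(R=0.3)
        for a0, a1 in [(-0.5, 0.8), (0.3, 1.4), (0.0, 1.0)]:
            model = RecalModel(alpha0=a0, alpha1=a1)
            c = expit(model.induced_cutpoint(policy))
            assert recalibrated_snb(model, data, policy) == pytest.approx(
                snb_at_cutpoint(data, float(c), policy), abs=1e-12
            )

    def test_model_json_round_trip(self, tmp_path):
        model = RecalModel(
            alpha0=-0.7,
            alpha1=0.96,
            method="constrained",
            constraint_bound=0.26,
            converged=True,
        )
        path = tmp_path / "model.json"
        model.to_json(path)
        assert RecalModel.from_json(path) == model
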