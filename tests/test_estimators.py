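import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from mrmediate import (EggerEstimator, IVWEstimator, MREstimate,
                       ModeEstimator, cochran_q, direction_consistent,
                       ivw, mode_estimate, mr_egger, wald_ratio, weighted_median)
from mrmediate.exceptions import (DegenerateInstrumentError,
                                  InsufficientInstrumentsError)

from _oracles import (cochran_q_oracle, egger_oracle, ivw_oracle,
                      mode_oracle, weighted_median_oracle)
from conftest import make_instruments


def _table(bx, by, sy, sx=None):
    bx = np.asarray(bx, float)
    return pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(len(bx))],
        "bx": bx, "sx": sx if sx is not None else np.full(len(bx), 0.01),
        "by": np.asarray(by, float), "sy": np.asarray(sy, float)})


class TestWaldRatio:
    def test_hand_arithmetic(self):
        e = wald_ratio(_table([0.1], [0.2], [0.05]))
        assert e.beta == pytest.approx(2.0)
        assert e.se == pytest.approx(0.5)

    def test_null_outcome(self):
        e = wald_ratio(_table([0.1], [0.0], [0.05]))
        assert e.beta == 0.0 and e.pvalue == pytest.approx(1.0)

    def test_orientation_invariance(self):
        a = wald_ratio(_table([0.1], [0.2], [0.05]))
        b = wald_ratio(_table([-0.1], [-0.2], [0.05]))
        assert a.beta == b.beta and a.se == b.se

    def test_zero_exposure_effect(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(_table([0.0], [0.2], [0.05]))


class TestIVW:
    def test_identical_ratios_recovered_exactly(self):
        t = _table([0.1, 0.2], [0.05, 0.10], [0.02, 0.03])
        fit = IVWEstimator().fit(t)
        assert fit.beta_ == pytest.approx(0.5, rel=1e-12)
        assert fit.scale_ == pytest.approx(0.0, abs=1e-8)
        assert np.isfinite(fit.se_)

    def test_unit_bx_equal_weights_is_mean(self):
        by = [0.1, 0.3, 0.2]
        fit = IVWEstimator().fit(_table([1, 1, 1], by, [0.05] * 3))
        assert fit.beta_ == pytest.approx(np.mean(by), rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_normal_equations_oracle(self, seed):
        t = make_instruments(seed, 20)
        beta, se_fixed, se_rand = ivw_oracle(t["bx"], t["by"], t["sy"])
        fixed = IVWEstimator(model="fixed").fit(t)
        rand = IVWEstimator(model="multiplicative_random").fit(t)
        assert fixed.beta_ == pytest.approx(beta, rel=1e-10)
        assert fixed.se_ == pytest.approx(se_fixed, rel=1e-10)
        assert rand.se_ == pytest.approx(se_rand, rel=1e-10)

    def test_random_se_never_below_fixed(self):
        for seed in range(30):
            t = make_instruments(seed, 8, noise=np.random.default_rng(seed).uniform(0.1, 3))
            f = IVWEstimator(model="fixed").fit(t)
            r = IVWEstimator(model="multiplicative_random").fit(t)
            assert r.se_ >= f.se_ - 1e-15
            assert r.beta_ == f.beta_

    def test_equals_weighted_mean_of_wald_ratios(self):
        """The fixed-effect IVW slope is the inverse-variance weighted mean of
        the per-SNP Wald ratios with first-order variances."""
        t = make_instruments(4, 25)
        theta = t["by"] / t["bx"]
        v = (t["sy"] / t["bx"]) ** 2
        want = float(np.sum(theta / v) / np.sum(1.0 / v))
        assert IVWEstimator(model="fixed").fit(t).beta_ == pytest.approx(want, rel=1e-8)

    def test_single_instrument_falls_back_to_wald(self):
        t = _table([0.1], [0.2], [0.05])
        e = ivw(t)
        assert e.method == "wald_ratio" and e.beta == pytest.approx(2.0)

    def test_zero_instruments_error(self):
        with pytest.raises(InsufficientInstrumentsError):
            IVWEstimator().fit(_table([], [], []))

    def test_binary_outcome_odds_ratio(self):
        t = make_instruments(9, 10)
        e = ivw(t, binary=True)
        assert e.odds_ratio == pytest.approx(np.exp(e.beta))
        assert e.or_ci_low == pytest.approx(np.exp(e.ci_low))


class TestEgger:
    def test_noiseless_line_recovered(self):
        bx = np.linspace(0.05, 0.4, 6)
        by = 0.05 + 0.3 * bx
        fit = EggerEstimator().fit(_table(bx, by, [0.02] * 6))
        assert fit.intercept_ == pytest.approx(0.05, abs=1e-12)
        assert fit.beta_ == pytest.approx(0.3, abs=1e-12)

    def test_shift_moves_intercept_only(self):
        t = make_instruments(6, 15)
        t.loc[:, "bx"] = np.abs(t["bx"])  # fixed orientation for the shift law
        base = EggerEstimator().fit(t)
        shifted = t.assign(by=t["by"] + 0.07)
        fit2 = EggerEstimator().fit(shifted)
        assert fit2.intercept_ - base.intercept_ == pytest.approx(0.07, rel=1e-9)
        assert fit2.beta_ == pytest.approx(base.beta_, rel=1e-9)

    @pytest.mark.parametrize("seed", [0, 3, 8])
    def test_matches_weighted_regression_oracle(self, seed):
        t = make_instruments(seed, 20, intercept=0.03)
        alpha, beta, se_a, se_b = egger_oracle(t["bx"], t["by"], t["sy"])
        fit = EggerEstimator().fit(t)
        assert fit.intercept_ == pytest.approx(alpha, rel=1e-10)
        assert fit.beta_ == pytest.approx(beta, rel=1e-10)
        assert fit.intercept_se_ == pytest.approx(se_a, rel=1e-10)
        assert fit.se_ == pytest.approx(se_b, rel=1e-10)

    def test_intercept_inference_uses_t(self):
        t = make_instruments(2, 5)
        fit = EggerEstimator().fit(t)
        z = fit.intercept_ / fit.intercept_se_
        assert fit.intercept_pvalue_ == pytest.approx(2 * st.t.sf(abs(z), 3))

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError, match="3"):
            EggerEstimator().fit(_table([0.1, 0.2], [0.1, 0.2], [0.01, 0.01]))


class TestWeightedMedian:
    def test_equal_weights_symmetric_ratios(self):
        t = _table([1, 1, 1], [1, 2, 3], [1, 1, 1])
        e = weighted_median(t, n_boot=0)
        assert e.beta == pytest.approx(2.0)

    def test_dominant_weight_lands_on_its_ratio(self):
        # middle instrument carries most of the weight
        t = _table([1.0, 5.0, 1.0], [1.0, 10.0, 3.0], [0.5, 0.1, 0.5])
        e = weighted_median(t, n_boot=0)
        assert e.beta == pytest.approx(2.0, abs=0.05)

    @pytest.mark.parametrize("seed", [1, 5])
    def test_matches_interpolation_oracle(self, seed):
        t = make_instruments(seed, 15)
        theta = (t["by"] / t["bx"]).to_numpy()
        w = (t["bx"] ** 2 / t["sy"] ** 2).to_numpy()
        assert weighted_median(t, n_boot=0).beta == pytest.approx(
            weighted_median_oracle(theta, w), rel=1e-10)

    def test_bootstrap_reproducible_under_seed(self):
        t = make_instruments(7, 15)
        a = weighted_median(t, n_boot=300, seed=11)
        b = weighted_median(t, n_boot=300, seed=11)
        c = weighted_median(t, n_boot=300, seed=12)
        assert a.se == b.se
        assert a.se != c.se
        assert a.se > 0


class TestMode:
    def test_degenerate_cluster(self):
        t = _table([0.1, 0.2, 0.4], [0.05, 0.10, 0.20], [0.01, 0.01, 0.01])
        e = mode_estimate(t, n_boot=50, seed=0)
        assert e.beta == pytest.approx(0.5)
        assert e.se > 0

    def test_mode_ignores_outlier(self):
        t = _table([1, 1, 1, 1], [0.99, 1.0, 1.01, 5.0], [0.05] * 4)
        e = mode_estimate(t, weighted=False, n_boot=0)
        assert abs(e.beta - 1.0) < 0.1
        assert e.beta < np.mean([0.99, 1.0, 1.01, 5.0])

    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_grid_oracle(self, weighted):
        t = make_instruments(13, 25)
        theta = (t["by"] / t["bx"]).to_numpy()
        w = ((t["bx"] ** 2 / t["sy"] ** 2).to_numpy() if weighted
             else np.ones(len(t)))
        want = mode_oracle(theta, w)
        got = mode_estimate(t, weighted=weighted, n_boot=0).beta
        assert got == pytest.approx(want, rel=1e-10)

    def test_bootstrap_reproducible(self):
        t = make_instruments(3, 12)
        a = mode_estimate(t, n_boot=200, seed=5)
        b = mode_estimate(t, n_boot=200, seed=5)
        assert a.se == b.se and a.se > 0

    def test_phi_must_be_positive(self):
        with pytest.raises(ValueError):
            ModeEstimator(phi=0.0).fit(make_instruments(1, 5))


class TestCochranQ:
    def test_identical_ratios(self):
        q, df, p = cochran_q(_table([0.1, 0.2], [0.05, 0.10], [0.02, 0.03]))
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 1 and p == pytest.approx(1.0)

    def test_two_instrument_closed_form(self):
        """For J=2, Q = (θ1−θ2)² / (v1+v2)."""
        bx, by, sy = [0.1, 0.2], [0.03, 0.12], [0.02, 0.05]
        theta = np.array(by) / np.array(bx)
        v = (np.array(sy) / np.array(bx)) ** 2
        want = (theta[0] - theta[1]) ** 2 / (v[0] + v[1])
        q, df, _ = cochran_q(_table(bx, by, sy))
        assert q == pytest.approx(want, rel=1e-12)

    def test_matches_oracle(self):
        t = make_instruments(21, 30, noise=2.0)
        q, _, _ = cochran_q(t)
        assert q == pytest.approx(cochran_q_oracle(t["bx"], t["by"], t["sy"]),
                                  rel=1e-10)

    def test_null_distribution_mean(self):
        """Homogeneous sets give Q ~ chi-square(J-1): the mean over many
        simulated sets approaches J-1."""
        rng = np.random.default_rng(0)
        j, reps = 8, 10_000
        bx = rng.uniform(0.1, 0.4, (reps, j))
        sy = rng.uniform(0.02, 0.08, (reps, j))
        by = 0.3 * bx + sy * rng.standard_normal((reps, j))
        theta = by / bx
        v = (sy / bx) ** 2
        mu = np.sum(theta / v, axis=1) / np.sum(1 / v, axis=1)
        q = np.sum((theta - mu[:, None]) ** 2 / v, axis=1)
        assert np.mean(q) == pytest.approx(j - 1, abs=4 * np.sqrt(2 * (j - 1) / reps))


class TestDirectionConsistency:
    def _est(self, betas):
        return {m: MREstimate(m, b, 0.1, 0.5, b - 0.2, b + 0.2, 5)
                for m, b in zip(["ivw", "egger", "weighted_median",
                                 "simple_mode", "weighted_mode"], betas)}

    def test_all_positive(self):
        assert direction_consistent(self._est([0.3, 0.2, 0.25, 0.1, 0.4]))

    def test_one_negative(self):
        assert not direction_consistent(self._est([0.3, -0.01, 0.25, 0.1, 0.4]))

    def test_zero_counts_as_inconsistent(self):
        assert not direction_consistent(self._est([0.3, 0.0, 0.2, 0.1, 0.4]))

    def test_all_negative(self):
        assert direction_consistent(self._est([-0.3, -0.2, -0.25, -0.1, -0.4]))

    def test_missing_method_error(self):
        est = self._est([0.3, 0.2, 0.25, 0.1, 0.4])
        del est["egger"]
        with pytest.raises(KeyError, match="egger"):
            direction_consistent(est)


def test_all_point_estimates_sign_flip_invariant():
    """Jointly negating (bx, by) pairs leaves every point estimate unchanged
    (the Egger estimator owes this to its internal bx >= 0 re-orientation)."""
    t = make_instruments(31, 18)
    rng = np.random.default_rng(2)
    flip = rng.random(len(t)) < 0.5
    t2 = t.copy()
    t2.loc[flip, ["bx", "by"]] *= -1.0
    assert ivw(t).beta == pytest.approx(ivw(t2).beta, rel=1e-12)
    assert mr_egger(t)[0].beta == pytest.approx(mr_egger(t2)[0].beta, rel=1e-12)
    assert weighted_median(t, n_boot=0).beta == pytest.approx(
        weighted_median(t2, n_boot=0).beta, rel=1e-12)
    for weighted in (False, True):
        assert mode_estimate(t, weighted=weighted, n_boot=0).beta == pytest.approx(
            mode_estimate(t2, weighted=weighted, n_boot=0).beta, rel=1e-12)


def test_sklearn_protocol_round_trip():
    from sklearn.base import clone
    est = ModeEstimator(weighted=False, phi=2.0, n_boot=17, random_state=4)
    params = est.get_params()
    assert params["phi"] == 2.0 and params["n_boot"] == 17
    twin = clone(est)
    assert twin.get_params() == params
    twin.set_params(phi=1.5)
    assert twin.phi == 1.5


def test_ci_is_normal_interval():
    t = make_instruments(50, 12)
    e = ivw(t)
    assert e.ci_low == pytest.approx(e.beta - 1.959964 * e.se, rel=1e-12)
    assert e.ci_high == pytest.approx(e.beta + 1.959964 * e.se, rel=1e-12)
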