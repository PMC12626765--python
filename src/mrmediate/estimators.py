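"""Causal-effect estimators for one harmonized exposure–outcome pair.

Input everywhere is the harmonized instrument table (columns ``bx, sx, by,
sy`` — exposure effect, its SE, outcome effect, its SE), one row per
independent variant. Per-variant Wald ratios θⱼ = byⱼ/bxⱼ with first-order
standard errors syⱼ/|bxⱼ| underlie all methods.

* :class:`IVWEstimator` — inverse-variance weighted estimate: weighted
  regression of by on bx through the origin with weights 1/sy². The
  multiplicative random-effects flavour inflates the fixed-effect SE by
  max(1, √(Q_resid/(J−1))), never deflating it.
* :class:`EggerEstimator` — the same regression with a free intercept; the
  intercept estimates average directional pleiotropy. Instruments are
  re-oriented so all bx ≥ 0 before fitting (the intercept is
  orientation-dependent); inference uses t with J−2 df.
* :class:`WeightedMedianEstimator` — weighted median of the ratios with
  weights bx²/sy²; valid if over half the weight comes from valid
  instruments. SE by seeded parametric bootstrap.
* :class:`ModeEstimator` — normal-kernel density argmax of the ratios
  (simple or weighted); robust if the largest cluster of instruments is
  valid. Bandwidth h = φ·0.9·min(sd, mad/0.6745)·J^(−1/5), density maximised
  on a 512-point grid spanning range(θ) ± 3h.

The estimator classes follow the scikit-learn protocol (``fit``,
``get_params``/``set_params``, trailing-underscore fitted attributes); the
module-level functions are thin wrappers returning :class:`MREstimate`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .exceptions import DegenerateInstrumentError, InsufficientInstrumentsError

logger = logging.getLogger(__name__)

#: Two-sided 95% normal quantile used for every confidence interval.
Z95 = 1.959964

_FIVE_METHODS = ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode")


@dataclass
class MREstimate:
    """One estimator's causal effect with uncertainty.

    ``odds_ratio`` fields are populated (exp-transformed) when the outcome
    is binary, i.e. when ``beta`` is on the log-odds scale.
    """

    method: str
    beta: float
    se: float
    pvalue: float
    ci_low: float
    ci_high: float
    n_snps: int
    odds_ratio: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None

    @classmethod
    def from_beta_se(cls, method, beta, se, n_snps, t_df=None, binary=False):
        """Build an estimate with normal (or t, if ``t_df`` given) inference."""
        beta, se = float(beta), float(se)
        if se > 0 and np.isfinite(se):
            z = beta / se
            if t_df is not None:
                p = 2.0 * st.t.sf(abs(z), t_df)
                q = st.t.ppf(0.975, t_df)
            else:
                p = 2.0 * st.norm.sf(abs(z))
                q = Z95
            lo, hi = beta - q * se, beta + q * se
        else:
            p, lo, hi = np.nan, np.nan, np.nan
        est = cls(method, beta, se, float(p), lo, hi, int(n_snps))
        if binary:
            est.odds_ratio = float(np.exp(beta))
            est.or_ci_low = float(np.exp(lo))
            est.or_ci_high = float(np.exp(hi))
        return est


def _as_arrays(instruments, min_n: int, method: str):
    """Validate the harmonized table and pull bx, by, sy as float arrays."""
    if isinstance(instruments, pd.DataFrame):
        for col in ("bx", "by", "sy"):
            if col not in instruments.columns:
                raise ValueError(f"instrument table lacks column {col!r}")
        bx = instruments["bx"].to_numpy(dtype=float)
        by = instruments["by"].to_numpy(dtype=float)
        sy = instruments["sy"].to_numpy(dtype=float)
    else:
        bx, by, sy = (np.asarray(a, dtype=float) for a in instruments)
    if not (len(bx) == len(by) == len(sy)):
        raise ValueError("bx, by, sy must have equal length")
    if len(bx) < min_n:
        raise InsufficientInstrumentsError(
            f"{method} needs >= {min_n} instruments, got {len(bx)}")
    if np.any(~np.isfinite(bx)) or np.any(~np.isfinite(by)):
        raise ValueError("non-finite effect estimates in instrument table")
    if np.any(~(sy > 0)):
        raise ValueError("all outcome standard errors must be > 0")
    return bx, by, sy


def wald_ratio(inst, binary: bool = False) -> MREstimate:
    """Single-instrument causal estimate by/bx with first-order SE sy/|bx|."""
    if isinstance(inst, pd.DataFrame):
        if len(inst) != 1:
            raise ValueError("wald_ratio takes exactly one instrument")
        inst = inst.iloc[0]
    bx, by, sy = float(inst["bx"]), float(inst["by"]), float(inst["sy"])
    if bx == 0:
        raise DegenerateInstrumentError("bx = 0: Wald ratio undefined")
    return MREstimate.from_beta_se("wald_ratio", by / bx, sy / abs(bx), 1, binary=binary)


class IVWEstimator(BaseEstimator):
    """Inverse-variance weighted causal estimate.

    Parameters
    ----------
    model : {"multiplicative_random", "fixed"}
        Random-effects flavour inflates the SE by the residual scale
        √(Q_resid/(J−1)), floored at 1 so the SE is never deflated.
    """

    def __init__(self, model: str = "multiplicative_random"):
        self.model = model

    def fit(self, instruments):
        if self.model not in ("multiplicative_random", "fixed"):
            raise ValueError(f"unknown IVW model {self.model!r}")
        bx, by, sy = _as_arrays(instruments, 2, "ivw")
        w = 1.0 / sy**2
        res = sm.WLS(by, bx[:, None], weights=w).fit()
        beta = float(res.params[0])
        # res.scale = Q_resid / (J-1); the unscaled (fixed-effect) variance is
        # (X'WX)^{-1}, robust even when the fit is exact (scale = 0).
        se_fixed = float(np.sqrt(res.normalized_cov_params[0, 0]))
        self.scale_ = float(np.sqrt(res.scale))
        self.se_fixed_ = se_fixed
        self.beta_ = beta
        if self.model == "multiplicative_random":
            self.se_ = se_fixed * max(1.0, self.scale_)
        else:
            self.se_ = se_fixed
        self.n_snps_ = len(bx)
        e = MREstimate.from_beta_se("ivw", self.beta_, self.se_, self.n_snps_)
        self.pvalue_, self.ci_low_, self.ci_high_ = e.pvalue, e.ci_low, e.ci_high
        return self

    def to_estimate(self, binary: bool = False) -> MREstimate:
        return MREstimate.from_beta_se("ivw", self.beta_, self.se_,
                                       self.n_snps_, binary=binary)


def _reorient_positive_bx(bx, by):
    """Negate (bx, by) pairs so every bx >= 0 (Egger convention)."""
    s = np.where(bx < 0, -1.0, 1.0)
    return bx * s, by * s


def _raw_egger_slope(instruments) -> float:
    """Weighted Egger slope *without* re-orientation (diagnostic only)."""
    bx, by, sy = _as_arrays(instruments, 3, "egger")
    res = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
    return float(res.params[1])


class EggerEstimator(BaseEstimator):
    """MR-Egger: weighted regression by = α + β·bx, intercept = pleiotropy.

    Fitted attributes: ``beta_``, ``se_``, ``pvalue_`` (slope; t with J−2
    df), ``intercept_``, ``intercept_se_``, ``intercept_pvalue_``. The SEs
    carry the residual-scale inflation floored at 1, as in IVW but with J−2
    denominator df.
    """

    def fit(self, instruments):
        bx, by, sy = _as_arrays(instruments, 3, "egger")
        bx, by = _reorient_positive_bx(bx, by)
        w = 1.0 / sy**2
        X = sm.add_constant(bx)
        res = sm.WLS(by, X, weights=w).fit()
        scale = float(np.sqrt(res.scale))  # √(Σw resid² / (J−2))
        infl = max(1.0, scale)
        se_unscaled = np.sqrt(np.diag(res.normalized_cov_params))
        self.n_snps_ = len(bx)
        self.df_resid_ = self.n_snps_ - 2
        self.scale_ = scale
        self.intercept_ = float(res.params[0])
        self.intercept_se_ = float(se_unscaled[0] * infl)
        self.intercept_pvalue_ = float(
            2.0 * st.t.sf(abs(self.intercept_ / self.intercept_se_), self.df_resid_))
        self.beta_ = float(res.params[1])
        self.se_ = float(se_unscaled[1] * infl)
        e = MREstimate.from_beta_se("egger", self.beta_, self.se_,
                                    self.n_snps_, t_df=self.df_resid_)
        self.pvalue_, self.ci_low_, self.ci_high_ = e.pvalue, e.ci_low, e.ci_high
        return self

    def to_estimate(self, binary: bool = False) -> MREstimate:
        return MREstimate.from_beta_se("egger", self.beta_, self.se_, self.n_snps_,
                                       t_df=self.df_resid_, binary=binary)


def _ratios_weights(bx, by, sy, weighted: bool):
    theta = by / bx
    se_theta = sy / np.abs(bx)
    if weighted:
        w = bx**2 / sy**2
    else:
        w = np.ones_like(theta)
    return theta, se_theta, w / w.sum()


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median (w normalised to sum 1)."""
    order = np.argsort(theta, kind="mergesort")
    th, ws = theta[order], w[order]
    p = np.cumsum(ws) - ws / 2.0
    return float(np.interp(0.5, p, th))


class WeightedMedianEstimator(BaseEstimator):
    """Weighted median of per-SNP ratios, weights bx²/sy².

    ``n_boot`` parametric-bootstrap resamples θⱼ ~ N(θⱼ, seⱼ) give the SE;
    ``random_state`` seeds the bootstrap (set ``n_boot=0`` for the point
    estimate only).
    """

    def __init__(self, n_boot: int = 1000, random_state: int | None = None):
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, instruments):
        bx, by, sy = _as_arrays(instruments, 3, "weighted_median")
        theta, se_theta, w = _ratios_weights(bx, by, sy, weighted=True)
        self.beta_ = _weighted_median(theta, w)
        self.n_snps_ = len(theta)
        self.se_ = self._bootstrap_se(theta, se_theta, w)
        e = MREstimate.from_beta_se("weighted_median", self.beta_,
                                    self.se_, self.n_snps_)
        self.pvalue_, self.ci_low_, self.ci_high_ = e.pvalue, e.ci_low, e.ci_high
        return self

    def _bootstrap_se(self, theta, se_theta, w):
        if self.n_boot < 2:
            return np.nan
        rng = np.random.default_rng(self.random_state)
        draws = theta + se_theta * rng.standard_normal((self.n_boot, len(theta)))
        order = np.argsort(draws, axis=1, kind="mergesort")
        th = np.take_along_axis(draws, order, axis=1)
        ws = w[order]
        p = np.cumsum(ws, axis=1) - ws / 2.0
        meds = np.array([np.interp(0.5, p[i], th[i]) for i in range(self.n_boot)])
        return float(np.std(meds, ddof=1))

    def to_estimate(self, binary: bool = False) -> MREstimate:
        return MREstimate.from_beta_se("weighted_median", self.beta_, self.se_,
                                       self.n_snps_, binary=binary)


def _kde_argmax(theta: np.ndarray, w: np.ndarray, h: float,
                grid_points: int = 512) -> float:
    """Argmax of the normal-kernel weighted density over the standard grid."""
    if h <= 0 or not np.isfinite(h):
        return float(theta[0])  # all ratios identical
    lo, hi = theta.min() - 3.0 * h, theta.max() + 3.0 * h
    grid = np.linspace(lo, hi, grid_points)
    dens = np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2) @ w
    return float(grid[int(np.argmax(dens))])


def _mode_bandwidth(theta: np.ndarray, phi: float) -> float:
    j = len(theta)
    s = float(np.std(theta, ddof=1))
    mad = float(np.median(np.abs(theta - np.median(theta)))) / 0.6745
    return phi * 0.9 * min(s, mad) * j ** (-1.0 / 5.0)


class ModeEstimator(BaseEstimator):
    """Mode-based causal estimate (simple or weighted kernel density).

    Parameters
    ----------
    weighted : bool
        Weight each ratio's kernel by bx²/sy² (weighted mode) or equally
        (simple mode).
    phi : float
        Bandwidth multiplier (1 = the rule-of-thumb bandwidth).
    n_boot, random_state :
        Parametric bootstrap for the SE, as in the weighted median.
    """

    def __init__(self, weighted: bool = True, phi: float = 1.0,
                 n_boot: int = 1000, random_state: int | None = None,
                 grid_points: int = 512):
        self.weighted = weighted
        self.phi = phi
        self.n_boot = n_boot
        self.random_state = random_state
        self.grid_points = grid_points

    def fit(self, instruments):
        if not self.phi > 0:
            raise ValueError("phi must be > 0")
        bx, by, sy = _as_arrays(instruments, 3, "mode")
        theta, se_theta, w = _ratios_weights(bx, by, sy, self.weighted)
        h = _mode_bandwidth(theta, self.phi)
        self.bandwidth_ = h
        self.beta_ = _kde_argmax(theta, w, h, self.grid_points)
        self.n_snps_ = len(theta)
        self.se_ = self._bootstrap_se(theta, se_theta, w)
        method = "weighted_mode" if self.weighted else "simple_mode"
        e = MREstimate.from_beta_se(method, self.beta_, self.se_, self.n_snps_)
        self.pvalue_, self.ci_low_, self.ci_high_ = e.pvalue, e.ci_low, e.ci_high
        return self

    def _bootstrap_se(self, theta, se_theta, w):
        if self.n_boot < 2:
            return np.nan
        rng = np.random.default_rng(self.random_state)
        j = len(theta)
        modes = np.empty(self.n_boot)
        done = 0
        chunk = max(1, int(2_000_000 // (self.grid_points * j)) or 1)
        while done < self.n_boot:
            b = min(chunk, self.n_boot - done)
            draws = theta + se_theta * rng.standard_normal((b, j))
            s = np.std(draws, axis=1, ddof=1)
            med = np.median(draws, axis=1)
            mad = np.median(np.abs(draws - med[:, None]), axis=1) / 0.6745
            h = self.phi * 0.9 * np.minimum(s, mad) * j ** (-1.0 / 5.0)
            h = np.where(h > 0, h, np.nan)
            lo = draws.min(axis=1) - 3.0 * h
            hi = draws.max(axis=1) + 3.0 * h
            step = (hi - lo) / (self.grid_points - 1)
            grid = lo[:, None] + step[:, None] * np.arange(self.grid_points)[None, :]
            z = (grid[:, :, None] - draws[:, None, :]) / h[:, None, None]
            dens = np.exp(-0.5 * z**2) @ w
            idx = np.argmax(dens, axis=1)
            got = grid[np.arange(b), idx]
            degenerate = ~np.isfinite(h)
            got[degenerate] = draws[degenerate, 0]
            modes[done:done + b] = got
            done += b
        return float(np.std(modes, ddof=1))

    def to_estimate(self, binary: bool = False) -> MREstimate:
        method = "weighted_mode" if self.weighted else "simple_mode"
        return MREstimate.from_beta_se(method, self.beta_, self.se_,
                                       self.n_snps_, binary=binary)


def cochran_q(instruments) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity test on the per-SNP Wald ratios.

    Q = Σ (θⱼ − θ_ivw)² / vⱼ with vⱼ = (syⱼ/bxⱼ)² and θ_ivw the
    inverse-variance weighted mean of the ratios; p from χ²(J−1).
    """
    bx, by, sy = _as_arrays(instruments, 2, "cochran_q")
    theta = by / bx
    v = (sy / bx) ** 2
    w = 1.0 / v
    theta_ivw = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum((theta - theta_ivw) ** 2 * w))
    df = len(theta) - 1
    return q, df, float(st.chi2.sf(q, df))


def direction_consistent(estimates: dict) -> bool:
    """True iff all five methods' betas share a strict sign (0 counts as no)."""
    missing = [m for m in _FIVE_METHODS if m not in estimates]
    if missing:
        raise KeyError(f"missing method estimate(s): {', '.join(missing)}")
    betas = np.array([estimates[m].beta for m in _FIVE_METHODS])
    return bool(np.all(betas > 0) or np.all(betas < 0))


# ---------------------------------------------------------------------------
# Functional wrappers


def ivw(instruments, model: str = "multiplicative_random",
        binary: bool = False) -> MREstimate:
    """IVW estimate; with a single instrument, falls back to the Wald ratio."""
    n = len(instruments)
    if n == 1:
        logger.info("ivw: single instrument, falling back to Wald ratio")
        return wald_ratio(instruments, binary=binary)
    return IVWEstimator(model=model).fit(instruments).to_estimate(binary=binary)


def mr_egger(instruments, binary: bool = False):
    """MR-Egger; returns (slope estimate, intercept, its SE, its p-value)."""
    fitted = EggerEstimator().fit(instruments)
    return (fitted.to_estimate(binary=binary), fitted.intercept_,
            fitted.intercept_se_, fitted.intercept_pvalue_)


def weighted_median(instruments, n_boot: int = 1000, seed: int | None = None,
                    binary: bool = False) -> MREstimate:
    return WeightedMedianEstimator(n_boot=n_boot, random_state=seed).fit(
        instruments).to_estimate(binary=binary)


def mode_estimate(instruments, weighted: bool = True, phi: float = 1.0,
                  n_boot: int = 1000, seed: int | None = None,
                  binary: bool = False) -> MREstimate:
    return ModeEstimator(weighted=weighted, phi=phi, n_boot=n_boot,
                         random_state=seed).fit(instruments).to_estimate(binary=binary)
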