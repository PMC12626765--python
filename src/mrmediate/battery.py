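"""The full estimator battery for one exposure–outcome pair.

``run_mr_battery`` chains the pipeline end to end: significance selection →
LD clumping → R²/F strength filter → harmonization → the five estimators
(IVW primary, MR-Egger, weighted median, simple and weighted mode) → the
sensitivity block (Cochran's Q, Egger intercept, five-method direction
consistency, reverse-direction IVW). The reverse arm re-runs the same
instrument machinery with the roles swapped, selecting instruments from the
outcome GWAS at its own threshold; a small reverse p-value signals that the
"outcome" drives the "exposure".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import estimators as est
from .config import MRConfig
from .exceptions import InsufficientInstrumentsError
from .harmonize import harmonize, kept
from .instruments import LDSource, select_instruments
from .sumstats import SumStats

logger = logging.getLogger(__name__)


@dataclass
class SensitivityReport:
    """Q, Egger-intercept, direction-consistency and reverse-MR diagnostics."""

    q_stat: float = np.nan
    q_df: int = 0
    q_pvalue: float = np.nan
    egger_intercept: float = np.nan
    egger_intercept_se: float = np.nan
    egger_intercept_pvalue: float = np.nan
    direction_consistent: bool | None = None
    reverse_pvalue: float = np.nan

    def verdicts(self, alpha: float = 0.05) -> dict:
        """Per-diagnostic pass flags at significance level ``alpha``.

        A missing (NaN) diagnostic passes: absence of evidence against the
        pair is not an exclusion, and an outcome with no significant
        instruments simply cannot be tested in reverse.
        """
        return {
            "no_heterogeneity": not (self.q_pvalue < alpha),
            "no_pleiotropy": not (self.egger_intercept_pvalue < alpha),
            "direction_consistent": bool(self.direction_consistent),
            "no_reverse_signal": not (self.reverse_pvalue < alpha),
        }


@dataclass
class BatteryResult:
    """Everything computed for one exposure–outcome pair."""

    exposure: str
    outcome: str
    estimates: dict = field(default_factory=dict)
    sensitivity: SensitivityReport = field(default_factory=SensitivityReport)
    harmonized: pd.DataFrame | None = None
    instrument_report: pd.DataFrame | None = None
    n_instruments: int = 0
    notes: list[str] = field(default_factory=list)

    @property
    def ivw(self) -> est.MREstimate | None:
        return self.estimates.get("ivw")

    def estimates_table(self) -> pd.DataFrame:
        rows = []
        for m, e in self.estimates.items():
            rows.append(dict(method=m, beta=e.beta, se=e.se, pvalue=e.pvalue,
                             ci_low=e.ci_low, ci_high=e.ci_high,
                             odds_ratio=e.odds_ratio, n_snps=e.n_snps))
        return pd.DataFrame(rows)


def _reverse_ivw_pvalue(exposure: SumStats, outcome: SumStats, ld: LDSource,
                        config: MRConfig, notes: list[str]) -> float:
    """IVW p-value of the outcome → exposure analysis (reverse MR)."""
    try:
        iv, _ = select_instruments(
            outcome, ld, p_threshold=config.p_reverse, r2_max=config.clump_r2,
            window_bp=config.clump_window_bp, f_min=config.f_min)
    except Exception as exc:  # e.g. missing eaf in the outcome GWAS
        notes.append(f"reverse arm unavailable: {exc}")
        return np.nan
    if len(iv) == 0:
        notes.append("reverse arm: no instruments at threshold "
                     f"{config.p_reverse:g}; reverse test not possible")
        return np.nan
    h = kept(harmonize(iv, exposure, config.policy))
    if len(h) == 0:
        notes.append("reverse arm: no harmonizable instruments")
        return np.nan
    if len(h) == 1:
        notes.append("reverse arm: single instrument, Wald ratio p reported")
    return est.ivw(h, model=config.ivw_model).pvalue


def run_mr_battery(exposure: SumStats, outcome: SumStats, ld: LDSource,
                   config: MRConfig | None = None, seed: int | None = None,
                   run_reverse: bool = True) -> BatteryResult:
    """Run the complete five-estimator battery with sensitivity analyses.

    Raises :class:`InsufficientInstrumentsError` when not even an IVW (or
    single-instrument Wald) estimate is possible; lesser failures are
    recorded in ``result.notes`` while the available estimates are returned.
    """
    config = config or MRConfig()
    seed = config.seed if seed is None else seed
    binary = outcome.trait_type == "binary"
    result = BatteryResult(exposure=exposure.trait_name, outcome=outcome.trait_name)

    iv, report = select_instruments(
        exposure, ld, p_threshold=config.p_instrument, r2_max=config.clump_r2,
        window_bp=config.clump_window_bp, f_min=config.f_min)
    result.instrument_report = report
    if len(iv) == 0:
        raise InsufficientInstrumentsError(
            f"{exposure.trait_name}: no instruments at p < {config.p_instrument:g} "
            f"with F > {config.f_min:g}")

    h_all = harmonize(iv, outcome, config.policy)
    result.harmonized = h_all
    h = kept(h_all)
    result.n_instruments = len(h)
    if len(h) == 0:
        raise InsufficientInstrumentsError(
            f"{exposure.trait_name} vs {outcome.trait_name}: "
            "no instruments survived harmonization")

    if len(h) == 1:
        result.notes.append("single instrument: IVW replaced by Wald ratio; "
                            "median/mode/Egger and Q unavailable")
    result.estimates["ivw"] = est.ivw(h, model=config.ivw_model, binary=binary)

    ss = np.random.SeedSequence(seed)
    med_seed, sm_seed, wm_seed = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)]
    if len(h) >= 3:
        slope, a, a_se, a_p = est.mr_egger(h, binary=binary)
        result.estimates["egger"] = slope
        result.sensitivity.egger_intercept = a
        result.sensitivity.egger_intercept_se = a_se
        result.sensitivity.egger_intercept_pvalue = a_p
        result.estimates["weighted_median"] = est.weighted_median(
            h, n_boot=config.n_boot, seed=med_seed, binary=binary)
        result.estimates["simple_mode"] = est.mode_estimate(
            h, weighted=False, phi=config.mode_phi, n_boot=config.n_boot,
            seed=sm_seed, binary=binary)
        result.estimates["weighted_mode"] = est.mode_estimate(
            h, weighted=True, phi=config.mode_phi, n_boot=config.n_boot,
            seed=wm_seed, binary=binary)
        result.sensitivity.direction_consistent = est.direction_consistent(
            result.estimates)
    else:
        result.notes.append(
            f"only {len(h)} instrument(s): Egger/median/mode need >= 3")

    if len(h) >= 2:
        q, q_df, q_p = est.cochran_q(h)
        result.sensitivity.q_stat = q
        result.sensitivity.q_df = q_df
        result.sensitivity.q_pvalue = q_p

    if run_reverse:
        result.sensitivity.reverse_pvalue = _reverse_ivw_pvalue(
            exposure, outcome, ld, config, result.notes)
    return result
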