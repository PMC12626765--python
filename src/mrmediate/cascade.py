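"""The multi-stage screening cascade and the mediation wrapper.

A screen runs the full estimator battery for every candidate trait pair and
then applies the exclusion filters in a fixed order:

1. primary-IVW significance (p < α; optional Benjamini–Hochberg mode),
2. five-method direction consistency (all betas strictly one sign),
3. no directional pleiotropy (Egger intercept p ≥ α),
4. no excess heterogeneity (Cochran's Q p ≥ α),
5. no reverse-causation signal (reverse IVW p ≥ α, or untestable).

The order matters for the audit counts and is not permutable. Every stage
records who entered, who passed, and why each dropped trait fell; counts
always conserve (entering = passing + dropped). Per-trait estimator
failures become drops at the first stage, never batch aborts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .battery import BatteryResult, run_mr_battery
from .config import MRConfig
from .instruments import LDSource
from .mediation import MediationResult, product_of_coefficients
from .sumstats import SumStats

logger = logging.getLogger(__name__)

STAGE_ORDER = ("ivw_significance", "direction_consistency", "pleiotropy",
               "heterogeneity", "reverse_causality")


@dataclass
class CascadeStage:
    """One filter stage's audit record; entering = passing + dropped."""

    stage_name: str
    entering: int
    passing: int
    dropped_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        assert self.passing + len(self.dropped_ids) == self.entering


@dataclass
class ScreenResult:
    results: dict[str, BatteryResult]
    failures: dict[str, str]
    audit: list[CascadeStage]
    survivors: list[str]

    def audit_table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"stage": s.stage_name, "entering": s.entering, "passing": s.passing,
             "dropped": len(s.dropped_ids)} for s in self.audit])

    def results_table(self) -> pd.DataFrame:
        rows = []
        for name, r in self.results.items():
            e = r.ivw
            s = r.sensitivity
            rows.append(dict(
                trait=name, n_snps=r.n_instruments,
                ivw_beta=e.beta if e else np.nan,
                ivw_se=e.se if e else np.nan,
                ivw_pvalue=e.pvalue if e else np.nan,
                odds_ratio=e.odds_ratio if e else np.nan,
                q_pvalue=s.q_pvalue, egger_intercept_pvalue=s.egger_intercept_pvalue,
                direction_consistent=s.direction_consistent,
                reverse_pvalue=s.reverse_pvalue,
                survivor=name in self.survivors))
        return pd.DataFrame(rows)


def _filter_cascade(results: Mapping[str, BatteryResult],
                    failures: Mapping[str, str],
                    config: MRConfig) -> tuple[list[CascadeStage], list[str]]:
    alpha = config.alpha
    alive = list(results.keys()) + list(failures.keys())
    audit: list[CascadeStage] = []

    ivw_p = {}
    for name, r in results.items():
        ivw_p[name] = r.ivw.pvalue if r.ivw is not None else np.nan
    if config.multiple_testing == "bh" and ivw_p:
        names = list(ivw_p)
        rej, adj, *_ = multipletests([ivw_p[n] for n in names],
                                     alpha=alpha, method="fdr_bh")
        ivw_sig = dict(zip(names, rej))
    else:
        ivw_sig = {n: bool(p < alpha) for n, p in ivw_p.items()}

    failures = dict(failures)

    def stage(name, predicate):
        nonlocal alive
        dropped: dict[str, str] = {}
        passing = []
        for trait in alive:
            if trait in failures:
                dropped[trait] = failures.pop(trait)
                continue
            ok, reason = predicate(trait, results[trait])
            if ok:
                passing.append(trait)
            else:
                dropped[trait] = reason
        audit.append(CascadeStage(name, len(alive), len(passing), dropped))
        alive = passing

    stage("ivw_significance", lambda t, r: (
        ivw_sig.get(t, False), f"ivw_p={ivw_p.get(t, np.nan):.3g}"))
    stage("direction_consistency", lambda t, r: (
        bool(r.sensitivity.direction_consistent),
        "five_methods_unavailable" if r.sensitivity.direction_consistent is None
        else "inconsistent_direction"))
    stage("pleiotropy", lambda t, r: (
        r.sensitivity.verdicts(alpha)["no_pleiotropy"],
        f"egger_intercept_p={r.sensitivity.egger_intercept_pvalue:.3g}"))
    stage("heterogeneity", lambda t, r: (
        r.sensitivity.verdicts(alpha)["no_heterogeneity"],
        f"q_p={r.sensitivity.q_pvalue:.3g}"))
    stage("reverse_causality", lambda t, r: (
        r.sensitivity.verdicts(alpha)["no_reverse_signal"],
        f"reverse_p={r.sensitivity.reverse_pvalue:.3g}"))
    return audit, alive


def _screen(pairs, ld: LDSource, config: MRConfig) -> ScreenResult:
    results: dict[str, BatteryResult] = {}
    failures: dict[str, str] = {}
    for trait, exposure, outcome in pairs:
        try:
            results[trait] = run_mr_battery(exposure, outcome, ld, config)
        except Exception as exc:
            logger.warning("battery failed for %s: %s", trait, exc)
            failures[trait] = f"battery_failed: {exc}"
    audit, survivors = _filter_cascade(results, failures, config)
    return ScreenResult(results=results, failures=failures,
                        audit=audit, survivors=survivors)


def step1_screen(metabolites: Mapping[str, SumStats], outcome: SumStats,
                 ld: LDSource, config: MRConfig | None = None) -> ScreenResult:
    """Screen many candidate exposures (metabolites) against one outcome."""
    config = config or MRConfig()
    pairs = [(name, stats, outcome) for name, stats in metabolites.items()]
    return _screen(pairs, ld, config)


def step2_screen(adiposity: SumStats, metabolites: Mapping[str, SumStats],
                 ld: LDSource, config: MRConfig | None = None) -> ScreenResult:
    """Screen one exposure against many outcomes (the step-1 survivors)."""
    config = config or MRConfig()
    pairs = [(name, adiposity, stats) for name, stats in metabolites.items()]
    return _screen(pairs, ld, config)


@dataclass
class ValidationVerdict:
    """Did an alternative exposure reproduce the exposure→mediator effect?"""

    battery: BatteryResult
    significant: bool
    direction_consistent: bool
    no_heterogeneity: bool
    no_pleiotropy: bool
    no_reverse_signal: bool

    @property
    def passed(self) -> bool:
        return (self.significant and self.direction_consistent
                and self.no_heterogeneity and self.no_pleiotropy
                and self.no_reverse_signal)


def validate_exposure_swap(alt_exposure: SumStats, mediator: SumStats,
                           ld: LDSource,
                           config: MRConfig | None = None) -> ValidationVerdict:
    """Re-run one battery with a proxy exposure and apply the full verdict."""
    config = config or MRConfig()
    r = run_mr_battery(alt_exposure, mediator, ld, config)
    v = r.sensitivity.verdicts(config.alpha)
    return ValidationVerdict(
        battery=r,
        significant=bool(r.ivw is not None and r.ivw.pvalue < config.alpha),
        direction_consistent=v["direction_consistent"],
        no_heterogeneity=v["no_heterogeneity"],
        no_pleiotropy=v["no_pleiotropy"],
        no_reverse_signal=v["no_reverse_signal"])


def estimate_mediation(exposure: SumStats, mediator: SumStats,
                       outcome: SumStats, ld: LDSource,
                       config: MRConfig | None = None,
                       full_delta: bool = False,
                       run_reverse: bool = False,
                       mediator_config: MRConfig | None = None
                       ) -> tuple[MediationResult, dict[str, BatteryResult]]:
    """Three IVW legs (E→M, M→O, E→O) + product of coefficients.

    ``mediator_config`` lets the mediator→outcome leg use its own instrument
    threshold (metabolite GWAS rarely have genome-wide hits at 5e-8).
    """
    config = config or MRConfig()
    mcfg = mediator_config or config
    legs = {
        "exposure_mediator": run_mr_battery(exposure, mediator, ld, config,
                                            run_reverse=run_reverse),
        "mediator_outcome": run_mr_battery(mediator, outcome, ld, mcfg,
                                           run_reverse=run_reverse),
        "exposure_outcome": run_mr_battery(exposure, outcome, ld, config,
                                           run_reverse=run_reverse),
    }
    em = legs["exposure_mediator"].ivw
    mo = legs["mediator_outcome"].ivw
    eo = legs["exposure_outcome"].ivw
    med = product_of_coefficients(em.beta, em.se, mo.beta, mo.se,
                                  eo.beta, eo.se, full_delta=full_delta)
    return med, legs
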