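"""Simulation studies that calibrate the pipeline against generator truth.

Each study repeatedly simulates summary statistics with
:mod:`mrmediate.simulate`, runs the real pipeline stages on them, and
measures an operating characteristic: the false-positive rate of the
primary IVW screen under a global null, the coverage of the IVW interval
under a homogeneous causal effect, recovery of the true mediation
proportion, and sensitivity/specificity of the full screening cascade.

Replicate triads are kept deliberately small (a few hundred panel variants)
so thousands of replicates run in seconds; the operating characteristics
being measured do not depend on panel size once the instrument counts and
per-variant strengths are fixed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import estimators as est
from .cascade import step1_screen
from .config import MRConfig
from .harmonize import harmonize, kept
from .instruments import select_instruments
from .simulate import TriadModel, simulate_metabolome, simulate_triad


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


#: Small panel used by the replicate studies: the default instrument blocks
#: plus a margin of null variants.
def _study_model(**overrides) -> TriadModel:
    base = dict(n_variants=160, n_instruments_e=100, n_instruments_m=15,
                allele_scramble=False)
    base.update(overrides)
    return TriadModel(**base)


def _ivw_arm(exposure, outcome, ld, config: MRConfig) -> est.MREstimate | None:
    """select → clump → F-filter → harmonize → IVW, or None if impossible."""
    iv, _ = select_instruments(
        exposure, ld, p_threshold=config.p_instrument, r2_max=config.clump_r2,
        window_bp=config.clump_window_bp, f_min=config.f_min)
    if len(iv) == 0:
        return None
    h = kept(harmonize(iv, outcome, config.policy))
    if len(h) == 0:
        return None
    return est.ivw(h, model=config.ivw_model)


def type1_error_study(n_reps: int = 1000, seed: int = 0,
                      config: MRConfig | None = None) -> dict:
    """Pass rate of the IVW significance stage under the global null.

    Simulates triads with a = b = c_direct = 0 (instrumented exposure, no
    downstream effects) and reports the fraction of replicates whose
    exposure→outcome IVW p-value falls below α. Nominally 5%; the
    multiplicative random-effects floor makes the primary IVW slightly
    conservative.
    """
    config = config or MRConfig()
    model = _study_model(a=0.0, b=0.0, c_direct=0.0)
    hits = 0
    used = 0
    for s in _spawn_seeds(seed, n_reps):
        sim = simulate_triad(replace(model, seed=int(s)))
        e = _ivw_arm(sim.exposure, sim.outcome, sim.ld, config)
        if e is None:
            continue
        used += 1
        hits += bool(e.pvalue < config.alpha)
    return {"rate": hits / used, "alpha": config.alpha, "n": used}


def ivw_coverage_study(n_reps: int = 2000, seed: int = 0,
                       true_effect: float = 0.5,
                       config: MRConfig | None = None) -> dict:
    """Empirical coverage of the IVW 95% CI under a homogeneous effect.

    The exposure acts on the outcome only directly (no mediation, no
    pleiotropy, no extra heterogeneity), so every instrument estimates the
    same causal effect and the nominal interval should cover it 95% of the
    time.
    """
    config = config or MRConfig()
    model = _study_model(a=0.0, b=0.0, c_direct=true_effect)
    covered = 0
    used = 0
    for s in _spawn_seeds(seed, n_reps):
        sim = simulate_triad(replace(model, seed=int(s)))
        e = _ivw_arm(sim.exposure, sim.outcome, sim.ld, config)
        if e is None:
            continue
        used += 1
        covered += bool(e.ci_low <= true_effect <= e.ci_high)
    return {"coverage": covered / used, "true_effect": true_effect, "n": used}


def mediation_recovery_study(n_reps: int = 500, seed: int = 0,
                             a: float = 0.2, b: float = 0.3,
                             c_direct: float = 0.3,
                             config: MRConfig | None = None) -> dict:
    """Recovery of the true mediation proportion a·b/(a·b + c_direct).

    Each replicate estimates the three legs by IVW (exposure instruments
    for E→M and E→O, mediator instruments for M→O) and forms the
    product-of-coefficients proportion; the study reports the median across
    replicates, which under the default settings should sit within a few
    percentage points of the generator truth.
    """
    from .mediation import product_of_coefficients

    config = config or MRConfig()
    model = _study_model(a=a, b=b, c_direct=c_direct)
    truth_pct = 100.0 * model.true_proportion
    props = []
    for s in _spawn_seeds(seed, n_reps):
        sim = simulate_triad(replace(model, seed=int(s)))
        em = _ivw_arm(sim.exposure, sim.mediator, sim.ld, config)
        mo = _ivw_arm(sim.mediator, sim.outcome, sim.ld, config)
        eo = _ivw_arm(sim.exposure, sim.outcome, sim.ld, config)
        if em is None or mo is None or eo is None:
            continue
        med = product_of_coefficients(em.beta, em.se, mo.beta, mo.se,
                                      eo.beta, eo.se)
        props.append(100.0 * med.proportion)
    return {"median_proportion_pct": float(np.median(props)),
            "true_proportion_pct": truth_pct, "n": len(props)}


def cascade_recovery_study(n_reps: int = 100, seed: int = 0, k: int = 20,
                           n_causal: int = 3,
                           config: MRConfig | None = None) -> dict:
    """Sensitivity/specificity of the step-1 screen on a known metabolome.

    ``k`` synthetic metabolites, the first ``n_causal`` causal on the
    outcome at the generator's default strength; a replicate counts as a
    joint success when the survivor set equals the causal set exactly.
    """
    config = config or MRConfig(n_boot=200)
    causal = tuple(range(1, n_causal + 1))
    base = TriadModel(allele_scramble=False)
    exact = 0
    all_found = 0
    false_pos = 0
    for s in _spawn_seeds(seed, n_reps):
        sim = simulate_metabolome(replace(base, seed=int(s)), k=k,
                                  causal_ids=causal)
        res = step1_screen(sim.metabolites, sim.outcome, sim.ld, config)
        got = {int(n[3:]) for n in res.survivors}
        exact += got == set(causal)
        all_found += set(causal) <= got
        false_pos += len(got - set(causal))
    return {"joint_success_rate": exact / n_reps,
            "sensitivity_all_causal_rate": all_found / n_reps,
            "false_survivors_per_rep": false_pos / n_reps,
            "k": k, "n_causal": n_causal, "n": n_reps}
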