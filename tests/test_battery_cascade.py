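import numpy as np
import pytest

from mrmediate import (MRConfig, TriadModel, estimate_mediation, run_mr_battery,
                       simulate_metabolome, simulate_triad, step1_screen,
                       step2_screen, validate_exposure_swap)
from mrmediate.validation import _spawn_seeds

CFG = MRConfig(n_boot=100, seed=0)


def _triads(n, seed, **model_kw):
    from dataclasses import replace
    base = TriadModel(n_variants=160, allele_scramble=False, **model_kw)
    for s in _spawn_seeds(seed, n):
        yield simulate_triad(replace(base, seed=int(s)))


class TestBattery:
    def test_full_battery_fields(self, triad):
        r = run_mr_battery(triad.exposure, triad.outcome, triad.ld, CFG)
        assert set(r.estimates) == {"ivw", "egger", "weighted_median",
                                    "simple_mode", "weighted_mode"}
        assert r.sensitivity.q_df == r.n_instruments - 1
        assert r.sensitivity.q_stat >= 0
        assert r.ivw.odds_ratio == pytest.approx(np.exp(r.ivw.beta))
        table = r.estimates_table()
        assert len(table) == 5 and table["n_snps"].nunique() == 1

    def test_ci_covers_true_effect_usually(self):
        """Under a clean direct effect the IVW interval should cover the
        truth in the vast majority of replicates (full coverage calibration
        is a dedicated study)."""
        hits = 0
        for sim in _triads(40, 1, a=0, b=0, c_direct=0.5):
            r = run_mr_battery(sim.exposure, sim.outcome, sim.ld, CFG,
                               run_reverse=False)
            hits += r.ivw.ci_low <= 0.5 <= r.ivw.ci_high
        assert hits >= 33

    def test_egger_intercept_quiet_without_pleiotropy(self):
        quiet = 0
        for sim in _triads(40, 2, a=0, b=0, c_direct=0.5):
            r = run_mr_battery(sim.exposure, sim.outcome, sim.ld, CFG,
                               run_reverse=False)
            quiet += r.sensitivity.egger_intercept_pvalue > 0.05
        assert quiet >= 30

    def test_reverse_causation_detected(self):
        """When the 'mediator' is driven by the outcome, the reverse arm
        must flag it with high power."""
        flagged = 0
        for sim in _triads(20, 3, a=0.0, b=0.0, reverse_frac=1.0):
            r = run_mr_battery(sim.mediator, sim.outcome, sim.ld, CFG)
            flagged += r.sensitivity.reverse_pvalue < 0.05
        assert flagged >= 16

    def test_battery_propagates_stage_failure(self, triad):
        from mrmediate.exceptions import InsufficientInstrumentsError
        from dataclasses import replace
        starved = replace(CFG, p_instrument=1e-300)
        with pytest.raises(InsufficientInstrumentsError, match="no instruments"):
            run_mr_battery(triad.exposure, triad.outcome, triad.ld, starved)

    def test_deterministic_given_seed(self, triad):
        a = run_mr_battery(triad.exposure, triad.outcome, triad.ld, CFG, seed=5)
        b = run_mr_battery(triad.exposure, triad.outcome, triad.ld, CFG, seed=5)
        for m in a.estimates:
            assert a.estimates[m].se == b.estimates[m].se


class TestCascade:
    def test_audit_conserves_and_composes(self):
        sim = simulate_metabolome(TriadModel(seed=6), k=8, causal_ids=(1, 2))
        res = step1_screen(sim.metabolites, sim.outcome, sim.ld, CFG)
        stages = res.audit
        assert [s.stage_name for s in stages] == [
            "ivw_significance", "direction_consistency", "pleiotropy",
            "heterogeneity", "reverse_causality"]
        assert stages[0].entering == 8
        for s in stages:
            assert s.passing + len(s.dropped_ids) == s.entering
        for prev, nxt in zip(stages, stages[1:]):
            assert nxt.entering == prev.passing
        assert len(res.survivors) == stages[-1].passing
        total_dropped = sum(len(s.dropped_ids) for s in stages)
        assert total_dropped + len(res.survivors) == 8

    def test_causal_metabolites_found(self):
        sim = simulate_metabolome(TriadModel(seed=41), k=8, causal_ids=(1, 2))
        res = step1_screen(sim.metabolites, sim.outcome, sim.ld, CFG)
        sig_stage = res.audit[0]
        entered_sig = {"met1", "met2"} - set(sig_stage.dropped_ids)
        assert entered_sig == {"met1", "met2"}  # both clear the IVW stage

    def test_pleiotropic_metabolite_dropped_at_pleiotropy_stage(self):
        base = TriadModel(seed=9, pleiotropy_mean=0.12, pleiotropy_sd=0.03)
        hits = 0
        for s in _spawn_seeds(10, 10):
            from dataclasses import replace
            sim = simulate_metabolome(replace(base, seed=int(s)), k=3,
                                      pleiotropic_ids=(1,))
            res = step1_screen(sim.metabolites, sim.outcome, sim.ld, CFG)
            dropped_pleio = "met1" in res.audit[2].dropped_ids
            hits += dropped_pleio or "met1" not in res.survivors
        assert hits >= 9  # directional pleiotropy must not survive

    def test_heterogeneous_metabolite_excluded(self):
        from dataclasses import replace
        base = TriadModel(seed=14, het_inflation=1.0)
        excluded = 0
        for s in _spawn_seeds(20, 8):
            sim = simulate_metabolome(replace(base, seed=int(s)), k=3,
                                      causal_ids=(1,), het_ids=(1,),
                                      het_factor=8.0)
            res = step1_screen(sim.metabolites, sim.outcome, sim.ld, CFG)
            excluded += "met1" not in res.survivors
        assert excluded >= 6

    def test_reverse_metabolite_dropped_at_reverse_stage(self):
        from dataclasses import replace
        base = TriadModel(seed=15)
        flagged = 0
        for s in _spawn_seeds(30, 8):
            sim = simulate_metabolome(replace(base, seed=int(s)), k=3,
                                      reverse_ids=(1,))
            res = step1_screen(sim.metabolites, sim.outcome, sim.ld, CFG)
            if "met1" in res.audit[-1].dropped_ids:
                flagged += 1
            elif "met1" not in res.survivors:
                flagged += 1  # fell at an earlier stage this replicate
        assert flagged >= 7

    def test_empty_metabolome_is_wellformed(self):
        sim = simulate_metabolome(TriadModel(seed=2), k=2)
        res = step1_screen({}, sim.outcome, sim.ld, CFG)
        assert res.survivors == []
        assert all(s.entering == 0 for s in res.audit)

    def test_step2_roles_swapped(self):
        """Step 2 uses the adiposity trait as the exposure against each
        metabolite; with a > 0 the causal mediator is recovered."""
        sim = simulate_triad(TriadModel(seed=21, a=0.35, b=0.0, c_direct=0.0,
                                        allele_scramble=False))
        cfg = MRConfig(n_boot=100, p_instrument=5e-8)
        res = step2_screen(sim.exposure, {"mediator": sim.mediator}, sim.ld, cfg)
        r = res.results["mediator"]
        assert r.ivw.pvalue < 0.05
        assert r.ivw.beta == pytest.approx(0.35, abs=4 * r.ivw.se)

    def test_battery_failure_becomes_drop_not_abort(self):
        sim = simulate_metabolome(TriadModel(seed=33), k=2, causal_ids=(1,))
        # a metabolite with no signal at an impossible threshold still screens
        from dataclasses import replace
        cfg = replace(CFG, p_instrument=1e-200)
        res = step1_screen(sim.metabolites, sim.outcome, sim.ld, cfg)
        assert res.survivors == []
        assert set(res.audit[0].dropped_ids) == {"met1", "met2"}
        assert all("battery_failed" in v for v in res.audit[0].dropped_ids.values())


class TestValidationSwap:
    def test_same_true_effect_concordant(self):
        sim = simulate_triad(TriadModel(seed=25, a=0.3, allele_scramble=False))
        v = validate_exposure_swap(sim.exposure, sim.mediator, sim.ld, CFG)
        assert v.significant and v.battery.ivw.beta > 0

    def test_null_alt_exposure_not_significant(self):
        hits = 0
        for sim in _triads(10, 26, a=0.0, b=0.0, c_direct=0.0):
            v = validate_exposure_swap(sim.exposure, sim.mediator, sim.ld, CFG)
            hits += v.significant
        assert hits <= 2

    def test_deterministic(self):
        sim = simulate_triad(TriadModel(seed=27, a=0.3, allele_scramble=False))
        a = validate_exposure_swap(sim.exposure, sim.mediator, sim.ld, CFG)
        b = validate_exposure_swap(sim.exposure, sim.mediator, sim.ld, CFG)
        assert a.passed == b.passed
        assert a.battery.ivw.beta == b.battery.ivw.beta


def test_estimate_mediation_identity_and_signs(triad):
    med, legs = estimate_mediation(triad.exposure, triad.mediator,
                                   triad.outcome, triad.ld, CFG)
    assert med.proportion * med.beta_eo == pytest.approx(med.indirect, rel=1e-12)
    assert set(legs) == {"exposure_mediator", "mediator_outcome",
                         "exposure_outcome"}
    assert np.isfinite(med.indirect_se) and med.indirect_se > 0
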