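"""Synthetic GWAS summary statistics with a known causal structure.

The generator emulates the statistical structure of the real inputs a
two-step screen consumes — a very large continuous adiposity GWAS, a
moderately sized metabolite GWAS, and a heavily imbalanced case-control
outcome GWAS — without any genotype-level simulation:

* a panel of independent variants on one synthetic chromosome with uniform
  1 Mb spacing (so clumping windows are exercised) and allele frequencies
  drawn uniformly from ``maf_range``;
* a true exposure → mediator → outcome chain with effects ``a`` (E→M),
  ``b`` (M→O) and a direct ``c_direct`` (E→O); the generator's true total
  effect is a·b + c_direct and the true mediation proportion a·b/(a·b+c');
* per-variant observed effects = true effects + N(0, se) with
  se = 1/√(2·N·EAF(1−EAF)) per trait — the standard summary-statistic
  sampling model for a standardized continuous trait; the binary outcome
  uses an effective sample size 4/(1/cases + 1/controls) so extreme
  case-control imbalance widens its intervals exactly as in real data;
* contamination channels: directional pleiotropy (a fraction of exposure
  instruments gain outcome effects aligned with their exposure-effect sign,
  so the Egger intercept can see them), excess heterogeneity (outcome noise
  inflated relative to the reported SE) and reverse-causal instruments
  (variants that drive the outcome directly, with the "mediator" responding
  downstream).

All randomness flows from one seed through named substreams, so the same
model yields bit-identical tables every time.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from .instruments import LDSource
from .sumstats import SumStats

_ALLELE_PAIRS = [(a, b) for a in "ACGT" for b in "ACGT" if a != b]


@dataclass
class TriadModel:
    """Parameters of one exposure–mediator–outcome simulation.

    Sample-size defaults mirror the data scale the pipeline targets: a
    330,762-person continuous adiposity GWAS, an 8,299-person metabolite
    GWAS and an 855-case / 345,118-control disease GWAS. Effect-size ranges
    are chosen so instruments clear genome-wide selection at those sample
    sizes with realistic strength (exposure |β| 0.02–0.06 SD ≈ single-digit
    percent variance explained across ~100 hits; metabolite |β| 0.15–0.35 SD
    for a handful of hits).
    """

    n_variants: int = 400
    n_instruments_e: int = 100
    n_instruments_m: int = 15
    maf_range: tuple[float, float] = (0.05, 0.5)
    beta_e_range: tuple[float, float] = (0.02, 0.06)
    beta_m_range: tuple[float, float] = (0.15, 0.35)
    beta_o_range: tuple[float, float] = (0.20, 0.35)
    a: float = 0.2
    b: float = 0.3
    c_direct: float = 0.3
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.1
    pleiotropy_sd: float = 0.05
    het_inflation: float = 1.0
    reverse_frac: float = 0.0
    reverse_scale: float = 0.8
    n_e: int = 330_762
    n_m: int = 8_299
    n_o_cases: int = 855
    n_o_controls: int = 345_118
    allele_scramble: bool = True
    ld_block: tuple[int, float] | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("pleiotropy_frac", "reverse_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        for name in ("n_variants", "n_e", "n_m", "n_o_cases", "n_o_controls"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_instruments_e + self.n_instruments_m > self.n_variants:
            raise ValueError("n_variants must cover all instrument blocks")
        if self.het_inflation < 1.0:
            raise ValueError("het_inflation must be >= 1")

    @property
    def n_o(self) -> int:
        return self.n_o_cases + self.n_o_controls

    @property
    def n_o_effective(self) -> float:
        """Effective sample size of the case-control outcome GWAS."""
        return 4.0 / (1.0 / self.n_o_cases + 1.0 / self.n_o_controls)

    @property
    def true_total(self) -> float:
        return self.a * self.b + self.c_direct

    @property
    def true_proportion(self) -> float:
        if self.true_total == 0:
            return np.nan
        return self.a * self.b / self.true_total


@dataclass
class TriadTruth:
    """Per-variant roles and true effects, plus the model's identities."""

    model: TriadModel
    variant_id: list[str]
    role: list[str]
    true_beta_e: np.ndarray
    true_beta_m: np.ndarray
    true_beta_o: np.ndarray
    true_total: float
    true_proportion: float

    def to_json(self, path) -> None:
        payload = {
            "model": {k: (list(v) if isinstance(v, tuple) else v)
                      for k, v in asdict(self.model).items()},
            "true_total": self.true_total,
            "true_proportion": self.true_proportion,
            "variants": [
                {"variant_id": v, "role": r, "beta_e": float(be),
                 "beta_m": float(bm), "beta_o": float(bo)}
                for v, r, be, bm, bo in zip(
                    self.variant_id, self.role, self.true_beta_e,
                    self.true_beta_m, self.true_beta_o)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class SimulatedTriad:
    exposure: SumStats
    mediator: SumStats
    outcome: SumStats
    ld: LDSource
    truth: TriadTruth


def _signed_uniform(rng, lo, hi, size):
    mag = rng.uniform(lo, hi, size)
    sign = rng.choice([-1.0, 1.0], size)
    return mag * sign


def _pvalues(beta, se):
    p = 2.0 * st.norm.sf(np.abs(beta) / se)
    return np.clip(p, 5e-324, 1.0)


def _observed_eaf(rng, maf, n):
    noise = rng.normal(0.0, np.sqrt(maf * (1.0 - maf) / (2.0 * n)))
    return np.clip(maf + noise, 1e-3, 1.0 - 1e-3)


def _trait_frame(rng, ids, pos, ea, oa, maf, true_beta, se, n, scramble):
    """Observed summary statistics for one trait over the panel.

    When ``scramble`` is set the reported allele orientation / strand is
    randomized per variant (the underlying association is unchanged), so
    harmonization has real work to do.
    """
    beta = true_beta + rng.normal(0.0, se)
    eaf = _observed_eaf(rng, maf, n)
    ea, oa = np.array(ea, dtype=object), np.array(oa, dtype=object)
    if scramble:
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        swap = rng.random(len(ids)) < 0.3
        beta = np.where(swap, -beta, beta)
        eaf = np.where(swap, 1.0 - eaf, eaf)
        ea2 = np.where(swap, oa, ea)
        oa2 = np.where(swap, ea, oa)
        flip = rng.random(len(ids)) < 0.3
        ea = np.array([comp[x] if f else x for x, f in zip(ea2, flip)], dtype=object)
        oa = np.array([comp[x] if f else x for x, f in zip(oa2, flip)], dtype=object)
    return pd.DataFrame({
        "variant_id": ids, "chr": "1", "pos": pos, "ea": ea, "oa": oa,
        "eaf": eaf, "beta": beta, "se": se,
        "pval": _pvalues(beta, se), "n": int(n),
    })


def _panel(rng, m: TriadModel):
    ids = [f"sv{i + 1}" for i in range(m.n_variants)]
    pos = (np.arange(m.n_variants) + 1) * 1_000_000
    maf = rng.uniform(*m.maf_range, m.n_variants)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), m.n_variants)
    ea = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oa = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    return ids, pos, maf, ea, oa


def _ld_for_panel(ids, ld_block):
    if ld_block is None:
        return LDSource(domain=set(ids))
    size, r2 = ld_block
    pairs = {}
    for start in range(0, len(ids), size):
        block = ids[start:start + size]
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                pairs[(block[i], block[j])] = r2
    return LDSource(pairs=pairs, domain=set(ids))


def simulate_triad(model: TriadModel) -> SimulatedTriad:
    """Simulate one exposure/mediator/outcome GWAS triad plus LD and truth."""
    m = model
    ss = np.random.SeedSequence(m.seed)
    rng_panel, rng_eff, rng_e, rng_m, rng_o = (
        np.random.default_rng(c) for c in ss.spawn(5))

    ids, pos, maf, ea, oa = _panel(rng_panel, m)
    nv = m.n_variants
    ne, nm = m.n_instruments_e, m.n_instruments_m
    n_rev = int(round(m.reverse_frac * nm))

    role = np.array(["null"] * nv, dtype=object)
    role[:ne] = "exposure_instrument"
    role[ne:ne + nm - n_rev] = "mediator_instrument"
    role[ne + nm - n_rev:ne + nm] = "reverse_instrument"

    gamma_e = np.zeros(nv)
    gamma_e[:ne] = _signed_uniform(rng_eff, *m.beta_e_range, ne)
    delta_m = np.zeros(nv)
    delta_m[ne:ne + nm - n_rev] = _signed_uniform(
        rng_eff, *m.beta_m_range, nm - n_rev)
    delta_o = np.zeros(nv)
    delta_o[ne + nm - n_rev:ne + nm] = _signed_uniform(
        rng_eff, *m.beta_o_range, n_rev)

    pleio = np.zeros(nv)
    n_pleio = int(round(m.pleiotropy_frac * ne))
    if n_pleio:
        which = rng_eff.choice(ne, n_pleio, replace=False)
        raw = rng_eff.normal(m.pleiotropy_mean, m.pleiotropy_sd, n_pleio)
        # align with the exposure-effect sign so the pleiotropy is
        # directional after the bx >= 0 Egger orientation
        pleio[which] = np.sign(gamma_e[which]) * raw
        role[which] = "pleiotropic_instrument"

    true_e = gamma_e
    forward_m = m.a * gamma_e + delta_m  # mediator variation heritable via E or own loci
    true_m = forward_m + m.reverse_scale * delta_o
    true_o = m.b * forward_m + m.c_direct * gamma_e + pleio + delta_o

    se_e = 1.0 / np.sqrt(2.0 * m.n_e * maf * (1.0 - maf))
    se_m = 1.0 / np.sqrt(2.0 * m.n_m * maf * (1.0 - maf))
    se_o = 1.0 / np.sqrt(2.0 * m.n_o_effective * maf * (1.0 - maf))

    exposure = SumStats("exposure", "continuous", _trait_frame(
        rng_e, ids, pos, ea, oa, maf, true_e, se_e, m.n_e, False))
    mediator = SumStats("mediator", "continuous", _trait_frame(
        rng_m, ids, pos, ea, oa, maf, true_m, se_m, m.n_m, m.allele_scramble))
    out_df = _trait_frame(
        rng_o, ids, pos, ea, oa, maf, true_o, se_o * np.sqrt(m.het_inflation),
        m.n_o, m.allele_scramble)
    # reported SE stays nominal; only the sampling noise was inflated
    out_df["se"] = se_o
    out_df["pval"] = _pvalues(out_df["beta"].to_numpy(), se_o)
    outcome = SumStats("outcome", "binary", out_df)

    truth = TriadTruth(model=m, variant_id=ids, role=list(role),
                       true_beta_e=true_e, true_beta_m=true_m,
                       true_beta_o=true_o, true_total=m.true_total,
                       true_proportion=m.true_proportion)
    return SimulatedTriad(exposure, mediator, outcome,
                          _ld_for_panel(ids, m.ld_block), truth)


@dataclass
class SimulatedMetabolome:
    """A panel-wide outcome GWAS plus one GWAS per synthetic metabolite."""

    metabolites: dict[str, SumStats]
    outcome: SumStats
    ld: LDSource
    truth: dict = field(default_factory=dict)


def simulate_metabolome(base: TriadModel, k: int, causal_ids=(),
                        pleiotropic_ids=(), het_ids=(), reverse_ids=(),
                        n_null_variants: int = 50,
                        het_factor: float = 6.0) -> SimulatedMetabolome:
    """Simulate ``k`` metabolite GWAS sharing one outcome GWAS.

    Each metabolite owns a block of ``base.n_instruments_m`` instrument
    variants on the shared panel. Metabolites listed in ``causal_ids``
    (1-based) causally raise/lower the outcome with effect ``base.b``;
    ``pleiotropic_ids`` get sign-aligned direct outcome effects at their
    instruments instead of a causal path; ``het_ids`` get outcome sampling
    noise inflated by ``het_factor`` at their instruments; ``reverse_ids``
    are *driven by* the outcome (their block variants act on the outcome
    directly, the metabolite responding with ``base.reverse_scale``).
    """
    causal = set(causal_ids)
    pleio_ids = set(pleiotropic_ids)
    hets = set(het_ids)
    revs = set(reverse_ids)
    for s, name in ((causal, "causal_ids"), (pleio_ids, "pleiotropic_ids"),
                    (hets, "het_ids"), (revs, "reverse_ids")):
        if not s <= set(range(1, k + 1)):
            raise ValueError(f"{name} must be a subset of 1..{k}")

    m = base
    nm = m.n_instruments_m
    nv = k * nm + n_null_variants
    ss = np.random.SeedSequence(m.seed)
    children = ss.spawn(3 + k)
    rng_panel = np.random.default_rng(children[0])
    rng_eff = np.random.default_rng(children[1])
    rng_o = np.random.default_rng(children[2])

    panel_model = TriadModel(**{**asdict(m), "n_variants": nv,
                                "n_instruments_e": 0, "n_instruments_m": 0,
                                "ld_block": None})
    ids, pos, maf, ea, oa = _panel(rng_panel, panel_model)
    se_m = 1.0 / np.sqrt(2.0 * m.n_m * maf * (1.0 - maf))
    se_o = 1.0 / np.sqrt(2.0 * m.n_o_effective * maf * (1.0 - maf))

    blocks = {j: slice((j - 1) * nm, j * nm) for j in range(1, k + 1)}
    delta = {}
    true_o = np.zeros(nv)
    o_noise_sd = se_o.copy()
    truth: dict = {"true_total": None, "metabolites": {}}

    for j in range(1, k + 1):
        d = _signed_uniform(rng_eff, *m.beta_m_range, nm)
        delta[j] = d
        sl = blocks[j]
        label = "null"
        if j in revs:
            label = "reverse"
            true_o[sl] += d  # block variants drive the outcome directly
        elif j in causal:
            label = "causal"
            true_o[sl] += m.b * d
        if j in pleio_ids:
            label = label + "+pleiotropic" if label != "null" else "pleiotropic"
            raw = rng_eff.normal(m.pleiotropy_mean, m.pleiotropy_sd, nm)
            true_o[sl] += np.sign(d) * raw
        if j in hets:
            label = label + "+heterogeneous" if label != "null" else "heterogeneous"
            o_noise_sd[sl] *= np.sqrt(het_factor)
        truth["metabolites"][j] = {"label": label, "b": m.b if j in causal else 0.0}

    out_df = _trait_frame(rng_o, ids, pos, ea, oa, maf, true_o, o_noise_sd,
                          m.n_o, m.allele_scramble)
    out_df["se"] = se_o
    out_df["pval"] = _pvalues(out_df["beta"].to_numpy(), se_o)
    outcome = SumStats("outcome", "binary", out_df)

    metabolites = {}
    for j in range(1, k + 1):
        rng_j = np.random.default_rng(children[2 + j])
        true_m = np.zeros(nv)
        sl = blocks[j]
        if j in revs:
            true_m[sl] = m.reverse_scale * delta[j]
        else:
            true_m[sl] = delta[j]
        name = f"met{j}"
        metabolites[name] = SumStats(name, "continuous", _trait_frame(
            rng_j, ids, pos, ea, oa, maf, true_m, se_m, m.n_m, False))

    return SimulatedMetabolome(metabolites=metabolites, outcome=outcome,
                               ld=_ld_for_panel(ids, m.ld_block), truth=truth)
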