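"""Allele harmonization of exposure and outcome summary statistics.

Two GWAS may report the same variant with the effect allele on either side
and on either DNA strand. Harmonization puts every instrument's exposure and
outcome effects on a shared effect-allele orientation:

* alleles identical → keep as-is (``kept_same``);
* outcome alleles swapped → negate the outcome beta, complement its
  frequency (``kept_flipped``);
* outcome alleles on the complementary strand (A↔T, C↔G per allele) →
  re-match after complementing (``kept_strand_flipped``; a combined
  strand-flip + swap also carries the sign change, recorded in the
  ``sign_flipped`` column);
* palindromic variants (A/T or C/G) cannot be strand-resolved from alleles
  alone — the policy either drops them all or resolves them by allele
  frequency, dropping those whose frequencies sit inside the ambiguity band
  around 0.5 or are missing;
* anything else → ``dropped_mismatch``; instruments absent from the outcome
  → ``dropped_missing``.

The output is a per-instrument audit table; every input instrument appears
exactly once with its action, so kept + dropped always equals the input
count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sumstats import SumStats

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

KEPT_ACTIONS = ("kept_same", "kept_flipped", "kept_strand_flipped")


def is_palindromic(ea: str, oa: str) -> bool:
    """True for A/T and C/G variants (allele pair is its own complement)."""
    return _COMP.get(ea) == oa


@dataclass
class HarmonizationPolicy:
    """How to treat palindromic variants and strand flips.

    ``palindrome_handling`` is ``"resolve_by_eaf"`` (orient by comparing
    frequencies, dropping when both lie within ``eaf_ambiguity_band`` of 0.5
    or either is missing) or ``"drop_all"``. ``allow_strand_flip`` permits
    complement-strand re-matching for non-palindromic variants.
    """

    palindrome_handling: str = "resolve_by_eaf"
    eaf_ambiguity_band: float = 0.08
    allow_strand_flip: bool = True

    def __post_init__(self):
        if self.palindrome_handling not in ("resolve_by_eaf", "drop_all"):
            raise ValueError(f"unknown palindrome_handling {self.palindrome_handling!r}")
        if not 0.0 < self.eaf_ambiguity_band < 0.5:
            raise ValueError("eaf_ambiguity_band must be in (0, 0.5)")


_DROPPED_TEMPLATE = dict(bx=np.nan, sx=np.nan, px=np.nan, eafx=np.nan,
                         by=np.nan, sy=np.nan, py=np.nan, eafy=np.nan,
                         sign_flipped=False)


def harmonize(exposure: SumStats, outcome: SumStats,
              policy: HarmonizationPolicy | None = None) -> pd.DataFrame:
    """Align each exposure instrument with its outcome record.

    Returns the audit table with one row per exposure instrument:
    ``variant_id, action, sign_flipped, bx, sx, px, eafx, by, sy, py, eafy``.
    Kept rows carry both effect pairs on the exposure's effect-allele
    orientation; dropped rows carry no effect fields.
    """
    policy = policy or HarmonizationPolicy()
    out_by_id = {r.variant_id: r for r in outcome.df.itertuples(index=False)}
    band_lo, band_hi = 0.5 - policy.eaf_ambiguity_band, 0.5 + policy.eaf_ambiguity_band

    rows = []
    for e in exposure.df.itertuples(index=False):
        rec = {"variant_id": e.variant_id, **_DROPPED_TEMPLATE}
        o = out_by_id.get(e.variant_id)
        if o is None:
            rec["action"] = "dropped_missing"
            rows.append(rec)
            continue

        by, eafy = float(o.beta), float(o.eaf) if pd.notna(o.eaf) else np.nan
        action = None
        sign_flipped = False

        if is_palindromic(e.ea, e.oa):
            if {o.ea, o.oa} != {e.ea, e.oa}:
                action = "dropped_mismatch"
            elif policy.palindrome_handling == "drop_all":
                action = "dropped_palindromic"
            else:
                # Label-align first, then use frequencies to detect a strand
                # flip (which for a palindrome masquerades as a swap).
                if (o.ea, o.oa) == (e.oa, e.ea):
                    by, eafy = -by, 1.0 - eafy
                    sign_flipped = not sign_flipped
                eafx = float(e.eaf) if pd.notna(e.eaf) else np.nan
                if np.isnan(eafx) or np.isnan(eafy):
                    action = "dropped_palindromic"
                elif band_lo <= eafx <= band_hi and band_lo <= eafy <= band_hi:
                    action = "dropped_palindromic"
                else:
                    if (eafx < 0.5) != (eafy < 0.5):
                        by, eafy = -by, 1.0 - eafy
                        sign_flipped = not sign_flipped
                    action = "kept_flipped" if sign_flipped else "kept_same"
        else:
            if (o.ea, o.oa) == (e.ea, e.oa):
                action = "kept_same"
            elif (o.ea, o.oa) == (e.oa, e.ea):
                by, eafy = -by, 1.0 - eafy
                sign_flipped = True
                action = "kept_flipped"
            elif policy.allow_strand_flip:
                c_ea, c_oa = _COMP[o.ea], _COMP[o.oa]
                if (c_ea, c_oa) == (e.ea, e.oa):
                    action = "kept_strand_flipped"
                elif (c_oa, c_ea) == (e.ea, e.oa):
                    by, eafy = -by, 1.0 - eafy
                    sign_flipped = True
                    action = "kept_strand_flipped"
                else:
                    action = "dropped_mismatch"
            else:
                action = "dropped_mismatch"

        rec["action"] = action
        if action in KEPT_ACTIONS:
            rec.update(bx=float(e.beta), sx=float(e.se), px=float(e.pval),
                       eafx=float(e.eaf) if pd.notna(e.eaf) else np.nan,
                       by=by, sy=float(o.se), py=float(o.pval), eafy=eafy,
                       sign_flipped=sign_flipped)
        rows.append(rec)

    cols = ["variant_id", "action", "sign_flipped",
            "bx", "sx", "px", "eafx", "by", "sy", "py", "eafy"]
    table = pd.DataFrame(rows, columns=cols)
    counts = table["action"].value_counts().to_dict()
    logger.info("harmonized %d instruments: %s", len(table), counts)
    return table


def kept(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Rows retained by harmonization (the estimator input)."""
    return harmonized[harmonized["action"].isin(KEPT_ACTIONS)].reset_index(drop=True)


def orientation_invariance_check(instruments: pd.DataFrame, seed: int = 0,
                                 rel_tol: float = 1e-9) -> dict:
    """Diagnostic: are estimator point estimates orientation-invariant?

    Jointly negates (bx, by) for a random half of the kept instruments and
    recomputes each point estimate. IVW, weighted median and both modes must
    not move; the raw Egger regression (slope fitted *without* the bx >= 0
    re-orientation) is orientation-dependent by construction and is flagged
    when it moves. Returns ``{"invariant": bool, "per_method": {...}}`` where
    ``invariant`` covers the orientation-free methods only.
    """
    from . import estimators as est  # deferred to avoid an import cycle

    H = kept(instruments).copy()
    rng = np.random.default_rng(seed)
    flip = rng.random(len(H)) < 0.5
    H2 = H.copy()
    H2.loc[flip, ["bx", "by"]] *= -1.0

    def close(x, y):
        return bool(abs(x - y) <= rel_tol * max(1.0, abs(x), abs(y)))

    per = {}
    per["ivw"] = close(est.ivw(H).beta, est.ivw(H2).beta)
    per["weighted_median"] = close(
        est.weighted_median(H, n_boot=0, seed=seed).beta,
        est.weighted_median(H2, n_boot=0, seed=seed).beta)
    per["simple_mode"] = close(
        est.mode_estimate(H, weighted=False, n_boot=0, seed=seed).beta,
        est.mode_estimate(H2, weighted=False, n_boot=0, seed=seed).beta)
    per["weighted_mode"] = close(
        est.mode_estimate(H, weighted=True, n_boot=0, seed=seed).beta,
        est.mode_estimate(H2, weighted=True, n_boot=0, seed=seed).beta)
    if len(H) >= 3:
        per["egger_raw"] = close(est._raw_egger_slope(H), est._raw_egger_slope(H2))
    report = {
        "invariant": all(v for k, v in per.items() if k != "egger_raw"),
        "per_method": per,
    }
    if not per.get("egger_raw", True):
        logger.info("raw Egger slope is orientation-dependent (expected); "
                    "the Egger estimator re-orients to bx >= 0 internally")
    return report
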