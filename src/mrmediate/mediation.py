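"""Product-of-coefficients mediation on MR estimates.

Given the exposure→mediator effect β_EM, the mediator→outcome effect β_MO
and the total exposure→outcome effect β_EO (each an IVW estimate from its
own two-sample MR), the indirect effect is β_EM·β_MO and the mediation
proportion is β_EM·β_MO / β_EO — the share of the exposure's effect
transmitted through the mediator.

The indirect-effect SE uses the first-order (Sobel) delta method with the
two legs treated as independent (they come from non-overlapping GWAS):

    se(ind) = √(β_MO²·se_EM² + β_EM²·se_MO²)

The default proportion interval treats β_EO as fixed and rescales the
indirect-effect interval: (ind ± 1.959964·se(ind)) / β_EO. A full delta
variant that also propagates the uncertainty of β_EO is available behind
``full_delta=True`` and is wider.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import Z95
from .exceptions import MediationError


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0 or not np.isfinite(x):
        return x
    return float(np.round(x, sig - 1 - int(np.floor(np.log10(abs(x))))))


def reconstruct_se_from_ci(ci_low: float, ci_high: float) -> float:
    """Recover a standard error from a symmetric 95% confidence interval."""
    if not ci_high > ci_low:
        raise ValueError(f"degenerate interval ({ci_low}, {ci_high})")
    return (ci_high - ci_low) / (2.0 * Z95)


@dataclass
class MediationResult:
    """Mediation legs, indirect effect and proportion with its interval."""

    beta_em: float
    se_em: float
    beta_mo: float
    se_mo: float
    beta_eo: float
    se_eo: float
    indirect: float
    indirect_se: float
    proportion: float
    proportion_ci_low: float
    proportion_ci_high: float
    full_delta: bool = False

    def summary(self) -> dict:
        """Display-rounded summary matching reporting convention:
        betas and the indirect effect to 3 decimals; the quoted proportion
        is the *rounded* indirect over the total, to 3 significant figures
        (in percent); interval bounds to 3 significant figures."""
        indirect_r = round(self.indirect, 3)
        prop_pct = _round_sig(100.0 * indirect_r / self.beta_eo)
        return {
            "beta_em": round(self.beta_em, 3),
            "beta_mo": round(self.beta_mo, 3),
            "beta_eo": round(self.beta_eo, 3),
            "indirect": indirect_r,
            "indirect_se": round(self.indirect_se, 4),
            "proportion_pct": prop_pct,
            "proportion_ci_low_pct": _round_sig(100.0 * self.proportion_ci_low),
            "proportion_ci_high_pct": _round_sig(100.0 * self.proportion_ci_high),
        }


def product_of_coefficients(beta_em: float, se_em: float,
                            beta_mo: float, se_mo: float,
                            beta_eo: float, se_eo: float,
                            full_delta: bool = False) -> MediationResult:
    """Indirect effect, its delta-method SE, and the mediation proportion.

    Parameters
    ----------
    beta_em, se_em : float
        Exposure → mediator effect and SE.
    beta_mo, se_mo : float
        Mediator → outcome effect and SE.
    beta_eo, se_eo : float
        Total exposure → outcome effect and SE. ``beta_eo`` must be nonzero.
    full_delta : bool
        Also propagate the total-effect uncertainty into the proportion
        interval (ratio delta method). Off by default: the fixed-total
        interval simply rescales the indirect-effect interval by β_EO.
    """
    for name, se in (("se_em", se_em), ("se_mo", se_mo), ("se_eo", se_eo)):
        if not se > 0:
            raise ValueError(f"{name} must be > 0, got {se}")
    if beta_eo == 0:
        raise MediationError("beta_eo = 0: mediation proportion undefined")

    indirect = beta_em * beta_mo
    indirect_var = beta_mo**2 * se_em**2 + beta_em**2 * se_mo**2
    indirect_se = float(np.sqrt(indirect_var))
    proportion = indirect / beta_eo

    if full_delta:
        prop_var = indirect_var / beta_eo**2 + indirect**2 * se_eo**2 / beta_eo**4
        prop_se = float(np.sqrt(prop_var))
        lo, hi = proportion - Z95 * prop_se, proportion + Z95 * prop_se
    else:
        lo = (indirect - Z95 * indirect_se) / beta_eo
        hi = (indirect + Z95 * indirect_se) / beta_eo
    if lo > hi:  # negative total effect flips the rescaled interval
        lo, hi = hi, lo

    return MediationResult(
        beta_em=beta_em, se_em=se_em, beta_mo=beta_mo, se_mo=se_mo,
        beta_eo=beta_eo, se_eo=se_eo, indirect=indirect,
        indirect_se=indirect_se, proportion=proportion,
        proportion_ci_low=lo, proportion_ci_high=hi, full_delta=full_delta)


def mediation_from_intervals(beta_em, ci_em, beta_mo, ci_mo, beta_eo, ci_eo,
                             full_delta: bool = False) -> MediationResult:
    """Convenience: run the product of coefficients from printed 95% CIs."""
    return product_of_coefficients(
        beta_em, reconstruct_se_from_ci(*ci_em),
        beta_mo, reconstruct_se_from_ci(*ci_mo),
        beta_eo, reconstruct_se_from_ci(*ci_eo),
        full_delta=full_delta)
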