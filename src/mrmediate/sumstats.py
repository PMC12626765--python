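"""GWAS summary-statistics tables: canonical schema, validated I/O.

One table holds one trait's per-variant association records. The canonical
dialect is tab-separated with fixed header names; ``column_map`` adapts
foreign headers (FinnGen, Neale-lab, GIANT dialects all differ) onto the
internal schema at the edge so everything downstream sees one layout.

Validation rules (rows failing them are dropped with a logged reason):

* alleles are single upper-case bases in {A, C, G, T} and differ from each
  other — indels / multi-character alleles are not analysable here;
* ``se`` strictly positive and finite;
* ``pval`` in (0, 1]; an exact 0 is clamped to the smallest positive float
  with a warning (some tools print underflowed p-values);
* ``pos`` >= 1, ``n`` >= 1, ``beta`` finite;
* ``eaf`` in (0, 1) when present; a missing eaf is *retained* but flagged —
  downstream variance-explained and palindrome resolution reject such rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DuplicateVariantError, SumStatsFormatError

logger = logging.getLogger(__name__)

#: Canonical column order of the internal schema.
CANONICAL_COLUMNS = ["variant_id", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n"]

_VALID_ALLELES = frozenset("ACGT")

#: Smallest positive float; p-values of exactly 0 are clamped here.
SMALLEST_PVALUE = 5e-324


@dataclass
class ReadReport:
    """Bookkeeping for one read: input rows = kept + dropped, always."""

    n_input: int = 0
    n_kept: int = 0
    drops: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.drops)


@dataclass
class SumStats:
    """One trait's summary statistics.

    Parameters
    ----------
    trait_name : str
        Human-readable trait label.
    trait_type : {"continuous", "binary"}
        Scale of ``beta``: SD units for continuous traits, log-odds for
        binary ones. Recorded as an assumption, not inferred.
    df : pandas.DataFrame
        Records in canonical column order, one row per variant.
    """

    trait_name: str
    trait_type: str
    df: pd.DataFrame
    read_report: ReadReport | None = None

    def __post_init__(self):
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous|binary, got {self.trait_type!r}")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise SumStatsFormatError(f"missing canonical columns: {missing}")
        dup = self.df["variant_id"][self.df["variant_id"].duplicated()]
        if len(dup):
            raise DuplicateVariantError(dup.unique().tolist())

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, mask_or_ids) -> "SumStats":
        """New SumStats restricted to a boolean mask or an iterable of ids."""
        if isinstance(mask_or_ids, (pd.Series, np.ndarray, list)) and len(mask_or_ids) == len(
            self.df
        ) and pd.api.types.is_bool_dtype(np.asarray(mask_or_ids)):
            sub = self.df[np.asarray(mask_or_ids)]
        else:
            ids = set(mask_or_ids)
            sub = self.df[self.df["variant_id"].isin(ids)]
        return SumStats(self.trait_name, self.trait_type, sub.reset_index(drop=True))


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Vectorised row validation; returns (clean frame, [(variant_id, reason)])."""
    ea = df["ea"].astype(str).str.upper()
    oa = df["oa"].astype(str).str.upper()
    df = df.assign(ea=ea, oa=oa)

    n_zero_p = int((df["pval"] == 0).sum())
    if n_zero_p:
        logger.warning("clamped %d p-value(s) of exactly 0 to %g", n_zero_p, SMALLEST_PVALUE)
        df.loc[df["pval"] == 0, "pval"] = SMALLEST_PVALUE

    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask, reason):
        fresh = mask & (reasons == "")
        reasons[fresh] = reason

    snp = ea.isin(_VALID_ALLELES) & oa.isin(_VALID_ALLELES)
    flag(~snp, "non-SNP or invalid allele")
    flag(ea == oa, "effect allele equals other allele")
    flag(~(pd.to_numeric(df["se"], errors="coerce") > 0), "se not positive")
    flag(~np.isfinite(pd.to_numeric(df["beta"], errors="coerce")), "beta not finite")
    flag(~(pd.to_numeric(df["pval"], errors="coerce") > 0)
         | ~(pd.to_numeric(df["pval"], errors="coerce") <= 1), "pval outside (0, 1]")
    flag(~(pd.to_numeric(df["pos"], errors="coerce") >= 1), "position < 1")
    flag(~(pd.to_numeric(df["n"], errors="coerce") >= 1), "sample size < 1")
    eaf = pd.to_numeric(df["eaf"], errors="coerce")
    bad_eaf = eaf.notna() & ~((eaf > 0) & (eaf < 1))
    flag(bad_eaf, "eaf outside (0, 1)")

    n_missing_eaf = int(eaf.isna().sum())
    if n_missing_eaf:
        logger.warning(
            "%d record(s) have missing eaf; retained but unusable for R²/F "
            "and palindrome resolution", n_missing_eaf)

    bad = reasons != ""
    drops = list(zip(df.loc[bad, "variant_id"].astype(str), reasons[bad]))
    for vid, reason in drops:
        logger.info("dropped %s: %s", vid, reason)
    return df[~bad].reset_index(drop=True), drops


def read_sumstats(
    path,
    column_map: dict[str, str] | None = None,
    trait_name: str | None = None,
    trait_type: str = "continuous",
) -> SumStats:
    """Read a tab-separated summary-statistics file into the canonical schema.

    Parameters
    ----------
    path : path-like
        Tab-separated file with a header line.
    column_map : dict, optional
        Mapping from file headers to canonical names, e.g.
        ``{"rsid": "variant_id", "af_alt": "eaf"}``. Canonical headers pass
        through unchanged.
    trait_name, trait_type :
        Metadata recorded on the returned :class:`SumStats`.

    Raises
    ------
    SumStatsFormatError
        If a mandatory column is absent after mapping.
    DuplicateVariantError
        If variant identifiers repeat.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA", "nan", ""],
                     float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SumStatsFormatError(f"missing mandatory column(s): {', '.join(missing)}")
    df = df[CANONICAL_COLUMNS].copy()
    df["variant_id"] = df["variant_id"].astype(str)
    df["chr"] = df["chr"].astype(str)
    for col in ("eaf", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("pos", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("int64")

    dup = df["variant_id"][df["variant_id"].duplicated()]
    if len(dup):
        raise DuplicateVariantError(dup.unique().tolist())

    n_input = len(df)
    clean, drops = _validate_rows(df)
    report = ReadReport(n_input=n_input, n_kept=len(clean), drops=drops)
    name = trait_name if trait_name is not None else str(path)
    return SumStats(name, trait_type, clean, read_report=report)


def write_sumstats(stats: SumStats, path) -> None:
    """Write the canonical tab-separated dialect at full float precision.

    Floats are printed with 17 significant digits so a write/read round trip
    is value-identical (including p-values down to the subnormal range).
    """
    stats.df.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="NA")
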