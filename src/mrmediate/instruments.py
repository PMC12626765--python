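"""Instrument selection: significance filter, LD clumping, R²/F strength.

The per-variant proportion of exposure variance explained is

    R² = 2β²·EAF(1−EAF) / (2β²·EAF(1−EAF) + 2·SE²·N·EAF(1−EAF))

which simplifies algebraically to β² / (β² + SE²·N); the simplified form is
used internally (identical algebra, fewer operations) and the long form is
kept as a test oracle. Instrument strength is F = R²(N−2)/(1−R²); variants
with F <= 10 are conventionally considered weak and are removed.

Clumping is greedy: repeatedly keep the smallest-p remaining variant and
discard every remaining variant on the same chromosome within the window
whose pairwise r² with it reaches the cutoff. Ties on p are broken by
(chromosome, position, variant_id) so the result does not depend on input
row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import MissingEAFError, MRMediateError
from .sumstats import SumStats

logger = logging.getLogger(__name__)


@dataclass
class LDSource:
    """Precomputed pairwise LD (r²) with an explicit completeness domain.

    Variant pairs absent from the table but inside the domain have r² = 0.
    Variants outside the domain are *conservatively treated as independent*,
    with a logged warning, because no reference information exists for them.
    """

    pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    domain: set[str] = field(default_factory=set)

    def __post_init__(self):
        for (a, b), r2 in self.pairs.items():
            if not 0.0 <= r2 <= 1.0:
                raise ValueError(f"r²({a},{b})={r2} outside [0, 1]")
            self.domain.add(a)
            self.domain.add(b)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.pairs.get((a, b), self.pairs.get((b, a), 0.0))

    def covers(self, variant_id: str) -> bool:
        return variant_id in self.domain

    @classmethod
    def from_table(cls, df: pd.DataFrame, extra_domain=()) -> "LDSource":
        pairs = {
            (str(a), str(b)): float(r)
            for a, b, r in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2])
        }
        return cls(pairs=pairs, domain=set(map(str, extra_domain)))

    @classmethod
    def read(cls, path) -> "LDSource":
        """Read tab-separated triples (variant_id_a, variant_id_b, r2).

        A row with an empty second field declares the first variant as part
        of the domain without any nonzero pair.
        """
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str}, keep_default_na=False)
        lone = df.iloc[:, 1] == ""
        src = cls.from_table(df[~lone], extra_domain=df.loc[lone, df.columns[0]])
        return src

    def write(self, path) -> None:
        rows = [(a, b, r2) for (a, b), r2 in sorted(self.pairs.items())]
        paired = {a for a, _ in self.pairs} | {b for _, b in self.pairs}
        rows += [(v, "", "") for v in sorted(self.domain - paired)]
        pd.DataFrame(rows, columns=["variant_id_a", "variant_id_b", "r2"]).to_csv(
            path, sep="\t", index=False)


def select_by_pvalue(stats: SumStats, threshold: float) -> SumStats:
    """Keep records with p strictly below ``threshold``; order preserved."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    return stats.subset((stats.df["pval"] < threshold).to_numpy())


def clump(stats: SumStats, ld: LDSource, r2_max: float = 0.001,
          window_bp: int = 10_000_000) -> SumStats:
    """Greedy LD clumping; discards at r² >= ``r2_max`` within ``window_bp``.

    The window is pairwise: |position difference| <= window_bp on the same
    chromosome.
    """
    df = stats.df
    if df.empty:
        return stats.subset([])
    order = df.sort_values(
        ["pval", "chr", "pos", "variant_id"], kind="mergesort").index.to_numpy()
    uncovered = [v for v in df["variant_id"] if not ld.covers(v)]
    if uncovered:
        logger.warning(
            "%d variant(s) absent from LD domain treated as independent "
            "(first: %s)", len(uncovered), uncovered[0])

    alive = {i: True for i in order}
    kept: list[str] = []
    chrom = df["chr"].to_dict()
    pos = df["pos"].to_dict()
    vid = df["variant_id"].to_dict()
    for i in order:
        if not alive[i]:
            continue
        kept.append(vid[i])
        alive[i] = False
        for j in order:
            if not alive[j]:
                continue
            if chrom[j] == chrom[i] and abs(pos[j] - pos[i]) <= window_bp:
                if ld.r2(vid[i], vid[j]) >= r2_max:
                    alive[j] = False
    keep_set = set(kept)
    return stats.subset(df["variant_id"].isin(keep_set).to_numpy())


def variance_explained(beta: float, eaf: float, se: float, n: float) -> float:
    """Per-variant R² on the exposure, via the simplified form β²/(β²+SE²N)."""
    beta = np.asarray(beta, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    se = np.asarray(se, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(~np.isfinite(eaf)):
        raise MissingEAFError("variance_explained requires a known eaf")
    if np.any((eaf <= 0) | (eaf >= 1)):
        raise ValueError("eaf must be in (0, 1)")
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if np.any(n < 3):
        raise ValueError("n must be >= 3")
    out = beta**2 / (beta**2 + se**2 * n)
    return float(out) if out.ndim == 0 else out


def f_statistic(r2, n):
    """Instrument F-statistic, F = R²(N−2)/(1−R²)."""
    r2 = np.asarray(r2, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((r2 < 0) | (r2 >= 1)):
        raise ValueError("r2 must be in [0, 1)")
    if np.any(n < 3):
        raise ValueError("n must be >= 3")
    out = r2 * (n - 2) / (1 - r2)
    return float(out) if out.ndim == 0 else out


def instrument_metrics(stats: SumStats) -> pd.DataFrame:
    """Per-record R² and F. Records with missing eaf are rejected by name."""
    df = stats.df
    missing = df.loc[df["eaf"].isna(), "variant_id"].tolist()
    if missing:
        raise MissingEAFError(
            f"missing eaf for variant(s): {', '.join(map(str, missing[:10]))}")
    r2 = variance_explained(df["beta"].to_numpy(), df["eaf"].to_numpy(),
                            df["se"].to_numpy(), df["n"].to_numpy())
    f = f_statistic(r2, df["n"].to_numpy())
    return pd.DataFrame({"variant_id": df["variant_id"], "r2": r2, "f_stat": f})


def filter_weak(stats: SumStats, metrics: pd.DataFrame, f_min: float = 10.0) -> SumStats:
    """Keep exactly the records with F strictly above ``f_min``."""
    m = metrics.set_index("variant_id")["f_stat"]
    unmatched = [v for v in stats.df["variant_id"] if v not in m.index]
    if unmatched:
        raise MRMediateError(
            f"no instrument metrics for variant(s): {', '.join(unmatched[:10])}")
    strong = stats.df["variant_id"].map(m) > f_min
    return stats.subset(strong.to_numpy())


def select_instruments(
    stats: SumStats,
    ld: LDSource,
    p_threshold: float = 1e-5,
    r2_max: float = 0.001,
    window_bp: int = 10_000_000,
    f_min: float = 10.0,
) -> tuple[SumStats, pd.DataFrame]:
    """Full selection pipeline: p-filter → clump → strength filter.

    Returns the retained instruments and a per-candidate report table
    (variant_id, r2, f_stat, kept_flag, drop_reason) covering every variant
    that passed the p-value stage.
    """
    sig = select_by_pvalue(stats, p_threshold)
    independent = clump(sig, ld, r2_max=r2_max, window_bp=window_bp)
    metrics = instrument_metrics(independent)
    strong = filter_weak(independent, metrics, f_min=f_min)

    kept = set(strong.df["variant_id"])
    indep = set(independent.df["variant_id"])
    report = pd.DataFrame({"variant_id": sig.df["variant_id"]})
    report = report.merge(metrics, on="variant_id", how="left")
    report["kept_flag"] = report["variant_id"].isin(kept)
    report["drop_reason"] = np.where(
        report["kept_flag"], "",
        np.where(report["variant_id"].isin(indep), "weak_instrument", "clumped"))
    return strong, report
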