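"""Tabular and plot exports, run manifests, logging setup."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

logger = logging.getLogger(__name__)


def setup_logging(out_dir: Path | None = None, level=logging.INFO) -> None:
    handlers = [logging.StreamHandler()]
    if out_dir is not None:
        handlers.append(logging.FileHandler(Path(out_dir) / "run.log"))
    logging.basicConfig(
        level=level, handlers=handlers, force=True,
        format="%(asctime)s %(name)s %(levelname)s %(message)s")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="NA")


def write_battery_tables(result, out_dir: Path, prefix: str) -> list[Path]:
    """Per-pair estimates + sensitivity block + harmonization audit."""
    out_dir = Path(out_dir)
    paths = []
    p = out_dir / f"{prefix}_estimates.tsv"
    write_table(result.estimates_table(), p)
    paths.append(p)
    s = result.sensitivity
    sens = pd.DataFrame([{
        "q_stat": s.q_stat, "q_df": s.q_df, "q_pvalue": s.q_pvalue,
        "egger_intercept": s.egger_intercept,
        "egger_intercept_se": s.egger_intercept_se,
        "egger_intercept_pvalue": s.egger_intercept_pvalue,
        "direction_consistent": s.direction_consistent,
        "reverse_pvalue": s.reverse_pvalue,
    }])
    p = out_dir / f"{prefix}_sensitivity.tsv"
    write_table(sens, p)
    paths.append(p)
    if result.harmonized is not None:
        p = out_dir / f"{prefix}_harmonization.tsv"
        write_table(result.harmonized, p)
        paths.append(p)
    return paths


def volcano_plot(results_table: pd.DataFrame, path) -> None:
    """Effect size vs −log10 p for a screen, with the α threshold line."""
    df = results_table.dropna(subset=["ivw_beta", "ivw_pvalue"])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(df["ivw_beta"], -np.log10(df["ivw_pvalue"]),
               c=np.where(df["survivor"], "crimson", "grey"), s=18)
    ax.axhline(-np.log10(0.05), color="red", ls="--", lw=0.8)
    ax.set_xlabel("IVW beta")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def forest_table(results: dict, path) -> None:
    """Plain tabular stand-in for a forest plot: OR and CI per trait."""
    rows = []
    for name, r in results.items():
        for method, e in r.estimates.items():
            rows.append(dict(trait=name, method=method, beta=e.beta, se=e.se,
                             ci_low=e.ci_low, ci_high=e.ci_high,
                             odds_ratio=e.odds_ratio, or_ci_low=e.or_ci_low,
                             or_ci_high=e.or_ci_high, pvalue=e.pvalue,
                             n_snps=e.n_snps))
    write_table(pd.DataFrame(rows), path)


@dataclass
class RunManifest:
    """What a CLI run consumed and produced, for reproducibility audits."""

    command: str
    seed: int
    config: dict
    started: float = field(default_factory=time.time)
    outputs: list[str] = field(default_factory=list)
    counts: dict = field(default_factory=dict)

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, out_dir: Path) -> Path:
        payload = {
            "command": self.command, "seed": self.seed, "config": self.config,
            "started": self.started, "finished": time.time(),
            "outputs": self.outputs, "counts": self.counts,
        }
        missing = [p for p in self.outputs if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"manifest lists missing outputs: {missing}")
        path = Path(out_dir) / "manifest.json"
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)
        return path
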