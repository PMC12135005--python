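"""Scoring allele-age estimates against simulated truth.

All statistics are computed on natural-log-transformed ages: with
``e_j = ln(t_hat_j) - ln(t_j)``,

* RMSLE  = sqrt(mean(e_j^2))
* bias   = mean(e_j)  (negative = underestimation)
* Pearson r and Spearman rho between ln(t_hat) and ln(t) (ties mid-ranked).

Undefined, flagged, or nonpositive estimates are excluded from the pairing
(with the exclusion count reported), never floored. Frequency-binned error
profiles use half-open-left percent bins: bin i holds derived frequencies in
((i-1)/100, i/100], frequency measured against the total number of sampled
haploid genomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .msh import ESTIMATE_COLUMNS, AgeEstimate, estimates_to_frame

__all__ = [
    "EvalReport",
    "FrequencyBin",
    "match_pairs",
    "compute_metrics",
    "binned_rmsle",
    "ingest_external_estimates",
    "evaluate",
    "write_report",
]

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["position", "k", "true_age_gen", "tc_hat_gen"]


@dataclass
class FrequencyBin:
    """Frequency binning scheme: 1% bins of derived frequency, or raw allele count."""

    kind: str = "percent"
    boundaries: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("percent", "allele_count"):
            raise ValueError(f"unknown binning kind: {self.kind!r}")


@dataclass
class EvalReport:
    """Headline metrics plus an optional per-frequency-bin error table."""

    n_pairs: int
    n_excluded: int
    rmsle: float
    bias: float
    pearson_r: float
    spearman_rho: float
    bins: pd.DataFrame | None = None
    log_base: str = "e"
    flags: str = "ok"

    def summary_lines(self) -> list[str]:
        return [
            f"log_base={self.log_base}",
            f"n_pairs={self.n_pairs}",
            f"n_excluded={self.n_excluded}",
            f"rmsle={self.rmsle:.4f}",
            f"bias={self.bias:.4f}",
            f"pearson_r={self.pearson_r:.4f}",
            f"spearman_rho={self.spearman_rho:.4f}",
            f"flags={self.flags}",
        ]


def _as_estimates_frame(estimates) -> pd.DataFrame:
    if isinstance(estimates, pd.DataFrame):
        missing = {"position", "tc_hat_gen"} - set(estimates.columns)
        if missing:
            raise ValueError(f"estimates frame is missing columns {sorted(missing)}")
        return estimates
    return estimates_to_frame(estimates)


def match_pairs(truth: pd.DataFrame, estimates) -> tuple[pd.DataFrame, int]:
    """Inner-join truth and estimates on position.

    Returns ``(pairs, n_excluded)`` where excluded counts matched variants
    whose estimate is flagged, NaN, or nonpositive. Duplicate positions in
    either input are rejected.
    """
    est = _as_estimates_frame(estimates)
    for name, frame in (("truth", truth), ("estimates", est)):
        if frame["position"].duplicated().any():
            raise ValueError(f"duplicate positions in {name} table")
    merged = truth.merge(est, on="position", how="inner", suffixes=("", "_est"))
    flags = merged["flags"] if "flags" in merged else pd.Series("ok", index=merged.index)
    good = (
        (flags == "ok")
        & np.isfinite(merged["tc_hat_gen"])
        & (merged["tc_hat_gen"] > 0)
        & (merged["true_age_gen"] > 0)
    )
    n_excluded = int((~good).sum())
    pairs = merged.loc[good].reset_index(drop=True)
    if "k" not in pairs:
        pairs["k"] = pairs.get("derived_count", pd.Series(np.nan, index=pairs.index))
    elif "derived_count" in pairs:
        pairs["k"] = pairs["k"].where(pairs["k"].notna(), pairs["derived_count"])
    return pairs[[c for c in PAIR_COLUMNS if c in pairs.columns]], n_excluded


def _log_errors(pairs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lt = np.log(pairs["true_age_gen"].to_numpy(dtype=float))
    le = np.log(pairs["tc_hat_gen"].to_numpy(dtype=float))
    return le, lt, le - lt


def compute_metrics(pairs: pd.DataFrame, n_excluded: int = 0) -> EvalReport:
    """RMSLE, bias, Pearson r, and Spearman rho on log-transformed ages."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 positive pairs to compute metrics")
    le, lt, e = _log_errors(pairs)
    rmsle = float(np.sqrt(np.mean(e**2)))
    bias = float(np.mean(e))
    flags = "ok"
    if np.ptp(le) == 0 or np.ptp(lt) == 0:
        pearson = spearman = np.nan
        flags = "zero-variance"
    else:
        pearson = float(stats.pearsonr(le, lt).statistic)
        spearman = float(stats.spearmanr(le, lt).statistic)
    return EvalReport(
        n_pairs=len(pairs),
        n_excluded=n_excluded,
        rmsle=rmsle,
        bias=bias,
        pearson_r=pearson,
        spearman_rho=spearman,
        flags=flags,
    )


def _percent_bin(k: np.ndarray, n_genomes: int) -> np.ndarray:
    # bin i holds frequencies in ((i-1)/100, i/100]; exact integer arithmetic
    return -(-100 * k.astype(np.int64) // n_genomes)


def binned_rmsle(
    pairs: pd.DataFrame,
    n_genomes: int,
    binning: FrequencyBin | None = None,
) -> pd.DataFrame:
    """Per-frequency-bin error table.

    Percent mode emits all 100 bins (empty bins with n = 0 and null
    statistics); allele-count mode groups by k directly. ``rmsle_norm`` is
    the bin's RMSLE divided by the bin's mean true age.
    """
    binning = binning or FrequencyBin("percent")
    k = pairs["k"].to_numpy(dtype=np.int64)
    if binning.kind == "percent":
        labels = _percent_bin(k, n_genomes)
        all_bins = np.arange(1, 101)
    else:
        labels = k
        all_bins = np.unique(k)
    rows = []
    for b in all_bins:
        sel = pairs.loc[labels == b]
        if len(sel) == 0:
            rows.append((int(b), 0, np.nan, np.nan, np.nan))
            continue
        _, _, e = _log_errors(sel)
        rmsle = float(np.sqrt(np.mean(e**2)))
        mean_true = float(sel["true_age_gen"].mean())
        rows.append((int(b), len(sel), mean_true, rmsle, rmsle / mean_true))
    return pd.DataFrame(
        rows, columns=["bin", "n", "mean_true_age", "rmsle", "rmsle_norm"]
    )


def ingest_external_estimates(path) -> list[AgeEstimate]:
    """Load any estimator's per-variant ages from a TSV.

    Accepts this package's own estimate tables (columns preserved verbatim)
    or a minimal external file with columns ``position`` and ``estimate``
    (generations) plus optional ``k``; external rows get method ``external``.
    Nonpositive or missing estimates are kept but flagged so the pairing
    stage excludes them.
    """
    df = pd.read_csv(path, sep="\t")
    if "tc_hat_gen" in df.columns:
        value_col = "tc_hat_gen"
    elif "estimate" in df.columns:
        value_col = "estimate"
    else:
        raise ValueError(f"{path}: need a 'tc_hat_gen' or 'estimate' column")
    if "position" not in df.columns:
        raise ValueError(f"{path}: missing 'position' column")
    if not pd.api.types.is_numeric_dtype(df[value_col]):
        raise ValueError(f"{path}: non-numeric estimates in column {value_col!r}")
    out = []
    for _, row in df.iterrows():
        value = float(row[value_col])
        flags = row.get("flags", None)
        if not isinstance(flags, str):
            flags = "ok" if np.isfinite(value) and value > 0 else "nonpositive"
        out.append(
            AgeEstimate(
                position=int(row["position"]),
                derived_count=int(row["k"]) if "k" in df.columns and pd.notna(row["k"]) else 0,
                t_c_hat=value,
                n_copies_used=int(row["n_copies"]) if "n_copies" in df.columns else 0,
                method=str(row["method"]) if "method" in df.columns else "external",
                flags=flags,
            )
        )
    return out


def evaluate(
    truth: pd.DataFrame,
    estimates,
    n_genomes: int | None = None,
    binning: FrequencyBin | None = None,
) -> EvalReport:
    """Pair, score, and (when ``n_genomes`` is given) bin in one call."""
    pairs, n_excluded = match_pairs(truth, estimates)
    report = compute_metrics(pairs, n_excluded=n_excluded)
    if n_genomes is not None:
        report.bins = binned_rmsle(pairs, n_genomes, binning)
    logger.info(
        "evaluate: %d pairs (%d excluded) rmsle=%.3f bias=%.3f r=%.3f rho=%.3f",
        report.n_pairs,
        report.n_excluded,
        report.rmsle,
        report.bias,
        report.pearson_r,
        report.spearman_rho,
    )
    return report


def write_report(report: EvalReport, path, bins_path=None) -> None:
    """Human-readable key=value summary, plus an optional per-bin CSV."""
    with open(path, "w") as fh:
        fh.write("\n".join(report.summary_lines()) + "\n")
    if bins_path is not None and report.bins is not None:
        report.bins.to_csv(bins_path, index=False)
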