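"""Donor-panel statistics: replicate summaries, Pearson correlations per
day, and linear fits of pattern metrics against matrix-protein readouts.

Per-well metrics (VoC, aggregate area) are summarized to per-(donor, day)
means with standard errors over technical replicates; each day's donor
means are then correlated against the donors' matrix-protein readouts
(sGAG in ug per ug DNA, Col2 in ng per ug DNA) with an accompanying
least-squares line.  Correlation on replicate means is the default;
pooled per-replicate correlation is available via ``pooled=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("swirlquant")

PROTEIN_COLUMNS = ("sgag_ug_per_ugDNA", "col2_ng_per_ugDNA")


@dataclass
class CorrelationResult:
    """Pearson correlation of one metric vs one protein on one day."""

    day: int
    metric: str
    protein: str
    r: float
    slope: float
    intercept: float
    n_donors: int
    p_permutation: Optional[float] = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("Pearson r must lie in [-1, 1]")


def replicate_summary(panel: pd.DataFrame, value: str = "voc") -> pd.DataFrame:
    """Per-(donor, day) mean and standard error over technical replicates.

    SEM uses the sample standard deviation (ddof=1) over n replicates;
    groups with a single replicate get SEM = NaN.
    """
    required = {"donor_id", "day", value}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel is missing columns: {sorted(missing)}")
    clean = panel.dropna(subset=[value])
    dropped = len(panel) - len(clean)
    if dropped:
        logger.warning("replicate_summary: dropped %d rows with missing %s", dropped, value)
    grouped = clean.groupby(["donor_id", "day"])[value]
    out = grouped.agg(mean="mean", n="count", sd=lambda v: v.std(ddof=1)).reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] < 2, ["sd", "sem"]] = np.nan
    return out.rename(columns={"mean": f"{value}_mean", "sem": f"{value}_sem",
                               "sd": f"{value}_sd"})


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation of two equal-length samples."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise ValueError("Pearson r undefined: a sample has zero variance")
    return float(stats.pearsonr(x, y).statistic)


def _permutation_p(x: np.ndarray, y: np.ndarray, r_obs: float, n_perm: int,
                   rng: np.random.Generator) -> float:
    hits = 0
    for _ in range(n_perm):
        r = pearson_correlation(x, rng.permutation(y))
        if abs(r) >= abs(r_obs):
            hits += 1
    return (hits + 1) / (n_perm + 1)


def correlate_by_day(
    panel: pd.DataFrame,
    proteins: pd.DataFrame,
    metrics: Sequence[str] = ("voc",),
    pooled: bool = False,
    permutation_p: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Pearson r and linear fit for each day x metric x protein combination.

    *panel* holds per-well rows (donor_id, day, replicate, metric
    columns); *proteins* holds one row per donor with the protein
    columns.  By default each metric is first averaged over replicates
    per donor (matching how donor panels are plotted); ``pooled=True``
    correlates raw replicate values instead.  Days with fewer than 3
    complete donors are skipped with a warning.  Set ``permutation_p`` to
    a positive repeat count to attach a two-sided permutation p-value.
    """
    for col in PROTEIN_COLUMNS:
        if col not in proteins.columns:
            raise ValueError(f"protein table is missing column {col!r}")
    if (proteins[list(PROTEIN_COLUMNS)] < 0).any().any():
        raise ValueError("protein readouts must be >= 0")
    rng = np.random.default_rng(seed)

    rows = []
    for metric in metrics:
        if pooled:
            merged_all = panel.merge(proteins, on="donor_id")
            value_col = metric
        else:
            summary = replicate_summary(panel, value=metric)
            merged_all = summary.merge(proteins, on="donor_id")
            value_col = f"{metric}_mean"
        for day in sorted(panel["day"].unique()):
            sub = merged_all[merged_all["day"] == day].dropna(subset=[value_col])
            n_donors = sub["donor_id"].nunique()
            if n_donors < 3:
                logger.warning("day %s: only %d donors with complete %s data; skipped",
                               day, n_donors, metric)
                continue
            x = sub[value_col].to_numpy(dtype=np.float64)
            for protein in PROTEIN_COLUMNS:
                y = sub[protein].to_numpy(dtype=np.float64)
                r = pearson_correlation(x, y)
                slope, intercept = np.polyfit(x, y, deg=1)
                res = CorrelationResult(
                    day=int(day), metric=metric, protein=protein, r=r,
                    slope=float(slope), intercept=float(intercept),
                    n_donors=int(n_donors),
                    p_permutation=(_permutation_p(x, y, r, permutation_p, rng)
                                   if permutation_p else None),
                )
                rows.append(res.__dict__)
    return pd.DataFrame(rows)
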