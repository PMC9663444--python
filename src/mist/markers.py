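"""Regional differential expression: per region, genes are ranked against
all other regions' spots with a two-sided Wilcoxon rank-sum test,
Benjamini-Hochberg adjustment within the region, and fold-change plus
adjusted-p filters."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_st import STData
from .region_detection import ISOLATED, RegionAssignment

__all__ = ["MarkerTable", "regional_markers", "write_marker_tables"]


@dataclass
class MarkerTable:
    """Filtered marker rows plus the unfiltered per-gene statistics.

    ``table`` holds only genes passing both thresholds (fold change above
    ``fc_min`` as a relative increase, adjusted p below ``alpha``), sorted
    by adjusted p within region.  ``stats`` keeps every (region, gene) row
    for calibration checks and export.
    """

    table: pd.DataFrame
    stats: pd.DataFrame
    fc_min: float
    alpha: float


def regional_markers(data: STData, assignment: RegionAssignment,
                     fc_min: float = 0.5, alpha: float = 0.01) -> MarkerTable:
    """Rank-sum markers of each region against the spots of all other
    regions (isolated spots excluded from both groups).

    ``fold_change`` is the relative change of group means,
    ``mean(region) / mean(rest) - 1``; the log1p-mean difference is
    reported alongside.  Regions with fewer than 3 spots are skipped.
    """
    if len(assignment.regions) < 2:
        raise ValueError("marker analysis requires at least two regions")
    counts = data.counts
    records = []
    for rid, region in enumerate(assignment.regions):
        rest = np.flatnonzero(
            (assignment.labels != ISOLATED) & (assignment.labels != rid)
        )
        if region.size < 3:
            warnings.warn(f"region {rid} has fewer than 3 spots; skipped")
            continue
        x = counts[region]
        y = counts[rest]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.mannwhitneyu(x, y, axis=0, alternative="two-sided",
                                     method="asymptotic")
        raw_p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        mean_x = x.mean(axis=0)
        mean_y = y.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.where(
                mean_y > 0,
                mean_x / np.where(mean_y > 0, mean_y, 1.0) - 1.0,
                np.where(mean_x > 0, np.inf, 0.0),
            )
        log_fc = np.log1p(x).mean(axis=0) - np.log1p(y).mean(axis=0)
        adj_p = multipletests(raw_p, method="fdr_bh")[1]
        for g in range(data.n_genes):
            records.append(
                {
                    "region": rid,
                    "gene": data.gene_ids[g],
                    "fold_change": fc[g],
                    "log_fc": log_fc[g],
                    "u_stat": float(np.atleast_1d(res.statistic)[g]),
                    "raw_p": raw_p[g],
                    "adjusted_p": adj_p[g],
                    "direction": "up" if fc[g] > 0 else "down",
                }
            )
    all_stats = pd.DataFrame.from_records(records)
    passing = all_stats[
        (all_stats["fold_change"] > fc_min) & (all_stats["adjusted_p"] < alpha)
    ].sort_values(["region", "adjusted_p"], kind="stable").reset_index(drop=True)
    return MarkerTable(table=passing, stats=all_stats, fc_min=fc_min, alpha=alpha)


def write_marker_tables(markers: MarkerTable, path_prefix: str) -> None:
    """One TSV per region (``<prefix>_region<id>.tsv``), ready for external
    gene-set enrichment tools."""
    for rid, sub in markers.table.groupby("region"):
        sub.to_csv(f"{path_prefix}_region{rid}.tsv", sep="\t", index=False)
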