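"""Holdout-experiment machinery and evaluation metrics.

Imputation accuracy is scored by RMSE / Pearson / Spearman on held-out
non-zero entries; region-detection quality by silhouette coefficients on
the PC embedding (TSC), on spatial coordinates (SSC), their sum (CSC), and
by the adjusted Rand index against reference labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .io_st import STData
from .region_detection import (
    ISOLATED,
    Embedding,
    RegionAssignment,
    build_weighted_graph,
    detect_regions,
)
from .imputation import impute_mist, impute_spknn

__all__ = [
    "HoldoutFolds",
    "make_holdout_folds",
    "apply_holdout",
    "rmse",
    "pcc",
    "spearman",
    "per_gene_spearman",
    "silhouette_scores",
    "adjusted_rand_index",
    "run_holdout_benchmark",
]


@dataclass
class HoldoutFolds:
    """Per-gene stratified partition of non-zero entries into folds.

    ``folds[f]`` is a ``(spots, genes)`` index pair; together the folds
    cover every non-zero entry of the eligible genes exactly once.
    """

    folds: list
    eligible_genes: np.ndarray
    seed: int
    n_folds: int


def make_holdout_folds(data: STData, n_folds: int = 5, min_frac: float = 0.5,
                       seed: int = 0) -> HoldoutFolds:
    """Partition each eligible gene's non-zero entries into ``n_folds``
    near-equal random groups (eligible = expressed in at least ``min_frac``
    of spots)."""
    expressed_frac = (data.counts > 0).mean(axis=0)
    eligible = np.flatnonzero(expressed_frac >= min_frac)
    if eligible.size == 0:
        raise ValueError(f"no gene is expressed in >= {min_frac:.0%} of spots")
    rng = np.random.default_rng(seed)
    fold_rows = [[] for _ in range(n_folds)]
    fold_cols = [[] for _ in range(n_folds)]
    for g in eligible:
        spots = np.flatnonzero(data.counts[:, g] > 0)
        spots = rng.permutation(spots)
        for f, chunk in enumerate(np.array_split(spots, n_folds)):
            fold_rows[f].extend(chunk.tolist())
            fold_cols[f].extend([int(g)] * chunk.size)
    folds = [
        (np.asarray(r, dtype=np.intp), np.asarray(c, dtype=np.intp))
        for r, c in zip(fold_rows, fold_cols)
    ]
    return HoldoutFolds(folds=folds, eligible_genes=eligible, seed=seed, n_folds=n_folds)


def apply_holdout(data: STData, folds: HoldoutFolds, fold_id: int) -> STData:
    """Copy of ``data`` with the fold's entries set to zero."""
    if not 0 <= fold_id < folds.n_folds:
        raise ValueError(f"fold_id must lie in [0, {folds.n_folds})")
    out = data.copy()
    rows, cols = folds.folds[fold_id]
    out.counts[rows, cols] = 0.0
    return out


def rmse(estimates, truth) -> float:
    """Root mean squared error, sqrt(sum((x - y)^2) / n)."""
    x = np.asarray(estimates, dtype=float)
    y = np.asarray(truth, dtype=float)
    if x.shape != y.shape:
        raise ValueError("estimates and truth must have equal length")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def pcc(estimates, truth) -> float:
    """Pearson correlation coefficient of two value lists."""
    x = np.asarray(estimates, dtype=float)
    y = np.asarray(truth, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc ** 2).sum()) * np.sqrt((yc ** 2).sum())
    if den == 0:
        raise ValueError("correlation undefined for constant input")
    return float((xc * yc).sum() / den)


def spearman(estimates, truth):
    """Spearman rank correlation and its p-value."""
    x = np.asarray(estimates, dtype=float)
    y = np.asarray(truth, dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def per_gene_spearman(reference: np.ndarray, estimate: np.ndarray) -> np.ndarray:
    """Spearman correlation per gene (column) between two matrices;
    NaN for constant columns."""
    out = np.full(reference.shape[1], np.nan)
    for g in range(reference.shape[1]):
        x, y = reference[:, g], estimate[:, g]
        if np.all(x == x[0]) or np.all(y == y[0]):
            continue
        out[g] = stats.spearmanr(x, y)[0]
    return out


def silhouette_scores(assignment: RegionAssignment, emb: Embedding, coords):
    """(TSC, SSC, CSC): Euclidean silhouettes on PC rows and on spatial
    coordinates, isolated spots excluded, and their sum."""
    mask = assignment.labels != ISOLATED
    labels = assignment.labels[mask]
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least two regions")
    tsc = float(silhouette_score(emb.pcs[mask], labels, metric="euclidean"))
    ssc = float(silhouette_score(np.asarray(coords)[mask].astype(float), labels,
                                 metric="euclidean"))
    return tsc, ssc, tsc + ssc


def adjusted_rand_index(labels_a, labels_b) -> float:
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(a, b))


SPARSITY_BINS = (0.2, 0.3, 0.4, 0.5, 0.6)


def per_gene_holdout_report(data: STData, folds: HoldoutFolds, fold_id: int,
                            denoised: np.ndarray) -> pd.DataFrame:
    """Per-gene RMSE on one fold's held-out entries, with each gene tagged
    by its nearest sparsity bin (fraction of zero entries)."""
    rows_idx, cols_idx = folds.folds[fold_id]
    sparsity = (data.counts == 0).mean(axis=0)
    records = []
    for g in np.unique(cols_idx):
        sel = cols_idx == g
        truth = data.counts[rows_idx[sel], g]
        est = denoised[rows_idx[sel], g]
        if truth.size == 0:
            continue
        bin_ = min(SPARSITY_BINS, key=lambda b: abs(b - sparsity[g]))
        records.append(
            {
                "gene": data.gene_ids[g],
                "sparsity": float(sparsity[g]),
                "sparsity_bin": bin_,
                "n_holdout": int(truth.size),
                "rmse": rmse(est, truth),
            }
        )
    return pd.DataFrame.from_records(records)


def run_holdout_benchmark(
    data: STData,
    layout: str = "square4",
    n_folds: int = 5,
    seed: int = 0,
    k: int = 5,
    n_extra: int | None = None,
    sigma: float = 0.1,
    q: int | None = None,
    p: int = 30,
    log1p: bool = True,
    detect_per_fold: bool = False,
    fold_ids=None,
) -> pd.DataFrame:
    """Per-fold holdout comparison of the ensemble imputer against the
    spatial-neighbour baseline on CPM data.

    Regions are detected once on the input matrix (the data an analyst
    actually has) and held fixed while each fold's entries are zeroed and
    re-imputed; pass ``detect_per_fold=True`` to re-run detection on every
    masked matrix instead.  RMSE / PCC are scored on the held-out entries
    only.
    """
    folds = make_holdout_folds(data, n_folds=n_folds, seed=seed)
    assignment = None
    if not detect_per_fold:
        assignment = detect_regions(data, sigma=sigma, q=q, p=p, layout=layout,
                                    log1p=log1p)
    rows = []
    for fold_id in fold_ids if fold_ids is not None else range(n_folds):
        masked = apply_holdout(data, folds, fold_id)
        if detect_per_fold:
            assignment = detect_regions(masked, sigma=sigma, q=q, p=p, layout=layout,
                                        log1p=log1p)
        r_idx, c_idx = folds.folds[fold_id]
        truth = data.counts[r_idx, c_idx]

        result = impute_mist(masked, assignment, k=k, n_extra=n_extra, rng_seed=seed)
        mist_est = result.denoised[r_idx, c_idx]

        from .region_detection import embed_pca, select_hvg

        emb = embed_pca(masked, select_hvg(masked),
                        p=min(p, masked.n_spots, masked.n_genes), log1p=log1p)
        graph = build_weighted_graph(masked, emb, layout)
        spknn_est = impute_spknn(masked, graph)[r_idx, c_idx]

        for method, est in (("mist", mist_est), ("spknn", spknn_est)):
            per_gene = [
                rmse(est[c_idx == g], truth[c_idx == g])
                for g in np.unique(c_idx)
            ]
            rows.append(
                {
                    "fold": fold_id,
                    "method": method,
                    "n_holdout": truth.size,
                    "rmse": rmse(est, truth),
                    "pcc": pcc(est, truth),
                    "rmse_gene_median": float(np.median(per_gene)),
                }
            )
    return pd.DataFrame(rows)
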