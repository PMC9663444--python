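"""Synthetic spatial transcriptomics fixtures: a spot lattice partitioned
into contiguous regions, region-specific low-rank expression, multiplicative
library-size variation, and uniform Bernoulli dropout.

Every stage of the pipeline can be exercised on these fixtures without any
external download, and the planted truth (labels, dense expression, dropout
mask) supports region-recovery and holdout benchmarks.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_st import STData, write_st_csv, write_visium
from .lattice import LAYOUTS, adjacent_pairs

__all__ = ["SyntheticTruth", "generate_lattice", "generate_synthetic_st", "write_fixture"]


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated fixture.

    ``dense_expr`` is the strictly positive pre-dropout matrix,
    ``region_labels`` the planted per-spot region id, ``boundary`` flags
    spots adjacent to a different region, and ``dropout_mask`` is ``True``
    where an entry was zeroed by dropout.
    """

    dense_expr: np.ndarray
    region_labels: np.ndarray
    boundary: np.ndarray
    dropout_mask: np.ndarray
    rank_per_region: int


def generate_lattice(rows: int, cols: int, layout: str = "square4") -> np.ndarray:
    """Full ``rows x cols`` grid of ``(row, col)`` lattice coordinates."""
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}")
    if rows < 2 or cols < 2:
        raise ValueError("rows and cols must both be >= 2")
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(int)


def _plant_labels(coords: np.ndarray, rows: int, cols: int, n_regions: int,
                  region_layout: str) -> np.ndarray:
    if region_layout == "blocks":
        # factor n_regions into a near-square grid of axis-aligned blocks
        gr = int(np.floor(np.sqrt(n_regions)))
        while n_regions % gr:
            gr -= 1
        gc = n_regions // gr
        rb = np.minimum((coords[:, 0] * gr) // rows, gr - 1)
        cb = np.minimum((coords[:, 1] * gc) // cols, gc - 1)
        return (rb * gc + cb).astype(int)
    if region_layout == "stripes":
        return np.minimum((coords[:, 1] * n_regions) // cols, n_regions - 1).astype(int)
    raise ValueError(f"unknown region_layout {region_layout!r}")


def generate_synthetic_st(
    rows: int,
    cols: int,
    n_genes: int,
    n_regions: int = 4,
    rank: int = 3,
    dropout_rate: float = 0.3,
    noise_sd: float = 0.0,
    seed: int = 0,
    layout: str = "square4",
    region_layout: str = "blocks",
    marker_boost: float = 5.0,
    coherence: float = 3.0,
    within_noise: float = 0.5,
    libsize_sd: float = 0.2,
    scale: float = 10.0,
):
    """Generate an observed :class:`~mist.io_st.STData` plus its truth.

    Each planted region draws its own gene-loading matrix, so the dense
    sub-matrix of region ``r`` is ``diag(libsize) @ U_r V_r^T`` with strictly
    positive factors — numerical rank at most ``rank`` when ``noise_sd`` is
    zero.  A block of genes per region receives a ``marker_boost`` multiplier
    to give each region a distinct marker programme.  Dropout zeroes entries
    independently with probability ``dropout_rate``.
    """
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must lie in [0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    coords = generate_lattice(rows, cols, layout)
    labels = _plant_labels(coords, rows, cols, n_regions, region_layout)
    m = coords.shape[0]

    sizes = np.bincount(labels, minlength=n_regions)
    if rank >= sizes.min() or rank >= n_genes:
        raise ValueError("rank must be smaller than every region size and n_genes")

    rng = np.random.default_rng(seed)
    gene_blocks = np.array_split(np.arange(n_genes), n_regions)
    # a common gene-loading background shared by all regions; each region
    # multiplies its own marker block, so between-region differences are
    # driven by the planted marker programmes rather than chance alignment
    v_common = rng.gamma(2.0, 1.0, size=(n_genes, rank)) + 0.2
    dense = np.zeros((m, n_genes))
    for r in range(n_regions):
        spots = np.flatnonzero(labels == r)
        # shared per-region factor direction (coherence) keeps all spots of a
        # region mutually correlated; the individual term adds within-region
        # variation without raising the rank
        base = rng.gamma(2.0, 1.0, size=rank) + 0.2
        u = (coherence * base[None, :]
             + within_noise * rng.gamma(2.0, 1.0, size=(spots.size, rank)) + 0.1)
        v = v_common.copy()
        v[gene_blocks[r]] *= marker_boost
        dense[spots] = u @ v.T
    if noise_sd > 0:
        dense = np.maximum(dense + rng.normal(0.0, noise_sd, size=dense.shape), 1e-3)
    libsize = rng.lognormal(0.0, libsize_sd, size=m)
    dense *= scale * libsize[:, None]

    dropout_mask = rng.random((m, n_genes)) < dropout_rate
    observed = np.where(dropout_mask, 0.0, dense)

    pairs = adjacent_pairs(coords, layout)
    boundary = np.zeros(m, dtype=bool)
    diff = labels[pairs[:, 0]] != labels[pairs[:, 1]]
    boundary[pairs[diff, 0]] = True
    boundary[pairs[diff, 1]] = True

    data = STData(
        observed,
        coords,
        gene_ids=[f"gene{j}" for j in range(n_genes)],
        spot_ids=[f"{r}x{c}" for r, c in coords],
        normalized=False,
    )
    truth = SyntheticTruth(dense, labels, boundary, dropout_mask, rank)
    return data, truth


def write_fixture(data: STData, truth: SyntheticTruth, path: str,
                  fmt: str = "csv") -> None:
    """Write a fixture to disk: expression in ``fmt`` (``csv`` or ``visium``)
    plus ``truth_labels.csv`` and ``truth_dense.csv``."""
    os.makedirs(path, exist_ok=True)
    if fmt == "csv":
        write_st_csv(data, os.path.join(path, "expression.csv"))
    elif fmt == "visium":
        write_visium(data, path)
    else:
        raise ValueError(f"unknown fixture format {fmt!r}")
    pd.DataFrame(
        {
            "spot_id": data.spot_ids,
            "row": data.coords[:, 0],
            "col": data.coords[:, 1],
            "region": truth.region_labels,
            "boundary": truth.boundary.astype(int),
        }
    ).to_csv(os.path.join(path, "truth_labels.csv"), index=False)
    pd.DataFrame(
        truth.dense_expr, index=data.spot_ids, columns=data.gene_ids
    ).to_csv(os.path.join(path, "truth_dense.csv"))
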