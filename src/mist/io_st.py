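"""Input/output, quality control and library-size normalisation for
spatial transcriptomics expression matrices.

The on-disk layouts understood here are the plain-file 10x Visium bundle
(MatrixMarket counts, barcode/feature lists, tissue-position table) and a
dense CSV with spots as rows labelled ``"<row>x<col>"``.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse

CPM_TOTAL = 1e6

__all__ = [
    "STData",
    "read_visium",
    "read_st_csv",
    "qc_filter",
    "normalize_cpm",
    "write_st_csv",
    "write_visium",
]


@dataclass
class STData:
    """A spot-by-gene expression matrix with spot lattice coordinates.

    Attributes
    ----------
    counts
        Dense ``(M, N)`` array of non-negative reals (raw counts or CPM).
    coords
        ``(M, 2)`` integer array of ``(row, col)`` lattice positions.
    gene_ids, spot_ids
        Unique identifiers for the N genes and M spots.
    normalized
        ``True`` once every row has been scaled to counts-per-million.
    """

    counts: np.ndarray
    coords: np.ndarray
    gene_ids: list = field(default_factory=list)
    spot_ids: list = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.coords = np.asarray(self.coords)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D spot-by-gene matrix")
        m, n = self.counts.shape
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contain non-finite values")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.coords.shape != (m, 2):
            raise ValueError(f"coords must have shape ({m}, 2)")
        if len(self.gene_ids) != n:
            raise ValueError("gene_ids length does not match matrix width")
        if len(self.spot_ids) != m:
            raise ValueError("spot_ids length does not match matrix height")
        if len(set(self.gene_ids)) != n:
            raise ValueError("gene_ids contain duplicates")
        if len(set(self.spot_ids)) != m:
            raise ValueError("spot_ids contain duplicates")
        coord_set = {tuple(xy) for xy in self.coords.tolist()}
        if len(coord_set) != m:
            raise ValueError("two spots share a lattice coordinate")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def copy(self) -> "STData":
        return replace(
            self,
            counts=self.counts.copy(),
            coords=self.coords.copy(),
            gene_ids=list(self.gene_ids),
            spot_ids=list(self.spot_ids),
        )

    def validate(self) -> None:
        """Re-run construction checks plus the CPM row-sum invariant."""
        self.__post_init__()
        if self.normalized:
            sums = self.counts.sum(axis=1)
            if not np.allclose(sums, CPM_TOTAL, rtol=1e-9, atol=0):
                raise ValueError("normalized flag set but rows do not sum to 1e6")


def _require(path: str, name: str, candidates) -> str:
    for cand in candidates:
        full = os.path.join(path, cand)
        if os.path.exists(full):
            return full
    raise FileNotFoundError(f"missing {name} file in {path!r} (looked for {candidates})")


_POSITION_COLS = ["barcode", "in_tissue", "array_row", "array_col"]


def read_visium(path: str) -> STData:
    """Read a plain-file Visium bundle, keeping only in-tissue spots.

    ``path`` must contain ``matrix.mtx`` (genes x barcodes), ``barcodes.tsv``,
    ``features.tsv`` and a ``tissue_positions[_list].csv`` table whose
    ``array_row``/``array_col`` fields provide the lattice coordinates.
    """
    mtx_file = _require(path, "matrix", ["matrix.mtx", "matrix.mtx.gz"])
    bc_file = _require(path, "barcodes", ["barcodes.tsv", "barcodes.tsv.gz"])
    ft_file = _require(path, "features", ["features.tsv", "features.tsv.gz", "genes.tsv"])
    pos_file = _require(
        path, "tissue positions", ["tissue_positions.csv", "tissue_positions_list.csv"]
    )

    mat = scio.mmread(mtx_file)
    if sparse.issparse(mat):
        mat = mat.toarray()
    counts = np.asarray(mat, dtype=float).T  # -> spots x genes

    barcodes = pd.read_csv(bc_file, header=None, sep="\t")[0].astype(str).tolist()
    features = pd.read_csv(ft_file, header=None, sep="\t")
    gene_ids = features[0].astype(str).tolist()

    with open(pos_file) as fh:
        first = fh.readline()
    has_header = "barcode" in first.lower()
    pos = pd.read_csv(pos_file, header=0 if has_header else None)
    if not has_header:
        pos.columns = _POSITION_COLS + list(pos.columns[4:])
    pos.columns = [str(c) for c in pos.columns]
    missing_cols = [c for c in _POSITION_COLS if c not in pos.columns]
    if missing_cols:
        raise ValueError(f"position table lacks columns {missing_cols}")
    pos = pos.set_index(pos["barcode"].astype(str))

    unmatched = [b for b in barcodes if b not in pos.index]
    if unmatched:
        raise ValueError(
            f"{len(unmatched)} barcode(s) absent from the position table: {unmatched}"
        )

    pos = pos.loc[barcodes]
    keep = pos["in_tissue"].to_numpy().astype(int) == 1
    coords = pos.loc[keep, ["array_row", "array_col"]].to_numpy().astype(int)
    spot_ids = [b for b, k in zip(barcodes, keep) if k]
    return STData(counts[keep], coords, gene_ids, spot_ids, normalized=False)


_LABEL_RE = re.compile(r"^\s*(-?\d+(?:\.\d+)?)\s*[xX×,_]\s*(-?\d+(?:\.\d+)?)\s*$")


def read_st_csv(path: str) -> STData:
    """Read a dense spot-by-gene CSV whose row labels encode coordinates
    as ``"<row>x<col>"``."""
    df = pd.read_csv(path, index_col=0)
    dup = df.index[df.index.duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate row label(s): {dup}")
    coords = []
    for label in df.index.astype(str):
        m = _LABEL_RE.match(label)
        if m is None:
            raise ValueError(f"row label {label!r} does not parse as '<row>x<col>'")
        coords.append((int(round(float(m.group(1)))), int(round(float(m.group(2))))))
    counts = df.to_numpy(dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative entry in expression table")
    return STData(
        counts,
        np.asarray(coords, dtype=int),
        [str(g) for g in df.columns],
        [str(s) for s in df.index],
        normalized=False,
    )


def qc_filter(
    data: STData,
    min_spots_per_gene: int = 10,
    min_umi: float = 1500,
    max_mito_frac: float = 0.3,
    mito_prefix=("MT-", "mt-"),
) -> STData:
    """Remove low-quality genes and spots from a raw count matrix.

    Genes observed (non-zero) in fewer than ``min_spots_per_gene`` spots are
    dropped first; then spots with total counts below ``min_umi`` or with a
    mitochondrial fraction above ``max_mito_frac`` are dropped.  A single
    pass, no re-iteration.
    """
    if data.normalized:
        raise ValueError("qc_filter operates on raw counts, not CPM")
    if isinstance(mito_prefix, str):
        mito_prefix = (mito_prefix,)

    gene_keep = np.count_nonzero(data.counts, axis=0) >= min_spots_per_gene
    counts = data.counts[:, gene_keep]
    gene_ids = [g for g, k in zip(data.gene_ids, gene_keep) if k]

    totals = counts.sum(axis=1)
    mito_cols = np.array([g.startswith(tuple(mito_prefix)) for g in gene_ids], dtype=bool)
    mito_totals = counts[:, mito_cols].sum(axis=1) if mito_cols.any() else np.zeros_like(totals)
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_frac = np.where(totals > 0, mito_totals / np.where(totals > 0, totals, 1), 0.0)
    spot_keep = (totals >= min_umi) & (mito_frac <= max_mito_frac)

    if not spot_keep.any() or not gene_keep.any():
        raise ValueError("empty matrix after QC")
    return STData(
        counts[spot_keep],
        data.coords[spot_keep],
        gene_ids,
        [s for s, k in zip(data.spot_ids, spot_keep) if k],
        normalized=False,
    )


def normalize_cpm(data: STData) -> STData:
    """Scale every spot to counts-per-million (rows sum to 1e6)."""
    if data.normalized:
        raise ValueError("data is already CPM-normalized")
    totals = data.counts.sum(axis=1)
    if np.any(totals <= 0):
        bad = [data.spot_ids[i] for i in np.flatnonzero(totals <= 0)]
        raise ValueError(f"zero-total spot(s) {bad}; run qc_filter first")
    out = data.copy()
    out.counts = data.counts * (CPM_TOTAL / totals)[:, None]
    out.normalized = True
    return out


def write_st_csv(data: STData, path: str) -> None:
    """Write the matrix as a dense CSV with ``"<row>x<col>"`` row labels."""
    labels = [f"{r}x{c}" for r, c in data.coords]
    pd.DataFrame(data.counts, index=labels, columns=data.gene_ids).to_csv(path)


def write_visium(data: STData, path: str) -> None:
    """Write a plain-file Visium-style bundle (all spots flagged in-tissue)."""
    os.makedirs(path, exist_ok=True)
    scio.mmwrite(os.path.join(path, "matrix.mtx"), sparse.csr_matrix(data.counts.T))
    with open(os.path.join(path, "barcodes.tsv"), "w") as fh:
        fh.write("\n".join(str(s) for s in data.spot_ids) + "\n")
    with open(os.path.join(path, "features.tsv"), "w") as fh:
        fh.write("\n".join(f"{g}\t{g}\tGene Expression" for g in data.gene_ids) + "\n")
    pos = pd.DataFrame(
        {
            "barcode": data.spot_ids,
            "in_tissue": 1,
            "array_row": data.coords[:, 0],
            "array_col": data.coords[:, 1],
        }
    )
    pos.to_csv(os.path.join(path, "tissue_positions.csv"), index=False)
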