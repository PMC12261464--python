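"""Cell×GO-BP functional profiles and their single-cell treatment.

The functional profile of a cell population is the matrix product of the
cell×gene count matrix with the binary gene×term annotation matrix: each
cell's entry for a term is the total count over the genes annotated to
that term. The profile is then treated like a count matrix in a classic
scRNA-seq workflow — per-cell total normalization with log1p, per-term
z-scaling, variable-feature selection, PCA, kNN graph, UMAP and Leiden
clustering — so that cells cluster by biological-process activity rather
than by gene identity.

Data live in an :class:`anndata.AnnData` with layers ``raw``,
``normalized`` and ``scaled``; scanpy performs the standard steps behind
this module's surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp

from .annotations import BinaryAnnotationMatrix
from .errors import DataError, UsageError

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Cell×gene counts with per-cell metadata.

    ``cell_meta`` is indexed by cell id and carries at least a
    ``cell_type`` column when cross-species comparison is requested.
    """

    cells: list[str]
    genes: list[str]
    counts: sp.csr_matrix
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if sp.issparse(self.counts):
            self.counts = sp.csr_matrix(self.counts)
        else:
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        if self.counts.nnz and self.counts.data.min() < 0:
            raise DataError("counts must be non-negative")


def read_counts_mtx(mtx_path, cells_path, genes_path) -> ExpressionMatrix:
    """Read counts from an MTX triplet with row=cell, column=gene sidecars."""
    from scipy.io import mmread

    counts = sp.csr_matrix(mmread(mtx_path))
    cells = _read_names(cells_path)
    genes = _read_names(genes_path)
    if counts.shape != (len(cells), len(genes)):
        raise DataError(
            f"matrix shape {counts.shape} does not match "
            f"{len(cells)} cells x {len(genes)} genes"
        )
    return ExpressionMatrix(cells=cells, genes=genes, counts=counts)


def read_counts_dense(path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a dense cell×gene table (first column = cell id, header = genes)."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    return ExpressionMatrix(
        cells=[str(c) for c in df.index],
        genes=[str(g) for g in df.columns],
        counts=sp.csr_matrix(df.to_numpy(dtype=float)),
    )


def read_cell_meta(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a cell-metadata table (first column = cell id)."""
    return pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)


def _read_names(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


class FunctionalProfile:
    """Cell×term functional profile with raw/normalized/scaled layers.

    Thin wrapper over AnnData: ``obs`` holds cell metadata (cell type,
    cluster labels), ``var`` is indexed by GO term id, ``obsm`` holds
    embeddings. Layer presence tracks pipeline progress.
    """

    def __init__(self, adata: ad.AnnData):
        self.adata = adata

    # -- convenience accessors -------------------------------------------
    @property
    def cells(self) -> list[str]:
        return list(self.adata.obs_names)

    @property
    def terms(self) -> list[str]:
        return list(self.adata.var_names)

    def layer(self, name: str) -> np.ndarray:
        if name not in self.adata.layers:
            raise UsageError(f"layer {name!r} not computed yet")
        x = self.adata.layers[name]
        return x.toarray() if sp.issparse(x) else np.asarray(x)

    @property
    def cell_meta(self) -> pd.DataFrame:
        return self.adata.obs

    def copy(self) -> "FunctionalProfile":
        return FunctionalProfile(self.adata.copy())


def build_profile(
    expr: ExpressionMatrix, bin_matrix: BinaryAnnotationMatrix
) -> FunctionalProfile:
    """Multiply counts with the binary annotation matrix over shared genes.

    Genes are aligned by id (inner join). All-zero term columns are
    dropped; all-zero cells are dropped with a logged count.
    """
    shared = [g for g in expr.genes if g in set(bin_matrix.genes)]
    if not shared:
        raise DataError("no genes shared between counts and annotations")
    e_idx = {g: i for i, g in enumerate(expr.genes)}
    b_idx = {g: i for i, g in enumerate(bin_matrix.genes)}
    counts = expr.counts[:, [e_idx[g] for g in shared]]
    indic = bin_matrix.matrix[[b_idx[g] for g in shared], :].astype(np.float64)

    raw = sp.csr_matrix(counts.astype(np.float64) @ indic)

    term_mask = np.asarray(raw.sum(axis=0)).ravel() > 0
    if not term_mask.any():
        raise DataError("annotation matrix is all-zero on the shared genes")
    cell_mask = np.asarray(raw.sum(axis=1)).ravel() > 0
    n_dropped = int((~cell_mask).sum())
    if n_dropped:
        logger.info("dropped %d cells with all-zero functional profiles", n_dropped)

    raw = raw[cell_mask, :][:, term_mask]
    obs = pd.DataFrame(index=pd.Index(np.array(expr.cells)[cell_mask], name="cell"))
    if len(expr.cell_meta):
        obs = obs.join(expr.cell_meta)
    adata = ad.AnnData(
        X=raw.copy(),
        obs=obs,
        var=pd.DataFrame(
            index=pd.Index(np.array(bin_matrix.terms)[term_mask], name="term")
        ),
        layers={"raw": raw},
    )
    return FunctionalProfile(adata)


def normalize(profile: FunctionalProfile, total: float = 1e4) -> FunctionalProfile:
    """Per-cell total-count normalization to ``total`` followed by ln(1+x).

    Cells with zero raw total are removed beforehand (none survive
    :func:`build_profile`, but re-normalization after subsetting can
    produce them).
    """
    adata = profile.adata
    totals = np.asarray(sp.csr_matrix(adata.layers["raw"]).sum(axis=1)).ravel()
    if (totals == 0).any():
        adata = adata[totals > 0].copy()
    adata.X = sp.csr_matrix(adata.layers["raw"]).astype(np.float64)
    sc.pp.normalize_total(adata, target_sum=total)
    sc.pp.log1p(adata)
    del adata.uns["log1p"]
    adata.layers["normalized"] = adata.X.copy()
    return FunctionalProfile(adata)


def scale(profile: FunctionalProfile, clip: float = 10.0) -> FunctionalProfile:
    """Per-term z-score across cells, clipped to ``[-clip, clip]``.

    Uses the sample (n−1) standard deviation; zero-variance terms are set
    to 0.
    """
    adata = profile.adata
    x = profile.layer("normalized")
    adata.layers["scaled"] = zscore_columns(x, clip=clip)
    return FunctionalProfile(adata)


def zscore_columns(x: np.ndarray, clip: float = 10.0) -> np.ndarray:
    """Columnwise z-score with ddof=1 and symmetric clipping."""
    x = np.asarray(x, dtype=np.float64)
    mean = x.mean(axis=0)
    if x.shape[0] > 1:
        sd = x.std(axis=0, ddof=1)
    else:
        sd = np.zeros(x.shape[1])
    out = np.zeros_like(x)
    nz = sd > 0
    out[:, nz] = (x[:, nz] - mean[nz]) / sd[nz]
    np.clip(out, -clip, clip, out=out)
    return out


def select_variable_terms(profile: FunctionalProfile, n: int = 2000) -> list[str]:
    """Rank terms by standardized dispersion and return the top ``n``.

    The statistic is the dispersion (variance/mean of the de-logged
    normalized layer), z-standardized within 20 equal-frequency mean bins —
    so a term is "variable" relative to terms of similar abundance. Ties
    are broken by term-id lexical order for determinism. If fewer than
    ``n`` terms exist, all are returned (ranked).
    """
    stat = standardized_dispersion(profile.layer("normalized"))
    terms = np.asarray(profile.terms)
    order = np.lexsort((terms, -stat))
    ranked = terms[order].tolist()
    profile.adata.var["dispersion_norm"] = stat
    profile.adata.var["highly_variable"] = False
    chosen = ranked[: min(n, len(ranked))]
    profile.adata.var.loc[chosen, "highly_variable"] = True
    return chosen


def standardized_dispersion(normalized: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Dispersion of expm1(normalized), z-scored within mean-abundance bins.

    Mirrors the classic mean-binned normalized-dispersion statistic. Bins
    with fewer than 2 members, or zero spread, fall back to a spread of 1
    so their members keep a finite score.
    """
    x = np.expm1(np.asarray(normalized, dtype=np.float64))
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    log_disp = np.log1p(disp)

    n_terms = len(mean)
    n_bins = max(1, min(n_bins, n_terms))
    # equal-frequency bins on the mean
    quantiles = np.quantile(mean, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(quantiles, mean, side="right") - 1, 0, n_bins - 1)
    stat = np.zeros(n_terms)
    for b in np.unique(bins):
        members = bins == b
        vals = log_disp[members]
        center = vals.mean()
        spread = vals.std(ddof=1) if members.sum() > 1 else 0.0
        if spread <= 0:
            spread = 1.0
        stat[members] = (vals - center) / spread
    return stat


def embed_and_cluster(
    profile: FunctionalProfile,
    n_pcs: int = 50,
    k_neighbors: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
    n_variable: int = 2000,
) -> FunctionalProfile:
    """PCA on variable terms, kNN graph, UMAP and Leiden clustering.

    All randomized steps (PCA solver, UMAP, Leiden refinement) consume
    ``seed``; the same seed yields identical labels and coordinates.
    """
    adata = profile.adata
    n_cells, n_terms = adata.shape
    if n_pcs >= min(n_cells, n_terms):
        raise UsageError(
            f"n_pcs={n_pcs} must be < min(cells, terms) = {min(n_cells, n_terms)}"
        )
    if "highly_variable" not in adata.var:
        select_variable_terms(profile, n=n_variable)
    adata.X = np.asarray(profile.layer("scaled"))
    sc.pp.pca(
        adata, n_comps=n_pcs, mask_var="highly_variable", svd_solver="arpack",
        random_state=seed,
    )
    sc.pp.neighbors(adata, n_neighbors=k_neighbors, n_pcs=n_pcs, random_state=seed)
    sc.tl.leiden(
        adata,
        resolution=resolution,
        random_state=seed,
        key_added="cluster",
        flavor="leidenalg",
    )
    sc.tl.umap(adata, random_state=seed)
    return FunctionalProfile(adata)


def write_profile(profile: FunctionalProfile, prefix: str) -> None:
    """Write layers as MTX triplets plus a metadata table with clusters/UMAP."""
    from scipy.io import mmwrite

    adata = profile.adata
    for name in ("raw", "normalized", "scaled"):
        if name in adata.layers:
            mmwrite(f"{prefix}.{name}.mtx", sp.coo_matrix(adata.layers[name]))
    with open(f"{prefix}.cells.txt", "w") as fh:
        fh.write("\n".join(profile.cells) + "\n")
    with open(f"{prefix}.terms.txt", "w") as fh:
        fh.write("\n".join(profile.terms) + "\n")
    meta = adata.obs.copy()
    if "X_umap" in adata.obsm:
        meta[["umap_1", "umap_2"]] = np.asarray(adata.obsm["X_umap"])
    meta.to_csv(f"{prefix}.cell_meta.tsv", sep="\t")


def read_profile(prefix: str) -> FunctionalProfile:
    """Reload a profile written by :func:`write_profile`."""
    from scipy.io import mmread

    cells = _read_names(f"{prefix}.cells.txt")
    terms = _read_names(f"{prefix}.terms.txt")
    meta = pd.read_csv(f"{prefix}.cell_meta.tsv", sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    layers = {}
    import os

    for name in ("raw", "normalized", "scaled"):
        path = f"{prefix}.{name}.mtx"
        if os.path.exists(path):
            layers[name] = sp.csr_matrix(mmread(path))
    adata = ad.AnnData(
        X=layers["raw"].copy(),
        obs=meta.loc[cells],
        var=pd.DataFrame(index=pd.Index(terms, name="term")),
        layers=layers,
    )
    return FunctionalProfile(adata)
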