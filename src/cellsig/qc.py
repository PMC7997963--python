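"""Cell/gene QC filters, log-normalization, per-gene scaling, downsampling.

Conventions follow the droplet-processing recipe this package reproduces:
cells with *more than* ``max_mito_fraction`` mitochondrial counts or *fewer
than* ``min_genes_per_cell`` detected genes are removed (strict inequalities,
so a cell at exactly 10% mito and exactly 500 genes is kept); among retained
cells, genes detected in more than ``min_cells_per_gene`` cells are kept.
Normalization is counts-per-``scale_factor`` followed by ``log1p``; scaling is
per-gene centering and division by the sample (n-1) standard deviation with
symmetric clipping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
from scipy import sparse

from .exceptions import ConfigError, EmptyResultError

logger = logging.getLogger(__name__)

LAYER_LOGNORM = "lognorm"
LAYER_SCALED = "scaled"


@dataclass(frozen=True)
class QCConfig:
    """QC and normalization thresholds.

    Defaults: cells above 10% mitochondrial content or below 500 detected
    genes are dropped; genes must be detected in more than 3 cells; counts are
    normalized to 10,000 per cell; scaled values are clipped at +/-10.
    """

    max_mito_fraction: float = 0.10
    min_genes_per_cell: int = 500
    min_cells_per_gene: int = 3
    scale_factor: float = 10_000.0
    clip_value: float | None = 10.0
    mito_prefix: str = "mt-"

    def __post_init__(self):
        if not 0 <= self.max_mito_fraction <= 1:
            raise ConfigError("max_mito_fraction must be in [0, 1]")
        if self.min_genes_per_cell < 0 or self.min_cells_per_gene < 0:
            raise ConfigError("QC count thresholds must be nonnegative")
        if self.scale_factor <= 0:
            raise ConfigError("scale_factor must be positive")
        if self.clip_value is not None and self.clip_value <= 0:
            raise ConfigError("clip_value must be positive or None")


def _counts(adata: ad.AnnData) -> sparse.csr_matrix:
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    return X.tocsr()


def mito_fraction(adata: ad.AnnData, mito_prefix: str = "mt-") -> np.ndarray:
    """Per-cell share of raw counts on mitochondrial genes (prefix match)."""
    X = _counts(adata)
    is_mito = adata.var_names.str.startswith(mito_prefix)
    total = np.asarray(X.sum(axis=1)).ravel()
    mito = np.asarray(X[:, np.flatnonzero(is_mito)].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return frac


def filter_cells(adata: ad.AnnData, qc: QCConfig = QCConfig()) -> ad.AnnData:
    """Remove high-mito and low-complexity cells (strict thresholds).

    Keeps cells with mito share <= ``max_mito_fraction`` AND detected genes
    >= ``min_genes_per_cell``, computed on raw counts.
    """
    X = _counts(adata)
    frac = mito_fraction(adata, qc.mito_prefix)
    n_detected = X.getnnz(axis=1)
    keep_mito = frac <= qc.max_mito_fraction
    keep_genes = n_detected >= qc.min_genes_per_cell
    keep = keep_mito & keep_genes
    logger.info(
        "filter_cells: removed %d/%d cells (%d mito > %.0f%%, %d genes < %d)",
        int((~keep).sum()), adata.n_obs, int((~keep_mito).sum()),
        100 * qc.max_mito_fraction, int((~keep_genes).sum()), qc.min_genes_per_cell,
    )
    if not keep.any():
        raise EmptyResultError("no cell passes QC; check thresholds and mito prefix")
    out = adata[keep].copy()
    out.uns["qc_cells_removed"] = {
        "total": int((~keep).sum()),
        "high_mito": int((~keep_mito).sum()),
        "low_genes": int((~keep_genes).sum()),
    }
    return out


def filter_genes(adata: ad.AnnData, qc: QCConfig = QCConfig()) -> ad.AnnData:
    """Keep genes detected (nonzero) in strictly more than ``min_cells_per_gene`` cells.

    Applied after :func:`filter_cells`, so detection is counted among retained
    cells only.
    """
    X = _counts(adata)
    n_cells_detected = X.getnnz(axis=0)
    keep = n_cells_detected > qc.min_cells_per_gene
    logger.info("filter_genes: removed %d/%d genes detected in <= %d cells",
                int((~keep).sum()), adata.n_vars, qc.min_cells_per_gene)
    out = adata[:, keep].copy()
    out.uns["qc_genes_removed"] = int((~keep).sum())
    return out


def normalize_log(adata: ad.AnnData, qc: QCConfig = QCConfig()) -> ad.AnnData:
    """Depth-normalize and log-transform: log1p(count / cell_total * scale_factor).

    Stores the result in ``adata.layers['lognorm']`` and returns the object.
    """
    X = _counts(adata).astype(np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise EmptyResultError(
            "cells with zero total counts present; run filter_cells first"
        )
    norm = X.multiply(qc.scale_factor / totals[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    adata.layers[LAYER_LOGNORM] = norm
    return adata


def scale_genes(adata: ad.AnnData, qc: QCConfig = QCConfig()) -> ad.AnnData:
    """Center each gene and divide by its sample (n-1) standard deviation.

    Operates on the log-normalized layer, stores a dense float32 matrix in
    ``adata.layers['scaled']``. Constant genes become all-zeros; values are
    clipped to ``[-clip_value, +clip_value]`` when clipping is enabled.
    """
    if adata.n_obs < 2:
        raise ConfigError("scaling needs at least 2 cells (sd undefined otherwise)")
    if LAYER_LOGNORM not in adata.layers:
        normalize_log(adata, qc)
    lay = adata.layers[LAYER_LOGNORM]
    X = lay.toarray().astype(np.float64) if sparse.issparse(lay) else np.array(lay, dtype=np.float64)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    nonconst = sd > 0
    X -= mean
    X[:, nonconst] /= sd[nonconst]
    X[:, ~nonconst] = 0.0
    if qc.clip_value is not None:
        np.clip(X, -qc.clip_value, qc.clip_value, out=X)
    adata.layers[LAYER_SCALED] = X.astype(np.float32)
    return adata


def downsample_equal(
    adata: ad.AnnData, group_key: str, n_per_group: int, seed: int
) -> ad.AnnData:
    """Uniform without-replacement subsample of ``n_per_group`` cells per group."""
    if group_key not in adata.obs:
        raise ConfigError(f"unknown obs column '{group_key}'")
    rng = np.random.default_rng(seed)
    keep = []
    for group, idx in adata.obs.groupby(group_key, observed=True).indices.items():
        if len(idx) < n_per_group:
            raise ConfigError(
                f"group '{group}' has {len(idx)} cells, fewer than the "
                f"requested {n_per_group}"
            )
        keep.append(rng.choice(idx, size=n_per_group, replace=False))
    keep = np.sort(np.concatenate(keep))
    logger.info("downsample_equal: kept %d cells (%d per %s group)",
                keep.size, n_per_group, group_key)
    return adata[keep].copy()
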