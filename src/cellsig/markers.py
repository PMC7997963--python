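"""One-vs-rest marker detection and cluster-composition shift tests.

Marker detection mirrors the classic one-vs-rest Wilcoxon recipe with limit
testing: a gene is only tested when it is detected in at least ``min_pct`` of
the cells in the cluster or in the rest, and when its average log fold-change
(natural log of mean expm1 expression + 1) is at least ``logfc_min`` in
magnitude. Surviving genes get a Wilcoxon rank-sum p-value and a Bonferroni
adjustment over the *total* number of genes in the matrix.

Composition shifts between the two conditions are tested per cluster with the
same Fisher exact routine used by the enrichment module, with BH adjustment
across clusters.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

from .exceptions import ConfigError
from .qc import LAYER_LOGNORM
from ._stats import bh_adjust, fisher_exact_2x2

logger = logging.getLogger(__name__)


def _lognorm_dense(adata: ad.AnnData, layer: str) -> np.ndarray:
    if layer not in adata.layers:
        raise ConfigError(f"layer '{layer}' missing; run normalize_log first")
    X = adata.layers[layer]
    return X.toarray().astype(np.float64) if sparse.issparse(X) else np.asarray(X, dtype=np.float64)


def log_fold_change(x_in: np.ndarray, x_out: np.ndarray) -> np.ndarray:
    """ln(mean(expm1(in)) + 1) - ln(mean(expm1(out)) + 1), per gene (columns)."""
    return np.log(np.expm1(x_in).mean(axis=0) + 1.0) - np.log(
        np.expm1(x_out).mean(axis=0) + 1.0
    )


def find_markers(
    adata: ad.AnnData,
    cluster_key: str = "cluster",
    layer: str = LAYER_LOGNORM,
    logfc_min: float = 0.25,
    min_pct: float = 0.25,
    fc_method: str = "expm1_mean",
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon markers per cluster with limit testing.

    Returns a DataFrame with columns ``gene, cluster, avg_logFC, pct.1, pct.2,
    p_val, p_val_adj`` containing only genes passing both pre-filters;
    ``.attrs['n_tested']`` records the number of Wilcoxon tests per cluster.
    ``fc_method='mean_diff'`` switches the fold-change to the simple
    difference of mean log expression.
    """
    if cluster_key not in adata.obs:
        raise ConfigError(f"obs column '{cluster_key}' not found")
    if fc_method not in ("expm1_mean", "mean_diff"):
        raise ConfigError(f"unknown fc_method '{fc_method}'")
    X = _lognorm_dense(adata, layer)
    clusters = np.asarray(adata.obs[cluster_key]).astype(str)
    labels = np.unique(clusters)
    if len(labels) < 2:
        raise ConfigError("marker detection needs at least 2 clusters")
    sizes = {lab: int((clusters == lab).sum()) for lab in labels}
    for lab, n in sizes.items():
        if n < 3:
            raise ConfigError(f"cluster '{lab}' has only {n} cells (< 3)")

    detected = X > 0
    genes = np.asarray(adata.var_names)
    n_genes_total = adata.n_vars
    rows = []
    n_tested = {}
    for lab in labels:
        in_mask = clusters == lab
        Xi, Xo = X[in_mask], X[~in_mask]
        pct_in = detected[in_mask].mean(axis=0)
        pct_out = detected[~in_mask].mean(axis=0)
        if fc_method == "expm1_mean":
            lfc = log_fold_change(Xi, Xo)
        else:
            lfc = Xi.mean(axis=0) - Xo.mean(axis=0)
        keep = (np.maximum(pct_in, pct_out) >= min_pct) & (np.abs(lfc) >= logfc_min)
        idx = np.flatnonzero(keep)
        n_tested[lab] = idx.size
        if idx.size == 0:
            continue
        res = stats.mannwhitneyu(
            Xi[:, idx], Xo[:, idx], alternative="two-sided",
            method="asymptotic", axis=0,
        )
        p = np.asarray(res.pvalue, dtype=float)
        rows.append(pd.DataFrame({
            "gene": genes[idx],
            "cluster": lab,
            "avg_logFC": lfc[idx],
            "pct.1": pct_in[idx],
            "pct.2": pct_out[idx],
            "p_val": p,
            "p_val_adj": np.minimum(p * n_genes_total, 1.0),
        }))
    out = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["gene", "cluster", "avg_logFC", "pct.1",
                                   "pct.2", "p_val", "p_val_adj"])
    )
    out = out.sort_values(["cluster", "p_val"], kind="stable").reset_index(drop=True)
    out.attrs["n_tested"] = n_tested
    logger.info("find_markers: tested %s genes per cluster",
                {k: int(v) for k, v in n_tested.items()})
    return out


def cluster_shift_fisher(
    cluster_labels, condition_labels, alternative: str = "two-sided"
) -> pd.DataFrame:
    """Per-cluster Fisher exact test of condition composition.

    For each cluster the 2x2 table is (in-cluster vs out-of-cluster) x
    (condition 1 vs condition 2). Returns one row per cluster with the table
    counts, odds ratio, raw p and BH-adjusted p across clusters.
    """
    clusters = np.asarray(cluster_labels).astype(str)
    conditions = np.asarray(condition_labels).astype(str)
    if clusters.shape != conditions.shape:
        raise ConfigError("cluster and condition label vectors differ in length")
    conds = np.unique(conditions)
    if len(conds) != 2:
        raise ConfigError(f"exactly two conditions required, found {list(conds)}")
    rows = []
    for lab in np.unique(clusters):
        in_c = clusters == lab
        a = int((in_c & (conditions == conds[0])).sum())
        b = int((in_c & (conditions == conds[1])).sum())
        c = int((~in_c & (conditions == conds[0])).sum())
        d = int((~in_c & (conditions == conds[1])).sum())
        odds, p = fisher_exact_2x2([[a, b], [c, d]], alternative=alternative)
        rows.append({
            "cluster": lab,
            f"n_{conds[0]}": a, f"n_{conds[1]}": b,
            f"rest_{conds[0]}": c, f"rest_{conds[1]}": d,
            "odds_ratio": odds, "p_val": p,
        })
    out = pd.DataFrame(rows)
    out["p_val_adj"] = bh_adjust(out["p_val"].to_numpy())
    return out
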