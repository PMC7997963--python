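"""Two-condition, multi-cluster scRNA-seq count simulator with planted effects.

The generative law is a gamma-Poisson (negative-binomial) droplet model:

* per-gene baseline means are log-normal across genes;
* each cluster multiplies a random subset of genes by log-normal modifiers,
  giving marker-like structure;
* planted signature effects multiply the member genes by ``exp(log_fold)`` in
  one condition only;
* per-cell expected expression is renormalized so that the designated
  mitochondrial genes (``mt-`` prefix) receive exactly the cell's drawn
  mitochondrial fraction, and the cell's total expected depth equals
  ``mean_depth`` times a log-normal size factor;
* counts are negative-binomial with variance mu + dispersion * mu^2.

Every drawn parameter is recorded in :class:`SimTruth`, so downstream stages
can be tested against ground truth without external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .exceptions import ConfigError
from .signatures import GeneSignature

logger = logging.getLogger(__name__)

MITO_PREFIX = "mt-"


@dataclass(frozen=True)
class PlantedEffect:
    """A signature-level expression shift planted in one condition.

    ``up_log_fold`` is the natural-log mean shift applied to the signature's
    up-regulated members in ``target_condition``; ``down_log_fold`` (typically
    negative) is applied to the down-regulated members.
    """

    signature: GeneSignature
    target_condition: str
    up_log_fold: float = 0.0
    down_log_fold: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic two-condition experiment.

    Defaults emulate a modest droplet experiment: overdispersed counts,
    ~5% mitochondrial content, 2x spread in library size, and a few
    transcriptionally distinct subpopulations shared by both conditions.
    """

    n_genes: int = 2000
    n_cells_per_condition: int = 500
    n_clusters: int = 3
    baseline_mean_log: float = 0.0
    baseline_sigma_log: float = 1.0
    dispersion: float = 0.5
    libsize_sigma: float = 0.35
    mean_depth: float = 2000.0
    mito_fraction_beta: tuple[float, float] = (2.0, 38.0)
    n_mito_genes: int = 13
    frac_cluster_genes: float = 0.10
    cluster_effect_sigma: float = 0.7
    conditions: tuple[str, str] = ("shNC", "shSELP")
    planted_effects: tuple[PlantedEffect, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_cells_per_condition < 1 or self.n_clusters < 1:
            raise ConfigError("n_genes, n_cells_per_condition, n_clusters must be >= 1")
        if self.dispersion <= 0 or self.mean_depth <= 0:
            raise ConfigError("dispersion and mean_depth must be positive")
        if self.libsize_sigma < 0:
            raise ConfigError("libsize_sigma must be nonnegative")
        a, b = self.mito_fraction_beta
        if a <= 0 or b <= 0:
            raise ConfigError("mito_fraction_beta parameters must be positive")
        if not 0 <= self.n_mito_genes < self.n_genes:
            raise ConfigError("n_mito_genes must be in [0, n_genes)")
        if len(set(self.conditions)) != 2:
            raise ConfigError("exactly two distinct condition labels required")
        object.__setattr__(self, "planted_effects", tuple(self.planted_effects))
        for eff in self.planted_effects:
            if eff.target_condition not in self.conditions:
                raise ConfigError(
                    f"planted effect targets unknown condition "
                    f"'{eff.target_condition}'"
                )


@dataclass(frozen=True)
class SimTruth:
    """Ground truth emitted alongside the simulated counts.

    ``gene_table`` is indexed by gene with the baseline mean, mito flag,
    per-cluster modifier columns (``cluster_mod_<k>``) and per-condition
    applied log-fold columns (``lfc_<condition>``). ``cell_table`` is indexed
    by barcode with condition, cluster, size factor, expected depth and drawn
    mitochondrial fraction.
    """

    gene_table: pd.DataFrame
    cell_table: pd.DataFrame
    config: SimConfig = field(repr=False, default=None)


def gene_names(config: SimConfig) -> list[str]:
    """The simulated gene universe: mito genes first, then numbered genes."""
    mito = [f"{MITO_PREFIX}{i + 1}" for i in range(config.n_mito_genes)]
    rest = [f"gene{i:05d}" for i in range(config.n_genes - config.n_mito_genes)]
    return mito + rest


def pick_signature(
    config: SimConfig, n_up: int, n_down: int = 0, name: str = "planted", seed: int = 0
) -> GeneSignature:
    """Draw a random non-mitochondrial signature from the simulated universe."""
    rng = np.random.default_rng(seed)
    pool = [g for g in gene_names(config) if not g.startswith(MITO_PREFIX)]
    if n_up + n_down > len(pool):
        raise ConfigError("signature larger than the non-mito gene universe")
    chosen = rng.choice(len(pool), size=n_up + n_down, replace=False)
    genes = [pool[i] for i in chosen]
    return GeneSignature(name, tuple(genes[:n_up]), tuple(genes[n_up:]))


def simulate_counts(config: SimConfig) -> tuple[ad.AnnData, SimTruth]:
    """Draw a count matrix and its ground truth from the generative model.

    Returns an :class:`anndata.AnnData` with raw integer counts in ``.X``
    (CSR), condition and cluster labels in ``.obs``, and the matching
    :class:`SimTruth`. Identical config (including seed) gives bit-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    genes = gene_names(config)
    gene_index = {g: i for i, g in enumerate(genes)}
    is_mito = np.array([g.startswith(MITO_PREFIX) for g in genes])
    n_genes = config.n_genes
    n_cells = 2 * config.n_cells_per_condition

    for eff in config.planted_effects:
        for g in eff.signature.members:
            if g not in gene_index:
                raise ConfigError(
                    f"planted signature '{eff.signature.name}' names gene "
                    f"'{g}' absent from the simulated universe"
                )

    baseline = np.exp(
        rng.normal(config.baseline_mean_log, config.baseline_sigma_log, n_genes)
    )

    # per-cluster multiplicative modifiers on a random non-mito gene subset
    cluster_mod = np.ones((config.n_clusters, n_genes))
    n_mod = int(round(config.frac_cluster_genes * n_genes))
    nonmito_idx = np.flatnonzero(~is_mito)
    for k in range(config.n_clusters):
        affected = rng.choice(nonmito_idx, size=min(n_mod, nonmito_idx.size),
                              replace=False)
        cluster_mod[k, affected] = np.exp(
            rng.normal(0.0, config.cluster_effect_sigma, affected.size)
        )

    # per-condition planted log-folds
    lfc = {cond: np.zeros(n_genes) for cond in config.conditions}
    for eff in config.planted_effects:
        for g in eff.signature.up_genes:
            lfc[eff.target_condition][gene_index[g]] += eff.up_log_fold
        for g in eff.signature.down_genes:
            lfc[eff.target_condition][gene_index[g]] += eff.down_log_fold

    condition = np.repeat(list(config.conditions), config.n_cells_per_condition)
    cluster = rng.integers(config.n_clusters, size=n_cells)
    size_factor = np.exp(rng.normal(0.0, config.libsize_sigma, n_cells))
    depth = config.mean_depth * size_factor
    a, b = config.mito_fraction_beta
    mito_frac = rng.beta(a, b, n_cells)

    # expected expression: baseline x cluster modifier x planted shift,
    # then renormalized per cell so mito share == drawn fraction and the
    # total equals the cell's expected depth
    mu = np.empty((n_cells, n_genes))
    for cond in config.conditions:
        mask = condition == cond
        mu[mask] = (baseline * np.exp(lfc[cond]))[None, :] * cluster_mod[cluster[mask]]
    nonmito_total = mu[:, ~is_mito].sum(axis=1)
    scale_nonmito = depth * (1.0 - mito_frac) / nonmito_total
    mu[:, ~is_mito] *= scale_nonmito[:, None]
    if is_mito.any():
        mito_total = mu[:, is_mito].sum(axis=1)
        mu[:, is_mito] *= (depth * mito_frac / mito_total)[:, None]

    shape = 1.0 / config.dispersion
    counts = rng.negative_binomial(shape, shape / (shape + mu)).astype(np.int32)

    obs = pd.DataFrame(
        {
            "condition": pd.Categorical(condition, categories=list(config.conditions)),
            "cluster": pd.Categorical(cluster.astype(str)),
        },
        index=[f"{cond}_{i:05d}" for cond, i in
               zip(condition, np.concatenate([np.arange(config.n_cells_per_condition)] * 2))],
    )
    var = pd.DataFrame({"is_mito": is_mito}, index=pd.Index(genes, name="gene"))
    adata = ad.AnnData(X=sparse.csr_matrix(counts), obs=obs, var=var)

    gene_table = pd.DataFrame({"baseline_mean": baseline, "is_mito": is_mito},
                              index=var.index)
    for k in range(config.n_clusters):
        gene_table[f"cluster_mod_{k}"] = cluster_mod[k]
    for cond in config.conditions:
        gene_table[f"lfc_{cond}"] = lfc[cond]
    cell_table = pd.DataFrame(
        {
            "condition": condition,
            "cluster": cluster.astype(str),
            "size_factor": size_factor,
            "expected_depth": depth,
            "mito_fraction": mito_frac,
        },
        index=obs.index.rename("barcode"),
    )
    truth = SimTruth(gene_table=gene_table, cell_table=cell_table, config=config)
    logger.info("simulated %d cells x %d genes (%d clusters, %d planted effects)",
                n_cells, n_genes, config.n_clusters, len(config.planted_effects))
    return adata, truth


def null_config(config: SimConfig) -> SimConfig:
    """The same experiment with all planted effects removed."""
    return replace(config, planted_effects=())
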