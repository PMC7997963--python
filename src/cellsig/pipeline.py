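"""End-to-end pipeline: QC -> normalize -> scale -> downsample -> score ->
CERNO -> FDR -> Fisher/Wilcoxon -> markers/composition.

Configured by a YAML file (or an equivalent dict) with exactly one input
source: either the paths of an MTX triplet + GMT file, or a ``sim`` block
describing a synthetic experiment. Each run writes result TSVs plus a
``manifest.json`` with the config hash, seed, package version and per-stage
entity counts, which together suffice to reproduce the run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .exceptions import ConfigError, PipelineStageError
from .enrichment import SignatureEnrichment
from .io import read_10x_mtx, read_gmt, write_10x, write_cerno_tsv, write_gmt, write_scores_tsv
from .markers import cluster_shift_fisher, find_markers
from .qc import QCConfig, downsample_equal, filter_cells, filter_genes, normalize_log, scale_genes
from .simulate import PlantedEffect, SimConfig, pick_signature, simulate_counts

logger = logging.getLogger(__name__)

CONFIG_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration.

    Exactly one of ``input`` (dict with ``mtx_dir`` and ``gmt``) and ``sim``
    (dict understood by :func:`build_sim_config`) must be given.
    """

    outdir: str
    seed: int = 0
    input: dict | None = None
    sim: dict | None = None
    qc: dict = field(default_factory=dict)
    downsample_per_group: int | None = None
    q_threshold: float = 0.05
    fisher_sided: str = "two-sided"
    cerno_matrix: str = "normalized"  # or "scaled"
    logfc_min: float = 0.25
    min_pct: float = 0.25
    condition_key: str = "condition"
    cluster_key: str = "cluster"
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.input is None) == (self.sim is None):
            raise ConfigError("config must set exactly one of 'input' and 'sim'")
        if self.cerno_matrix not in ("normalized", "scaled"):
            raise ConfigError("cerno_matrix must be 'normalized' or 'scaled'")
        if self.input is not None:
            for key in ("mtx_dir", "gmt"):
                if key not in self.input:
                    raise ConfigError(f"input block missing '{key}'")
                if not Path(self.input[key]).exists():
                    raise ConfigError(f"input path does not exist: {self.input[key]}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.pop("schema_version", None)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {"schema_version": CONFIG_SCHEMA_VERSION}
        d.update({k: v for k, v in self.__dict__.items()})
        return d


def build_sim_config(sim: dict, seed: int) -> tuple[SimConfig, list]:
    """Translate a config 'sim' block into a SimConfig with planted effects.

    The block may carry a ``planted`` list of
    ``{name, n_up, n_down, target_condition, up_log_fold, down_log_fold}``
    entries; member genes are drawn deterministically from the universe.
    """
    sim = dict(sim)
    planted_spec = sim.pop("planted", [])
    base = SimConfig(**sim, seed=seed)
    effects, signatures = [], []
    for i, spec in enumerate(planted_spec):
        sig = pick_signature(
            base, n_up=int(spec.get("n_up", 50)), n_down=int(spec.get("n_down", 0)),
            name=spec.get("name", f"planted_{i}"), seed=seed + 1000 + i,
        )
        signatures.append(sig)
        effects.append(PlantedEffect(
            signature=sig,
            target_condition=spec.get("target_condition", base.conditions[1]),
            up_log_fold=float(spec.get("up_log_fold", 0.0)),
            down_log_fold=float(spec.get("down_log_fold", 0.0)),
        ))
    from dataclasses import replace
    return replace(base, planted_effects=tuple(effects)), signatures


def _stage(name):
    def decorate(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage name attached
                raise PipelineStageError(name, exc) from exc
        return wrapped
    return decorate


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts_log: dict[str, int] = {}

    @_stage("input")
    def load():
        if config.sim is not None:
            sim_config, sigs = build_sim_config(config.sim, config.seed)
            adata, truth = simulate_counts(sim_config)
            truth.gene_table.to_csv(outdir / "sim_truth_genes.tsv", sep="\t")
            truth.cell_table.to_csv(outdir / "sim_truth_cells.tsv", sep="\t")
            if not sigs:
                raise ConfigError("sim block needs at least one planted "
                                  "signature (effect sizes may be 0)")
            write_gmt(sigs, outdir / "signatures.gmt")
            return adata, sigs
        adata = read_10x_mtx(config.input["mtx_dir"])
        sigs = read_gmt(config.input["gmt"])
        if not sigs:
            raise ConfigError("GMT file contains no signatures")
        return adata, sigs

    adata, signatures = load()
    counts_log["cells_in"], counts_log["genes_in"] = adata.shape
    qc = QCConfig(**config.qc)

    @_stage("qc")
    def do_qc(adata):
        adata = filter_cells(adata, qc)
        adata = filter_genes(adata, qc)
        return adata

    adata = do_qc(adata)
    counts_log["cells_qc"], counts_log["genes_qc"] = adata.shape

    @_stage("normalize")
    def do_norm(adata):
        return scale_genes(normalize_log(adata, qc), qc)

    adata = do_norm(adata)

    if config.downsample_per_group is not None:
        adata = _stage("downsample")(downsample_equal)(
            adata, config.condition_key, config.downsample_per_group,
            config.seed + 7,
        )
    counts_log["cells_final"] = adata.n_obs

    cerno_layer = "lognorm" if config.cerno_matrix == "normalized" else "scaled"
    summary_rows = []
    all_scores = []

    @_stage("enrichment")
    def do_enrich(sig):
        model = SignatureEnrichment(
            adata, sig, condition_key=config.condition_key,
            cerno_layer=cerno_layer, q_threshold=config.q_threshold,
            alternative=config.fisher_sided,
        )
        return model.fit()

    for sig in signatures:
        res = do_enrich(sig)
        all_scores.append(res.scores)
        write_cerno_tsv(res.cerno, outdir / f"cerno_{sig.name}.tsv",
                        config.q_threshold)
        ct = res.condition_test
        summary_rows.append({
            "signature": sig.name,
            "a": int(ct.table[0, 0]), "b": int(ct.table[0, 1]),
            "c": int(ct.table[1, 0]), "d": int(ct.table[1, 1]),
            "odds_ratio": ct.odds_ratio, "fisher_p": ct.p,
            "enriched_condition": ct.enriched_condition,
            "wilcoxon_p": res.wilcoxon_p,
        })
    write_scores_tsv(all_scores, outdir / "scores.tsv")
    import pandas as pd
    pd.DataFrame(summary_rows).to_csv(outdir / "enrichment_summary.tsv",
                                      sep="\t", index=False)

    if config.cluster_key in adata.obs:
        markers = _stage("markers")(find_markers)(
            adata, cluster_key=config.cluster_key,
            logfc_min=config.logfc_min, min_pct=config.min_pct,
        )
        markers.to_csv(outdir / "markers.tsv", sep="\t", index=False)
        counts_log["marker_rows"] = len(markers)
        comp = _stage("composition")(cluster_shift_fisher)(
            np.asarray(adata.obs[config.cluster_key]).astype(str),
            np.asarray(adata.obs[config.condition_key]).astype(str),
        )
        comp.to_csv(outdir / "composition.tsv", sep="\t", index=False)

    # hash identifies the analysis, not where it was written
    hashed = {k: v for k, v in config.to_dict().items() if k != "outdir"}
    config_yaml = yaml.safe_dump(hashed, sort_keys=True)
    manifest = {
        "package": "cellsig",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_yaml.encode()).hexdigest(),
        "counts": counts_log,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))
    logger.info("pipeline complete: %s", counts_log)
    return manifest
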