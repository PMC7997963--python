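"""Simulation studies: type-I error and power of the condition-enrichment test.

These routines run the full per-cell pipeline (simulate -> normalize -> CERNO
-> FDR -> Fisher) many times and summarize the rejection behavior. They back
both the calibration tests and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .enrichment import cerno_cell, fdr_correct, fisher_condition_enrichment
from .qc import normalize_log, scale_genes
from .scoring import score_signature
from .simulate import PlantedEffect, SimConfig, pick_signature, simulate_counts


@dataclass(frozen=True)
class StudyResult:
    """Summary of repeated simulation runs of the condition-enrichment test."""

    n_runs: int
    rejections: int
    correct_direction: int
    score_direction_correct: int
    fisher_p: np.ndarray

    @property
    def rejection_rate(self) -> float:
        return self.rejections / self.n_runs


def _study_config(n_cells: int, n_genes: int) -> SimConfig:
    return SimConfig(n_genes=n_genes, n_cells_per_condition=n_cells)


def run_enrichment_study(
    n_runs: int,
    seed: int,
    up_log_fold: float = 0.0,
    n_cells: int = 500,
    n_genes: int = 2000,
    signature_size: int = 50,
    alpha: float = 0.05,
    compute_scores: bool = False,
) -> StudyResult:
    """Repeat simulate -> CERNO -> FDR -> Fisher; count rejections.

    With ``up_log_fold = 0`` this measures the type-I error of the Fisher
    condition comparison; with a positive fold it measures power, the fraction
    of rejections naming the target condition, and (when ``compute_scores``)
    whether the mean combined signature score is higher in the target
    condition.
    """
    base = _study_config(n_cells, n_genes)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    rejections = correct = score_correct = 0
    pvals = np.empty(n_runs)
    for i, run_seed in enumerate(seeds):
        sig = pick_signature(base, n_up=signature_size, name="study",
                             seed=int(run_seed) + 1)
        effects = ()
        target = base.conditions[1]
        if up_log_fold != 0.0:
            effects = (PlantedEffect(sig, target, up_log_fold=up_log_fold),)
        config = replace(base, planted_effects=effects, seed=int(run_seed))
        adata, _ = simulate_counts(config)
        normalize_log(adata)
        cerno = fdr_correct(cerno_cell(adata, sig))
        fisher = fisher_condition_enrichment(cerno, q_threshold=0.05)
        pvals[i] = fisher.p
        if fisher.p < alpha:
            rejections += 1
            if fisher.enriched_condition == target:
                correct += 1
        if compute_scores:
            scale_genes(adata)
            combined = score_signature(adata, sig)["combined"].score
            labels = np.asarray(adata.obs["condition"]).astype(str)
            if combined[labels == target].mean() > combined[labels != target].mean():
                score_correct += 1
    return StudyResult(
        n_runs=n_runs, rejections=rejections, correct_direction=correct,
        score_direction_correct=score_correct, fisher_p=pvals,
    )
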