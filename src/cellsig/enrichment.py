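"""Per-cell CERNO enrichment and cross-condition aggregation.

The CERNO statistic is Fisher's combination of the log-transformed relative
ranks of the signature genes within one cell:

    F = -2 * sum_{i=1..N} ln(r_i / N_tot),        F ~ chi-square(2N)

where genes are ranked *descending* by normalized expression (rank 1 = most
expressed, average ranks for ties), ``N`` is the resolved signature size and
``N_tot`` the number of genes in the matrix. Highly expressed signature genes
give small relative ranks and hence a large F; the per-cell p-value is the
upper tail of the chi-square law with 2N degrees of freedom.

Per-cell p-values are FDR-adjusted (Benjamini-Hochberg) separately within each
condition; a Fisher exact test then asks whether one condition holds more
significantly enriched cells than the other. A two-sided Wilcoxon rank-sum
test on the per-cell signature scores is reported alongside.

The :class:`SignatureEnrichment` model bundles the whole procedure:
construct it from an AnnData and a signature, call :meth:`fit`, and read the
:class:`SignatureEnrichmentResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .exceptions import ConfigError
from .qc import LAYER_LOGNORM, LAYER_SCALED
from ._stats import bh_adjust, fisher_exact_2x2
from .scoring import SignatureScores, score_signature
from .signatures import GeneSignature

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CernoResult:
    """Per-cell CERNO statistics for one signature.

    ``table`` is indexed by barcode with columns ``condition``, ``F``, ``p``
    and — after FDR correction — ``q``. ``n_signature`` is N (resolved
    members used), ``n_total`` is N_tot.
    """

    signature_name: str
    n_signature: int
    n_total: int
    table: pd.DataFrame = field(repr=False)

    @property
    def has_q(self) -> bool:
        return "q" in self.table.columns


@dataclass(frozen=True)
class ConditionEnrichmentResult:
    """Fisher exact comparison of enriched-cell counts between two conditions.

    ``table`` rows are conditions, columns ``(enriched, not_enriched)``.
    """

    signature_name: str
    conditions: tuple[str, str]
    table: np.ndarray
    odds_ratio: float
    p: float
    alternative: str
    q_threshold: float

    @property
    def enriched_condition(self) -> str:
        """Condition with the larger fraction of significantly enriched cells."""
        frac = self.table[:, 0] / self.table.sum(axis=1)
        return self.conditions[int(np.argmax(frac))]


def cerno_from_ranks(ranks: np.ndarray, n_total: int) -> np.ndarray:
    """F = -2 sum ln(r_i / N_tot) for one or many cells.

    ``ranks`` has shape (n_cells, N) or (N,); ranks of 1..N_tot (fractional
    average ranks allowed).
    """
    r = np.atleast_2d(np.asarray(ranks, dtype=np.float64))
    if n_total < r.shape[1]:
        raise ConfigError("n_total smaller than signature size")
    if (r < 1).any() or (r > n_total).any():
        raise ConfigError("ranks must lie in [1, n_total]")
    F = -2.0 * np.log(r / n_total).sum(axis=1)
    return F if np.ndim(ranks) > 1 else float(F[0])


def cerno_cell(
    adata: ad.AnnData,
    sig: GeneSignature,
    layer: str = LAYER_LOGNORM,
    condition_key: str = "condition",
) -> CernoResult:
    """Per-cell CERNO statistic F and chi-square upper-tail p-value.

    Genes are ranked descending by the chosen expression layer within each
    cell. For bidirectional signatures the up-regulated members define the
    tested set (enrichment of the down set would have the opposite sign and
    is not combined).
    """
    if layer not in adata.layers:
        raise ConfigError(f"layer '{layer}' missing; run normalize_log first")
    resolved = sig.resolve(adata.var_names)
    members = resolved.up_genes or resolved.down_genes
    lookup = {g: i for i, g in enumerate(adata.var_names)}
    idx = np.array([lookup[g] for g in members], dtype=int)
    X = adata.layers[layer]
    X = np.asarray(X.toarray() if hasattr(X, "toarray") else X, dtype=np.float64)
    ranks = rankdata(-X, axis=1)  # descending: rank 1 = highest expression
    F = cerno_from_ranks(ranks[:, idx], adata.n_vars)
    n = idx.size
    p = stats.chi2.sf(F, df=2 * n)
    table = pd.DataFrame(
        {
            "condition": np.asarray(adata.obs[condition_key]).astype(str)
            if condition_key in adata.obs else "all",
            "F": F,
            "p": p,
        },
        index=adata.obs_names.rename("barcode"),
    )
    return CernoResult(signature_name=resolved.name, n_signature=n,
                       n_total=adata.n_vars, table=table)


def fdr_correct(result: CernoResult) -> CernoResult:
    """Benjamini-Hochberg adjustment applied separately within each condition."""
    table = result.table.copy()
    q = np.empty(len(table))
    for _, idx in table.groupby("condition", observed=True).indices.items():
        q[idx] = bh_adjust(table["p"].to_numpy()[idx])
    table["q"] = np.minimum(q, 1.0)
    return replace(result, table=table)


def fisher_condition_enrichment(
    result: CernoResult,
    q_threshold: float = 0.05,
    alternative: str = "two-sided",
) -> ConditionEnrichmentResult:
    """Fisher exact test: is one condition richer in CERNO-enriched cells?

    A cell is "enriched" when its FDR-adjusted q is below ``q_threshold``.
    """
    if not result.has_q:
        raise ConfigError("run fdr_correct before the condition comparison")
    conditions = sorted(result.table["condition"].unique())
    if len(conditions) != 2:
        raise ConfigError(
            f"exactly two conditions required, found {conditions}"
        )
    rows = []
    for cond in conditions:
        sub = result.table[result.table["condition"] == cond]
        enriched = int((sub["q"] < q_threshold).sum())
        rows.append([enriched, len(sub) - enriched])
    table = np.array(rows, dtype=np.int64)
    odds, p = fisher_exact_2x2(table, alternative=alternative)
    return ConditionEnrichmentResult(
        signature_name=result.signature_name,
        conditions=(conditions[0], conditions[1]),
        table=table, odds_ratio=odds, p=p,
        alternative=alternative, q_threshold=q_threshold,
    )


def wilcoxon_score_test(
    scores: SignatureScores | np.ndarray, condition_labels
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test of scores by condition.

    Exact enumeration when both groups have <= 8 cells and no ties occur,
    otherwise the normal approximation with tie and continuity correction.
    Returns ``(U statistic, p)``.
    """
    values = scores.score if isinstance(scores, SignatureScores) else np.asarray(scores)
    labels = np.asarray(condition_labels).astype(str)
    if len(labels) != len(values):
        raise ConfigError("labels and scores differ in length")
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ConfigError(f"exactly two groups required, found {list(groups)}")
    x = values[labels == groups[0]]
    y = values[labels == groups[1]]
    if x.size == 0 or y.size == 0:
        raise ConfigError("both groups must be nonempty")
    no_ties = len(np.unique(np.concatenate([x, y]))) == x.size + y.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


class SignatureEnrichment:
    """Model: does one condition express a gene signature more than the other?

    Parameters
    ----------
    adata
        Cells x genes AnnData with ``lognorm`` (and, for scoring, ``scaled``)
        layers and a two-level condition column in ``.obs``.
    signature
        The gene signature to test.
    condition_key
        Name of the obs column holding the two condition labels.
    cerno_layer, score_layer
        Expression layers used for the CERNO ranks and the signature scores.
    q_threshold, alternative
        Per-cell FDR cutoff defining "enriched", and the sidedness of the
        cross-condition Fisher test.
    """

    def __init__(
        self,
        adata: ad.AnnData,
        signature: GeneSignature,
        condition_key: str = "condition",
        cerno_layer: str = LAYER_LOGNORM,
        score_layer: str = LAYER_SCALED,
        q_threshold: float = 0.05,
        alternative: str = "two-sided",
    ):
        if condition_key not in adata.obs:
            raise ConfigError(f"obs column '{condition_key}' not found")
        self.adata = adata
        self.signature = signature
        self.condition_key = condition_key
        self.cerno_layer = cerno_layer
        self.score_layer = score_layer
        self.q_threshold = q_threshold
        self.alternative = alternative

    def fit(self) -> "SignatureEnrichmentResults":
        scores = score_signature(self.adata, self.signature, self.score_layer)
        cerno = fdr_correct(
            cerno_cell(self.adata, self.signature, self.cerno_layer,
                       self.condition_key)
        )
        fisher = fisher_condition_enrichment(
            cerno, q_threshold=self.q_threshold, alternative=self.alternative
        )
        labels = np.asarray(self.adata.obs[self.condition_key]).astype(str)
        wilcoxon = {
            method: wilcoxon_score_test(s, labels) for method, s in scores.items()
        }
        return SignatureEnrichmentResults(
            model=self, scores=scores, cerno=cerno,
            condition_test=fisher, wilcoxon=wilcoxon,
        )


@dataclass(frozen=True)
class SignatureEnrichmentResults:
    """Fitted results of :class:`SignatureEnrichment`.

    ``scores`` holds the per-cell rank / expression-sum / combined scores;
    ``cerno`` the per-cell F, p and q; ``condition_test`` the 2x2 Fisher
    comparison; ``wilcoxon`` maps score method -> (U, p) for the two-sided
    rank-sum test of scores between conditions.
    """

    model: SignatureEnrichment = field(repr=False)
    scores: dict[str, SignatureScores] = field(repr=False)
    cerno: CernoResult = field(repr=False)
    condition_test: ConditionEnrichmentResult
    wilcoxon: dict[str, tuple[float, float]]

    @property
    def cerno_p(self) -> float:
        """Fisher p-value of the cross-condition CERNO enrichment comparison."""
        return self.condition_test.p

    @property
    def wilcoxon_p(self) -> float:
        """Two-sided rank-sum p on the combined signature score."""
        return self.wilcoxon["combined"][1]

    def score_means(self) -> pd.DataFrame:
        """Mean per-cell score per condition, per method."""
        labels = np.asarray(self.model.adata.obs[self.model.condition_key]).astype(str)
        rows = {}
        for method, s in self.scores.items():
            rows[method] = pd.Series(s.score).groupby(labels).mean()
        return pd.DataFrame(rows)

    def summary(self) -> str:
        ct = self.condition_test
        lines = [
            f"Signature enrichment: {self.cerno.signature_name}",
            f"  cells: {len(self.cerno.table)}   genes (N_tot): {self.cerno.n_total}"
            f"   signature size (N): {self.cerno.n_signature}",
            f"  conditions: {ct.conditions[0]} vs {ct.conditions[1]}",
            "  enriched cells (q < {:g}): {} / {}  vs  {} / {}".format(
                ct.q_threshold,
                ct.table[0, 0], ct.table[0].sum(), ct.table[1, 0], ct.table[1].sum(),
            ),
            f"  CERNO condition test (Fisher, {ct.alternative}): "
            f"OR = {ct.odds_ratio:.4g}, p = {ct.p:.4g}",
            f"  enriched condition: {ct.enriched_condition}",
        ]
        for method, (u, p) in self.wilcoxon.items():
            lines.append(f"  Wilcoxon rank-sum on {method} score: U = {u:.4g}, "
                         f"p = {p:.4g}")
        means = self.score_means()
        lines.append("  mean scores per condition:")
        for cond, row in means.iterrows():
            vals = ", ".join(f"{m} = {v:.4g}" for m, v in row.items())
            lines.append(f"    {cond}: {vals}")
        return "\n".join(lines)

    def plot_score_distribution(self, method: str = "combined", ax=None):
        """Histogram of per-cell scores split by condition."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        labels = np.asarray(self.model.adata.obs[self.model.condition_key]).astype(str)
        s = self.scores[method].score
        for cond in np.unique(labels):
            ax.hist(s[labels == cond], bins=40, alpha=0.5, label=str(cond),
                    density=True)
        ax.set_xlabel(f"{method} signature score")
        ax.set_ylabel("density")
        ax.set_title(self.cerno.signature_name)
        ax.legend()
        return ax
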