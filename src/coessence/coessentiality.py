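"""Pairwise co-essentiality: dependency-profile correlation across cell lines.

Two genes are co-essential when their knockout fitness effects rise and fall
together across many cell lines, which is strong evidence of shared function.
The statistic is the Pearson correlation r of the two dependency profiles
over pairwise-complete observations (cell lines where both genes were
measured). Significance cutoffs are not fixed constants: they are calibrated
per matrix by permuting each gene's profile across cell lines — destroying
all pairwise structure while preserving marginals and per-gene missingness —
and taking tail quantiles of the resulting null correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import DependencyMatrix

logger = logging.getLogger(__name__)

MIN_PAIRWISE_OBS = 3


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r between two genes' dependency profiles.

    ``n_obs`` is the number of cell lines where both values are present.
    """

    gene_a: str
    gene_b: str
    r: float
    n_obs: int

    def swapped(self) -> "CorrelationResult":
        return CorrelationResult(self.gene_b, self.gene_a, self.r, self.n_obs)


@dataclass(frozen=True)
class ThresholdEstimate:
    """Permutation-calibrated correlation cutoffs (r_neg < 0 < r_pos)."""

    r_pos: float
    r_neg: float
    n_permutations: int
    tail_quantile: float
    seed: int

    def __post_init__(self) -> None:
        if not (self.r_neg < 0.0 < self.r_pos):
            raise ValueError(
                f"thresholds must straddle zero, got ({self.r_neg}, {self.r_pos})"
            )

    def passes(self, r: float) -> bool:
        return r > self.r_pos or r < self.r_neg


@dataclass
class AssociationTable:
    """Ranked correlation partners of a query gene, one direction.

    Rows are ``(partner, r, n_obs, copub_index, novel)`` sorted by |r|
    descending (ties broken by partner symbol).
    """

    query_gene: str
    direction: str  # "positive" | "negative"
    rows: list[tuple[str, float, int, float, bool]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.rows, columns=["partner", "r", "n_obs", "copub_index", "novel"]
        )
        frame.insert(0, "query", self.query_gene)
        return frame

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    def partners(self) -> list[str]:
        return [row[0] for row in self.rows]


def _pair_stats(
    x: np.ndarray, y: np.ndarray, method: str = "pearson"
) -> tuple[float, int]:
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < MIN_PAIRWISE_OBS:
        raise ValueError(
            f"insufficient overlap: only {n} pairwise-complete observations "
            f"(minimum {MIN_PAIRWISE_OBS})"
        )
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("constant profile over the complete pairs")
    if method == "pearson":
        r = float(stats.pearsonr(xs, ys).statistic)
    elif method == "spearman":
        r = float(stats.spearmanr(xs, ys).statistic)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return r, n


def correlate_pair(
    dep: DependencyMatrix, gene_a: str, gene_b: str, method: str = "pearson"
) -> CorrelationResult:
    """Correlation of two dependency profiles over pairwise-complete lines.

    Pearson by default — the convention for gene-effect scores; Spearman
    rank correlation is available via ``method="spearman"``.
    """
    x = dep.profile(gene_a).to_numpy()
    y = dep.profile(gene_b).to_numpy()
    r, n = _pair_stats(x, y, method=method)
    return CorrelationResult(gene_a, gene_b, r, n)


def _pairwise_correlations(
    values: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs pairwise-complete Pearson r for a gene × line matrix.

    Returns (r, n_obs) square arrays. Pairs with fewer than
    MIN_PAIRWISE_OBS shared observations or a zero-variance profile get NaN.
    Implemented with masked matrix products; each gene is pre-centered by
    its own mean (Pearson r is shift-invariant) to keep the one-pass sums
    well conditioned.
    """
    valid = ~np.isnan(values)
    counts = valid.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        means = np.nansum(values, axis=1, keepdims=True) / np.maximum(counts, 1)
    x = np.where(valid, values - means, 0.0)
    v = valid.astype(float)
    n = v @ v.T
    sx = x @ v.T
    sy = sx.T
    sxy = x @ x.T
    sxx = (x * x) @ v.T
    syy = sxx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        var_x = n * sxx - sx * sx
        var_y = n * syy - sy * sy
        denom = np.sqrt(var_x * var_y)
        r = cov / denom
    bad = (n < MIN_PAIRWISE_OBS) | (var_x <= 0) | (var_y <= 0)
    r[bad] = np.nan
    r = np.clip(r, -1.0, 1.0)
    return r, n.astype(int)


def correlation_matrix(
    dep: DependencyMatrix, method: str = "pearson"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene × gene pairwise-complete correlation and n_obs DataFrames."""
    genes = dep.gene_ids
    notna = dep.data.notna().to_numpy().astype(int)
    if method == "pearson":
        r, n = _pairwise_correlations(dep.values)
        return (
            pd.DataFrame(r, index=genes, columns=genes),
            pd.DataFrame(n, index=genes, columns=genes),
        )
    if method == "spearman":
        r = dep.data.T.corr(method="spearman", min_periods=MIN_PAIRWISE_OBS)
        n = pd.DataFrame(notna @ notna.T, index=genes, columns=genes)
        return r, n
    raise ValueError(f"unknown correlation method {method!r}")


def correlate_all(
    dep: DependencyMatrix, query: str | None = None
) -> tuple[list[CorrelationResult], dict[str, int]]:
    """Correlate a query gene against all others, or all unordered pairs.

    Pairs failing the minimum-overlap or variance preconditions are skipped
    and tallied in the returned summary.
    """
    genes = dep.gene_ids
    if query is not None and query not in set(genes):
        raise KeyError(f"query gene not found: {query!r}")
    r, n = _pairwise_correlations(dep.values)
    results: list[CorrelationResult] = []
    skipped = 0
    if query is not None:
        qi = genes.index(query)
        for j, g in enumerate(genes):
            if j == qi:
                continue
            if np.isnan(r[qi, j]):
                skipped += 1
                continue
            results.append(CorrelationResult(query, g, float(r[qi, j]), int(n[qi, j])))
    else:
        iu, ju = np.triu_indices(len(genes), k=1)
        for i, j in zip(iu, ju):
            if np.isnan(r[i, j]):
                skipped += 1
                continue
            results.append(
                CorrelationResult(genes[i], genes[j], float(r[i, j]), int(n[i, j]))
            )
    return results, {"n_skipped": skipped}


def n_unordered_pairs(n_genes: int) -> int:
    """Number of unordered gene pairs in an ``n_genes`` universe."""
    return n_genes * (n_genes - 1) // 2


class PermutationThresholdEstimator(BaseEstimator):
    """Calibrate co-essentiality cutoffs from a permutation null.

    Each permutation round independently shuffles every gene's profile
    across cell lines (missing entries travel with the shuffle, so each
    gene keeps its own missingness count) and computes pairwise-complete
    Pearson r for a random subsample of gene pairs. The pooled null
    correlations give the cutoffs: ``r_pos_`` is the upper
    ``tail_quantile`` quantile and ``r_neg_`` the lower.

    Parameters
    ----------
    n_permutations:
        Number of shuffle rounds; at least 100.
    tail_quantile:
        Tail mass per side, in (0, 0.5). Default 0.005.
    pairs_per_round:
        Gene pairs sampled per round (caps the quadratic cost).
    random_state:
        Integer seed; the whole procedure is reproducible from it.
    """

    def __init__(
        self,
        n_permutations: int = 100,
        tail_quantile: float = 0.005,
        pairs_per_round: int = 10_000,
        random_state: int = 0,
    ):
        self.n_permutations = n_permutations
        self.tail_quantile = tail_quantile
        self.pairs_per_round = pairs_per_round
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be at least 100")
        if not (0.0 < self.tail_quantile < 0.5):
            raise ValueError("tail_quantile must lie in (0, 0.5)")
        values = X.values if isinstance(X, DependencyMatrix) else np.asarray(X, float)
        n_genes, n_lines = values.shape
        if n_genes < 2:
            raise ValueError("need at least 2 genes")
        rng = np.random.default_rng(self.random_state)
        max_pairs = n_unordered_pairs(n_genes)
        n_pairs = min(self.pairs_per_round, max_pairs)
        nulls: list[np.ndarray] = []
        for _ in range(self.n_permutations):
            perm = np.argsort(rng.random(values.shape), axis=1)
            shuffled = np.take_along_axis(values, perm, axis=1)
            ii = rng.integers(0, n_genes, size=2 * n_pairs)
            jj = rng.integers(0, n_genes, size=2 * n_pairs)
            keep = ii != jj
            ii, jj = ii[keep][:n_pairs], jj[keep][:n_pairs]
            nulls.append(_sampled_pair_correlations(shuffled, ii, jj))
        pooled = np.concatenate(nulls)
        pooled = pooled[~np.isnan(pooled)]
        if pooled.size * self.tail_quantile < 10:
            raise ValueError(
                f"only {pooled.size} null correlations pooled; too few to "
                f"estimate the {self.tail_quantile} tail — increase "
                "n_permutations or pairs_per_round"
            )
        self.r_pos_ = float(np.quantile(pooled, 1.0 - self.tail_quantile))
        self.r_neg_ = float(np.quantile(pooled, self.tail_quantile))
        self.n_null_ = int(pooled.size)
        return self

    def threshold_estimate(self) -> ThresholdEstimate:
        return ThresholdEstimate(
            r_pos=self.r_pos_,
            r_neg=self.r_neg_,
            n_permutations=self.n_permutations,
            tail_quantile=self.tail_quantile,
            seed=self.random_state,
        )


def _sampled_pair_correlations(
    values: np.ndarray, ii: np.ndarray, jj: np.ndarray
) -> np.ndarray:
    """Pairwise-complete Pearson r for an explicit list of row pairs."""
    a = values[ii]
    b = values[jj]
    ok = ~(np.isnan(a) | np.isnan(b))
    a = np.where(ok, a, 0.0)
    b = np.where(ok, b, 0.0)
    n = ok.sum(axis=1)
    sa = a.sum(axis=1)
    sb = b.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * (a * b).sum(axis=1) - sa * sb
        va = n * (a * a).sum(axis=1) - sa * sa
        vb = n * (b * b).sum(axis=1) - sb * sb
        r = cov / np.sqrt(va * vb)
    r[(n < MIN_PAIRWISE_OBS) | (va <= 0) | (vb <= 0)] = np.nan
    return np.clip(r, -1.0, 1.0)


def permutation_thresholds(
    dep: DependencyMatrix,
    n_permutations: int = 100,
    tail_quantile: float = 0.005,
    seed: int = 0,
    pairs_per_round: int = 10_000,
) -> ThresholdEstimate:
    """Functional wrapper over :class:`PermutationThresholdEstimator`."""
    est = PermutationThresholdEstimator(
        n_permutations=n_permutations,
        tail_quantile=tail_quantile,
        pairs_per_round=pairs_per_round,
        random_state=seed,
    ).fit(dep)
    return est.threshold_estimate()


def analytic_null_quantile(n_obs: int, tail_quantile: float) -> float:
    """Null quantile of Pearson r for independent normal data at n_obs.

    Uses the exact t transform r = t / sqrt(t² + n − 2) with t the
    Student-t quantile at n − 2 degrees of freedom.
    """
    t = stats.t.ppf(1.0 - tail_quantile, df=n_obs - 2)
    return float(t / np.sqrt(t * t + n_obs - 2))


def association_table(
    dep: DependencyMatrix,
    query: str,
    thresholds: ThresholdEstimate,
    copub=None,
    index_cutoff: float = 5.0,
) -> tuple[AssociationTable, AssociationTable]:
    """Ranked positive and negative association tables for a query gene.

    Partners with r above ``thresholds.r_pos`` land in the positive table,
    below ``thresholds.r_neg`` in the negative table; each row carries the
    pair's co-publication index and novelty flag when a
    :class:`~coessence.literature.CopublicationIndex` is supplied.
    """
    from .literature import novelty_flag

    results, _ = correlate_all(dep, query=query)
    pos_rows = []
    neg_rows = []
    for res in results:
        if not thresholds.passes(res.r):
            continue
        idx = copub.index(query, res.gene_b) if copub is not None else 0.0
        novel = novelty_flag(abs(res.r), idx, index_cutoff=index_cutoff)
        row = (res.gene_b, res.r, res.n_obs, idx, novel)
        (pos_rows if res.r > 0 else neg_rows).append(row)
    key = lambda row: (-abs(row[1]), row[0])  # noqa: E731
    return (
        AssociationTable(query, "positive", sorted(pos_rows, key=key)),
        AssociationTable(query, "negative", sorted(neg_rows, key=key)),
    )
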