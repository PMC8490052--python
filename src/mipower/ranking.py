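"""Feature ranking: mutual information, chi-square and correlation.

Three univariate rankers are applied to the 11 band-power features.
Mutual information and the chi-square statistic both score the
dependency of a (discretized) feature on the class label; Pearson
correlation instead flags redundant feature pairs, which are discarded
greedily.  Each ranker is run over several subsampled iterations and
the final selection aggregates occurrence counts across iterations, so
a feature must rank highly consistently — not just once — to survive.

Continuous features are discretized with equal-frequency binning
(4 bins by default), which makes the MI and chi-square scores invariant
to any strictly monotone rescaling of a feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .subbands import FeatureMatrix

__all__ = [
    "ChiSquareResult",
    "RankingResult",
    "CorrelationMap",
    "equal_frequency_bins",
    "mutual_information_score",
    "chi_square_score",
    "correlation_coefficient",
    "correlation_map",
    "discard_correlated",
    "rank_features",
]

METHODS = ("mutual_information", "chi_square", "correlation")
_ALIASES = {"mi": "mutual_information", "chi2": "chi_square", "corr": "correlation"}

#: Default selection sizes: top 6 of 11 for mutual information, top 5 of
#: 11 for chi-square (correlation keeps whatever survives the discard).
DEFAULT_K = {"mutual_information": 6, "chi_square": 5}

DEFAULT_N_BINS = 4
DEFAULT_CORR_THRESHOLD = 0.85
DEFAULT_SUBSAMPLE = 0.8


def equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize a feature into (up to) ``n_bins`` equal-frequency bins.

    Quantile edges with ties collapsed; returns integer bin ids.  A
    constant feature yields a single bin.
    """
    x = np.asarray(x, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="left")


def _contingency(bin_ids: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Observed counts, bins x classes."""
    classes, y = np.unique(labels, return_inverse=True)
    bins = np.unique(bin_ids)
    table = np.zeros((len(bins), len(classes)))
    for i, b in enumerate(bins):
        for j in range(len(classes)):
            table[i, j] = np.sum((bin_ids == b) & (y == j))
    return table


def mutual_information_score(
    feature: np.ndarray,
    labels: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
) -> float:
    """Mutual information (nats) between a binned feature and the class.

    I = sum p(a,b) log[p(a,b) / (p(a) p(b))], the plug-in estimate on
    the joint histogram; zero-probability cells contribute nothing.
    """
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels)
    if len(feature) != len(labels) or len(feature) < 2:
        raise ValueError("feature and labels must share a length >= 2")
    bin_ids = equal_frequency_bins(feature, n_bins)
    if len(np.unique(bin_ids)) < 2:
        warnings.warn(
            "constant feature occupies a single bin; MI is 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    joint = _contingency(bin_ids, labels)
    p = joint / joint.sum()
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (pa * pb))
    return float(np.nansum(terms))


class ChiSquareResult(NamedTuple):
    statistic: float
    p_value: float
    dof: int
    alpha: float


def chi_square_score(
    feature: np.ndarray,
    labels: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    alpha: float = 0.05,
) -> ChiSquareResult:
    """Chi-square test of independence between a binned feature and the class.

    The statistic is sum (F_O - F_E)^2 / F_E over the bins x classes
    contingency table, with expected counts from the marginals.  Bins
    whose expected count falls below 1 are merged with their neighbor.
    """
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels)
    if len(feature) != len(labels) or len(feature) < 2:
        raise ValueError("feature and labels must share a length >= 2")
    bin_ids = equal_frequency_bins(feature, n_bins)
    observed = _contingency(bin_ids, labels)
    observed = _merge_sparse_bins(observed)
    n_rows, n_cols = observed.shape
    if n_rows < 2 or n_cols < 2:
        warnings.warn(
            "degenerate contingency table; chi-square statistic is 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return ChiSquareResult(0.0, 1.0, 0, alpha)
    total = observed.sum()
    expected = observed.sum(axis=1, keepdims=True) * observed.sum(axis=0, keepdims=True) / total
    statistic = float(((observed - expected) ** 2 / expected).sum())
    dof = (n_rows - 1) * (n_cols - 1)
    p_value = float(stats.chi2.sf(statistic, dof))
    return ChiSquareResult(statistic, p_value, dof, alpha)


def _merge_sparse_bins(observed: np.ndarray) -> np.ndarray:
    """Merge adjacent feature bins while any expected cell is below 1."""
    observed = observed.copy()
    while observed.shape[0] > 2:
        total = observed.sum()
        expected = (
            observed.sum(axis=1, keepdims=True)
            * observed.sum(axis=0, keepdims=True)
            / total
        )
        if expected.min() >= 1:
            break
        row = int(np.argmin(expected.min(axis=1)))
        neighbor = row - 1 if row > 0 else row + 1
        warnings.warn(
            f"expected count below 1 in bin {row}; merging with bin {neighbor}",
            RuntimeWarning,
            stacklevel=3,
        )
        observed[neighbor] += observed[row]
        observed = np.delete(observed, row, axis=0)
    return observed


def correlation_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two feature columns.

    r = (k sum(AB) - sum(A) sum(B)) /
        sqrt[(k sum(A^2) - sum(A)^2)(k sum(B^2) - sum(B)^2)]
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("inputs must share a length >= 2")
    k = len(a)
    var_a = k * np.sum(a**2) - np.sum(a) ** 2
    var_b = k * np.sum(b**2) - np.sum(b) ** 2
    if var_a <= 0 or var_b <= 0:
        raise ValueError("correlation undefined for a constant input")
    num = k * np.sum(a * b) - np.sum(a) * np.sum(b)
    r = num / np.sqrt(var_a * var_b)
    return float(np.clip(r, -1.0, 1.0))


@dataclass
class CorrelationMap:
    """Pairwise feature correlations plus the pairs above threshold.

    ``pairs`` holds (i, j, r) with canonical 1-based indices, i < j.
    """

    matrix: pd.DataFrame
    pairs: list[tuple[int, int, float]]
    threshold: float


def correlation_map(
    features: FeatureMatrix | pd.DataFrame,
    threshold: float = DEFAULT_CORR_THRESHOLD,
) -> CorrelationMap:
    """Full pairwise correlation matrix and the highly correlated pairs.

    A constant column cannot carry a correlation; its entries are set to
    0 (diagonal stays 1) with a warning.
    """
    df = features.features if isinstance(features, FeatureMatrix) else features
    if df.shape[1] < 2:
        raise ValueError("need at least 2 features")
    values = df.to_numpy(dtype=float)
    p = values.shape[1]
    matrix = np.eye(p)
    constant = values.std(axis=0) == 0
    for name in df.columns[constant]:
        warnings.warn(
            f"constant column {name!r}; correlations set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    for i in range(p):
        for j in range(i + 1, p):
            if constant[i] or constant[j]:
                r = 0.0
            else:
                r = correlation_coefficient(values[:, i], values[:, j])
            matrix[i, j] = matrix[j, i] = r
    pairs = [
        (i + 1, j + 1, float(matrix[i, j]))
        for i in range(p)
        for j in range(i + 1, p)
        if abs(matrix[i, j]) >= threshold
    ]
    mat = pd.DataFrame(matrix, index=df.columns, columns=df.columns)
    return CorrelationMap(matrix=mat, pairs=pairs, threshold=threshold)


def discard_correlated(cmap: CorrelationMap) -> list[int]:
    """Greedy removal of redundant features; returns survivors (1-based).

    While any remaining pair exceeds the threshold, the worst-offending
    pair is found and the member with the higher mean absolute
    correlation to all remaining features is discarded (ties go to the
    higher index).  Survivors are returned in canonical order.
    """
    matrix = cmap.matrix.to_numpy()
    p = matrix.shape[0]
    remaining = list(range(p))
    while True:
        sub = np.abs(matrix[np.ix_(remaining, remaining)])
        np.fill_diagonal(sub, 0.0)
        if sub.size == 0 or sub.max() < cmap.threshold:
            break
        i_loc, j_loc = np.unravel_index(np.argmax(sub), sub.shape)
        mean_i = sub[i_loc].sum() / (len(remaining) - 1)
        mean_j = sub[j_loc].sum() / (len(remaining) - 1)
        if mean_i > mean_j:
            drop_loc = i_loc
        elif mean_j > mean_i:
            drop_loc = j_loc
        else:
            drop_loc = max(i_loc, j_loc, key=lambda loc: remaining[loc])
        remaining.pop(drop_loc)
    return [idx + 1 for idx in remaining]


@dataclass
class RankingResult:
    """Outcome of one ranking method over the iteration protocol."""

    method: str
    per_iteration_scores: pd.DataFrame
    per_iteration_ranks: pd.DataFrame
    selected: list[int]
    selection_rule: str
    n_iterations: int
    seed: int = 0
    extras: dict = field(default_factory=dict)


def _scores_one_iteration(
    values: np.ndarray,
    labels: np.ndarray,
    method: str,
    n_bins: int,
    threshold: float,
) -> tuple[np.ndarray, list[int] | None]:
    """Per-feature scores (higher = better) and, for correlation, survivors."""
    p = values.shape[1]
    if method == "mutual_information":
        scores = np.array(
            [mutual_information_score(values[:, j], labels, n_bins) for j in range(p)]
        )
        return scores, None
    if method == "chi_square":
        scores = np.array(
            [chi_square_score(values[:, j], labels, n_bins).statistic for j in range(p)]
        )
        return scores, None
    # correlation: a feature is better the LESS redundant it is, so the
    # score is the negated mean absolute correlation to the other features
    df = pd.DataFrame(values)
    cmap = correlation_map(df, threshold)
    abs_mat = np.abs(cmap.matrix.to_numpy())
    np.fill_diagonal(abs_mat, 0.0)
    mean_abs = abs_mat.sum(axis=0) / (p - 1)
    survivors = discard_correlated(cmap)
    return -mean_abs, survivors


def rank_features(
    features: FeatureMatrix,
    labels: np.ndarray | None = None,
    method: str = "mutual_information",
    n_iterations: int = 10,
    k: int | None = None,
    seed: int = 0,
    n_bins: int = DEFAULT_N_BINS,
    subsample: float = DEFAULT_SUBSAMPLE,
    threshold: float = DEFAULT_CORR_THRESHOLD,
) -> RankingResult:
    """Iterated feature ranking with occurrence-count aggregation.

    Each iteration scores every feature on a seeded random subsample of
    80% of the trials and records the resulting ranks (1 = best).  For
    MI and chi-square the final selection is the ``k`` features with the
    most top-k appearances across iterations (ties broken by higher
    mean score); for correlation it is the features surviving the
    correlated-pair discard in a majority of iterations.
    """
    method = _ALIASES.get(method, method)
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; valid: {METHODS}")
    y = np.asarray(labels if labels is not None else features.labels)
    values = features.values
    n, p = values.shape
    if method != "correlation":
        k = DEFAULT_K[method] if k is None else k
        if k <= 0:
            raise ValueError("k must be positive")
        if k > p:
            raise ValueError(f"k={k} exceeds the number of features {p}")

    rng = np.random.default_rng(seed)
    n_sub = max(2, int(round(subsample * n)))
    score_rows, rank_rows = [], []
    survivor_counts = np.zeros(p)
    for _ in range(n_iterations):
        idx = rng.choice(n, size=n_sub, replace=False)
        scores, survivors = _scores_one_iteration(
            values[idx], y[idx], method, n_bins, threshold
        )
        # rank 1 = best; stable tie-break by feature order
        order = np.lexsort((np.arange(p), -scores))
        ranks = np.empty(p, dtype=int)
        ranks[order] = np.arange(1, p + 1)
        score_rows.append(scores)
        rank_rows.append(ranks)
        if survivors is not None:
            for s in survivors:
                survivor_counts[s - 1] += 1

    columns = list(features.features.columns)
    scores_df = pd.DataFrame(score_rows, columns=columns)
    ranks_df = pd.DataFrame(rank_rows, columns=columns)

    if method == "correlation":
        selected = [
            j + 1 for j in range(p) if survivor_counts[j] > n_iterations / 2
        ]
        rule = (
            f"features surviving the |r| >= {threshold} correlated-pair "
            f"discard in a majority of {n_iterations} iterations"
        )
        extras = {"survivor_counts": survivor_counts.tolist()}
    else:
        top_counts = (ranks_df.to_numpy() <= k).sum(axis=0)
        mean_scores = scores_df.to_numpy().mean(axis=0)
        order = np.lexsort((np.arange(p), -mean_scores, -top_counts))
        selected = [int(j) + 1 for j in order[:k]]
        rule = (
            f"{k} features with the most top-{k} appearances over "
            f"{n_iterations} iterations (ties by higher mean score)"
        )
        extras = {"top_counts": top_counts.tolist()}
    return RankingResult(
        method=method,
        per_iteration_scores=scores_df,
        per_iteration_ranks=ranks_df,
        selected=selected,
        selection_rule=rule,
        n_iterations=n_iterations,
        seed=seed,
        extras=extras,
    )
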