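"""Comparison machinery: per-trait statistics, PCA composite baseline, and
agreement measures between rating procedures."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from phenosalt.fce import (
    ConstantTraitWarning,
    FuzzyEvaluation,
    TraitMatrix,
    entropy_weights,
    standardize,
)

__all__ = [
    "TraitStats",
    "PcaResult",
    "coefficient_of_variation",
    "trait_stats_table",
    "variance_contribution",
    "pca_composite",
    "consistency_rate",
    "rank_agreement",
]


@dataclass
class TraitStats:
    """One row of the trait statistics table."""

    trait_name: str
    cv: float  # coefficient of variation, raw values
    h: float  # entropy divergence 1 - E, standardized values
    var: float  # signed variance contribution rate


@dataclass
class PcaResult:
    sample_ids: list[str]
    pc1_scores: np.ndarray
    ranks: np.ndarray  # 1 = best (highest composite score)
    explained_fraction: float

    def __post_init__(self) -> None:
        self.pc1_scores = np.asarray(self.pc1_scores, dtype=float)
        self.ranks = np.asarray(self.ranks, dtype=int)
        n = len(self.sample_ids)
        if sorted(self.ranks) != list(range(1, n + 1)):
            raise ValueError("ranks must be a permutation of 1..n")
        if not 0.0 < self.explained_fraction <= 1.0:
            raise ValueError("explained_fraction must be in (0, 1]")


def coefficient_of_variation(values: Sequence[float] | np.ndarray) -> float:
    """Sample standard deviation (n-1 denominator) over the mean."""
    v = np.asarray(values, dtype=float)
    mean = v.mean()
    if mean == 0.0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(v.std(ddof=1) / mean)


def _zscore_columns(X: np.ndarray) -> np.ndarray:
    """Column z-scores; constant columns become all-zero."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    Z = np.zeros_like(X, dtype=float)
    ok = sd > 0
    Z[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
    return Z


def _pc1(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """PC1 of the correlation structure: (loadings, scores, explained)."""
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for PCA")
    Z = _zscore_columns(X)
    cov = (Z.T @ Z) / (n - 1)
    total = np.trace(cov)
    if total <= 0:
        raise ValueError("degenerate covariance: no trait varies")
    eigvals, eigvecs = np.linalg.eigh(cov)
    loadings = eigvecs[:, -1]
    scores = Z @ loadings
    explained = float(eigvals[-1] / total)
    return loadings, scores, explained


def trait_stats_table(matrix: TraitMatrix) -> list[TraitStats]:
    """CV (raw), entropy divergence (standardized) and variance contribution
    rate for every trait."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConstantTraitWarning)
        wv = entropy_weights(standardize(matrix))
    var = variance_contribution(matrix)
    rows = []
    for j, name in enumerate(matrix.trait_names):
        rows.append(
            TraitStats(
                trait_name=name,
                cv=coefficient_of_variation(matrix.values[:, j]),
                h=float(wv.divergences[j]),
                var=float(var[j]),
            )
        )
    return rows


def variance_contribution(matrix: TraitMatrix) -> np.ndarray:
    """Signed PC1 loadings normalized to sum to 1.

    The normalization v / sum(v) is invariant to the overall sign of the
    eigenvector, so no reference orientation is needed.
    """
    loadings, _, _ = _pc1(matrix.values)
    total = loadings.sum()
    if abs(total) < 1e-12:
        raise ValueError(
            "variance contribution undefined: PC1 loadings sum to zero"
        )
    return loadings / total


def pca_composite(matrix: TraitMatrix, reference_trait: str) -> PcaResult:
    """PC1 composite score and 1..n ranking (rank 1 = highest score).

    Traits are z-scored; PC1 comes from the correlation structure and is
    oriented so the composite score correlates positively with
    ``reference_trait``.
    """
    if reference_trait not in matrix.trait_names:
        raise KeyError(f"reference trait {reference_trait!r} not in matrix")
    j = matrix.trait_names.index(reference_trait)
    ref = matrix.values[:, j]
    if ref.std() == 0:
        raise ValueError(f"reference trait {reference_trait!r} is constant")
    _, scores, explained = _pc1(matrix.values)
    corr = np.corrcoef(scores, ref)[0, 1] if scores.std() > 0 else 0.0
    if corr < 0:
        scores = -scores
    order = np.argsort(-scores, kind="stable")
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(1, len(scores) + 1)
    return PcaResult(
        sample_ids=list(matrix.sample_ids),
        pc1_scores=scores,
        ranks=ranks,
        explained_fraction=explained,
    )


def consistency_rate(
    ratings_a: Mapping[str, str], ratings_b: Mapping[str, str]
) -> float:
    """Fraction of samples assigned the same grade by both procedures."""
    if set(ratings_a) != set(ratings_b):
        only_a = sorted(set(ratings_a) - set(ratings_b))
        only_b = sorted(set(ratings_b) - set(ratings_a))
        raise ValueError(
            f"sample id mismatch: only in a={only_a}, only in b={only_b}"
        )
    if not ratings_a:
        raise ValueError("no samples to compare")
    same = sum(1 for sid in ratings_a if ratings_a[sid] == ratings_b[sid])
    return same / len(ratings_a)


def rank_agreement(fce: Sequence[FuzzyEvaluation], pca: PcaResult) -> float:
    """Spearman correlation between FCE expected scores and the PCA
    composite ordering (average ranks on ties)."""
    fce_by_id = {e.sample_id: e for e in fce}
    if set(fce_by_id) != set(pca.sample_ids):
        raise ValueError("sample id mismatch between FCE results and PCA result")
    expected = np.array([fce_by_id[sid].expected_score for sid in pca.sample_ids])
    rho = sps.spearmanr(expected, pca.pc1_scores).statistic
    return float(rho)
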