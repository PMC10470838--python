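"""Entropy-weighted fuzzy comprehensive evaluation of a trait matrix.

The pipeline is: min-max standardize every trait to [0, 1] with negative
indicators flipped, derive per-trait weights from the information entropy of
the standardized value shares, map each standardized value to memberships in
four ordered grades through trapezoidal membership functions, compose the
per-trait memberships with the weights (weighted-average operator), and grade
each sample by maximum membership.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "TraitMatrix",
    "EvaluationSet",
    "MembershipParams",
    "WeightVector",
    "FuzzyEvaluation",
    "standardize",
    "entropy_weights",
    "grade_membership",
    "fuzzy_matrix",
    "fuzzy_compose",
    "rate",
    "evaluate",
]

DEFAULT_GRADES = ("Very tolerant", "Intermediate", "Susceptible", "Very susceptible")
DEFAULT_SCORES = (100.0, 75.0, 50.0, 25.0)
DEFAULT_BREAKPOINTS = (0.2, 0.3, 0.45, 0.55, 0.7, 0.8)


class ConstantTraitWarning(UserWarning):
    """A trait with no variation was standardized to the 0.5 convention."""


@dataclass
class TraitMatrix:
    """n samples x m traits with a per-trait polarity flag.

    ``polarity[j]`` is ``"positive"`` when larger raw values indicate higher
    tolerance and ``"negative"`` when smaller raw values do.
    """

    sample_ids: list[str]
    trait_names: list[str]
    values: np.ndarray
    polarity: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.trait_names = [str(t) for t in self.trait_names]
        self.polarity = list(self.polarity)
        n, m = self.n_samples, self.n_traits
        if self.values.ndim != 2 or self.values.shape != (n, m):
            raise ValueError(
                f"values must be a {n}x{m} matrix, got shape {self.values.shape}"
            )
        if n < 2:
            raise ValueError("need at least 2 samples")
        if m < 1:
            raise ValueError("need at least 1 trait")
        if len(self.polarity) != m:
            raise ValueError("polarity must have one entry per trait")
        bad = set(self.polarity) - {"positive", "negative"}
        if bad:
            raise ValueError(f"invalid polarity values: {sorted(bad)}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trait values must be finite with no missing entries")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        if len(set(self.trait_names)) != m:
            raise ValueError("trait names must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)


@dataclass(frozen=True)
class EvaluationSet:
    """Ordered grade labels (most tolerant first) and their scores."""

    grades: tuple[str, ...] = DEFAULT_GRADES
    scores: tuple[float, ...] = DEFAULT_SCORES

    def __post_init__(self) -> None:
        if len(self.grades) != len(self.scores):
            raise ValueError("grades and scores must have the same length")
        if any(a <= b for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("scores must be strictly decreasing")


@dataclass(frozen=True)
class MembershipParams:
    """Six breakpoints x1 < ... < x6 of the trapezoidal membership family.

    The defaults place a transition band of full width 0.1 around each of the
    quartile critical values 0.25, 0.5 and 0.75 of the standardized scale.
    """

    breakpoints: tuple[float, ...] = DEFAULT_BREAKPOINTS

    def __post_init__(self) -> None:
        bp = tuple(float(b) for b in self.breakpoints)
        object.__setattr__(self, "breakpoints", bp)
        if len(bp) != 6:
            raise ValueError("exactly six breakpoints required")
        if not all(a < b for a, b in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if bp[0] < 0.0 or bp[-1] > 1.0:
            raise ValueError("breakpoints must lie in [0, 1]")


@dataclass
class WeightVector:
    """Per-trait entropy weights with the underlying entropies/divergences."""

    trait_names: list[str]
    weights: np.ndarray
    divergences: np.ndarray
    entropies: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.divergences = np.asarray(self.divergences, dtype=float)
        self.entropies = np.asarray(self.entropies, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


@dataclass
class FuzzyEvaluation:
    """Per-sample result: membership grid, composed vector, grade and score."""

    sample_id: str
    r: np.ndarray  # m x 4 per-trait grade memberships
    b: np.ndarray  # composed 4-vector
    grade: str
    score: float
    tie: bool = False
    grade_scores: tuple[float, ...] = DEFAULT_SCORES

    @property
    def expected_score(self) -> float:
        """Defuzzified score sum_k b_k * score_k."""
        return float(np.dot(self.b, self.grade_scores))


def standardize(matrix: TraitMatrix) -> TraitMatrix:
    """Min-max standardize every trait to [0, 1], flipping negative traits.

    A constant trait cannot be rescaled; it is mapped to all-0.5 with a
    :class:`ConstantTraitWarning` and receives zero weight downstream (its
    value shares are uniform, so its entropy is maximal).
    """
    X = matrix.values
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = hi - lo
    out = np.empty_like(X)
    for j in range(matrix.n_traits):
        if span[j] == 0.0:
            warnings.warn(
                f"trait {matrix.trait_names[j]!r} is constant; "
                "standardized to 0.5 and will carry zero weight",
                ConstantTraitWarning,
                stacklevel=2,
            )
            out[:, j] = 0.5
        elif matrix.polarity[j] == "positive":
            out[:, j] = (X[:, j] - lo[j]) / span[j]
        else:
            out[:, j] = (hi[j] - X[:, j]) / span[j]
    return TraitMatrix(
        sample_ids=list(matrix.sample_ids),
        trait_names=list(matrix.trait_names),
        values=out,
        polarity=["positive"] * matrix.n_traits,
    )


def entropy_weights(standardized: TraitMatrix) -> WeightVector:
    """Entropy weights from standardized value shares.

    For trait j with standardized values x'_ij the shares are
    p_ij = x'_ij / sum_i x'_ij (0 log 0 := 0), the normalized entropy is
    E_j = -(1/log2 n) sum_i p_ij log2 p_ij in [0, 1], the divergence is
    d_j = 1 - E_j, and the weight is w_j = d_j / sum_j d_j.
    """
    X = standardized.values
    n, m = X.shape
    if np.any(X < 0):
        raise ValueError("entropy weights require non-negative standardized values")
    col_sums = X.sum(axis=0)
    entropies = np.empty(m)
    for j in range(m):
        if col_sums[j] == 0.0:
            # all-zero column carries no information either way; treat as
            # uniform shares (maximal entropy, zero weight)
            entropies[j] = 1.0
            continue
        p = X[:, j] / col_sums[j]
        nz = p > 0
        entropies[j] = -np.sum(p[nz] * np.log2(p[nz])) / np.log2(n)
    divergences = 1.0 - entropies
    # guard tiny negative values from rounding
    divergences = np.clip(divergences, 0.0, None)
    total = divergences.sum()
    if total <= 0.0:
        raise ValueError("no discriminating information: every trait is constant")
    return WeightVector(
        trait_names=list(standardized.trait_names),
        weights=divergences / total,
        divergences=divergences,
        entropies=entropies,
    )


def grade_membership(
    x: float | np.ndarray, params: MembershipParams | None = None
) -> np.ndarray:
    """Trapezoidal memberships of a standardized value in the four grades.

    Returns the memberships ordered most tolerant first. Values outside
    [0, 1] are clamped. For every x the four memberships sum to 1 (partition
    of unity of the piecewise-linear family).
    """
    if params is None:
        params = MembershipParams()
    x1, x2, x3, x4, x5, x6 = params.breakpoints
    xv = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
    scalar = xv.ndim == 0
    xv = np.atleast_1d(xv)

    top = np.where(
        xv >= x6, 1.0, np.where(xv >= x5, (xv - x5) / (x6 - x5), 0.0)
    )
    mid_hi = np.select(
        [
            (xv >= x3) & (xv < x4),
            (xv >= x4) & (xv < x5),
            (xv >= x5) & (xv < x6),
        ],
        [(xv - x3) / (x4 - x3), 1.0, (x6 - xv) / (x6 - x5)],
        default=0.0,
    )
    mid_lo = np.select(
        [
            (xv >= x1) & (xv < x2),
            (xv >= x2) & (xv < x3),
            (xv >= x3) & (xv < x4),
        ],
        [(xv - x1) / (x2 - x1), 1.0, (x4 - xv) / (x4 - x3)],
        default=0.0,
    )
    bottom = np.where(
        xv < x1, 1.0, np.where(xv < x2, (x2 - xv) / (x2 - x1), 0.0)
    )
    out = np.stack([top, mid_hi, mid_lo, bottom], axis=-1)
    return out[0] if scalar else out


def fuzzy_matrix(
    sample_row: Sequence[float] | np.ndarray, params: MembershipParams | None = None
) -> np.ndarray:
    """Per-trait grade memberships for one sample: an m x 4 grid."""
    row = np.asarray(sample_row, dtype=float)
    if row.ndim != 1:
        raise ValueError("sample_row must be one-dimensional")
    return grade_membership(row, params)


def fuzzy_compose(weights: WeightVector | np.ndarray, r: np.ndarray) -> np.ndarray:
    """Weighted-average composition b_k = sum_j w_j r_jk."""
    w = weights.weights if isinstance(weights, WeightVector) else np.asarray(weights, float)
    r = np.asarray(r, dtype=float)
    if r.ndim != 2 or r.shape[0] != w.shape[0]:
        raise ValueError(
            f"dimension mismatch: {w.shape[0]} weights vs membership grid {r.shape}"
        )
    return w @ r


def rate(
    b: np.ndarray, evaluation_set: EvaluationSet | None = None
) -> tuple[str, float, bool]:
    """Grade by maximum membership; returns (grade, score, tie_flag).

    Ties (within 1e-12) are broken toward the more tolerant grade and
    flagged.
    """
    if evaluation_set is None:
        evaluation_set = EvaluationSet()
    b = np.asarray(b, dtype=float)
    if b.shape != (len(evaluation_set.grades),):
        raise ValueError("b must have one entry per grade")
    k = int(np.argmax(b))
    tie = bool(np.sum(b >= b[k] - 1e-12) > 1)
    return evaluation_set.grades[k], float(evaluation_set.scores[k]), tie


def evaluate(
    matrix: TraitMatrix,
    params: MembershipParams | None = None,
    evaluation_set: EvaluationSet | None = None,
) -> tuple[list[FuzzyEvaluation], WeightVector]:
    """Full evaluation chain over a raw trait matrix.

    Standardizes, derives entropy weights, builds each sample's membership
    grid, composes it with the weights and grades by maximum membership.
    Returns the per-sample evaluations and the weight vector used.
    """
    if params is None:
        params = MembershipParams()
    if evaluation_set is None:
        evaluation_set = EvaluationSet()
    std = standardize(matrix)
    wv = entropy_weights(std)
    results = []
    for i, sid in enumerate(std.sample_ids):
        r = fuzzy_matrix(std.values[i], params)
        b = fuzzy_compose(wv, r)
        grade, score, tie = rate(b, evaluation_set)
        results.append(
            FuzzyEvaluation(
                sample_id=sid,
                r=r,
                b=b,
                grade=grade,
                score=score,
                tie=tie,
                grade_scores=evaluation_set.scores,
            )
        )
    return results, wv
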