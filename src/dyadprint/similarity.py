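"""The core identification statistic.

A child is compared (Pearson correlation of feature vectors) against
every parent in the cohort. The *winning rate* of child i is the
fraction of stranger parents whose similarity to the child is exceeded
by the child's own parent (ties get half credit); averaging over
children gives the "accuracy". Its chance level is 50% for every cohort
size, unlike conventional rank-1 identification whose chance level is
1/N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .cohort import DyadCohort, ValidationError


@dataclass
class SimilarityMatrix:
    """children × parents Pearson correlations; entry (i, i) is the true
    dyad under the cohort's dyad ordering."""

    children: list[str]
    parents: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.children), len(self.parents)):
            raise ValidationError(
                f"similarity shape {self.values.shape} does not match id lists"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite similarity value")
        if np.any(np.abs(self.values) > 1 + 1e-10):
            raise ValidationError("similarity outside [-1, 1]")

    @property
    def n(self) -> int:
        return len(self.children)

    def permute_parents(self, perm: Sequence[int]) -> "SimilarityMatrix":
        """Reassign parents: child i's 'own' parent becomes parents[perm[i]].

        Because Pearson correlations between fixed vectors do not depend
        on the dyad map, shuffling the parent-child mapping is exactly a
        column permutation of this matrix.
        """
        perm = list(perm)
        return SimilarityMatrix(
            list(self.children), [self.parents[j] for j in perm], self.values[:, perm]
        )

    def subset(self, indices: Sequence[int]) -> "SimilarityMatrix":
        idx = list(indices)
        return SimilarityMatrix(
            [self.children[i] for i in idx],
            [self.parents[i] for i in idx],
            self.values[np.ix_(idx, idx)],
        )


@dataclass
class AccuracyEstimate:
    """Point accuracy with optional resampling inference attached."""

    accuracy: float
    per_child_winning_rate: np.ndarray
    ci95: tuple[float, float] | None = None
    permutation_p: float | None = None
    boot_draws: np.ndarray | None = None
    null_draws: np.ndarray | None = None
    n_boot: int = 0
    n_perm: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        rates = np.asarray(self.per_child_winning_rate, dtype=float)
        if not np.isclose(self.accuracy, rates.mean()):
            raise ValidationError("accuracy must equal the mean per-child winning rate")
        self.per_child_winning_rate = rates


def _row_standardize(X: np.ndarray, who: Sequence[str]) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValidationError(
            f"zero-variance feature vector for subject(s) {[who[i] for i in zero[:5]]}"
        )
    return Xc / norms[:, None]


def similarity_matrix(
    cohort: DyadCohort, feature_mask: "Iterable[str] | None" = None
) -> SimilarityMatrix:
    """Full N×N matrix of Pearson correlations between every child's and
    every parent's feature vector, optionally restricted to a mask of
    feature ids (per-vector mean/SD are taken over the masked entries
    only)."""
    if feature_mask is not None:
        mask = list(feature_mask)
        if not mask:
            raise ValidationError("empty feature mask")
        cohort = cohort.mask_features(mask)
    if cohort.children.n_features < 3:
        raise ValidationError(
            f"need at least 3 features to correlate, got {cohort.children.n_features}"
        )
    zc = _row_standardize(cohort.children.values, cohort.child_ids)
    zp = _row_standardize(cohort.parents.values, cohort.parent_ids)
    vals = np.clip(zc @ zp.T, -1.0, 1.0)
    return SimilarityMatrix(cohort.child_ids, cohort.parent_ids, vals)


def per_child_winning_rates(sim: SimilarityMatrix, direction: str = "child") -> np.ndarray:
    """rate_i = [#strangers beaten + 0.5·#ties] / (N−1).

    ``direction='child'`` (default) compares child i's own parent against
    stranger parents along row i; ``'parent'`` runs the transposed,
    parent-centric comparison.
    """
    if direction == "child":
        S, ids = sim.values, sim.parents
    else:
        S, ids = sim.values.T, sim.children
    if S.shape[0] != S.shape[1]:
        raise ValidationError("winning rates require a square similarity matrix")
    n = S.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 dyads")
    d = np.diag(S)
    # strangers are identified by id, not position: a bootstrap resample
    # may list the same dyad twice, and a copy of the child's own parent
    # is not a stranger
    _, codes = np.unique(ids, return_inverse=True)
    stranger = codes[None, :] != codes[:, None]
    n_strangers = stranger.sum(axis=1)
    if np.any(n_strangers == 0):
        raise ValidationError("a dyad has no stranger comparisons")
    wins = ((d[:, None] > S) & stranger).sum(axis=1)
    ties = ((d[:, None] == S) & stranger).sum(axis=1)
    return (wins + 0.5 * ties) / n_strangers


def winning_rate_accuracy(sim: SimilarityMatrix, direction: str = "child") -> AccuracyEstimate:
    """Point winning-rate accuracy with per-child rates (no resampling)."""
    rates = per_child_winning_rates(sim, direction=direction)
    return AccuracyEstimate(accuracy=float(rates.mean()), per_child_winning_rate=rates)


def winning_rate(sim: SimilarityMatrix) -> float:
    """Scalar accuracy; the default statistic for resampling."""
    return float(per_child_winning_rates(sim).mean())


def sampling_procedure_accuracy(
    sim: SimilarityMatrix, n_draws: int, seed: "int | np.random.Generator | None" = None
) -> float:
    """Monte-Carlo pairwise-classification equivalent of the winning
    rate: repeatedly draw a random child and a random stranger parent and
    score whether the own-parent similarity exceeds the stranger's
    (half credit on ties). Converges to :func:`winning_rate` as
    n_draws → ∞; chance level is 50% for any N.
    """
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S = sim.values
    n = sim.n
    i = rng.integers(0, n, size=n_draws)
    j = rng.integers(0, n - 1, size=n_draws)
    j = j + (j >= i)  # stranger: uniform over parents other than i's own
    own = S[i, i]
    stranger = S[i, j]
    score = (own > stranger) + 0.5 * (own == stranger)
    return float(score.mean())


def conventional_identification(sim: SimilarityMatrix, direction: str = "child") -> float:
    """Rank-1 fingerprinting baseline: a child scores 1 only if their own
    parent attains the strict row-maximum similarity (ties at the max
    share credit 1/#tied). Chance level is 1/N."""
    S = sim.values if direction == "child" else sim.values.T
    n = S.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 dyads")
    rowmax = S.max(axis=1)
    at_max = S == rowmax[:, None]
    own_at_max = at_max[np.arange(n), np.arange(n)]
    credit = np.where(own_at_max, 1.0 / at_max.sum(axis=1), 0.0)
    return float(credit.mean())
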