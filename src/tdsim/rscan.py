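"""Similarity-to-centroid sets C_R and the cross-R correlation scan.

For a panel of n trials, C_R collects each trial's similarity S_R to the
panel centroid (the discretized mean dominance proportions). Correlating
C_R1 with C_R2 across a grid of dynamic levels shows how strongly the
duration-focused (small R) and timing-focused (large R) views of the panel
agree, and suggests an R that is consistent with both extremes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import DegenerateDistributionError, TDSError
from .metrics import DiscretizedCentroid, discretize_trial, dissimilarity
from .trial import TrialSet

__all__ = [
    "SimilaritySet",
    "CorrelationGrid",
    "CentroidSimilarity",
    "similarity_set",
    "correlate_sets",
    "correlation_grid",
    "recommend_R",
    "R_from_min_switch_interval",
]


@dataclass(frozen=True)
class SimilaritySet:
    """Per-trial similarity to the panel centroid at one dynamic level R."""

    R: int
    entries: dict[str, float]

    @property
    def trial_ids(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def values(self) -> np.ndarray:
        return np.array(list(self.entries.values()), dtype=float)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, trial_id: str) -> float:
        return self.entries[trial_id]


@dataclass(frozen=True)
class CorrelationGrid:
    """Symmetric matrix of Pearson correlations between C_R1 and C_R2."""

    R_values: tuple[int, ...]
    r: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.r, index=self.R_values, columns=self.R_values)


class CentroidSimilarity(BaseEstimator):
    """Score trials by their S_R similarity to the panel centroid.

    fit() learns the centroid (mean of the discretized trial matrices, which
    equals the discretized mean curve by linearity); transform() returns one
    similarity per trial. By default the scored trial is included in the
    centroid; set ``leave_one_out=True`` to exclude it when scoring the
    fitted panel.

    Parameters
    ----------
    R : int, default=1
        Dynamic level (number of time intervals).
    metric : {"euclidean", "manhattan"}, default="euclidean"
    leave_one_out : bool, default=False
    """

    def __init__(self, R: int = 1, metric: str = "euclidean",
                 leave_one_out: bool = False):
        self.R = R
        self.metric = metric
        self.leave_one_out = leave_one_out

    def fit(self, X: TrialSet, y=None):
        if not isinstance(X, TrialSet):
            raise TypeError("CentroidSimilarity expects a TrialSet")
        if X.n < 2:
            raise TDSError(
                "similarity to the centroid needs n >= 2 trials "
                "(the centroid of a single trial is the trial itself)"
            )
        if self.R < 1:
            raise TDSError(f"R must be a positive integer, got {self.R}")
        q = X.lexicon.q
        mats = np.stack([discretize_trial(t, self.R, q).X for t in X])
        self.n_attributes_ = q
        self.trial_ids_ = X.trial_ids
        self.matrices_ = mats
        self.centroid_ = DiscretizedCentroid(P=mats.mean(axis=0), R=int(self.R))
        return self

    def transform(self, X: TrialSet | None = None) -> np.ndarray:
        if not hasattr(self, "centroid_"):
            from sklearn.exceptions import NotFittedError

            raise NotFittedError("CentroidSimilarity is not fitted")
        P = self.centroid_.P
        if X is None or (isinstance(X, TrialSet) and X.trial_ids == self.trial_ids_):
            mats = self.matrices_
            n = mats.shape[0]
            out = np.empty(n)
            for j in range(n):
                ref = (n * P - mats[j]) / (n - 1) if self.leave_one_out else P
                out[j] = 1.0 - dissimilarity(mats[j], ref, metric=self.metric)
            return out
        mats = np.stack(
            [discretize_trial(t, self.R, self.n_attributes_).X for t in X]
        )
        return np.array(
            [1.0 - dissimilarity(m, P, metric=self.metric) for m in mats]
        )

    def fit_transform(self, X: TrialSet, y=None) -> np.ndarray:
        return self.fit(X).transform()

    def similarity_set(self, X: TrialSet) -> SimilaritySet:
        values = self.fit_transform(X)
        return SimilaritySet(
            R=int(self.R), entries=dict(zip(X.trial_ids, values.tolist()))
        )


def similarity_set(
    trials: TrialSet,
    R: int,
    metric: str = "euclidean",
    leave_one_out: bool = False,
) -> SimilaritySet:
    """C_R: each trial's similarity to the panel centroid at level R."""
    est = CentroidSimilarity(R=R, metric=metric, leave_one_out=leave_one_out)
    return est.similarity_set(trials)


def correlate_sets(C1: SimilaritySet, C2: SimilaritySet) -> float:
    """Pearson correlation between two similarity sets, matched by trial id."""
    if set(C1.entries) != set(C2.entries):
        raise TDSError("similarity sets cover different trials")
    if len(C1) < 3:
        raise TDSError("correlation needs at least 3 trials")
    x = np.array([C1.entries[i] for i in C1.trial_ids])
    y = np.array([C2.entries[i] for i in C1.trial_ids])
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDistributionError(
            f"similarity set (R={C1.R if np.std(x) == 0 else C2.R}) has zero "
            "variance; correlation undefined"
        )
    return float(stats.pearsonr(x, y).statistic)


def correlation_grid(
    trials: TrialSet, R_values: Sequence[int], metric: str = "euclidean"
) -> CorrelationGrid:
    """Full symmetric grid of correlations between C_R over a list of levels."""
    R_values = tuple(int(R) for R in R_values)
    if len(set(R_values)) != len(R_values) or any(R < 1 for R in R_values):
        raise TDSError("R_values must be distinct positive integers")
    sets = [similarity_set(trials, R, metric=metric) for R in R_values]
    m = len(R_values)
    r = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            try:
                r[i, j] = r[j, i] = correlate_sets(sets[i], sets[j])
            except TDSError as exc:
                raise TDSError(
                    f"correlation failed for (R1={R_values[i]}, "
                    f"R2={R_values[j]}): {exc}"
                ) from exc
    return CorrelationGrid(R_values=R_values, r=r)


def recommend_R(grid: CorrelationGrid, criterion: str = "max-min") -> int:
    """Pick the level whose similarities agree best with every other level.

    Scores each R by the minimum (``"max-min"``) or mean (``"max-mean"``) of
    its off-diagonal correlations and returns the best-scoring R; ties break
    toward the smaller R for parsimony.
    """
    if criterion not in ("max-min", "max-mean"):
        raise TDSError(f"unknown criterion {criterion!r}")
    m = len(grid.R_values)
    if m < 2:
        raise TDSError("recommend_R needs a grid over at least two R values")
    if not np.all(np.isfinite(grid.r)):
        raise TDSError("correlation grid contains non-finite entries")
    off = grid.r[~np.eye(m, dtype=bool)].reshape(m, m - 1)
    scores = off.min(axis=1) if criterion == "max-min" else off.mean(axis=1)
    order = np.lexsort((grid.R_values, -scores))  # best score, then smallest R
    return int(grid.R_values[order[0]])


def R_from_min_switch_interval(trials: TrialSet, quantile: float = 0.05) -> int:
    """Dynamic level matched to the panel's fastest attribute switching.

    Intervals finer than the shortest time a panelist needs between two
    button presses carry no behavioral information, so R is chosen as
    floor(mean task duration / switching interval), where the interval is a
    low quantile (default the 5th percentile) of all inter-selection gaps in
    seconds.
    """
    if not 0 <= quantile <= 1:
        raise TDSError("quantile must lie in [0, 1]")
    gaps: list[float] = []
    durations: list[float] = []
    for t in trials:
        if t.duration_seconds is None:
            continue
        durations.append(t.duration_seconds)
        onsets = [onset for attr, onset in t.events if attr >= 1]
        for a, b in zip(onsets, onsets[1:]):
            gaps.append((b - a) * t.duration_seconds)
    if not gaps:
        raise TDSError(
            "no trial has two or more timed selections with a known duration; "
            "use recommend_R on a correlation grid instead"
        )
    interval = float(np.quantile(gaps, quantile))
    if interval <= 0:
        raise TDSError("switching interval quantile is zero")
    return max(1, int(np.floor(np.mean(durations) / interval)))
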