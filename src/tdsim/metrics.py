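"""Discretization and the S_R similarity index between TDS trials.

A trial's binary dominance functions are averaged over R equal time intervals,

    X_i[k] = R * integral of x_i(t) over [k/R, (k+1)/R],

giving a (q+1) x R matrix whose k-th column is the vector of dominance
durations inside interval k (a probability vector, since exactly one
attribute is dominant at any instant). The same conversion applies to a
dominance-proportion curve, yielding the panel centroid P_i[k].

The similarity index between two discretized trials (or a trial and the
centroid) is

    S_R(A, B) = 1 - (1 / (sqrt(2) * R)) * sum_k || A[:, k] - B[:, k] ||_2,

i.e. one minus the average per-interval Euclidean distance in the
(q+1)-dimensional attribute space, normalized so its maximum — attained by
two trials that each select a single, different attribute throughout — is
exactly 1. R is the "dynamic level": R=1 compares only total dominance
durations, large R compares the timing of selections.

Note that the "none" state (index 0) participates in the sum: a trial that
starts selecting late genuinely differs from one that starts immediately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ShapeError, TDSError
from .trial import DominanceCurve, TDSTrial, TrialSet

__all__ = [
    "DiscretizedTrial",
    "DiscretizedCentroid",
    "discretize_trial",
    "discretize_curve",
    "dissimilarity",
    "similarity",
    "interval_seconds",
    "TrialDiscretizer",
]

_METRICS = ("euclidean", "manhattan")


@dataclass(frozen=True)
class DiscretizedTrial:
    """(q+1) x R matrix of per-interval dominance durations for one trial."""

    X: np.ndarray
    R: int
    trial_id: str = ""

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", X)
        if X.ndim != 2 or X.shape[1] != self.R:
            raise ShapeError(f"matrix shape {X.shape} inconsistent with R={self.R}")

    def to_frame(self, labels=None):
        """Wide table: rows attributes (index 0 = none), columns intervals."""
        import pandas as pd

        idx = list(labels) if labels is not None else list(range(self.X.shape[0]))
        return pd.DataFrame(self.X, index=idx, columns=range(self.R))


@dataclass(frozen=True)
class DiscretizedCentroid:
    """(q+1) x R matrix of per-interval mean dominance proportions."""

    P: np.ndarray
    R: int

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        object.__setattr__(self, "P", P)
        if P.ndim != 2 or P.shape[1] != self.R:
            raise ShapeError(f"matrix shape {P.shape} inconsistent with R={self.R}")


def _segments_to_matrix(segments, R: int, n_attributes: int) -> np.ndarray:
    """Exact interval-overlap discretization of a piecewise-constant function.

    For each constant piece, its overlap with every interval [k/R, (k+1)/R]
    is accumulated in closed form — the integrand is a step function, so no
    quadrature is needed.
    """
    out = np.zeros((n_attributes + 1, R))
    for attr, s, e in segments:
        k0 = int(np.floor(s * R))
        k1 = min(int(np.ceil(e * R)), R)
        for k in range(k0, k1):
            lo = max(s, k / R)
            hi = min(e, (k + 1) / R)
            if hi > lo:
                out[attr, k] += (hi - lo) * R
    return out


def discretize_trial(trial: TDSTrial, R: int, n_attributes: int) -> DiscretizedTrial:
    """Average the trial's binary dominance functions over R equal intervals."""
    if R < 1:
        raise TDSError(f"R must be a positive integer, got {R}")
    X = _segments_to_matrix(trial.segments(), int(R), n_attributes)
    return DiscretizedTrial(X=X, R=int(R), trial_id=trial.trial_id)


def discretize_curve(curve: DominanceCurve, R: int) -> DiscretizedCentroid:
    """Average a dominance-proportion curve over R equal intervals.

    Because the integral is linear, this equals the element-wise mean of the
    discretized matrices of the trials the curve came from.
    """
    if R < 1:
        raise TDSError(f"R must be a positive integer, got {R}")
    R = int(R)
    q1 = curve.values.shape[1]
    P = np.zeros((q1, R))
    bp = curve.breakpoints
    for seg in range(curve.values.shape[0]):
        s, e = bp[seg], bp[seg + 1]
        k0 = int(np.floor(s * R))
        k1 = min(int(np.ceil(e * R)), R)
        for k in range(k0, k1):
            lo = max(s, k / R)
            hi = min(e, (k + 1) / R)
            if hi > lo:
                P[:, k] += curve.values[seg] * (hi - lo) * R
    return DiscretizedCentroid(P=P, R=R)


def _as_matrix(obj) -> tuple[np.ndarray, int]:
    if isinstance(obj, DiscretizedTrial):
        return obj.X, obj.R
    if isinstance(obj, DiscretizedCentroid):
        return obj.P, obj.R
    arr = np.asarray(obj, dtype=float)
    if arr.ndim != 2:
        raise ShapeError("expected a (q+1) x R matrix")
    return arr, arr.shape[1]


def dissimilarity(A, B, metric: str = "euclidean") -> float:
    """Normalized average per-interval distance between two discretized trials.

    ``euclidean`` divides the summed per-interval L2 distances by sqrt(2)*R;
    ``manhattan`` divides the summed L1 distances by 2*R. Both normalizations
    put the maximum — disjoint single-attribute trials — at exactly 1.
    """
    if metric not in _METRICS:
        raise TDSError(f"metric must be one of {_METRICS}, got {metric!r}")
    Xa, Ra = _as_matrix(A)
    Xb, Rb = _as_matrix(B)
    if Ra != Rb:
        raise ShapeError(f"cannot compare R={Ra} with R={Rb}")
    if Xa.shape != Xb.shape:
        raise ShapeError(f"attribute dimensions differ: {Xa.shape} vs {Xb.shape}")
    diff = Xa - Xb
    if metric == "euclidean":
        return float(np.linalg.norm(diff, axis=0).sum() / (np.sqrt(2.0) * Ra))
    return float(np.abs(diff).sum() / (2.0 * Ra))


def similarity(A, B, metric: str = "euclidean") -> float:
    """S_R = 1 - dissimilarity; 1 for identical trials, 0 for maximally distinct."""
    return 1.0 - dissimilarity(A, B, metric=metric)


def interval_seconds(mean_duration_s: float, R: int) -> float:
    """Real-time length of one discretization interval.

    For a mean task duration of 30 s, R=20 gives 1.5 s per interval and
    R=10 gives 3 s.
    """
    if mean_duration_s <= 0:
        raise TDSError("mean_duration_s must be positive")
    if R < 1:
        raise TDSError("R must be a positive integer")
    return float(mean_duration_s) / int(R)


class TrialDiscretizer(TransformerMixin, BaseEstimator):
    """Transformer mapping a TrialSet to an (n, q+1, R) array of matrices.

    Parameters
    ----------
    R : int, default=1
        Number of equal time intervals (the dynamic level).

    Attributes
    ----------
    n_attributes_ : int
        q, taken from the fitted TrialSet's lexicon.
    trial_ids_ : tuple of str
    """

    def __init__(self, R: int = 1):
        self.R = R

    def fit(self, X: TrialSet, y=None):
        if not isinstance(X, TrialSet):
            raise TypeError("TrialDiscretizer expects a TrialSet")
        if self.R < 1:
            raise TDSError(f"R must be a positive integer, got {self.R}")
        self.n_attributes_ = X.lexicon.q
        self.trial_ids_ = X.trial_ids
        return self

    def transform(self, X: TrialSet) -> np.ndarray:
        if not hasattr(self, "n_attributes_"):
            from sklearn.exceptions import NotFittedError

            raise NotFittedError("TrialDiscretizer is not fitted")
        return np.stack(
            [discretize_trial(t, self.R, self.n_attributes_).X for t in X]
        )
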