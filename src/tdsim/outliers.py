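"""Outlier screening of TDS trials by similarity to the panel centroid.

A trial whose similarity to the centroid is unusually LOW is a candidate
outlier; high similarity means the trial represents the panel well, so the
screen is strictly one-sided. For each dynamic level R:

1. test the similarity set C_R for normality (one-sample Kolmogorov-Smirnov);
2. if normality is not rejected (p > 0.05), flag trials below mu - 1.64*sigma
   (95% coverage) or mu - 2.33*sigma (99%), with mu and sigma the sample mean
   and standard deviation of C_R;
3. otherwise fall back to a one-sided box-plot rule, flagging trials below
   Q1 - k*IQR.

Because small R compares dominance durations and large R compares timing,
the flagged set can legitimately change with R: a trial that spends typical
total time on each attribute but in an atypical order is an inlier at R=1
and an outlier at large R.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, OutlierMixin

from .errors import DegenerateDistributionError, TDSError
from .rscan import SimilaritySet, similarity_set
from .trial import TrialSet

__all__ = [
    "ScreenResult",
    "OutlierReport",
    "ks_normality",
    "detect_outliers_normal",
    "detect_outliers_iqr",
    "robust_location_scale",
    "outlier_analysis",
    "SimilarityOutlierScreen",
]

# one-sided normal z values as conventionally printed (not recomputed to
# more digits): 95% coverage uses 1.64, 99% uses 2.33
_Z = {0.95: 1.64, 0.99: 2.33}


def _values(C) -> np.ndarray:
    if isinstance(C, SimilaritySet):
        return C.values()
    return np.asarray(C, dtype=float)


def ks_normality(C, mode: str = "plugin") -> float:
    """One-sample KS p-value of C against a normal with estimated moments.

    ``mode="plugin"`` tests against N(mean, sd) with the parameters plugged
    in; ``mode="lilliefors"`` applies the Lilliefors correction for estimated
    parameters, which is statistically preferable but more conservative (the
    plug-in p-value is biased upward). Plug-in is the default gate.
    """
    x = _values(C)
    if x.size < 5:
        raise TDSError(f"KS normality test needs n >= 5, got n={x.size}")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise DegenerateDistributionError(
            "all similarity values identical; normality test undefined"
        )
    if mode == "plugin":
        return float(stats.kstest(x, "norm", args=(float(np.mean(x)), sd)).pvalue)
    if mode == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors

        return float(lilliefors(x, dist="norm")[1])
    raise TDSError(f"mode must be 'plugin' or 'lilliefors', got {mode!r}")


def detect_outliers_normal(
    C: SimilaritySet,
    coverage: float = 0.95,
    location_scale: tuple[float, float] | None = None,
) -> tuple[tuple[str, ...], float]:
    """One-sided normal-range screen: flag entries strictly below mu - z*sigma.

    Returns (flagged trial ids, threshold). Entries exactly at the threshold
    are inliers (the acceptance range is [mu - z*sigma, +inf)); entries above
    the mean are never flagged regardless of magnitude. ``location_scale``
    substitutes robust estimates for the sample moments.
    """
    if coverage not in _Z:
        raise TDSError(f"coverage must be one of {sorted(_Z)}, got {coverage}")
    x = C.values()
    if x.size < 5:
        raise TDSError(f"normal screen needs n >= 5, got n={x.size}")
    if location_scale is None:
        mu, sigma = float(np.mean(x)), float(np.std(x, ddof=1))
    else:
        mu, sigma = map(float, location_scale)
    if sigma == 0:
        warnings.warn(
            "zero spread in similarity values; no trial can be flagged",
            stacklevel=2,
        )
        return (), mu
    threshold = mu - _Z[coverage] * sigma
    flagged = tuple(tid for tid, v in C.entries.items() if v < threshold)
    return flagged, threshold


def detect_outliers_iqr(C: SimilaritySet, k: float = 1.5) -> tuple[tuple[str, ...], float]:
    """One-sided box-plot screen: flag entries below Q1 - k*IQR.

    Quartiles use the linear-interpolation convention. Only the low side is
    screened, consistent with the normal-range rule. Returns (flagged ids,
    lower fence).
    """
    if k <= 0:
        raise TDSError("k must be positive")
    x = C.values()
    if x.size < 5:
        raise TDSError(f"IQR screen needs n >= 5, got n={x.size}")
    q1, q3 = np.quantile(x, [0.25, 0.75], method="linear")
    fence = float(q1 - k * (q3 - q1))
    flagged = tuple(tid for tid, v in C.entries.items() if v < fence)
    return flagged, fence


def robust_location_scale(C) -> tuple[float, float]:
    """Shortest-half robust location and scale (univariate MCD analog).

    Finds the contiguous sub-sample of h = ceil((n+1)/2) sorted points with
    the smallest range; its mean and standard deviation (the latter inflated
    by the consistency factor alpha / P(chi2_3 <= chi2_1(alpha)) so the
    estimator is consistent for normal data) replace the raw moments when
    gross low outliers would otherwise drag the mean down.
    """
    x = np.sort(_values(C))
    n = x.size
    if n < 10:
        raise TDSError(f"robust location/scale needs n >= 10, got n={n}")
    h = int(np.ceil((n + 1) / 2))
    ranges = x[h - 1 :] - x[: n - h + 1]
    i = int(np.argmin(ranges))
    sub = x[i : i + h]
    loc = float(np.mean(sub))
    raw_sd = float(np.std(sub, ddof=1))
    if raw_sd == 0:
        return loc, 0.0
    alpha = h / n
    factor = alpha / stats.chi2.cdf(stats.chi2.ppf(alpha, 1), 3)
    return loc, raw_sd * float(np.sqrt(factor))


@dataclass(frozen=True)
class ScreenResult:
    """Screening outcome for one dynamic level R."""

    R: int
    n: int
    mean: float
    std: float
    ks_p: float
    screen: str  # "normal" | "iqr"
    coverage: float
    threshold: float
    flagged: tuple[str, ...]


@dataclass(frozen=True)
class OutlierReport:
    """Per-R screening results over one panel."""

    trial_ids: tuple[str, ...]
    results: tuple[ScreenResult, ...]

    @property
    def R_values(self) -> tuple[int, ...]:
        return tuple(res.R for res in self.results)

    def flagged_at(self, R: int) -> tuple[str, ...]:
        for res in self.results:
            if res.R == R:
                return res.flagged
        raise KeyError(R)

    def flag_frame(self):
        """Boolean trials x R table of flags."""
        import pandas as pd

        data = {
            res.R: [tid in res.flagged for tid in self.trial_ids]
            for res in self.results
        }
        return pd.DataFrame(data, index=list(self.trial_ids))

    def flag_table(self, only_flagged: bool = True):
        """Trials x R table with "+" marks, one row per (ever-)flagged trial."""
        frame = self.flag_frame()
        if only_flagged:
            frame = frame.loc[frame.any(axis=1)]
        return frame.map(lambda b: "+" if b else "")

    def to_dict(self) -> dict:
        return {
            "trial_ids": list(self.trial_ids),
            "results": [
                {
                    "R": res.R,
                    "n": res.n,
                    "mean": res.mean,
                    "std": res.std,
                    "ks_p": res.ks_p,
                    "screen": res.screen,
                    "coverage": res.coverage,
                    "threshold": res.threshold,
                    "flagged": list(res.flagged),
                }
                for res in self.results
            ],
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def _screen_one(
    C: SimilaritySet,
    coverage: float,
    ks_mode: str,
    alpha: float,
    iqr_k: float,
    robust: bool,
) -> ScreenResult:
    x = C.values()
    mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    if sd == 0:
        warnings.warn(
            f"R={C.R}: all similarity values identical; nothing to flag",
            stacklevel=3,
        )
        return ScreenResult(
            R=C.R, n=x.size, mean=mu, std=0.0, ks_p=float("nan"),
            screen="normal", coverage=coverage, threshold=mu, flagged=(),
        )
    p = ks_normality(C, mode=ks_mode)
    if p > alpha:
        loc_scale = robust_location_scale(C) if robust else None
        flagged, threshold = detect_outliers_normal(
            C, coverage=coverage, location_scale=loc_scale
        )
        screen = "normal"
    else:
        flagged, threshold = detect_outliers_iqr(C, k=iqr_k)
        screen = "iqr"
    return ScreenResult(
        R=C.R, n=x.size, mean=mu, std=sd, ks_p=p, screen=screen,
        coverage=coverage, threshold=threshold, flagged=flagged,
    )


def outlier_analysis(
    trials: TrialSet,
    R_values: Sequence[int],
    coverage: float = 0.95,
    metric: str = "euclidean",
    ks_mode: str = "plugin",
    alpha: float = 0.05,
    iqr_k: float = 1.5,
    robust: bool = False,
) -> OutlierReport:
    """Run the normality-gated one-sided screen at every requested R."""
    R_values = tuple(int(R) for R in R_values)
    if not R_values:
        raise TDSError("R_values must be non-empty")
    results = []
    for R in R_values:
        try:
            C = similarity_set(trials, R, metric=metric)
            results.append(
                _screen_one(C, coverage, ks_mode, alpha, iqr_k, robust)
            )
        except TDSError as exc:
            raise TDSError(f"outlier screen failed at R={R}: {exc}") from exc
    return OutlierReport(trial_ids=trials.trial_ids, results=tuple(results))


class SimilarityOutlierScreen(OutlierMixin, BaseEstimator):
    """sklearn-style outlier detector over a panel of TDS trials.

    ``fit`` runs :func:`outlier_analysis`; ``predict`` returns -1 for trials
    flagged at any fitted R and +1 otherwise (sklearn outlier convention).
    The full per-R detail lives in ``report_``.

    Parameters
    ----------
    R_values : sequence of int, default=(1, 3, 10, 30, 50, 100)
        Dynamic levels to screen at.
    coverage : {0.95, 0.99}, default=0.95
        One-sided coverage of the normal acceptance range.
    metric : {"euclidean", "manhattan"}, default="euclidean"
    ks_mode : {"plugin", "lilliefors"}, default="plugin"
    alpha : float, default=0.05
        Normality-gate significance level.
    iqr_k : float, default=1.5
        Whisker multiplier of the box-plot fallback.
    robust : bool, default=False
        Use shortest-half location/scale in the normal screen.
    """

    def __init__(
        self,
        R_values: Sequence[int] = (1, 3, 10, 30, 50, 100),
        coverage: float = 0.95,
        metric: str = "euclidean",
        ks_mode: str = "plugin",
        alpha: float = 0.05,
        iqr_k: float = 1.5,
        robust: bool = False,
    ):
        self.R_values = R_values
        self.coverage = coverage
        self.metric = metric
        self.ks_mode = ks_mode
        self.alpha = alpha
        self.iqr_k = iqr_k
        self.robust = robust

    def fit(self, X: TrialSet, y=None):
        if not isinstance(X, TrialSet):
            raise TypeError("SimilarityOutlierScreen expects a TrialSet")
        self.report_ = outlier_analysis(
            X,
            self.R_values,
            coverage=self.coverage,
            metric=self.metric,
            ks_mode=self.ks_mode,
            alpha=self.alpha,
            iqr_k=self.iqr_k,
            robust=self.robust,
        )
        self.trial_ids_ = X.trial_ids
        return self

    def predict(self, X: TrialSet | None = None) -> np.ndarray:
        if not hasattr(self, "report_"):
            from sklearn.exceptions import NotFittedError

            raise NotFittedError("SimilarityOutlierScreen is not fitted")
        if X is not None and X.trial_ids != self.trial_ids_:
            raise TDSError("predict only covers the fitted panel")
        ever = self.report_.flag_frame().any(axis=1).to_numpy()
        return np.where(ever, -1, 1)

    def fit_predict(self, X: TrialSet, y=None) -> np.ndarray:
        return self.fit(X).predict()
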