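"""Core TDS data model: trials as binary dominance step functions.

A TDS trial records which single attribute a panelist judges dominant at each
moment while eating a sample. We represent the trial as an ordered sequence of
(attribute index, onset) events on normalized time [0, 1]; the implied binary
dominance functions x_i(t) are right-continuous step functions with exactly
one attribute (including the pre-first-press "none" state, index 0) dominant
at every t:

    sum_{i=0..q} x_i(t) = 1   for all t in [0, 1].

Averaging the indicators of n trials pointwise gives the dominance-proportion
curve p_i(t) = (1/n) * sum_j x_i^(j)(t), the quantity plotted as a TDS curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import LexiconError, TDSError, ValidationError
from .lexicon import AttributeLexicon

__all__ = [
    "TDSTrial",
    "TrialSet",
    "DominanceCurve",
    "build_trial",
    "dominance_durations",
    "dominance_proportions",
    "smooth_curve",
]


@dataclass(frozen=True)
class TDSTrial:
    """One TDS trial on normalized time.

    ``events`` holds (attribute_index, onset) pairs with strictly increasing
    onsets in [0, 1). The segment before the first event carries attribute 0
    ("none"); each event's attribute stays dominant until the next event or
    the end of the trial (half-open segments, right-continuous).
    """

    trial_id: str
    events: tuple[tuple[int, float], ...]
    panel_id: str = ""
    replicate: int = 1
    duration_seconds: float | None = None

    def __post_init__(self) -> None:
        prev = -1.0
        seen_attr = False
        for pos, (attr, onset) in enumerate(self.events):
            if not 0.0 <= onset < 1.0:
                raise ValidationError(
                    f"trial {self.trial_id!r}: event {pos} onset {onset} "
                    "outside [0, 1)"
                )
            if onset <= prev:
                raise ValidationError(
                    f"trial {self.trial_id!r}: event {pos} onset {onset} "
                    f"not after previous onset {prev}"
                )
            if attr == 0 and seen_attr:
                raise ValidationError(
                    f"trial {self.trial_id!r}: 'none' (attribute 0) cannot "
                    "recur after an attribute has been selected"
                )
            if attr < 0:
                raise ValidationError(
                    f"trial {self.trial_id!r}: negative attribute index {attr}"
                )
            if attr >= 1:
                seen_attr = True
            prev = onset
        for (a1, _), (a2, _) in zip(self.events, self.events[1:]):
            if a1 == a2:
                raise ValidationError(
                    f"trial {self.trial_id!r}: consecutive events share "
                    f"attribute {a1}; collapse duplicates with build_trial"
                )
        if self.duration_seconds is not None and self.duration_seconds <= 0:
            raise ValidationError(
                f"trial {self.trial_id!r}: duration_seconds must be positive"
            )
        if self.replicate < 1:
            raise ValidationError(f"trial {self.trial_id!r}: replicate must be >= 1")

    # -- step-function views -------------------------------------------------

    def segments(self) -> list[tuple[int, float, float]]:
        """Constant segments (attribute, start, end) covering [0, 1]."""
        evs = list(self.events)
        if not evs or evs[0][1] > 0.0:
            evs = [(0, 0.0)] + evs
        out = []
        for pos, (attr, start) in enumerate(evs):
            end = evs[pos + 1][1] if pos + 1 < len(evs) else 1.0
            out.append((attr, start, end))
        return out

    def evaluate(self, t: float) -> int:
        """Dominant attribute index at normalized time ``t``.

        Segments are half-open [onset, next onset); t = 1 returns the final
        segment's attribute.
        """
        if not 0.0 <= t <= 1.0:
            raise TDSError(f"t={t} outside normalized time [0, 1]")
        attr = 0
        for a, onset in self.events:
            if onset <= t:
                attr = a
            else:
                break
        return attr

    @property
    def n_selections(self) -> int:
        """Number of attribute button presses (excluding the none state)."""
        return sum(1 for a, _ in self.events if a >= 1)

    def max_attribute(self) -> int:
        return max((a for a, _ in self.events), default=0)


@dataclass(frozen=True)
class TrialSet:
    """n trials sharing one attribute lexicon."""

    lexicon: AttributeLexicon
    trials: tuple[TDSTrial, ...]

    def __post_init__(self) -> None:
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate trial ids: {dupes}")
        q = self.lexicon.q
        for t in self.trials:
            if t.max_attribute() > q:
                raise LexiconError(
                    f"trial {t.trial_id!r} uses attribute index "
                    f"{t.max_attribute()} but lexicon has q={q}"
                )

    @property
    def n(self) -> int:
        return len(self.trials)

    @property
    def trial_ids(self) -> tuple[str, ...]:
        return tuple(t.trial_id for t in self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __len__(self) -> int:
        return len(self.trials)

    def get(self, trial_id: str) -> TDSTrial:
        for t in self.trials:
            if t.trial_id == trial_id:
                return t
        raise KeyError(trial_id)

    def replace(self, trial: TDSTrial) -> "TrialSet":
        """Return a new set with the same-id trial replaced."""
        if trial.trial_id not in self.trial_ids:
            raise KeyError(trial.trial_id)
        return TrialSet(
            self.lexicon,
            tuple(trial if t.trial_id == trial.trial_id else t for t in self.trials),
        )


@dataclass(frozen=True)
class DominanceCurve:
    """Piecewise-constant dominance proportions p_i(t) on [0, 1].

    ``breakpoints`` has m+1 strictly increasing entries from 0 to 1;
    ``values`` is an (m, q+1) array whose rows are probability vectors over
    attributes 0..q, constant on [breakpoints[k], breakpoints[k+1]).
    """

    breakpoints: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "values", v)
        if bp.ndim != 1 or bp.size < 2 or bp[0] != 0.0 or bp[-1] != 1.0:
            raise ValidationError("breakpoints must run from 0 to 1")
        if np.any(np.diff(bp) <= 0):
            raise ValidationError("breakpoints must be strictly increasing")
        if v.shape[0] != bp.size - 1:
            raise ValidationError("one value row per segment required")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValidationError("proportions must lie in [0, 1]")
        if not np.allclose(v.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("each segment's proportions must sum to 1")

    @property
    def n_attributes(self) -> int:
        """q (excluding the none state)."""
        return self.values.shape[1] - 1

    def value_at(self, t: float) -> np.ndarray:
        """Proportion vector at ``t`` (right-continuous; t=1 -> last segment)."""
        if not 0.0 <= t <= 1.0:
            raise TDSError(f"t={t} outside [0, 1]")
        k = int(np.searchsorted(self.breakpoints, t, side="right")) - 1
        k = min(max(k, 0), self.values.shape[0] - 1)
        return self.values[k]


# ---------------------------------------------------------------------------
# construction and evaluation
# ---------------------------------------------------------------------------


def build_trial(
    raw_events: Sequence[tuple[str | int, float]],
    start: float,
    stop: float,
    *,
    lexicon: AttributeLexicon,
    trial_id: str,
    panel_id: str = "",
    replicate: int = 1,
) -> TDSTrial:
    """Build a validated trial from raw button-press timestamps in seconds.

    Timestamps are mapped affinely onto normalized time via
    ``(timestamp - start) / (stop - start)``; consecutive re-presses of the
    same attribute are collapsed (a selected button stays selected until
    another is pressed, so a re-press is a no-op). A press at exactly ``stop``
    would select for zero time and is dropped with a warning.
    """
    if stop <= start:
        raise TDSError(f"stop ({stop}) must be after start ({start})")
    span = float(stop - start)

    prev_ts = None
    events: list[tuple[int, float]] = []
    for pos, (attr, ts) in enumerate(raw_events):
        label = attr
        idx = lexicon.index(attr) if isinstance(attr, str) else int(attr)
        if not 0 <= idx <= lexicon.q:
            raise LexiconError(f"attribute index {idx} outside 0..{lexicon.q}")
        if ts < start or ts > stop:
            raise ValidationError(
                f"trial {trial_id!r}: event {pos} ({label!r} @ {ts}s) outside "
                f"[{start}, {stop}]"
            )
        if prev_ts is not None and ts <= prev_ts:
            raise ValidationError(
                f"trial {trial_id!r}: event {pos} ({label!r} @ {ts}s) not "
                f"after previous timestamp {prev_ts}s"
            )
        prev_ts = ts
        if ts == stop:
            warnings.warn(
                f"trial {trial_id!r}: event {pos} at the stop instant selects "
                "for zero time; dropped",
                stacklevel=2,
            )
            continue
        if events and events[-1][0] == idx:
            continue  # re-press of the selected button
        events.append((idx, (ts - start) / span))

    if not any(a >= 1 for a, _ in events):
        warnings.warn(
            f"trial {trial_id!r}: no attribute was ever selected; "
            "'none' is dominant throughout",
            stacklevel=2,
        )
    return TDSTrial(
        trial_id=trial_id,
        events=tuple(events),
        panel_id=panel_id,
        replicate=replicate,
        duration_seconds=span,
    )


def dominance_durations(trial: TDSTrial, n_attributes: int) -> np.ndarray:
    """Total normalized time each attribute 0..q is dominant; sums to 1."""
    if trial.max_attribute() > n_attributes:
        raise LexiconError(
            f"trial {trial.trial_id!r} uses attribute {trial.max_attribute()} "
            f"but q={n_attributes}"
        )
    out = np.zeros(n_attributes + 1)
    for attr, s, e in trial.segments():
        out[attr] += e - s
    return out


def dominance_proportions(trials: TrialSet) -> DominanceCurve:
    """Pointwise average of the trials' indicator functions (the TDS curve).

    The result is piecewise constant on the union of all trials' onsets; on
    each segment, value i is the fraction of trials whose dominant attribute
    is i (a multiple of 1/n).
    """
    if trials.n < 1:
        raise TDSError("dominance_proportions needs at least one trial")
    cuts = {0.0, 1.0}
    for t in trials:
        cuts.update(onset for _, onset in t.events)
    bp = np.array(sorted(cuts))
    q = trials.lexicon.q
    values = np.zeros((bp.size - 1, q + 1))
    for t in trials:
        # right-continuity: the attribute on [bp[k], bp[k+1]) is the one at bp[k]
        for k in range(bp.size - 1):
            values[k, t.evaluate(bp[k])] += 1.0
    values /= trials.n
    return DominanceCurve(bp, values)


def smooth_curve(
    curve: DominanceCurve, window: float, *, grid_size: int = 2001
) -> DominanceCurve:
    """Centered moving average of the curve over a normalized-time window.

    The curve is resampled on a uniform grid and averaged with a centered
    boxcar (edge values extended at the boundaries, so each output row stays a
    convex combination of probability rows and the simplex constraint is
    preserved). ``window=0`` returns the input unchanged. Smoothing is a
    presentation aid: similarity and outlier computations use raw curves.
    """
    if window < 0:
        raise TDSError("window must be >= 0")
    if window > 1:
        raise TDSError("window must be <= 1 (normalized time)")
    if window == 0:
        return curve

    from scipy.ndimage import uniform_filter1d

    grid = np.linspace(0.0, 1.0, grid_size, endpoint=False)
    idx = np.clip(
        np.searchsorted(curve.breakpoints, grid, side="right") - 1,
        0,
        curve.values.shape[0] - 1,
    )
    sampled = curve.values[idx]
    size = max(1, int(round(window * grid_size)))
    if size % 2 == 0:
        size += 1
    smoothed = uniform_filter1d(sampled, size=size, axis=0, mode="nearest")
    # re-normalize defensively against float drift; rows are already ~simplex
    smoothed = np.clip(smoothed, 0.0, None)
    smoothed /= smoothed.sum(axis=1, keepdims=True)
    bp = np.append(grid, 1.0)
    return DominanceCurve(bp, smoothed)
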