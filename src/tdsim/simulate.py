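"""Semi-Markov synthetic TDS trial generator.

Real TDS event logs are rarely published, so the package ships a generator
that emulates a sensory panel: each trial is a semi-Markov chain over the
attribute set — the next attribute is drawn from a transition matrix, and the
time spent on the current attribute from an explicit sojourn distribution
(gamma or lognormal; button-press gaps are heavy-tailed). Temporal structure
of the kind real foods show (different attributes dominating early, middle
and late in the mouth) is produced by phase-dependent transition matrices
that switch on thirds of the task.

The strawberry-like preset follows the qualitative structure reported for
strawberry panels: sweet/juicy/fruity/watery dominate early, aromatic and
sour rise in the middle, sour (with light) dominates late; mean task
duration ~30 s with gamma sojourns of mean 2.5 s, so panelists switch
attributes on a seconds scale, mostly slower than 1 s.

Outlier archetypes can be planted into a simulated panel:

- ``single_attribute``: one attribute held for the whole trial (dominance
  durations of everything else are 0) — an outlier at R=1;
- ``rare_attributes``: the least-likely attributes selected throughout — an
  outlier at small-to-medium R;
- ``time_shifted``: the target trial with its selection timeline reversed
  (the pre-selection lead-in stays in place), so every dominance duration is
  unchanged but the timing is maximally shifted — an inlier at R=1 and an
  outlier at large R.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np

from .errors import TDSError, ValidationError
from .lexicon import STRAWBERRY_ATTRIBUTES, AttributeLexicon
from .trial import TDSTrial, TrialSet, build_trial

__all__ = [
    "SemiMarkovSpec",
    "simulate_trial",
    "simulate_panel",
    "inject_outlier",
    "strawberry_like_spec",
    "transition_from_weights",
    "expected_duration_fractions",
]

_FAMILIES = ("gamma", "lognormal", "constant")


def transition_from_weights(weights: np.ndarray) -> np.ndarray:
    """Zero-diagonal transition matrix with next-state odds given by weights.

    Row i is the weight vector with entry i removed and renormalized:
    T[i, j] = w[j] / (sum(w) - w[i]) for j != i.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or np.any(w < 0) or w.sum() <= 0:
        raise ValidationError("weights must be a non-negative vector with mass")
    q = w.size
    T = np.tile(w, (q, 1))
    np.fill_diagonal(T, 0.0)
    rowsum = T.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    return T / rowsum


@dataclass(frozen=True)
class SemiMarkovSpec:
    """Parameterization of the semi-Markov trial generator.

    Attributes 1..q are the lexicon entries; all times are in seconds.
    ``transition`` rows must sum to 1 with zero diagonal (a row of zeros is
    allowed and means the state is absorbing — held until the stop button).
    ``phase_transitions``, when given, overrides ``transition`` with one
    matrix per phase; ``phase_boundaries`` are fractions of the task
    duration (default thirds).
    """

    lexicon: AttributeLexicon
    initial: np.ndarray
    transition: np.ndarray
    sojourn_mean: np.ndarray
    sojourn_shape: np.ndarray
    sojourn_family: str = "gamma"
    duration_mean: float = 30.0
    duration_sd: float = 0.0
    duration_min: float = 1.0
    lead_in_mean: float = 0.0
    phase_transitions: np.ndarray | None = None
    phase_boundaries: tuple[float, ...] = (0.0, 1 / 3, 2 / 3, 1.0)

    def __post_init__(self) -> None:
        q = self.lexicon.q
        object.__setattr__(self, "initial", np.asarray(self.initial, dtype=float))
        object.__setattr__(self, "transition", np.asarray(self.transition, dtype=float))
        object.__setattr__(self, "sojourn_mean", np.broadcast_to(
            np.asarray(self.sojourn_mean, dtype=float), (q,)).copy())
        object.__setattr__(self, "sojourn_shape", np.broadcast_to(
            np.asarray(self.sojourn_shape, dtype=float), (q,)).copy())
        if self.phase_transitions is not None:
            object.__setattr__(
                self, "phase_transitions",
                np.asarray(self.phase_transitions, dtype=float),
            )
        self.validate()

    def validate(self) -> None:
        q = self.lexicon.q
        problems: list[str] = []
        if self.initial.shape != (q,):
            problems.append(f"initial must have shape ({q},)")
        elif np.any(self.initial < 0) or not np.isclose(self.initial.sum(), 1.0):
            problems.append("initial must be a probability vector")
        mats = [("transition", self.transition)]
        if self.phase_transitions is not None:
            n_phases = len(self.phase_boundaries) - 1
            if self.phase_transitions.shape != (n_phases, q, q):
                problems.append(
                    f"phase_transitions must have shape ({n_phases}, {q}, {q})"
                )
            else:
                mats += [
                    (f"phase {p} transition", self.phase_transitions[p])
                    for p in range(n_phases)
                ]
        for name, T in mats:
            if T.shape != (q, q):
                problems.append(f"{name} must be {q}x{q}")
                continue
            if np.any(np.diag(T) != 0):
                problems.append(f"{name} diagonal must be zero")
            rows = T.sum(axis=1)
            bad = [
                i for i, s in enumerate(rows)
                if not (np.isclose(s, 1.0) or s == 0.0)
            ]
            if bad or np.any(T < 0):
                problems.append(
                    f"{name} rows {bad} must sum to 1 (or 0 for absorbing)"
                )
        if np.any(self.sojourn_mean <= 0) or np.any(self.sojourn_shape <= 0):
            problems.append("sojourn parameters must be positive")
        if self.sojourn_family not in _FAMILIES:
            problems.append(f"sojourn_family must be one of {_FAMILIES}")
        if self.duration_mean <= 0 or self.duration_sd < 0 or self.duration_min <= 0:
            problems.append("duration parameters must be positive")
        if self.lead_in_mean < 0:
            problems.append("lead_in_mean must be >= 0")
        bounds = np.asarray(self.phase_boundaries, dtype=float)
        if bounds[0] != 0 or bounds[-1] != 1 or np.any(np.diff(bounds) <= 0):
            problems.append("phase_boundaries must increase from 0 to 1")
        if problems:
            raise ValidationError("invalid SemiMarkovSpec: " + "; ".join(problems))

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "attributes": list(self.lexicon.names),
            "initial": self.initial.tolist(),
            "transition": self.transition.tolist(),
            "sojourn_family": self.sojourn_family,
            "sojourn_mean": self.sojourn_mean.tolist(),
            "sojourn_shape": self.sojourn_shape.tolist(),
            "duration_mean": self.duration_mean,
            "duration_sd": self.duration_sd,
            "duration_min": self.duration_min,
            "lead_in_mean": self.lead_in_mean,
            "phase_boundaries": list(self.phase_boundaries),
        }
        if self.phase_transitions is not None:
            d["phase_transitions"] = self.phase_transitions.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SemiMarkovSpec":
        pt = d.get("phase_transitions")
        return cls(
            lexicon=AttributeLexicon(d["attributes"]),
            initial=np.asarray(d["initial"], dtype=float),
            transition=np.asarray(d["transition"], dtype=float),
            sojourn_mean=np.asarray(d["sojourn_mean"], dtype=float),
            sojourn_shape=np.asarray(d["sojourn_shape"], dtype=float),
            sojourn_family=d.get("sojourn_family", "gamma"),
            duration_mean=float(d.get("duration_mean", 30.0)),
            duration_sd=float(d.get("duration_sd", 0.0)),
            duration_min=float(d.get("duration_min", 1.0)),
            lead_in_mean=float(d.get("lead_in_mean", 0.0)),
            phase_transitions=None if pt is None else np.asarray(pt, dtype=float),
            phase_boundaries=tuple(d.get("phase_boundaries", (0.0, 1 / 3, 2 / 3, 1.0))),
        )


def _draw_sojourn(spec: SemiMarkovSpec, state: int, rng: np.random.Generator) -> float:
    m = spec.sojourn_mean[state]
    k = spec.sojourn_shape[state]
    if spec.sojourn_family == "gamma":
        return float(rng.gamma(shape=k, scale=m / k))
    if spec.sojourn_family == "lognormal":
        return float(rng.lognormal(mean=np.log(m) - k**2 / 2, sigma=k))
    return float(m)  # constant


def _phase_index(spec: SemiMarkovSpec, frac: float) -> int:
    bounds = spec.phase_boundaries
    k = int(np.searchsorted(bounds, frac, side="right")) - 1
    return min(max(k, 0), len(bounds) - 2)


def _transition_at(spec: SemiMarkovSpec, frac: float) -> np.ndarray:
    if spec.phase_transitions is None:
        return spec.transition
    return spec.phase_transitions[_phase_index(spec, frac)]


def simulate_trial(
    spec: SemiMarkovSpec,
    seed: int | np.random.Generator,
    trial_id: str = "sim",
    panel_id: str = "",
    replicate: int = 1,
    duration: float | None = None,
) -> TDSTrial:
    """Draw one trial: duration, optional none lead-in, then alternating
    state and sojourn draws until the stop button; the final sojourn is
    truncated at the stop time. Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if duration is None:
        duration = spec.duration_mean
        if spec.duration_sd > 0:
            for _ in range(100):
                duration = rng.normal(spec.duration_mean, spec.duration_sd)
                if duration >= spec.duration_min:
                    break
            duration = max(duration, spec.duration_min)
    elif duration <= 0:
        raise TDSError("duration must be positive")

    t = 0.0
    if spec.lead_in_mean > 0:
        # cap so the trial always contains at least one selection
        t = min(float(rng.exponential(spec.lead_in_mean)), 0.9 * duration)

    q = spec.lexicon.q
    state = int(rng.choice(q, p=spec.initial))
    events: list[tuple[int, float]] = []
    while t < duration:
        events.append((state + 1, t))
        t += _draw_sojourn(spec, state, rng)
        if t >= duration:
            break
        row = _transition_at(spec, t / duration)[state]
        total = row.sum()
        if total == 0:  # absorbing: hold until stop
            break
        state = int(rng.choice(q, p=row / total))
    return build_trial(
        events,
        start=0.0,
        stop=duration,
        lexicon=spec.lexicon,
        trial_id=trial_id,
        panel_id=panel_id,
        replicate=replicate,
    )


def _panel_letters(i: int) -> str:
    """0 -> A, 25 -> Z, 26 -> AA, ... (spreadsheet-style panel ids)."""
    letters = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        letters = chr(ord("A") + rem) + letters
    return letters


def simulate_panel(
    spec: SemiMarkovSpec, n_panels: int, replicates: int, seed: int
) -> TrialSet:
    """Simulate a panel study: ``n_panels x replicates`` trials.

    Trial ids follow the panel-letter/replicate-digit convention ("A1" is
    panel A's first trial); child seeds are derived deterministically from
    the master seed, so the full TrialSet is reproducible.
    """
    if n_panels < 1 or replicates < 1:
        raise TDSError("n_panels and replicates must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_panels * replicates)
    trials = []
    for p in range(n_panels):
        pid = _panel_letters(p)
        for rep in range(1, replicates + 1):
            rng = np.random.default_rng(children[p * replicates + rep - 1])
            trials.append(
                simulate_trial(
                    spec, rng, trial_id=f"{pid}{rep}", panel_id=pid, replicate=rep
                )
            )
    return TrialSet(spec.lexicon, tuple(trials))


def _attraction_weights(spec: SemiMarkovSpec) -> np.ndarray:
    """Average next-state probability of each attribute across all phases."""
    if spec.phase_transitions is not None:
        mats = spec.phase_transitions
    else:
        mats = spec.transition[None]
    return np.asarray(mats).mean(axis=(0, 1))


def inject_outlier(
    trials: TrialSet,
    archetype: str,
    target_id: str,
    spec: SemiMarkovSpec | None = None,
    seed: int = 0,
    attribute: str | int | None = None,
) -> TrialSet:
    """Replace one trial with an outlier archetype; all other trials are
    returned bit-identical.

    ``single_attribute`` needs ``attribute``; ``rare_attributes`` needs the
    generating ``spec`` (it is re-simulated under an inverted-preference spec
    with the target trial's own duration); ``time_shifted`` deterministically
    reverses the target trial's own selection timeline, so its dominance
    durations are preserved exactly.
    """
    target = trials.get(target_id)

    if archetype == "single_attribute":
        if attribute is None:
            raise TDSError("single_attribute archetype needs `attribute`")
        idx = (
            trials.lexicon.index(attribute)
            if isinstance(attribute, str)
            else int(attribute)
        )
        if not 1 <= idx <= trials.lexicon.q:
            raise TDSError(f"attribute index {idx} outside 1..{trials.lexicon.q}")
        new = TDSTrial(
            trial_id=target.trial_id,
            events=((idx, 0.0),),
            panel_id=target.panel_id,
            replicate=target.replicate,
            duration_seconds=target.duration_seconds,
        )
        return trials.replace(new)

    if archetype == "time_shifted":
        segs = target.segments()
        if segs[0][0] == 0:  # keep the none lead-in at the start
            lead_end, rest = segs[0][2], segs[1:]
        else:
            lead_end, rest = 0.0, segs
        events: list[tuple[int, float]] = []
        t = lead_end
        for attr, s, e in reversed(rest):
            if t < 1.0:
                events.append((attr, t))
            t += e - s
        new = TDSTrial(
            trial_id=target.trial_id,
            events=tuple(events),
            panel_id=target.panel_id,
            replicate=target.replicate,
            duration_seconds=target.duration_seconds,
        )
        return trials.replace(new)

    if archetype == "rare_attributes":
        if spec is None:
            raise TDSError("rare_attributes archetype needs the generating `spec`")
        rare = 1.0 / (_attraction_weights(spec) + 1e-9)
        rare /= rare.sum()
        pert = dc_replace(
            spec,
            initial=rare,
            transition=transition_from_weights(rare),
            phase_transitions=None,
        )
        new = simulate_trial(
            pert,
            seed,
            trial_id=target.trial_id,
            panel_id=target.panel_id,
            replicate=target.replicate,
            duration=target.duration_seconds,
        )
        return trials.replace(new)

    raise TDSError(
        "archetype must be 'single_attribute', 'rare_attributes' or "
        f"'time_shifted', got {archetype!r}"
    )


# phase weight tables for the strawberry-like preset: early phase favors
# sweet/juicy/fruity/watery, middle aromatic/sour, late sour/light
_STRAWBERRY_PHASE_WEIGHTS = np.array(
    [
        # sweet, sour, fruity, green, watery, juicy, aromatic, light
        [0.34, 0.03, 0.16, 0.03, 0.12, 0.26, 0.03, 0.03],  # early
        [0.10, 0.30, 0.06, 0.05, 0.06, 0.08, 0.31, 0.04],  # middle
        [0.04, 0.50, 0.02, 0.06, 0.03, 0.03, 0.12, 0.20],  # late
    ]
)


def strawberry_like_spec() -> SemiMarkovSpec:
    """Preset emulating a strawberry TDS panel.

    Eight attributes; phase-dependent transitions on thirds of the task so
    that sweet/juicy/fruity/watery dominate the early phase, aromatic and
    sour the middle, and sour (with light) the late phase; task duration
    N(30 s, 4 s) truncated at 10 s; gamma sojourns with mean 2.5 s and shape
    2; ~1 s exponential lead-in before the first press.
    """
    init = _STRAWBERRY_PHASE_WEIGHTS[0]
    phase_T = np.stack(
        [transition_from_weights(w) for w in _STRAWBERRY_PHASE_WEIGHTS]
    )
    return SemiMarkovSpec(
        lexicon=STRAWBERRY_ATTRIBUTES,
        initial=init / init.sum(),
        transition=phase_T[1],  # fallback if phases are stripped
        sojourn_mean=np.full(8, 2.5),
        sojourn_shape=np.full(8, 2.0),
        sojourn_family="gamma",
        duration_mean=30.0,
        duration_sd=4.0,
        duration_min=10.0,
        lead_in_mean=1.0,
        phase_transitions=phase_T,
    )


def expected_duration_fractions(spec: SemiMarkovSpec) -> np.ndarray:
    """Long-run expected fraction of time each attribute 1..q is dominant.

    For each phase, the stationary distribution pi of the (embedded)
    transition matrix weighted by sojourn means gives the occupancy; phases
    are averaged by their lengths. Edge effects (lead-in, truncation of the
    final sojourn, phase-boundary mixing) are ignored, so this is the
    long-trial limit, not the exact finite-trial mean.
    """
    if spec.phase_transitions is not None:
        mats = spec.phase_transitions
        lengths = np.diff(np.asarray(spec.phase_boundaries))
    else:
        mats = spec.transition[None]
        lengths = np.array([1.0])
    out = np.zeros(spec.lexicon.q)
    for T, w in zip(mats, lengths):
        vals, vecs = np.linalg.eig(T.T)
        k = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, k])
        pi = np.abs(pi) / np.abs(pi).sum()
        occ = pi * spec.sojourn_mean
        out += w * occ / occ.sum()
    return out / out.sum()
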