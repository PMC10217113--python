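"""Independent oracles used by the tests.

These deliberately avoid the production code paths: discretization is checked
against a midpoint Riemann sum on a fine grid, dominance proportions against
direct pointwise averaging, and Pearson correlation against its textbook
formula.
"""

from __future__ import annotations

import numpy as np


def evaluate_on_grid(trial, n_grid: int) -> np.ndarray:
    """Dominant attribute at the midpoints of n_grid uniform cells."""
    onsets = np.array([o for _, o in trial.events])
    attrs = np.array([0] + [a for a, _ in trial.events])
    t = (np.arange(n_grid) + 0.5) / n_grid
    return attrs[np.searchsorted(onsets, t, side="right")]


def riemann_discretize(trial, R: int, q: int, n_grid: int = 100_000) -> np.ndarray:
    """Quadrature version of the per-interval dominance-duration matrix."""
    vals = evaluate_on_grid(trial, n_grid)
    cell = np.minimum(np.arange(n_grid) * R // n_grid, R - 1)
    counts = np.zeros((q + 1, R))
    np.add.at(counts, (vals, cell), 1.0)
    per_cell = np.bincount(cell, minlength=R).astype(float)
    return counts / per_cell


def pearson_by_hand(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx, dy = x - x.mean(), y - y.mean()
    return float((dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum()))


def random_trial(rng: np.random.Generator, q: int, max_events: int = 10,
                 trial_id: str = "rnd", grid: int = 1000):
    """Random valid trial with onsets on a 1/grid lattice (rational inputs)."""
    from tdsim import TDSTrial

    k = int(rng.integers(0, max_events + 1))
    if q == 1:
        k = min(k, 1)  # with one attribute, consecutive switches are impossible
    if k == 0:
        return TDSTrial(trial_id=trial_id, events=())
    cells = np.sort(rng.choice(grid, size=k, replace=False))
    attrs = []
    prev = 0
    for _ in range(k):
        a = int(rng.integers(1, q + 1))
        while a == prev:
            a = int(rng.integers(1, q + 1))
        attrs.append(a)
        prev = a
    events = tuple((a, c / grid) for a, c in zip(attrs, cells))
    return TDSTrial(trial_id=trial_id, events=events)
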