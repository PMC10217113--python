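"""Core data model: trial construction, evaluation, durations, curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tdsim
from tdsim import (
    AttributeLexicon,
    DominanceCurve,
    LexiconError,
    TDSError,
    TDSTrial,
    TrialSet,
    ValidationError,
    build_trial,
    dominance_durations,
    dominance_proportions,
    smooth_curve,
)

from _oracles import random_trial


@st.composite
def trials_strategy(draw, q=4):
    """Valid trials with onsets on a 1/1000 lattice, no consecutive repeats."""
    k = draw(st.integers(min_value=0, max_value=8))
    cells = sorted(draw(st.sets(st.integers(0, 999), min_size=k, max_size=k)))
    attrs, prev = [], 0
    for _ in cells:
        a = draw(st.integers(1, q).filter(lambda x: x != prev))
        attrs.append(a)
        prev = a
    return TDSTrial(
        trial_id="h", events=tuple((a, c / 1000) for a, c in zip(attrs, cells))
    )


class TestLexicon:
    def test_reserved_and_invalid_labels_rejected(self):
        with pytest.raises(LexiconError):
            AttributeLexicon(("sweet", "none"))
        with pytest.raises(LexiconError):
            AttributeLexicon(("sweet", "sweet"))
        with pytest.raises(LexiconError):
            AttributeLexicon(())

    def test_index_roundtrip(self, lex4):
        assert lex4.q == 4
        assert lex4.index("none") == 0
        assert lex4.index("sour") == 2
        assert lex4.label(2) == "sour"
        with pytest.raises(LexiconError):
            lex4.index("umami")


class TestBuildTrial:
    def test_linear_rescale_of_timestamps(self, lex4):
        t = build_trial(
            [("sweet", 5.0), ("sour", 20.0)], 0.0, 30.0,
            lexicon=lex4, trial_id="t",
        )
        assert t.events == ((1, pytest.approx(1 / 6)), (2, pytest.approx(2 / 3)))
        assert t.duration_seconds == 30.0

    def test_repress_of_same_button_is_a_noop(self, lex4):
        t = build_trial(
            [("sweet", 5.0), ("sweet", 12.0), ("sour", 20.0)], 0.0, 30.0,
            lexicon=lex4, trial_id="t",
        )
        assert len(t.events) == 2
        assert [a for a, _ in t.events] == [1, 2]

    def test_empty_trial_is_valid_with_warning(self, lex4):
        with pytest.warns(UserWarning, match="no attribute"):
            t = build_trial([], 0.0, 30.0, lexicon=lex4, trial_id="t")
        assert t.evaluate(0.5) == 0

    def test_nonmonotone_timestamps_name_the_event(self, lex4):
        with pytest.raises(ValidationError, match="event 1 .*sour.* @ 4"):
            build_trial(
                [("sweet", 5.0), ("sour", 4.0)], 0.0, 30.0,
                lexicon=lex4, trial_id="t",
            )

    def test_out_of_window_and_bad_bounds(self, lex4):
        with pytest.raises(ValidationError, match="outside"):
            build_trial([("sweet", 31.0)], 0.0, 30.0, lexicon=lex4, trial_id="t")
        with pytest.raises(TDSError):
            build_trial([], 30.0, 30.0, lexicon=lex4, trial_id="t")
        with pytest.raises(LexiconError):
            build_trial([("umami", 5.0)], 0.0, 30.0, lexicon=lex4, trial_id="t")


class TestEvaluate:
    @pytest.mark.parametrize(
        "t, expected",
        [(0.1, 0), (0.2, 1), (0.5, 1), (1.0, 1)],
    )
    def test_halfopen_segments_and_closure_at_one(self, t, expected):
        trial = TDSTrial(trial_id="x", events=((1, 0.2),))
        assert trial.evaluate(t) == expected

    def test_outside_unit_interval_rejected(self):
        trial = TDSTrial(trial_id="x", events=((1, 0.2),))
        for bad in (-0.01, 1.01):
            with pytest.raises(TDSError):
                trial.evaluate(bad)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(trials_strategy())
    def test_exactly_one_attribute_dominant(self, trial):
        """At every sampled t exactly one indicator is 1 (unit simplex)."""
        for t in np.linspace(0, 1, 23):
            a = trial.evaluate(float(t))
            x = np.zeros(5)
            x[a] = 1.0
            assert x.sum() == 1.0


class TestDominanceDurations:
    def test_two_segment_split(self):
        trial = TDSTrial(trial_id="x", events=((1, 0.0), (2, 0.5)))
        np.testing.assert_allclose(
            dominance_durations(trial, 4), [0, 0.5, 0.5, 0, 0]
        )

    def test_empty_trial_all_none(self):
        np.testing.assert_allclose(
            dominance_durations(TDSTrial(trial_id="x", events=()), 2), [1, 0, 0]
        )

    def test_matches_fine_grid_riemann_sum(self):
        trial = TDSTrial(trial_id="x", events=((1, 0.0), (2, 0.3)))
        grid = np.linspace(0, 1, 100_001)[:-1] + 0.5e-5
        counts = np.array(
            [np.mean([trial.evaluate(float(t)) == i for t in grid[::100]])
             for i in range(3)]
        )
        np.testing.assert_allclose(
            dominance_durations(trial, 2), counts, atol=1e-3
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(trials_strategy())
    def test_durations_sum_to_one(self, trial):
        assert dominance_durations(trial, 4).sum() == pytest.approx(1.0, abs=1e-12)


class TestDominanceProportions:
    def test_two_opposite_trials_average_to_half(self, lex4):
        ts = TrialSet(
            lex4,
            (
                TDSTrial(trial_id="a", events=((1, 0.0),)),
                TDSTrial(trial_id="b", events=((2, 0.0),)),
            ),
        )
        curve = dominance_proportions(ts)
        for t in (0.0, 0.33, 0.9):
            v = curve.value_at(t)
            assert v[1] == v[2] == 0.5

    def test_single_trial_curve_is_its_indicators(self, lex4):
        trial = TDSTrial(trial_id="a", events=((1, 0.25), (3, 0.75),))
        curve = dominance_proportions(TrialSet(lex4, (trial,)))
        for t in (0.0, 0.3, 0.8, 1.0):
            v = curve.value_at(t)
            assert v[trial.evaluate(t)] == 1.0

    def test_matches_pointwise_average_oracle(self, lex4, rng):
        trials = tuple(
            random_trial(rng, q=4, trial_id=f"r{i}") for i in range(3)
        )
        ts = TrialSet(lex4, trials)
        curve = dominance_proportions(ts)
        for t in rng.uniform(0, 1, size=100):
            expected = np.zeros(5)
            for tr in trials:
                expected[tr.evaluate(float(t))] += 1 / 3
            np.testing.assert_allclose(curve.value_at(float(t)), expected)

    def test_empty_set_rejected(self, lex4):
        with pytest.raises(TDSError):
            dominance_proportions(TrialSet(lex4, ()))

    def test_values_are_multiples_of_one_over_n(self, straw_panel):
        curve = dominance_proportions(straw_panel)
        scaled = curve.values * straw_panel.n
        np.testing.assert_allclose(scaled, np.round(scaled), atol=1e-9)


class TestSmoothCurve:
    def test_window_zero_is_identity(self, lex4):
        curve = dominance_proportions(
            TrialSet(lex4, (TDSTrial(trial_id="a", events=((1, 0.5),)),))
        )
        assert smooth_curve(curve, 0.0) is curve

    def test_constant_curve_unchanged(self):
        curve = DominanceCurve(
            np.array([0.0, 1.0]), np.array([[0.25, 0.25, 0.5]])
        )
        sm = smooth_curve(curve, 0.2)
        np.testing.assert_allclose(sm.values, np.tile([0.25, 0.25, 0.5], (sm.values.shape[0], 1)))

    def test_step_becomes_ramp_matching_convolution(self):
        curve = DominanceCurve(
            np.array([0.0, 0.5, 1.0]), np.array([[1.0, 0.0], [0.0, 1.0]])
        )
        w = 0.1
        sm = smooth_curve(curve, w, grid_size=4001)
        mid = 0.5 * (sm.breakpoints[:-1] + sm.breakpoints[1:])
        # boxcar-convolved step: linear ramp of width w centred on the step;
        # tolerance covers the odd-integer rounding of the window size
        expected = np.clip((mid - 0.5) / w + 0.5, 0.0, 1.0)
        np.testing.assert_allclose(sm.values[:, 1], expected, atol=5e-3)
        np.testing.assert_allclose(sm.values.sum(axis=1), 1.0, atol=1e-12)

    def test_simplex_preserved_on_random_input(self, straw_panel):
        sm = smooth_curve(dominance_proportions(straw_panel), 0.07)
        assert np.all(sm.values >= 0)
        np.testing.assert_allclose(sm.values.sum(axis=1), 1.0, atol=1e-12)

    def test_bad_windows_rejected(self, straw_panel):
        curve = dominance_proportions(straw_panel)
        with pytest.raises(TDSError):
            smooth_curve(curve, -0.1)
        with pytest.raises(TDSError):
            smooth_curve(curve, 1.5)


class TestTrialSetValidation:
    def test_duplicate_ids_rejected(self, lex4):
        t = TDSTrial(trial_id="a", events=((1, 0.0),))
        with pytest.raises(ValidationError, match="duplicate"):
            TrialSet(lex4, (t, t))

    def test_attribute_outside_lexicon_rejected(self):
        small = AttributeLexicon(("sweet",))
        with pytest.raises(LexiconError):
            TrialSet(small, (TDSTrial(trial_id="a", events=((2, 0.0),)),))

    def test_none_cannot_recur_after_selection(self):
        with pytest.raises(ValidationError, match="none"):
            TDSTrial(trial_id="a", events=((1, 0.1), (0, 0.5)))
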