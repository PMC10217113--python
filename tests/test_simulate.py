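"""Semi-Markov generator: determinism, degenerate specs, structure recovery."""

import numpy as np
import pytest

import tdsim
from tdsim import (
    AttributeLexicon,
    SemiMarkovSpec,
    TDSError,
    ValidationError,
    dominance_durations,
    expected_duration_fractions,
    inject_outlier,
    simulate_panel,
    simulate_trial,
    transition_from_weights,
)


def _two_state_spec(**overrides):
    lex = AttributeLexicon(("a", "b"))
    defaults = dict(
        lexicon=lex,
        initial=np.array([1.0, 0.0]),
        transition=np.array([[0.0, 1.0], [1.0, 0.0]]),
        sojourn_mean=np.array([3.0, 3.0]),
        sojourn_shape=np.array([2.0, 2.0]),
        duration_mean=30.0,
    )
    defaults.update(overrides)
    return SemiMarkovSpec(**defaults)


class TestSpecValidation:
    def test_bad_rows_and_parameters_named(self):
        lex = AttributeLexicon(("a", "b"))
        with pytest.raises(ValidationError, match="rows"):
            SemiMarkovSpec(
                lexicon=lex,
                initial=np.array([0.5, 0.5]),
                transition=np.array([[0.0, 0.5], [1.0, 0.0]]),
                sojourn_mean=3.0,
                sojourn_shape=2.0,
            )
        with pytest.raises(ValidationError, match="diagonal"):
            SemiMarkovSpec(
                lexicon=lex,
                initial=np.array([0.5, 0.5]),
                transition=np.array([[0.5, 0.5], [1.0, 0.0]]),
                sojourn_mean=3.0,
                sojourn_shape=2.0,
            )
        with pytest.raises(ValidationError, match="sojourn"):
            _two_state_spec(sojourn_mean=np.array([3.0, -1.0]))

    def test_yaml_dict_roundtrip(self, straw_spec, tmp_path):
        path = tmp_path / "spec.yaml"
        tdsim.save_spec(straw_spec, path)
        back = tdsim.load_spec(path)
        np.testing.assert_allclose(back.initial, straw_spec.initial)
        np.testing.assert_allclose(
            back.phase_transitions, straw_spec.phase_transitions
        )
        assert back.lexicon.names == straw_spec.lexicon.names


class TestSimulateTrial:
    def test_single_absorbing_attribute_covers_whole_trial(self):
        lex = AttributeLexicon(("only",))
        spec = SemiMarkovSpec(
            lexicon=lex,
            initial=np.array([1.0]),
            transition=np.zeros((1, 1)),
            sojourn_mean=5.0,
            sojourn_shape=2.0,
        )
        t = simulate_trial(spec, seed=3)
        np.testing.assert_allclose(dominance_durations(t, 1), [0.0, 1.0])

    def test_deterministic_alternation_switches_at_half(self):
        spec = _two_state_spec(
            sojourn_family="constant", sojourn_mean=np.array([15.0, 15.0])
        )
        t = simulate_trial(spec, seed=0)
        assert t.events == ((1, 0.0), (2, 0.5))

    def test_seed_determinism(self, straw_spec):
        a = simulate_trial(straw_spec, seed=11)
        b = simulate_trial(straw_spec, seed=11)
        c = simulate_trial(straw_spec, seed=12)
        assert a.events == b.events and a.duration_seconds == b.duration_seconds
        assert a.events != c.events

    def test_simulated_trials_pass_core_validation(self, straw_spec):
        # TDSTrial.__post_init__ enforces the one-dominant-attribute model;
        # construction succeeding for many seeds is the property
        for s in range(50):
            t = simulate_trial(straw_spec, seed=s)
            assert dominance_durations(t, 8).sum() == pytest.approx(1.0)

    def test_occupancy_matches_stationary_expectation(self):
        """Homogeneous chain: empirical mean durations approach pi_i*m_i."""
        lex = AttributeLexicon(("a", "b", "c"))
        w = np.array([0.5, 0.3, 0.2])
        spec = SemiMarkovSpec(
            lexicon=lex,
            initial=w,
            transition=transition_from_weights(w),
            sojourn_mean=np.array([2.0, 3.0, 4.0]),
            sojourn_shape=2.0,
            duration_mean=120.0,  # long trials damp start/end truncation
        )
        expected = expected_duration_fractions(spec)
        rng = np.random.default_rng(8)
        occ = np.mean(
            [dominance_durations(simulate_trial(spec, rng), 3)[1:] for _ in range(3000)],
            axis=0,
        )
        np.testing.assert_allclose(occ, expected, atol=0.02)

    def test_sojourn_and_transition_recovery(self):
        """Uncensored sojourns and observed transitions match the spec."""
        lex = AttributeLexicon(("a", "b", "c"))
        T = np.array([[0.0, 0.7, 0.3], [0.4, 0.0, 0.6], [0.5, 0.5, 0.0]])
        spec = SemiMarkovSpec(
            lexicon=lex,
            initial=np.full(3, 1 / 3),
            transition=T,
            sojourn_mean=np.array([2.0, 3.0, 4.0]),
            sojourn_shape=2.0,
            duration_mean=100.0,
        )
        rng = np.random.default_rng(4)
        sojourns = {1: [], 2: [], 3: []}
        trans = np.zeros((3, 3))
        for _ in range(800):
            t = simulate_trial(spec, rng)
            evs = t.events
            for (a1, o1), (a2, o2) in zip(evs, evs[1:]):
                sojourns[a1].append((o2 - o1) * t.duration_seconds)
                trans[a1 - 1, a2 - 1] += 1
        for i, mean in enumerate([2.0, 3.0, 4.0], start=1):
            x = np.array(sojourns[i])
            se = x.std(ddof=1) / np.sqrt(x.size)
            assert abs(x.mean() - mean) < 3 * se + 1e-9
        freq = trans / trans.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(freq, T, atol=0.03)


class TestSimulatePanel:
    def test_17_by_3_gives_51_trials_with_panel_ids(self, straw_panel):
        assert straw_panel.n == 51
        assert straw_panel.trial_ids[:3] == ("A1", "A2", "A3")
        assert straw_panel.trial_ids[-1] == "Q3"

    def test_minimal_panel(self, straw_spec):
        ts = simulate_panel(straw_spec, 1, 1, seed=0)
        assert ts.n == 1 and ts.trial_ids == ("A1",)

    def test_seed_determinism_and_sensitivity(self, straw_spec):
        a = simulate_panel(straw_spec, 3, 2, seed=5)
        b = simulate_panel(straw_spec, 3, 2, seed=5)
        c = simulate_panel(straw_spec, 3, 2, seed=6)
        assert all(x.events == y.events for x, y in zip(a, b))
        assert any(x.events != y.events for x, y in zip(a, c))


class TestInjectOutlier:
    def test_single_attribute_concentrates_duration(self, straw_panel):
        out = inject_outlier(
            straw_panel, "single_attribute", "N1", attribute="sour"
        )
        d = dominance_durations(out.get("N1"), 8)
        assert np.count_nonzero(d[1:]) == 1
        assert d[straw_panel.lexicon.index("sour")] == 1.0

    def test_time_shift_preserves_durations_but_not_timing(self, straw_panel):
        out = inject_outlier(straw_panel, "time_shifted", "C3")
        orig, new = straw_panel.get("C3"), out.get("C3")
        np.testing.assert_allclose(
            dominance_durations(orig, 8), dominance_durations(new, 8),
            atol=1e-9,
        )
        a = tdsim.discretize_trial(orig, 100, 8)
        b = tdsim.discretize_trial(new, 100, 8)
        assert tdsim.similarity(a, b) < 0.7

    def test_other_trials_untouched(self, straw_panel, straw_spec):
        for archetype, kwargs in [
            ("single_attribute", {"attribute": "sour"}),
            ("time_shifted", {}),
            ("rare_attributes", {"spec": straw_spec, "seed": 9}),
        ]:
            out = inject_outlier(straw_panel, archetype, "C3", **kwargs)
            for tid in straw_panel.trial_ids:
                if tid != "C3":
                    assert out.get(tid) is straw_panel.get(tid)

    def test_rare_attributes_prefers_unlikely_states(self, straw_panel, straw_spec):
        out = inject_outlier(
            straw_panel, "rare_attributes", "E1", spec=straw_spec, seed=3
        )
        d = dominance_durations(out.get("E1"), 8)[1:]
        w = tdsim.simulate._attraction_weights(straw_spec)
        rare_mass = d[w < np.median(w)].sum()
        assert rare_mass > 0.5

    def test_unknown_archetype_and_missing_args(self, straw_panel):
        with pytest.raises(TDSError, match="archetype"):
            inject_outlier(straw_panel, "chaotic", "C3")
        with pytest.raises(TDSError, match="attribute"):
            inject_outlier(straw_panel, "single_attribute", "C3")


class TestStrawberryPreset:
    def test_spec_is_valid_and_has_phases(self, straw_spec):
        assert straw_spec.lexicon.q == 8
        assert straw_spec.phase_transitions.shape == (3, 8, 8)
        assert straw_spec.duration_mean == 30.0

    def test_phase_ordering_of_sweet_and_sour(self, straw_spec):
        """Averaged over many trials, sweet dominates early more than late
        and sour dominates late more than early."""
        rng = np.random.default_rng(17)
        early = np.zeros(9)
        late = np.zeros(9)
        n = 1000
        for _ in range(n):
            t = simulate_trial(straw_spec, rng)
            X = tdsim.discretize_trial(t, 3, 8).X
            early += X[:, 0] / n
            late += X[:, 2] / n
        sweet = straw_spec.lexicon.index("sweet")
        sour = straw_spec.lexicon.index("sour")
        assert early[sweet] > late[sweet]
        assert late[sour] > early[sour]
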