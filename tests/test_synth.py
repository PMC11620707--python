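"""Generators: lexicon filtering/matching, trial sequences, pattern
templates, the BOLD forward model and behavioral simulation."""

import collections

import numpy as np
import pandas as pd
import pytest

from semdecode import synth
from semdecode.synth import CONDITIONS, PSEUDOWORD, LexiconError


class TestLexicon:
    def test_default_counts_and_partition(self, lexicon):
        words = lexicon.words
        by_cat = collections.Counter(w.category for w in words)
        assert by_cat == {"tool": 70, "animal": 70}
        assert len(lexicon.lists) == 10
        assert all(len(v) == 14 for v in lexicon.lists.values())
        # lists are disjoint and their union is the word set
        labels = [w.label for v in lexicon.lists.values() for w in v]
        assert len(labels) == len(set(labels)) == 140
        assert set(labels) == {w.label for w in words}
        # each list has one role; each category has 2 target + 3 prime lists
        assert set(lexicon.roles.values()) == {"prime", "target"}
        for cat in ("tool", "animal"):
            roles = [lexicon.roles[lid] for lid, lst in lexicon.lists.items()
                     if lst[0].category == cat]
            assert sorted(roles) == ["prime", "prime", "prime", "target", "target"]

    def test_rating_filter_exhaustive_scan(self):
        lex = synth.generate_lexicon(10, 5.0, seed=5)
        for w in lex.words:
            assert w.imageability >= 5.0
            if w.category == "tool":
                assert w.manipulability >= 5.0

    def test_threshold_is_respected(self):
        lex = synth.generate_lexicon(20, 6.5, seed=2)
        assert all(w.imageability >= 6.5 for w in lex.words)

    @pytest.mark.parametrize("n", [0, -5])
    def test_empty_category_rejected(self, n):
        with pytest.raises(LexiconError, match="empty category"):
            synth.generate_lexicon(n, 5.0, seed=0)

    def test_indivisible_count_rejected(self):
        with pytest.raises(LexiconError, match="divisible"):
            synth.generate_lexicon(12, 5.0, seed=0)

    def test_lists_are_matched(self, lexicon):
        vals = {
            "log_frequency": lambda w: np.log10(w.written_frequency),
            "n_letters": lambda w: w.n_letters,
            "n_syllables": lambda w: w.n_syllables,
            "n_neighbors": lambda w: w.n_neighbors,
        }
        for name, get in vals.items():
            all_vals = np.array([get(w) for w in lexicon.words])
            sd = all_vals.std(ddof=1)
            means = [np.mean([get(w) for w in lst])
                     for lst in lexicon.lists.values()]
            assert (max(means) - min(means)) / sd < 0.25, name

    def test_deterministic(self):
        a = synth.generate_lexicon(20, 5.0, seed=9)
        b = synth.generate_lexicon(20, 5.0, seed=9)
        assert a == b


class TestPrimingDesign:
    def test_default_trial_counts(self, default_trials):
        counts = collections.Counter(t.condition for t in default_trials)
        assert len(default_trials) == 84
        assert counts == {"ToolPrimed": 14, "ToolUnprimed": 14,
                          "AnimalPrimed": 14, "AnimalUnprimed": 14,
                          PSEUDOWORD: 28}

    @pytest.mark.parametrize("seed", range(5))
    def test_counts_exact_for_every_seed(self, lexicon, seed):
        trials = synth.build_priming_design(lexicon, 14, 28, (5, 7), seed=seed)
        counts = collections.Counter(t.condition for t in trials)
        assert all(counts[c] == 14 for c in CONDITIONS)
        assert counts[PSEUDOWORD] == 28

    def test_iti_range_scan(self, default_trials):
        assert all(5.0 <= t.iti <= 7.0 for t in default_trials)

    def test_onsets_strictly_increasing(self, default_trials):
        onsets = [t.prime_onset for t in default_trials]
        assert all(b > a for a, b in zip(onsets, onsets[1:]))

    def test_pair_category_structure(self, default_trials):
        for t in default_trials:
            if t.condition == "ToolPrimed":
                assert t.prime.category == t.target.category == "tool"
                assert t.prime.label != t.target.label
            elif t.condition == "AnimalPrimed":
                assert t.prime.category == t.target.category == "animal"
                assert t.prime.label != t.target.label
            elif t.condition == "ToolUnprimed":
                assert (t.prime.category, t.target.category) == ("animal", "tool")
            elif t.condition == "AnimalUnprimed":
                assert (t.prime.category, t.target.category) == ("tool", "animal")
            else:
                assert t.target.category == "pseudoword"
                assert t.prime.category in ("tool", "animal")

    def test_targets_never_reused(self, default_trials):
        targets = [t.target.label for t in default_trials]
        assert len(targets) == len(set(targets))

    def test_empty_design(self, lexicon):
        assert synth.build_priming_design(lexicon, 0, 0, (5, 7), seed=0) == []

    def test_too_small_lexicon_rejected(self, small_lexicon):
        with pytest.raises(ValueError, match="lexicon too small"):
            synth.build_priming_design(small_lexicon, 14, 28, (5, 7), seed=0)

    def test_events_table(self, default_trials):
        ev = synth.priming_events(default_trials)
        assert set(ev["trial_type"]) == set(CONDITIONS) | {PSEUDOWORD,
                                                           "response_window"}
        word = ev[ev["trial_type"] != "response_window"]
        assert (word["duration"] == 0.8).all()
        resp = ev[ev["trial_type"] == "response_window"]
        assert (resp["duration"] == 1.5).all()


class TestMotorDesign:
    def test_default_repetitions(self):
        events = synth.build_motor_design("tool", 15)
        phases = collections.Counter(e.phase for e in events)
        assert phases == {"planning": 30, "execution": 30, "rest": 15}
        assert all(e.effector == "tool" for e in events)

    def test_single_repetition_duration(self):
        events = synth.build_motor_design("hand", 1)
        assert events[-1].onset + events[-1].duration == 26.0

    def test_onsets_match_cumulative_sum_oracle(self):
        events = synth.build_motor_design("tool", 3)
        durations = [4.0, 4.0, 4.0, 4.0, 10.0] * 3
        expected = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        assert np.allclose([e.onset for e in events], expected)
        assert [e.duration for e in events] == durations

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            synth.build_motor_design("foot", 15)
        with pytest.raises(ValueError):
            synth.build_motor_design("tool", 0)


class TestPatternTemplates:
    @pytest.mark.parametrize("seed", range(20))
    def test_correlation_recovery(self, seed):
        tmpl = synth.make_pattern_templates(1000, 0.6, 0.0, seed=seed)
        m = np.stack([tmpl[c] for c in CONDITIONS])
        corr = np.corrcoef(m)
        assert abs(corr[0, 1] - 0.6) < 0.1
        assert abs(corr[2, 3] - 0.6) < 0.1
        for i, j in [(0, 2), (0, 3), (1, 2), (1, 3)]:
            assert abs(corr[i, j]) < 0.1

    def test_symmetric_null_structure(self):
        tmpl = synth.make_pattern_templates(2000, 0.5, 0.5, seed=1)
        m = np.stack([tmpl[c] for c in CONDITIONS])
        corr = np.corrcoef(m)
        off = corr[np.triu_indices(4, 1)]
        assert np.all(np.abs(off - 0.5) < 0.1)

    def test_templates_are_demeaned(self):
        tmpl = synth.make_pattern_templates(500, 0.6, 0.1, seed=2)
        for v in tmpl.values():
            assert abs(v.mean()) < 1e-12

    def test_infeasible_structure_rejected(self):
        # rho_within 0, rho_across -0.9 has a negative eigenvalue
        with pytest.raises(ValueError, match="infeasible|rho"):
            synth.make_pattern_templates(100, 0.0, -0.9, seed=0)
        with pytest.raises(ValueError):
            synth.make_pattern_templates(1, 0.5, 0.0, seed=0)

    def test_simulate_patterns_shape_and_determinism(self):
        a = synth.simulate_patterns(5, 40, 0.6, 0.0, seed=3)
        b = synth.simulate_patterns(5, 40, 0.6, 0.0, seed=3)
        assert a.shape == (5, 4, 40)
        np.testing.assert_array_equal(a, b)

    def test_simulate_patterns_offsets(self):
        pats = synth.simulate_patterns(200, 50, 0.0, 0.0, noise_sd=0.5,
                                       mean_offsets={"ToolUnprimed": 2.0},
                                       seed=4)
        means = pats.mean(axis=(0, 2))
        assert abs(means[CONDITIONS.index("ToolUnprimed")] - 2.0) < 0.1
        assert np.all(np.abs(np.delete(means, 1)) < 0.1)


def _simple_truth(amplitudes, **kwargs):
    return synth.GroundTruth(
        condition_amplitude_maps={"roi": amplitudes}, **kwargs)


class TestSimulateBold:
    grid = (4, 4, 3)
    layout = {"roi": np.array([[0, 0, 0], [1, 2, 1], [3, 3, 2]])}

    def _events(self):
        return pd.DataFrame({"onset": [4.8], "duration": [0.8],
                             "trial_type": ["ToolPrimed"]})

    def test_null_signal_constant_baseline(self):
        truth = _simple_truth({"ToolPrimed": 0.0}, noise_sd=0.0, baseline=100.0)
        run = synth.simulate_bold(self._events(), truth, self.grid, self.layout,
                                  tr=2.4, seed=0, duration=48.0)
        assert run.data.shape == (4, 4, 3, 20)
        np.testing.assert_allclose(run.data, 100.0)

    def test_single_event_matches_convolution_oracle(self):
        from scipy.stats import gamma

        truth = _simple_truth({"ToolPrimed": np.array([1.0, 2.0, -1.0])},
                              noise_sd=0.0, baseline=0.0)
        run = synth.simulate_bold(self._events(), truth, self.grid, self.layout,
                                  tr=2.4, seed=0, duration=48.0)
        # independent discrete convolution on a 0.1 s grid
        dt = 0.1
        t = np.arange(0, 32, dt)
        hrf = gamma.pdf(t, 6) - gamma.pdf(t, 16) / 6
        hrf = hrf / hrf.max()
        box = np.zeros(480)
        box[48:56] = 1.0
        expected = np.convolve(box, hrf)[:480][::24]
        for amp, (i, j, k) in zip([1.0, 2.0, -1.0], self.layout["roi"]):
            np.testing.assert_allclose(run.data[i, j, k], amp * expected,
                                       atol=1e-10)
        outside = np.ones(self.grid, dtype=bool)
        outside[tuple(self.layout["roi"].T)] = False
        assert np.abs(run.data[outside]).max() == 0.0

    def test_forward_model_linearity(self):
        ev1 = pd.DataFrame({"onset": [2.0], "duration": [0.8],
                            "trial_type": ["ToolPrimed"]})
        ev2 = pd.DataFrame({"onset": [20.0], "duration": [4.0],
                            "trial_type": ["AnimalPrimed"]})
        both = pd.concat([ev1, ev2], ignore_index=True)
        truth = _simple_truth({"ToolPrimed": 1.5, "AnimalPrimed": 0.7},
                              noise_sd=0.0, baseline=0.0)
        kw = dict(grid=self.grid, roi_layout=self.layout, tr=2.4, seed=0,
                  duration=60.0)
        r1 = synth.simulate_bold(ev1, truth, **kw)
        r2 = synth.simulate_bold(ev2, truth, **kw)
        r12 = synth.simulate_bold(both, truth, **kw)
        np.testing.assert_allclose(r12.data, r1.data + r2.data, atol=1e-10)

    def test_bit_identical_reproducibility(self):
        truth = _simple_truth({"ToolPrimed": 1.0}, noise_sd=1.0, ar1=0.3)
        kw = dict(grid=self.grid, roi_layout=self.layout, tr=2.4, seed=42,
                  duration=48.0)
        a = synth.simulate_bold(self._events(), truth, **kw)
        b = synth.simulate_bold(self._events(), truth, **kw)
        np.testing.assert_array_equal(a.data, b.data)

    def test_event_beyond_run_end_rejected(self):
        truth = _simple_truth({"ToolPrimed": 1.0})
        with pytest.raises(ValueError, match="beyond run end"):
            synth.simulate_bold(self._events(), truth, self.grid, self.layout,
                                tr=2.4, seed=0, duration=3.0)

    def test_noise_marginal_sd(self):
        truth = _simple_truth({"ToolPrimed": 0.0}, noise_sd=2.0, ar1=0.4,
                              baseline=0.0)
        run = synth.simulate_bold(self._events(), truth, (10, 10, 5),
                                  {"roi": np.array([[0, 0, 0]])},
                                  tr=2.4, seed=1, duration=480.0)
        assert abs(run.data.std() - 2.0) < 0.05


class TestBehavior:
    def test_determinism(self, default_trials):
        truth = synth.GroundTruth()
        a = synth.simulate_behavior(default_trials, truth, 5, seed=1)
        b = synth.simulate_behavior(default_trials, truth, 5, seed=1)
        pd.testing.assert_frame_equal(a, b)

    def test_null_effects_equal_means(self, default_trials):
        bp = synth.BehaviorParams(rt_mean_ms={c: 950.0 for c in
                                              list(CONDITIONS) + [PSEUDOWORD]})
        truth = synth.GroundTruth(behavior=bp)
        rec = synth.simulate_behavior(default_trials, truth, 400, seed=2)
        means = rec.groupby("condition")["rt_ms"].mean()
        assert means.max() - means.min() < 15.0

    def test_omissions_beyond_deadline(self, default_trials):
        bp = synth.BehaviorParams(sigma_trial=0.6)  # fat trial noise
        truth = synth.GroundTruth(behavior=bp)
        rec = synth.simulate_behavior(default_trials, truth, 50, seed=3)
        assert rec["rt_ms"].isna().any()
        assert (rec.loc[rec["rt_ms"].isna(), "accuracy"] == 0).all()
        assert rec["rt_ms"].max() <= 2000.0

    def test_condition_means_match_targets(self, default_trials):
        # the generator is mean-parameterized: condition means reproduce the
        # configured targets in expectation
        truth = synth.GroundTruth()
        rec = synth.simulate_behavior(default_trials, truth, 2000, seed=4)
        correct = rec[(rec["accuracy"] == 1) & rec["rt_ms"].notna()]
        grand = (correct.groupby(["subject", "condition"])["rt_ms"].mean()
                 .groupby("condition").mean())
        targets = {"ToolPrimed": 945, "ToolUnprimed": 1017,
                   "AnimalPrimed": 901, "AnimalUnprimed": 962}
        for cond, target in targets.items():
            assert abs(grand[cond] - target) < 10.0, cond


def test_truth_json_roundtrip():
    truth = synth.GroundTruth(
        condition_amplitude_maps={"roi": {"ToolPrimed": np.array([1.0, -0.5])}},
        mean_offsets={"ToolUnprimed": 0.5}, noise_sd=1.2, ar1=0.25,
        background_amplitude_maps={"planning_tool": np.zeros((2, 2, 2))})
    back = synth.truth_from_json(synth.truth_to_json(truth))
    np.testing.assert_allclose(
        back.condition_amplitude_maps["roi"]["ToolPrimed"], [1.0, -0.5])
    assert back.noise_sd == 1.2 and back.ar1 == 0.25
    assert back.background_amplitude_maps["planning_tool"].shape == (2, 2, 2)


def test_events_tsv_roundtrip(tmp_path, default_trials):
    ev = synth.priming_events(default_trials)
    path = tmp_path / "events.tsv"
    synth.write_events_tsv(path, ev)
    back = synth.read_events_tsv(path)
    pd.testing.assert_frame_equal(ev, back)
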