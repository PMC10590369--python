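"""Theme aggregation, weekly processes and their averages."""

import numpy as np
import pandas as pd
import pytest

import traceclust as tc
from traceclust.errors import ConfigurationError
from traceclust.themes import (
    OTHERS,
    frame_to_processes,
    identity_theme_map,
    processes_to_frame,
)

from conftest import make_process


class TestThemeMap:
    def test_others_always_present(self):
        tm = tc.ThemeMap(theme_names=("A", "B"), assignment={0: "A"})
        assert tm.theme_names[-1] == OTHERS

    def test_unassigned_topics_go_to_others(self):
        tm = tc.ThemeMap(theme_names=("A", OTHERS), assignment={0: "A"})
        assert tm.theme_of(5) == OTHERS

    def test_out_of_range_topic_rejected(self):
        tm = tc.ThemeMap(theme_names=("A", OTHERS), assignment={7: "A"})
        with pytest.raises(ConfigurationError, match="outside"):
            tm.validate_for(3)

    def test_yaml_round_trip(self, tmp_path):
        tm = tc.ThemeMap(
            theme_names=("Evaluation", "Courses", OTHERS),
            assignment={8: "Evaluation", 10: "Evaluation", 1: "Courses"},
        )
        tm.to_yaml(tmp_path / "themes.yaml")
        back = tc.ThemeMap.from_yaml(tmp_path / "themes.yaml")
        assert back.assignment == tm.assignment
        assert set(back.theme_names) == set(tm.theme_names)

    def test_duplicate_assignment_rejected(self, tmp_path):
        (tmp_path / "bad.yaml").write_text("themes:\n  A: [0]\n  B: [0]\n")
        with pytest.raises(ConfigurationError, match="both"):
            tc.ThemeMap.from_yaml(tmp_path / "bad.yaml")


class TestTopicsToThemes:
    def test_forced_summation(self):
        tm = tc.ThemeMap(theme_names=("A", "B", OTHERS), assignment={0: "A", 1: "A", 2: "B"})
        out = tc.topics_to_themes(np.array([0.3, 0.2, 0.5]), tm)
        np.testing.assert_allclose(out, [0.5, 0.5, 0.0])

    def test_empty_assignment_all_to_others(self):
        tm = tc.ThemeMap(theme_names=(OTHERS,), assignment={})
        out = tc.topics_to_themes(np.array([0.4, 0.6]), tm)
        np.testing.assert_allclose(out, [1.0])

    def test_uniform_symmetry(self):
        names = tuple(f"T{i}" for i in range(6))
        tm = tc.ThemeMap(theme_names=names, assignment={i: names[i] for i in range(6)})
        out = tc.topics_to_themes(np.full(6, 1 / 6), tm)
        np.testing.assert_allclose(out[:6], 1 / 6)

    def test_mass_conserved_exactly(self):
        rng = np.random.default_rng(0)
        vec = rng.dirichlet(np.ones(9))
        tm = tc.ThemeMap(
            theme_names=("A", "B", OTHERS),
            assignment={0: "A", 3: "A", 5: "B"},
        )
        out = tc.topics_to_themes(vec, tm)
        assert out.sum() == pytest.approx(vec.sum(), abs=0)

    def test_aggregation_commutes_with_averaging(self):
        rng = np.random.default_rng(1)
        mat = rng.dirichlet(np.ones(5), size=20)
        tm = tc.ThemeMap(theme_names=("A", "B", OTHERS), assignment={0: "A", 1: "B", 2: "B"})
        via_mean = tc.topics_to_themes(mat.mean(axis=0), tm)
        via_each = tc.topics_to_themes(mat, tm).mean(axis=0)
        np.testing.assert_allclose(via_mean, via_each, atol=1e-12)


class TestBuildProcesses:
    def _meta_and_doc_topic(self):
        meta = pd.DataFrame(
            {
                "actor_id": ["a", "a", "b", "a"],
                "year": [2019, 2019, 2019, 2019],
                "week": [3, 5, 1, 30],
                "total": [40, 50, 30, 60],
            }
        )
        doc_topic = np.array(
            [[0.9, 0.1], [0.2, 0.8], [0.5, 0.5], [1.0, 0.0]]
        )
        return meta, doc_topic

    def test_active_weeks_and_counts(self):
        meta, dt = self._meta_and_doc_topic()
        window = tc.spring_window(2019, last_week=22)
        procs = tc.build_processes(meta, dt, identity_theme_map(2), window)
        proc_a = next(p for p in procs if p.actor_id == "a")
        assert list(np.nonzero(proc_a.C)[0]) == [2, 4]  # weeks 3 and 5
        assert proc_a.C[2] == 40 and proc_a.C[4] == 50
        assert np.all(np.isnan(proc_a.P[0]))

    def test_window_excludes_out_of_range_documents(self):
        meta, dt = self._meta_and_doc_topic()
        window = tc.spring_window(2019, last_week=22)
        procs = tc.build_processes(meta, dt, identity_theme_map(2), window)
        proc_a = next(p for p in procs if p.actor_id == "a")
        assert proc_a.C.sum() == 90  # the week-30 document is excluded

    def test_empty_window_rejected(self):
        meta, dt = self._meta_and_doc_topic()
        with pytest.raises(ConfigurationError):
            tc.build_processes(meta, dt, identity_theme_map(2), [])

    def test_cluster_mean_tracks_planted_trajectory(self, small_config, small_log):
        # on well-separated generator output with the true theme map, the
        # per-cluster mean theme share should track the planted trajectory
        events, truth = small_log
        weeked = tc.assign_weeks(events)
        weeked, _ = tc.remove_general_use(weeked)
        weeked, _ = tc.filter_low_activity_weeks(weeked)
        corpus = tc.build_corpus(weeked, tc.build_vocabulary(weeked))
        fit = tc.fit_lda(corpus, small_config.n_topics_true, seed=1)
        dt = tc.assign_topic_distributions(fit, corpus)
        tm = identity_theme_map(fit.n_topics)
        window = [
            (y, w)
            for (y, w) in truth.week_calendar
        ]
        procs = tc.build_processes(corpus.meta, dt, tm, window)
        # learned topics are a permutation of planted themes; check that each
        # cluster's actors are more similar within than across clusters
        by_cluster = {}
        for p in procs:
            by_cluster.setdefault(truth.cluster_of_actor[p.actor_id], []).append(p)
        for c, members in by_cluster.items():
            stack = np.stack([np.nan_to_num(p.P) for p in members])
            within = np.abs(stack - stack.mean(axis=0)).mean()
            assert within < 0.35


class TestMeanWeeklyThemeDistribution:
    def test_mean_of_one_is_itself(self, toy_window):
        P = [[0.6, 0.4]] * 4
        proc = make_process("a", toy_window, P, [10, 10, 0, 10])
        df = tc.mean_weekly_theme_distribution([proc], ["A", "B"])
        active = df[(df["week"] == 1) & (df["theme"] == "A")]
        assert active["mean_probability"].iloc[0] == pytest.approx(0.6)
        gap = df[(df["week"] == 3) & (df["theme"] == "A")]
        assert np.isnan(gap["mean_probability"].iloc[0])
        assert gap["n_active"].iloc[0] == 0

    def test_two_identical_actors(self, toy_window):
        P = [[0.3, 0.7]] * 4
        procs = [
            make_process("a", toy_window, P, [5, 5, 5, 5]),
            make_process("b", toy_window, P, [9, 9, 9, 9]),
        ]
        df = tc.mean_weekly_theme_distribution(procs, ["A", "B"])
        np.testing.assert_allclose(
            df[df["theme"] == "A"]["mean_probability"], 0.3
        )

    def test_hand_built_two_actor_means(self, toy_window):
        pa = make_process("a", toy_window, [[1.0, 0.0]] * 4, [10, 10, 10, 10])
        pb = make_process("b", toy_window, [[0.0, 1.0]] * 4, [10, 0, 10, 10])
        df = tc.mean_weekly_theme_distribution([pa, pb], ["A", "B"])
        a_means = df[df["theme"] == "A"].sort_values("week")["mean_probability"]
        np.testing.assert_allclose(a_means, [0.5, 1.0, 0.5, 0.5])

    def test_weighted_mean_uses_counts(self, toy_window):
        pa = make_process("a", toy_window, [[1.0, 0.0]] * 4, [30, 1, 1, 1])
        pb = make_process("b", toy_window, [[0.0, 1.0]] * 4, [10, 1, 1, 1])
        df = tc.mean_weekly_theme_distribution([pa, pb], ["A", "B"], weighted=True)
        w1_a = df[(df["week"] == 1) & (df["theme"] == "A")]["mean_probability"].iloc[0]
        assert w1_a == pytest.approx(0.75)


def test_process_frame_round_trip(toy_window):
    pa = make_process("a", toy_window, [[0.2, 0.8]] * 4, [10, 0, 5, 25])
    pb = make_process("b", toy_window, [[0.7, 0.3]] * 4, [0, 3, 0, 8])
    frame = processes_to_frame([pa, pb], ["A", "B"])
    back, names = frame_to_processes(frame, toy_window)
    assert names == ["A", "B"]
    for orig, rec in zip([pa, pb], back):
        assert orig.actor_id == rec.actor_id
        np.testing.assert_array_equal(orig.C, rec.C)
        act = orig.C > 0
        np.testing.assert_allclose(orig.P[act], rec.P[act])
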