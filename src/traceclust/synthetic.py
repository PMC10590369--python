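"""Seeded synthetic event-log generator with planted cluster structure.

Real platform logs of this kind are typically confidential, so the package
ships a generator that emulates the statistical structure the analysis
assumes: several latent actor clusters, each following its own weekly
trajectory of *theme* mixture weights; themes composed of *topics*, each a
probability distribution over target-action tokens; overdispersed weekly
event counts; a configurable fraction of injected general-use events (the
tokens the preprocessing removes); and occasional low-activity weeks that
exercise the weekly event-count filter.

The generative model for one actor-week is::

    n_task  ~ NegativeBinomial(mean, dispersion)      # task events
    theme_e ~ Categorical(trajectory[cluster, week])   # per event
    topic_e ~ Uniform(topics in theme_e)
    token_e ~ topic_word[topic_e]
    n_gen   ~ Poisson(n_task * r / (1 - r))            # general-use events

so that the expected fraction of general-use events is ``r``.  With
probability ``low_activity_week_prob`` the task count is resampled uniformly
below the filtering threshold, planting weeks the preprocessing must drop.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from traceclust.errors import ConfigurationError
from traceclust.ingest import (
    DEFAULT_MIN_WEEKLY_EVENTS,
    DEFAULT_REMOVAL_LIST,
    TraceEvent,
)

#: breakpoints of a piecewise-linear weekly weight curve: [(week, weight), ...]
TrajectoryCurve = list[tuple[float, float]]


@dataclass
class SyntheticConfig:
    """Full description of a synthetic log: actors, clusters, topics, rates.

    ``trajectory_spec`` maps cluster index -> theme name -> piecewise-linear
    weight curve over weeks; each week's theme weights are normalized to sum
    to one.  ``theme_map_true`` maps topic index -> theme name.  If
    ``topic_word`` is None, the non-general vocabulary is partitioned into
    disjoint equal blocks, one per topic, uniform within the block.
    """

    n_actors: int
    n_weeks: int
    n_clusters: int
    vocabulary: list[str]
    n_topics_true: int
    theme_map_true: dict[int, str]
    trajectory_spec: dict[int, dict[str, TrajectoryCurve]]
    events_per_week_mean: float = 120.0
    events_per_week_dispersion: float = 2.0
    general_use_rate: float = 0.25
    low_activity_week_prob: float = 0.05
    seed: int = 0
    start_year: int = 2019
    topic_word: np.ndarray | None = None
    general_tokens: frozenset[str] = field(
        default_factory=lambda: frozenset(DEFAULT_REMOVAL_LIST)
    )

    @property
    def theme_names(self) -> list[str]:
        """Theme labels in first-appearance order of the topic map."""
        seen: list[str] = []
        for t in sorted(self.theme_map_true):
            name = self.theme_map_true[t]
            if name not in seen:
                seen.append(name)
        return seen

    @property
    def task_tokens(self) -> list[str]:
        """Vocabulary tokens that are not general-use (order preserved)."""
        return [t for t in self.vocabulary if t not in self.general_tokens]

    def validate(self) -> None:
        if self.n_actors < 0:
            raise ConfigurationError("n_actors must be >= 0")
        if self.n_weeks < 1:
            raise ConfigurationError("n_weeks must be >= 1")
        if self.n_clusters < 1:
            raise ConfigurationError("n_clusters must be >= 1")
        if self.n_actors and self.n_clusters > self.n_actors:
            raise ConfigurationError("n_clusters must not exceed n_actors")
        missing = sorted(set(self.general_tokens) - set(self.vocabulary))
        if missing:
            raise ConfigurationError(
                f"vocabulary must include the general-use tokens; missing {missing}"
            )
        if not self.task_tokens:
            raise ConfigurationError("vocabulary has no non-general task tokens")
        if self.n_topics_true < 1:
            raise ConfigurationError("n_topics_true must be >= 1")
        if sorted(self.theme_map_true) != list(range(self.n_topics_true)):
            raise ConfigurationError(
                "theme_map_true must assign every topic index 0..n_topics_true-1"
            )
        if self.events_per_week_mean <= 0:
            raise ConfigurationError("events_per_week_mean must be > 0")
        if self.events_per_week_dispersion <= 0:
            raise ConfigurationError("events_per_week_dispersion must be > 0")
        if not 0.0 <= self.general_use_rate < 1.0:
            raise ConfigurationError("general_use_rate must be in [0, 1)")
        if not 0.0 <= self.low_activity_week_prob <= 1.0:
            raise ConfigurationError("low_activity_week_prob must be in [0, 1]")
        themes = set(self.theme_names)
        if sorted(self.trajectory_spec) != list(range(self.n_clusters)):
            raise ConfigurationError(
                "trajectory_spec must cover cluster indices 0..n_clusters-1"
            )
        for c, curves in self.trajectory_spec.items():
            if set(curves) != themes:
                raise ConfigurationError(
                    f"trajectory_spec cluster {c} must define a curve for every "
                    f"theme in {sorted(themes)}"
                )
        traj = self.trajectories()
        if np.any(traj < 0):
            raise ConfigurationError("trajectory_spec weights must be non-negative")
        if not np.allclose(traj.sum(axis=2), 1.0, atol=1e-9):
            raise ConfigurationError(
                "trajectory_spec weekly weights must normalize to 1"
            )
        tw = self.topic_word_matrix()
        if tw.shape != (self.n_topics_true, len(self.task_tokens)):
            raise ConfigurationError(
                "topic_word must have shape (n_topics_true, n_task_tokens)"
            )
        if np.any(tw < 0) or not np.allclose(tw.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("topic_word rows must be distributions")

    def trajectories(self) -> np.ndarray:
        """Evaluate the piecewise-linear curves: (n_clusters, n_weeks, n_themes).

        Each week's theme weights are renormalized to sum to one.
        """
        weeks = np.arange(1, self.n_weeks + 1, dtype=float)
        themes = self.theme_names
        out = np.zeros((self.n_clusters, self.n_weeks, len(themes)))
        for c in range(self.n_clusters):
            for m, theme in enumerate(themes):
                pts = sorted(self.trajectory_spec[c][theme])
                xs = [p[0] for p in pts]
                ys = [p[1] for p in pts]
                out[c, :, m] = np.interp(weeks, xs, ys)
        totals = out.sum(axis=2, keepdims=True)
        if np.any(totals <= 0):
            raise ConfigurationError(
                "trajectory_spec weights sum to zero on some week"
            )
        return out / totals

    def topic_word_matrix(self) -> np.ndarray:
        """Topic-word distributions over the task vocabulary (K x V_task)."""
        if self.topic_word is not None:
            return np.asarray(self.topic_word, dtype=float)
        v = len(self.task_tokens)
        k = self.n_topics_true
        # disjoint equal blocks, uniform within each block
        tw = np.zeros((k, v))
        bounds = np.linspace(0, v, k + 1).astype(int)
        for t in range(k):
            lo, hi = bounds[t], bounds[t + 1]
            if hi <= lo:
                raise ConfigurationError(
                    "n_topics_true exceeds the number of task tokens"
                )
            tw[t, lo:hi] = 1.0 / (hi - lo)
        return tw

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "n_actors": self.n_actors,
            "n_weeks": self.n_weeks,
            "n_clusters": self.n_clusters,
            "vocabulary": list(self.vocabulary),
            "n_topics_true": self.n_topics_true,
            "theme_map_true": {int(k): v for k, v in self.theme_map_true.items()},
            "trajectory_spec": {
                int(c): {
                    th: [[float(w), float(y)] for w, y in curve]
                    for th, curve in curves.items()
                }
                for c, curves in self.trajectory_spec.items()
            },
            "events_per_week_mean": self.events_per_week_mean,
            "events_per_week_dispersion": self.events_per_week_dispersion,
            "general_use_rate": self.general_use_rate,
            "low_activity_week_prob": self.low_activity_week_prob,
            "seed": self.seed,
            "start_year": self.start_year,
            "topic_word": None
            if self.topic_word is None
            else np.asarray(self.topic_word).tolist(),
            "general_tokens": sorted(self.general_tokens),
        }
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        data = yaml.safe_load(Path(path).read_text())
        tw = data.get("topic_word")
        return cls(
            n_actors=data["n_actors"],
            n_weeks=data["n_weeks"],
            n_clusters=data["n_clusters"],
            vocabulary=list(data["vocabulary"]),
            n_topics_true=data["n_topics_true"],
            theme_map_true={int(k): v for k, v in data["theme_map_true"].items()},
            trajectory_spec={
                int(c): {
                    th: [tuple(p) for p in curve] for th, curve in curves.items()
                }
                for c, curves in data["trajectory_spec"].items()
            },
            events_per_week_mean=data.get("events_per_week_mean", 120.0),
            events_per_week_dispersion=data.get("events_per_week_dispersion", 2.0),
            general_use_rate=data.get("general_use_rate", 0.25),
            low_activity_week_prob=data.get("low_activity_week_prob", 0.05),
            seed=data.get("seed", 0),
            start_year=data.get("start_year", 2019),
            topic_word=None if tw is None else np.asarray(tw, dtype=float),
            general_tokens=frozenset(
                data.get("general_tokens", DEFAULT_REMOVAL_LIST)
            ),
        )


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover.

    ``task_counts`` / ``general_counts`` map (actor_id, week_index) to the
    number of task / injected general-use events in that actor-week;
    ``week_calendar[w-1]`` gives the ISO (year, week) pair of generator week
    ``w`` so that date-based week assignment round-trips exactly.
    """

    cluster_of_actor: dict[str, int]
    topic_word_true: np.ndarray
    task_tokens: list[str]
    theme_trajectory_true: dict[int, np.ndarray]
    theme_names: list[str]
    week_calendar: list[tuple[int, int]]
    task_counts: dict[tuple[str, int], int]
    general_counts: dict[tuple[str, int], int]

    @property
    def n_general_injected(self) -> int:
        return sum(self.general_counts.values())

    def to_json(self, path: str | Path) -> None:
        data = {
            "cluster_of_actor": self.cluster_of_actor,
            "topic_word_true": self.topic_word_true.tolist(),
            "task_tokens": self.task_tokens,
            "theme_trajectory_true": {
                int(c): t.tolist() for c, t in self.theme_trajectory_true.items()
            },
            "theme_names": self.theme_names,
            "week_calendar": [list(w) for w in self.week_calendar],
            "task_counts": [
                [a, w, c] for (a, w), c in sorted(self.task_counts.items())
            ],
            "general_counts": [
                [a, w, c] for (a, w), c in sorted(self.general_counts.items())
            ],
        }
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(data))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        return cls(
            cluster_of_actor=data["cluster_of_actor"],
            topic_word_true=np.asarray(data["topic_word_true"], dtype=float),
            task_tokens=data["task_tokens"],
            theme_trajectory_true={
                int(c): np.asarray(t, dtype=float)
                for c, t in data["theme_trajectory_true"].items()
            },
            theme_names=data["theme_names"],
            week_calendar=[tuple(w) for w in data["week_calendar"]],
            task_counts={(a, w): c for a, w, c in data["task_counts"]},
            general_counts={(a, w): c for a, w, c in data["general_counts"]},
        )


def _week_monday(start_year: int, week: int) -> _dt.date:
    """Monday of generator week ``week`` (1-based), weeks running
    consecutively from ISO week 1 of ``start_year``."""
    base = _dt.date.fromisocalendar(start_year, 1, 1)
    return base + _dt.timedelta(days=7 * (week - 1))


def generate_log(config: SyntheticConfig) -> tuple[list[TraceEvent], GroundTruth]:
    """Generate a synthetic trace log and its ground truth.

    Deterministic given ``config.seed``.  Events are emitted grouped by
    actor and week, with day-resolved dates consistent with each event's
    week.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    if config.n_actors == 0:
        return [], GroundTruth(
            cluster_of_actor={},
            topic_word_true=config.topic_word_matrix(),
            task_tokens=config.task_tokens,
            theme_trajectory_true={},
            theme_names=config.theme_names,
            week_calendar=[],
            task_counts={},
            general_counts={},
        )

    width = max(3, len(str(config.n_actors - 1)))
    actor_ids = [f"actor_{i:0{width}d}" for i in range(config.n_actors)]
    cluster_of_actor = {a: i % config.n_clusters for i, a in enumerate(actor_ids)}

    traj = config.trajectories()  # (C, W, M)
    tw = config.topic_word_matrix()  # (K, V_task)
    task_tokens = np.asarray(config.task_tokens, dtype=object)
    general_tokens = np.asarray(
        sorted(config.general_tokens & set(config.vocabulary)), dtype=object
    )
    themes = config.theme_names
    topics_in_theme = {
        m: [t for t, th in config.theme_map_true.items() if th == name]
        for m, name in enumerate(themes)
    }

    r = config.events_per_week_dispersion
    mean = config.events_per_week_mean
    p_nb = r / (r + mean)
    gen_rate = config.general_use_rate

    week_calendar = []
    for w in range(1, config.n_weeks + 1):
        iso = _week_monday(config.start_year, w).isocalendar()
        week_calendar.append((iso.year, iso.week))

    events: list[TraceEvent] = []
    task_counts: dict[tuple[str, int], int] = {}
    general_counts: dict[tuple[str, int], int] = {}

    for actor in actor_ids:
        cluster = cluster_of_actor[actor]
        for w in range(1, config.n_weeks + 1):
            n_task = int(rng.negative_binomial(r, p_nb))
            if rng.random() < config.low_activity_week_prob:
                n_task = int(rng.integers(0, DEFAULT_MIN_WEEKLY_EVENTS))
            n_gen = 0
            if gen_rate > 0 and n_task > 0:
                n_gen = int(rng.poisson(n_task * gen_rate / (1.0 - gen_rate)))
            task_counts[(actor, w)] = n_task
            general_counts[(actor, w)] = n_gen

            monday = _week_monday(config.start_year, w)
            n_total = n_task + n_gen
            if n_total == 0:
                continue
            theme_idx = rng.choice(len(themes), size=n_task, p=traj[cluster, w - 1])
            offsets = rng.integers(0, 7, size=n_total)
            tokens: list[str] = []
            for m in theme_idx:
                cand = topics_in_theme[int(m)]
                topic = cand[int(rng.integers(len(cand)))] if len(cand) > 1 else cand[0]
                tokens.append(str(rng.choice(task_tokens, p=tw[topic])))
            if n_gen:
                tokens.extend(
                    str(t) for t in rng.choice(general_tokens, size=n_gen)
                )
            for tok, off in zip(tokens, offsets):
                events.append(
                    TraceEvent(
                        actor_id=actor,
                        date=monday + _dt.timedelta(days=int(off)),
                        target_action=tok,
                    )
                )

    truth = GroundTruth(
        cluster_of_actor=cluster_of_actor,
        topic_word_true=tw,
        task_tokens=list(config.task_tokens),
        theme_trajectory_true={
            c: traj[c].copy() for c in range(config.n_clusters)
        },
        theme_names=list(themes),
        week_calendar=week_calendar,
        task_counts=task_counts,
        general_counts=general_counts,
    )
    return events, truth


def generate_lda_corpus(
    n_topics: int = 4,
    vocab_size: int = 40,
    n_docs: int = 200,
    tokens_per_doc: int = 200,
    doc_topic_alpha: float = 0.3,
    seed: int = 0,
):
    """Sample a corpus directly from the LDA generative model.

    Topic-word distributions have disjoint support (equal vocabulary
    blocks, uniform within each); per-document topic mixtures are
    Dirichlet(alpha) draws.  Returns (corpus, topic_word_true,
    doc_topic_true).  Used to benchmark topic recovery and model selection
    without the full event-log machinery.
    """
    from traceclust.documents import DocumentCorpus, Vocabulary
    import pandas as pd
    import scipy.sparse as sp

    rng = np.random.default_rng(seed)
    tokens = [f"object_{i:03d}>acted" for i in range(vocab_size)]
    vocab = Vocabulary.from_tokens(tokens)
    tw = np.zeros((n_topics, vocab_size))
    bounds = np.linspace(0, vocab_size, n_topics + 1).astype(int)
    for t in range(n_topics):
        tw[t, bounds[t] : bounds[t + 1]] = 1.0 / (bounds[t + 1] - bounds[t])
    # map block columns onto the sorted vocabulary order
    order = np.array([vocab.index[t] for t in tokens])
    tw_sorted = np.zeros_like(tw)
    tw_sorted[:, order] = tw
    doc_topic = rng.dirichlet([doc_topic_alpha] * n_topics, size=n_docs)
    rows = np.zeros((n_docs, vocab_size), dtype=np.int64)
    for d in range(n_docs):
        mix = doc_topic[d] @ tw_sorted
        rows[d] = rng.multinomial(tokens_per_doc, mix)
    matrix = sp.csr_matrix(rows)
    meta = pd.DataFrame(
        {
            "actor_id": [f"doc_{d:04d}" for d in range(n_docs)],
            "year": 2019,
            "week": [(d % 50) + 1 for d in range(n_docs)],
            "total": rows.sum(axis=1),
        }
    )
    return DocumentCorpus(vocab, matrix, meta), tw_sorted, doc_topic


def example_config(
    n_actors: int = 30,
    n_weeks: int = 22,
    n_clusters: int = 3,
    n_topics_true: int = 6,
    n_task_tokens: int = 36,
    events_per_week_mean: float = 120.0,
    events_per_week_dispersion: float = 2.0,
    general_use_rate: float = 0.25,
    low_activity_week_prob: float = 0.05,
    separation: float = 0.85,
    seed: int = 0,
) -> SyntheticConfig:
    """A ready-made well-separated configuration with planted clusters.

    Each cluster concentrates ``separation`` of its weekly theme mass on its
    own theme, drifting slightly over the weeks (so trajectories are genuine
    time courses, not constants); the remaining mass is split evenly over
    the other themes.  Themes own two consecutive topics each by default.
    """
    n_themes = n_clusters
    theme_names = [f"theme_{m + 1}" for m in range(n_themes)]
    topics_per_theme = max(1, n_topics_true // n_themes)
    theme_map = {
        t: theme_names[min(t // topics_per_theme, n_themes - 1)]
        for t in range(n_topics_true)
    }
    lo = (1.0 - separation) / max(1, n_themes - 1)
    drift = min(0.025, 0.5 * lo)
    spec: dict[int, dict[str, TrajectoryCurve]] = {}
    for c in range(n_clusters):
        curves: dict[str, TrajectoryCurve] = {}
        for m, name in enumerate(theme_names):
            if m == c:
                curves[name] = [
                    (1.0, separation - 2 * drift),
                    (float(n_weeks), separation + 2 * drift),
                ]
            else:
                curves[name] = [(1.0, lo + drift), (float(n_weeks), lo - drift)]
        spec[c] = curves
    task_vocab = [
        f"object_{i:02d}>{act}"
        for i, act in enumerate(
            ["updated", "created", "deleted", "graded", "viewed", "submitted"]
            * (n_task_tokens // 6 + 1)
        )
    ][:n_task_tokens]
    vocabulary = task_vocab + sorted(DEFAULT_REMOVAL_LIST)
    return SyntheticConfig(
        n_actors=n_actors,
        n_weeks=n_weeks,
        n_clusters=n_clusters,
        vocabulary=vocabulary,
        n_topics_true=n_topics_true,
        theme_map_true=theme_map,
        trajectory_spec=spec,
        events_per_week_mean=events_per_week_mean,
        events_per_week_dispersion=events_per_week_dispersion,
        general_use_rate=general_use_rate,
        low_activity_week_prob=low_activity_week_prob,
        seed=seed,
    )
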