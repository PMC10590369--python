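"""Topic-to-theme aggregation and actor-week theme processes.

Topics are grouped manually into a handful of named *themes* (e.g.
Evaluation, Courses, Progress tracking, Situation tracking, Final grading);
a document's theme distribution is obtained simply by summing the topic
probabilities of the topics in each theme.  Topics not assigned to any
named theme fall into the catch-all theme "Others".

An actor's *process* over a week window is the pair (P, C): for each week
t, the theme probability vector P(t) (defined exactly on weeks where the
actor has a surviving document) and the event count C(t) (zero on weeks
without one).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from traceclust.errors import ConfigurationError

OTHERS = "Others"


@dataclass(frozen=True)
class ThemeMap:
    """Ordered theme names plus a topic-index -> theme-name assignment.

    Unassigned topics implicitly map to "Others", which is always present
    as the last theme.
    """

    theme_names: tuple[str, ...]
    assignment: dict[int, str]

    def __post_init__(self):
        if OTHERS not in self.theme_names:
            object.__setattr__(
                self, "theme_names", tuple(self.theme_names) + (OTHERS,)
            )
        unknown = {t for t in self.assignment.values() if t not in self.theme_names}
        if unknown:
            raise ConfigurationError(
                f"assignment uses theme(s) {sorted(unknown)} not in theme_names"
            )

    @property
    def n_themes(self) -> int:
        return len(self.theme_names)

    def theme_of(self, topic: int) -> str:
        return self.assignment.get(topic, OTHERS)

    def validate_for(self, n_topics: int) -> None:
        bad = [t for t in self.assignment if not 0 <= t < n_topics]
        if bad:
            raise ConfigurationError(
                f"theme map assigns topic index(es) {bad} outside 0..{n_topics - 1}"
            )

    def to_yaml(self, path: str | Path) -> None:
        grouped: dict[str, list[int]] = {n: [] for n in self.theme_names if n != OTHERS}
        for t, name in sorted(self.assignment.items()):
            grouped.setdefault(name, []).append(t)
        Path(path).write_text(yaml.safe_dump({"themes": grouped}, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThemeMap":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict) or "themes" not in data:
            raise ConfigurationError(f"{path}: expected a top-level 'themes' mapping")
        grouped = data["themes"]
        assignment = {}
        for name, topics in grouped.items():
            for t in topics or []:
                if t in assignment:
                    raise ConfigurationError(
                        f"topic {t} assigned to both {assignment[t]!r} and {name!r}"
                    )
                assignment[int(t)] = name
        return cls(theme_names=tuple(grouped), assignment=assignment)


def identity_theme_map(n_topics: int) -> ThemeMap:
    """One theme per topic — used when the manual grouping step is skipped."""
    names = tuple(f"topic_{k}" for k in range(n_topics))
    return ThemeMap(theme_names=names, assignment={k: names[k] for k in range(n_topics)})


def topics_to_themes(topic_vector: np.ndarray, theme_map: ThemeMap) -> np.ndarray:
    """Sum topic probabilities within each theme; mass is conserved exactly.

    Works on a single vector (K,) or a matrix (D, K); returns the same
    leading shape over ``theme_map.theme_names``.
    """
    vec = np.asarray(topic_vector, dtype=float)
    single = vec.ndim == 1
    mat = vec[None, :] if single else vec
    K = mat.shape[1]
    theme_map.validate_for(K)
    A = np.zeros((K, theme_map.n_themes))
    pos = {name: m for m, name in enumerate(theme_map.theme_names)}
    for k in range(K):
        A[k, pos[theme_map.theme_of(k)]] = 1.0
    out = mat @ A
    return out[0] if single else out


@dataclass
class ThemeProcess:
    """One actor's weekly theme trajectory over a fixed week window.

    ``weeks[t]`` is the (year, week) pair of window position t (0-based);
    ``P[t]`` is the theme distribution (NaN row when inactive); ``C[t]`` is
    the event count, zero on weeks with no surviving document.
    """

    actor_id: str
    weeks: list[tuple[int, int]]
    P: np.ndarray  # (T, M)
    C: np.ndarray  # (T,) int

    @property
    def active(self) -> np.ndarray:
        return self.C > 0


def spring_window(year: int, last_week: int = 22) -> list[tuple[int, int]]:
    """Weeks 1..last_week of one year — the spring-semester window."""
    return [(year, w) for w in range(1, last_week + 1)]


def build_processes(
    meta: pd.DataFrame,
    doc_topic: np.ndarray,
    theme_map: ThemeMap,
    window: list[tuple[int, int]],
) -> list[ThemeProcess]:
    """Assemble per-actor weekly theme processes over a week window.

    ``meta`` must have columns actor_id, year, week, total aligned row-wise
    with ``doc_topic``.  Documents outside the window are ignored; actors
    with no active week in the window get no process.
    """
    if not window:
        raise ConfigurationError("week window is empty")
    theme_vectors = topics_to_themes(doc_topic, theme_map)
    T = len(window)
    M = theme_map.n_themes
    pos = {wk: t for t, wk in enumerate(window)}
    by_actor: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for i, row in enumerate(meta.itertuples(index=False)):
        t = pos.get((int(row.year), int(row.week)))
        if t is None:
            continue
        actor = row.actor_id
        if actor not in by_actor:
            P = np.full((T, M), np.nan)
            C = np.zeros(T, dtype=int)
            by_actor[actor] = (P, C)
        P, C = by_actor[actor]
        P[t] = theme_vectors[i]
        C[t] = int(row.total)
    return [
        ThemeProcess(actor_id=a, weeks=list(window), P=P, C=C)
        for a, (P, C) in sorted(by_actor.items())
    ]


def mean_weekly_theme_distribution(
    processes: list[ThemeProcess],
    theme_names: tuple[str, ...] | list[str],
    weighted: bool = False,
) -> pd.DataFrame:
    """Per-week mean theme distribution over active actors.

    Unweighted by default (each active actor counts equally); with
    ``weighted=True`` actors are weighted by their weekly event counts.
    Returns a long DataFrame (year, week, theme, mean_probability,
    n_active); weeks with no active actor appear with NaN means.
    """
    if not processes:
        raise ConfigurationError("no processes to average")
    window = processes[0].weeks
    T = len(window)
    M = len(theme_names)
    sums = np.zeros((T, M))
    wsum = np.zeros(T)
    n_active = np.zeros(T, dtype=int)
    for proc in processes:
        if proc.weeks != window:
            raise ConfigurationError("processes are on different week windows")
        act = proc.active
        w = proc.C[act].astype(float) if weighted else np.ones(act.sum())
        sums[act] += proc.P[act] * w[:, None]
        wsum[act] += w
        n_active[act] += 1
    means = np.full((T, M), np.nan)
    ok = wsum > 0
    means[ok] = sums[ok] / wsum[ok, None]
    records = []
    for t, (year, week) in enumerate(window):
        for m, theme in enumerate(theme_names):
            records.append(
                {
                    "year": year,
                    "week": week,
                    "theme": theme,
                    "mean_probability": means[t, m],
                    "n_active": int(n_active[t]),
                }
            )
    return pd.DataFrame(records)


def processes_to_frame(
    processes: list[ThemeProcess], theme_names: tuple[str, ...] | list[str]
) -> pd.DataFrame:
    """Long-format export: actor_id, year, week, theme, probability, events."""
    records = []
    for proc in processes:
        for t, (year, week) in enumerate(proc.weeks):
            if proc.C[t] <= 0:
                continue
            for m, theme in enumerate(theme_names):
                records.append(
                    {
                        "actor_id": proc.actor_id,
                        "year": year,
                        "week": week,
                        "theme": theme,
                        "probability": proc.P[t, m],
                        "events": int(proc.C[t]),
                    }
                )
    return pd.DataFrame(records)


def frame_to_processes(
    frame: pd.DataFrame, window: list[tuple[int, int]]
) -> tuple[list[ThemeProcess], list[str]]:
    """Inverse of :func:`processes_to_frame` over a given window."""
    theme_names = list(dict.fromkeys(frame["theme"]))
    pos = {wk: t for t, wk in enumerate(window)}
    out = []
    for actor, grp in frame.groupby("actor_id", sort=True):
        P = np.full((len(window), len(theme_names)), np.nan)
        C = np.zeros(len(window), dtype=int)
        for (year, week), g in grp.groupby(["year", "week"]):
            t = pos.get((int(year), int(week)))
            if t is None:
                continue
            probs = g.set_index("theme")["probability"]
            P[t] = [probs[th] for th in theme_names]
            C[t] = int(g["events"].iloc[0])
        out.append(ThemeProcess(actor_id=str(actor), weeks=list(window), P=P, C=C))
    return out, theme_names
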