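"""Cluster-level process summaries, peak-week detection and figures.

For each cluster the summary holds the per-week mean theme distribution
over the cluster's *active* actors (actors with a surviving document that
week) — weeks where no member is active are flagged rather than imputed.
A *peak week* of a theme group (e.g. the grading demand, Evaluation +
Final grading) is a strict local maximum of the group's weekly share with
prominence at least a configurable threshold; endpoints are never peaks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_prominences

from traceclust.errors import ConfigurationError
from traceclust.themes import ThemeProcess

#: the Discussion-style default grouping: evaluation plus final grading
GRADING_DEMAND = ("Evaluation", "Final grading")


@dataclass
class ClusterProcessSummary:
    """Per-cluster weekly mean theme distributions and active-actor counts."""

    clusters: list[int]
    weeks: list[tuple[int, int]]
    theme_names: list[str]
    mean: dict[int, np.ndarray]  # cluster -> (T, M), NaN where none active
    n_active: dict[int, np.ndarray]  # cluster -> (T,) int
    sizes: dict[int, int]

    def to_frame(self) -> pd.DataFrame:
        records = []
        for c in self.clusters:
            for t, (year, week) in enumerate(self.weeks):
                for m, theme in enumerate(self.theme_names):
                    records.append(
                        {
                            "cluster": c,
                            "year": year,
                            "week": week,
                            "theme": theme,
                            "mean_probability": self.mean[c][t, m],
                            "n_active": int(self.n_active[c][t]),
                        }
                    )
        return pd.DataFrame(records)

    def group_share(self, cluster: int, theme_group) -> np.ndarray:
        """Weekly summed share of a theme group for one cluster (NaN = no data)."""
        idx = [self.theme_names.index(th) for th in theme_group]
        return self.mean[cluster][:, idx].sum(axis=1)


@dataclass
class PeakReport:
    """Peak weeks of a theme group's share series, per cluster."""

    theme_group: tuple[str, ...]
    min_prominence: float
    peaks: dict[int, list[int]]  # cluster -> 1-based window week positions
    peak_weeks: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "theme_group": list(self.theme_group),
                    "min_prominence": self.min_prominence,
                    "peaks": {str(c): p for c, p in self.peaks.items()},
                    "peak_weeks": {
                        str(c): [list(w) for w in ws]
                        for c, ws in self.peak_weeks.items()
                    },
                },
                indent=2,
            )
        )


def summarize_clusters(
    processes: list[ThemeProcess],
    labels: dict[str, int],
    theme_names: list[str] | tuple[str, ...],
) -> ClusterProcessSummary:
    """Unweighted per-cluster, per-week mean over active actors."""
    by_id = {p.actor_id: p for p in processes}
    missing = sorted(set(labels) - set(by_id))
    if missing:
        raise ConfigurationError(
            f"labeled actor(s) without a process: {missing[:10]}"
        )
    if not labels:
        raise ConfigurationError("no labels given")
    window = next(iter(by_id.values())).weeks
    T, M = len(window), len(theme_names)
    clusters = sorted(set(labels.values()))
    mean = {c: np.full((T, M), np.nan) for c in clusters}
    n_active = {c: np.zeros(T, dtype=int) for c in clusters}
    sizes = {c: 0 for c in clusters}
    sums = {c: np.zeros((T, M)) for c in clusters}
    for actor, c in labels.items():
        proc = by_id[actor]
        sizes[c] += 1
        act = proc.active
        sums[c][act] += proc.P[act]
        n_active[c][act] += 1
    for c in clusters:
        ok = n_active[c] > 0
        mean[c][ok] = sums[c][ok] / n_active[c][ok, None]
    return ClusterProcessSummary(
        clusters=clusters,
        weeks=list(window),
        theme_names=list(theme_names),
        mean=mean,
        n_active=n_active,
        sizes=sizes,
    )


def peak_positions(series: np.ndarray, min_prominence: float) -> list[int]:
    """Strict local maxima with prominence >= threshold; 0-based positions.

    Endpoints are never peaks.  Weeks without data (NaN) are treated as
    zero activity share.
    """
    s = np.nan_to_num(np.asarray(series, dtype=float), nan=0.0)
    idx, _ = find_peaks(s)
    # strictness: exclude plateau maxima, keep s(t-1) < s(t) > s(t+1) only
    idx = np.array(
        [i for i in idx if s[i] > s[i - 1] and s[i] > s[i + 1]], dtype=int
    )
    if len(idx) == 0:
        return []
    prom = peak_prominences(s, idx)[0]
    return [int(i) for i, p in zip(idx, prom) if p >= min_prominence]


def detect_peaks(
    summary: ClusterProcessSummary,
    theme_group=GRADING_DEMAND,
    min_prominence: float = 0.02,
) -> PeakReport:
    """Peak weeks of a theme group's weekly share, per cluster."""
    group = tuple(theme_group)
    if not group:
        raise ConfigurationError("theme_group is empty")
    unknown = [th for th in group if th not in summary.theme_names]
    if unknown:
        raise ConfigurationError(f"unknown theme(s) in group: {unknown}")
    peaks: dict[int, list[int]] = {}
    peak_weeks: dict[int, list[tuple[int, int]]] = {}
    for c in summary.clusters:
        pos = peak_positions(summary.group_share(c, group), min_prominence)
        peaks[c] = [p + 1 for p in pos]
        peak_weeks[c] = [summary.weeks[p] for p in pos]
    return PeakReport(
        theme_group=group,
        min_prominence=min_prominence,
        peaks=peaks,
        peak_weeks=peak_weeks,
    )


def render_figures(
    summary: ClusterProcessSummary,
    out_dir: str | Path,
    fmt: str = "png",
) -> list[Path]:
    """Stacked-area charts of weekly theme means, one per cluster plus an
    overall chart, with the underlying numbers emitted as CSV.

    Theme colors follow the fixed order of ``summary.theme_names``.
    Clusters with no active actor anywhere get an explicit "no data"
    annotation instead of an area plot.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = summary.to_frame()
    csv_path = out_dir / "cluster_summary.csv"
    frame.to_csv(csv_path, index=False)
    written = [csv_path]

    weeks = np.arange(1, len(summary.weeks) + 1)
    cmap = plt.get_cmap("tab10")
    colors = [cmap(m % 10) for m in range(len(summary.theme_names))]

    def _plot(ax, means: np.ndarray, title: str) -> None:
        data = np.nan_to_num(means, nan=0.0).T
        if np.all(~np.isfinite(means)) or data.sum() == 0:
            ax.text(0.5, 0.5, "no data", ha="center", va="center")
        else:
            ax.stackplot(
                weeks, data, labels=summary.theme_names, colors=colors
            )
            ax.legend(loc="upper right", fontsize="small")
        ax.set_title(title)
        ax.set_xlabel("week")
        ax.set_ylabel("theme share")
        ax.set_ylim(0, 1)

    for c in summary.clusters:
        fig, ax = plt.subplots(figsize=(7, 4))
        _plot(ax, summary.mean[c], f"cluster {c} (n={summary.sizes[c]})")
        path = out_dir / f"cluster_{c}.{fmt}"
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)
        written.append(path)

    # overall chart: actors pooled over clusters, weighted by active counts
    T, M = len(summary.weeks), len(summary.theme_names)
    tot = np.zeros((T, M))
    n_tot = np.zeros(T)
    for c in summary.clusters:
        act = summary.n_active[c] > 0
        tot[act] += np.nan_to_num(summary.mean[c][act]) * summary.n_active[c][
            act, None
        ]
        n_tot += summary.n_active[c]
    overall = np.full((T, M), np.nan)
    ok = n_tot > 0
    overall[ok] = tot[ok] / n_tot[ok, None]
    fig, ax = plt.subplots(figsize=(7, 4))
    _plot(ax, overall, "all actors")
    path = out_dir / f"overall.{fmt}"
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    written.append(path)
    return written
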