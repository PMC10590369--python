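"""End-to-end orchestration of the analysis protocol from one config.

The pipeline runs, in order: ingest (read + the two preprocessing
filters) -> corpus construction -> LDA model selection -> theme
aggregation -> per-window processes -> pairwise dissimilarity ->
complete-linkage clustering -> cluster reports.  Every intermediate
artifact is written to disk, each week window is clustered independently,
and a manifest records the config hash, seeds, per-stage row counts and
package version so a run is fully reproducible.

Input is either a trace-log CSV or a synthetic-data configuration; the
theme map is optional — without one, raw topics are used as themes
(identity map) and the manifest flags it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import traceclust
from traceclust import clustering as _clustering
from traceclust import dissimilarity as _dissimilarity
from traceclust import documents as _documents
from traceclust import ingest as _ingest
from traceclust import reporting as _reporting
from traceclust import synthetic as _synthetic
from traceclust import themes as _themes
from traceclust import topics as _topics
from traceclust.errors import ConfigurationError, PipelineStageError


@dataclass
class PipelineConfig:
    """Everything one run needs; see the YAML schema in the docs."""

    output_dir: str
    input_csv: str | None = None
    synthetic: _synthetic.SyntheticConfig | None = None
    date_dialect: str = "dayfirst"
    removal_list: list[str] | str = "default"
    min_weekly_events: int = 25
    week_windows: list[dict] | None = None  # [{"year": 2019, "first_week": 1, "last_week": 22}]
    topic_range: tuple[int, int] = (10, 20)
    n_inits: int = 50
    master_seed: int = 0
    force_n_topics: int | None = None
    lda_max_iter: int = 20
    bic_param_mode: str = "topic_word"
    theme_map_path: str | None = None
    log_base: float = 2.0
    js_sqrt: bool = True
    missing_pair: str = "max"
    k: int = 6
    min_prominence: float = 0.02
    theme_group: list[str] = field(default_factory=lambda: list(_reporting.GRADING_DEMAND))
    render: bool = True

    def removal_set(self) -> frozenset[str]:
        if self.removal_list == "default":
            return _ingest.DEFAULT_REMOVAL_LIST
        return frozenset(self.removal_list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        syn = data.pop("synthetic", None)
        cfg = cls(**{**data, "topic_range": tuple(data.get("topic_range", (10, 20)))})
        if syn is not None:
            if isinstance(syn, str):
                cfg.synthetic = _synthetic.SyntheticConfig.from_yaml(syn)
            else:
                raise ConfigurationError(
                    "synthetic must be a path to a synthetic-config YAML"
                )
        return cfg

    def config_hash(self) -> str:
        blob = repr(sorted(self.__dict__.items(), key=lambda kv: kv[0]))
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_config(config: PipelineConfig) -> list[str]:
    """All detectable problems at once; an empty list means clean."""
    issues = []
    if config.input_csv is None and config.synthetic is None:
        issues.append("one of input_csv or synthetic is required")
    if config.input_csv is not None and not Path(config.input_csv).exists():
        issues.append(f"input_csv not found: {config.input_csv}")
    if config.date_dialect not in ("dayfirst", "iso"):
        issues.append(f"unknown date_dialect {config.date_dialect!r}")
    if config.min_weekly_events < 1:
        issues.append("min_weekly_events must be >= 1")
    lo, hi = config.topic_range
    if lo > hi:
        issues.append(f"empty topic range {lo}:{hi}")
    if lo < 2:
        issues.append("topic range must start at >= 2")
    if config.n_inits < 1:
        issues.append("n_inits must be >= 1")
    if config.k < 1:
        issues.append("k must be >= 1")
    if config.missing_pair not in ("max", "drop"):
        issues.append(f"unknown missing_pair policy {config.missing_pair!r}")
    if config.theme_map_path is not None and not Path(config.theme_map_path).exists():
        issues.append(f"theme_map_path not found: {config.theme_map_path}")
    if config.synthetic is not None:
        try:
            config.synthetic.validate()
        except ConfigurationError as exc:
            issues.append(f"synthetic: {exc}")
    for w in config.week_windows or []:
        if not {"year", "first_week", "last_week"} <= set(w):
            issues.append(f"window {w} needs year, first_week, last_week")
        elif w["first_week"] > w["last_week"]:
            issues.append(f"window {w} has an empty week range")
    return issues


def _windows_from_events(events) -> list[list[tuple[int, int]]]:
    """Default: one window per calendar year present, covering its weeks."""
    by_year: dict[int, set[int]] = {}
    for ev in events:
        by_year.setdefault(ev.year, set()).add(ev.week)
    return [
        [(year, w) for w in range(min(weeks), max(weeks) + 1)]
        for year, weeks in sorted(by_year.items())
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    issues = validate_config(config)
    if issues:
        raise ConfigurationError("; ".join(issues))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "version": traceclust.__version__,
        "master_seed": config.master_seed,
        "stages": {},
    }

    def _write_manifest():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    def _stage(name: str):
        class _Ctx:
            def __enter__(self):
                return manifest["stages"].setdefault(name, {})

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    manifest["stages"][name]["error"] = str(exc)
                    _write_manifest()
                    raise PipelineStageError(name, exc) from exc
                _write_manifest()

        return _Ctx()

    truth = None
    with _stage("ingest") as st:
        if config.synthetic is not None:
            events, truth = _synthetic.generate_log(config.synthetic)
            _ingest.write_trace_log(events, out / "log.csv")
            truth.to_json(out / "ground_truth.json")
            config.synthetic.to_yaml(out / "synthetic_config.yaml")
            st["n_rows"] = len(events)
        else:
            events, report = _ingest.read_trace_log(
                config.input_csv, dialect=config.date_dialect
            )
            st.update(report.to_dict())
        weeked = _ingest.assign_weeks(events)
        weeked, removed = _ingest.remove_general_use(weeked, config.removal_set())
        weeked, dropped = _ingest.filter_low_activity_weeks(
            weeked, config.min_weekly_events
        )
        _ingest.write_weeked_events(weeked, out / "clean.csv")
        st["n_removed_general_use"] = int(sum(removed.values()))
        st["removed_per_token"] = {t: int(c) for t, c in sorted(removed.items())}
        st["n_dropped_low_activity_weeks"] = len(dropped)
        st["n_events_clean"] = len(weeked)
        (out / "preprocess_report.json").write_text(
            json.dumps(
                {
                    "removed_per_token": st["removed_per_token"],
                    "dropped_actor_weeks": [
                        [a, y, w, c] for (a, y, w), c in sorted(dropped.items())
                    ],
                },
                indent=2,
            )
        )

    with _stage("documents") as st:
        vocab = _documents.build_vocabulary(weeked)
        corpus = _documents.build_corpus(weeked, vocab)
        corpus.save(out / "corpus")
        st["n_documents"] = corpus.n_documents
        st["vocabulary_size"] = len(vocab)
        st["n_tokens"] = corpus.n_tokens_total

    with _stage("topic_model") as st:
        lo, hi = config.topic_range
        report = _topics.model_selection(
            corpus,
            topic_range=range(lo, hi + 1),
            n_inits=config.n_inits,
            master_seed=config.master_seed,
            force_n_topics=config.force_n_topics,
            max_iter=config.lda_max_iter,
            bic_param_mode=config.bic_param_mode,
        )
        fit = report.selected
        (out / "selection_report.json").write_text(
            json.dumps(report.to_json_dict(), indent=2)
        )
        fit.save(out / "model")
        st["selected_n_topics"] = fit.n_topics
        st["selected_seed"] = fit.seed
        st["selected_bic"] = fit.bic

    with _stage("themes") as st:
        if config.theme_map_path is not None:
            theme_map = _themes.ThemeMap.from_yaml(config.theme_map_path)
            st["theme_map"] = "user-supplied"
        else:
            theme_map = _themes.identity_theme_map(fit.n_topics)
            st["theme_map"] = "identity (no theme map configured)"
        theme_map.validate_for(fit.n_topics)
        doc_topic = _topics.assign_topic_distributions(fit, corpus)
        if config.week_windows:
            windows = [
                [
                    (w["year"], wk)
                    for wk in range(w["first_week"], w["last_week"] + 1)
                ]
                for w in config.week_windows
            ]
        else:
            windows = _windows_from_events(weeked)
        st["n_windows"] = len(windows)
        processes_per_window = []
        for window in windows:
            procs = _themes.build_processes(corpus.meta, doc_topic, theme_map, window)
            processes_per_window.append(procs)
            tag = f"{window[0][0]}_w{window[0][1]:02d}-{window[-1][1]:02d}"
            _themes.processes_to_frame(procs, theme_map.theme_names).to_csv(
                out / f"processes_{tag}.csv", index=False
            )
        st["n_processes"] = [len(p) for p in processes_per_window]

    results = []
    for window, procs in zip(windows, processes_per_window):
        tag = f"{window[0][0]}_w{window[0][1]:02d}-{window[-1][1]:02d}"
        with _stage(f"dissimilarity[{tag}]") as st:
            matrix = _dissimilarity.pairwise_dissimilarity(
                procs,
                log_base=config.log_base,
                sqrt=config.js_sqrt,
                missing_pair=config.missing_pair,
            )
            matrix.to_csv(out / f"dissimilarity_{tag}.csv")
            st["n_actors"] = len(matrix.actor_ids)
            st["n_undefined_pairs"] = len(matrix.undefined_pairs)

        with _stage(f"clustering[{tag}]") as st:
            dendro = _clustering.complete_linkage(matrix)
            (out / f"dendrogram_{tag}.nwk").write_text(dendro.to_newick())
            k = min(config.k, dendro.n_leaves)
            result = _clustering.cut(dendro, k=k)
            result.to_csv(out / f"labels_{tag}.csv")
            sil = _clustering.silhouette_report(matrix)
            sil.to_csv(out / f"silhouette_{tag}.csv", index=False)
            st["k"] = result.k

        with _stage(f"reporting[{tag}]") as st:
            summary = _reporting.summarize_clusters(
                procs, result.labels, theme_map.theme_names
            )
            group = [
                th for th in config.theme_group if th in theme_map.theme_names
            ]
            peak_report = None
            if group:
                peak_report = _reporting.detect_peaks(
                    summary, group, config.min_prominence
                )
                peak_report.to_json(out / f"peaks_{tag}.json")
            rep_dir = out / f"reports_{tag}"
            if config.render:
                _reporting.render_figures(summary, rep_dir)
            else:
                rep_dir.mkdir(parents=True, exist_ok=True)
                summary.to_frame().to_csv(
                    rep_dir / "cluster_summary.csv", index=False
                )
            st["cluster_sizes"] = {str(c): n for c, n in summary.sizes.items()}
        results.append(
            {
                "window": tag,
                "labels": result.labels,
                "summary": summary,
                "matrix": matrix,
            }
        )

    manifest["windows"] = [r["window"] for r in results]
    if truth is not None:
        manifest["ground_truth"] = str(out / "ground_truth.json")
    _write_manifest()
    manifest["_results"] = results  # in-memory only; not serialized
    return manifest
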