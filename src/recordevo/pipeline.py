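"""End-to-end analysis pipeline and report bundle assembly.

Ties the stages together: load or simulate an annual-best panel, compute
the span-comparison evolution table and rankings, fit the Gaussian record
model per event and classify band deviations, build the TSRF correlation
network, and write everything to an output directory with a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .gembris import (
    DEFAULT_CONSECUTIVE_K,
    DeviationReport,
    classify_event_deviation,
    fit_gaussian_baseline,
)
from .network import (
    DEFAULT_ALPHA,
    DEFAULT_BASELINE_YEAR,
    DEFAULT_R_THRESHOLD,
    build_network,
    compute_tsrf,
    correlation_matrix,
)
from .records import (
    DEFAULT_SPAN_A,
    DEFAULT_SPAN_B,
    EventCatalog,
    PanelError,
    compare_spans,
    load_default_catalog,
    rank_events,
    read_annual_bests,
    write_annual_bests,
)
from .simulate import default_panel_spec, panel_spec_from_yaml, simulate_panel

logger = logging.getLogger("recordevo")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``panel_path`` (a CSV in the event_id,year,mark schema) or
    ``spec_path`` (a panel-spec YAML) may be given; with neither, the
    packaged default synthetic spec is simulated.
    """

    panel_path: str | None = None
    spec_path: str | None = None
    out_dir: str = "recordevo_out"
    fit_window: tuple[int, int] = (1992, 2001)
    projection: tuple[int, int] = (2002, 2018)
    baseline_year: int = DEFAULT_BASELINE_YEAR
    span_a: tuple[int, int] = DEFAULT_SPAN_A
    span_b: tuple[int, int] = DEFAULT_SPAN_B
    r_threshold: float = DEFAULT_R_THRESHOLD
    alpha: float = DEFAULT_ALPHA
    require_significance: bool = True
    fdr_correction: bool = False
    k_consecutive: int = DEFAULT_CONSECUTIVE_K
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("fit_window", "projection", "span_a", "span_b"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """In-memory results of a pipeline run (also written to out_dir)."""

    panel: dict
    evolution: pd.DataFrame
    ranking: pd.DataFrame
    deviation_reports: dict[str, DeviationReport]
    R: pd.DataFrame
    p: pd.DataFrame
    network: object
    out_dir: Path
    manifest: dict = field(default_factory=dict)


def _float_csv(df: pd.DataFrame, path: Path, **kw) -> None:
    # repr-precision floats so reruns are byte-identical
    df.to_csv(path, float_format="%.17g", **kw)


def load_panel(config: RunConfig, catalog: EventCatalog):
    """Resolve the input panel: read CSV, simulate from YAML spec, or
    simulate the packaged default spec (seeded by the config)."""
    if config.panel_path:
        return read_annual_bests(config.panel_path, catalog), "file"
    if config.spec_path:
        spec = panel_spec_from_yaml(config.spec_path)
        return simulate_panel(spec, seed=config.seed), "spec"
    return simulate_panel(default_panel_spec(seed=config.seed)), "default-spec"


def run_pipeline(config: RunConfig, catalog: EventCatalog | None = None) -> ReportBundle:
    """Run the full analysis and write the report bundle to out_dir.

    Outputs: the resolved panel (panel.csv), the evolution table
    (evolution.csv) and ranking (ranking.csv), one deviation CSV per event
    under deviations/ plus deviation_summary.json, the correlation matrices
    (correlation_R.csv / correlation_p.csv), the network edge list, the
    adjacency matrix, components.json, a GraphML file, and manifest.json
    recording the config hash, versions, stage timings and record counts.
    The run is deterministic given panel + config (+ seed when simulating).
    """
    catalog = catalog or load_default_catalog()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
        "outputs": [],
        "complete": False,
    }
    timings = manifest["stages"]

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = {"seconds": round(time.perf_counter() - self.t0, 4)}
                if exc is not None:
                    manifest["failed_stage"] = name
                    _write_manifest(out, manifest)
                    logger.error("stage %s failed: %s", name, exc)
                else:
                    logger.info("stage %s: done", name)
                return False

        return _T()

    def emit(name: str):
        manifest["outputs"].append(name)

    try:
        with stage("input"):
            panel, source = load_panel(config, catalog)
            if not panel:
                raise PanelError("input stage: empty panel")
            manifest["panel_source"] = source
            manifest["n_events"] = len(panel)
            manifest["n_marks"] = sum(len(s.marks) for s in panel.values())
            write_annual_bests(panel, out / "panel.csv")
            emit("panel.csv")

        with stage("evolve"):
            evolution = compare_spans(panel, config.span_a, config.span_b)
            ranking = rank_events(evolution, catalog)
            _float_csv(evolution, out / "evolution.csv")
            _float_csv(ranking, out / "ranking.csv")
            emit("evolution.csv")
            emit("ranking.csv")

        with stage("predict"):
            dev_dir = out / "deviations"
            dev_dir.mkdir(exist_ok=True)
            reports: dict[str, DeviationReport] = {}
            summary = {}
            for event_id, series in panel.items():
                model = fit_gaussian_baseline(series, config.fit_window)
                report = classify_event_deviation(
                    series, model, config.projection, config.k_consecutive
                )
                reports[event_id] = report
                _float_csv(report.to_frame(), dev_dir / f"{event_id}.csv", index=False)
                emit(f"deviations/{event_id}.csv")
                summary[event_id] = {
                    "systematic_deviation": report.systematic_deviation,
                    "side": report.side,
                    "mu": model.mu,
                    "sigma": model.sigma,
                }
            with open(out / "deviation_summary.json", "w", encoding="utf-8") as fh:
                json.dump(summary, fh, indent=2, sort_keys=True)
            emit("deviation_summary.json")

        with stage("network"):
            tsrf = compute_tsrf(panel, config.baseline_year, catalog)
            R, p = correlation_matrix(tsrf)
            net = build_network(
                R, p, config.r_threshold, config.alpha,
                require_significance=config.require_significance,
                fdr_correction=config.fdr_correction,
            )
            _float_csv(tsrf.values, out / "tsrf.csv")
            _float_csv(R, out / "correlation_R.csv")
            _float_csv(p, out / "correlation_p.csv")
            _float_csv(net.edge_table(), out / "network_edges.csv", index=False)
            net.adjacency().to_csv(out / "network_adjacency.csv")
            net.write_graphml(out / "network.graphml")
            components = sorted(
                (sorted(c) for c in net.components), key=lambda c: (-len(c), c)
            )
            with open(out / "components.json", "w", encoding="utf-8") as fh:
                json.dump(components, fh, indent=2)
            for name in ("tsrf.csv", "correlation_R.csv", "correlation_p.csv",
                         "network_edges.csv", "network_adjacency.csv",
                         "network.graphml", "components.json"):
                emit(name)
    finally:
        manifest["complete"] = "failed_stage" not in manifest
        _write_manifest(out, manifest)

    return ReportBundle(
        panel=panel, evolution=evolution, ranking=ranking,
        deviation_reports=reports, R=R, p=p, network=net,
        out_dir=out, manifest=manifest,
    )


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# headline summary for real panels
# ---------------------------------------------------------------------------

def headline_summary(
    panel: dict,
    catalog: EventCatalog | None = None,
    span_a: tuple[int, int] = DEFAULT_SPAN_A,
    span_b: tuple[int, int] = DEFAULT_SPAN_B,
    marathon_spans: tuple[tuple[int, int], tuple[int, int]] = ((1992, 2002), (2018, 2008)),
) -> dict:
    """Headline record-evolution numbers for a panel.

    Computes the quantities conventionally quoted for the real 1992-2018
    panel: the 1992->2018 percent improvement of the 200m backstroke and
    the marathon, the ratio of the smallest swimming improvement (400m
    freestyle) to the largest track-and-field improvement (100m sprint),
    and the marathon's rank by mean improvement over the configured spans.
    On synthetic panels the same quantities are computed from the
    generated data; reproducing the published real-data values requires a
    user-supplied curated federation panel in the CSV schema.
    """
    from .records import improvement_percent

    catalog = catalog or load_default_catalog()
    out: dict = {}
    y0, y1 = span_a[0], span_b[1] if span_b[1] >= span_b[0] else span_b[0]

    def imp(event_id):
        return improvement_percent(panel[event_id], y0, y1)

    if "200m_back" in panel:
        out["backstroke_200m_improvement_pct"] = imp("200m_back")
    if "marathon" in panel:
        out["marathon_improvement_pct"] = imp("marathon")
    if "400m_free" in panel and "100m" in panel:
        track_field = [
            e for e in panel
            if e in catalog and catalog[e].category in
            ("sprint", "middle/long running", "marathon", "hurdles", "jump")
        ]
        largest_tf = max(track_field, key=imp)
        out["largest_track_field_event"] = largest_tf
        ratio = imp("400m_free") / imp(largest_tf) if imp(largest_tf) != 0 else float("nan")
        out["freestyle400_to_track_ratio"] = ratio
    comparison = compare_spans(panel, marathon_spans[0], marathon_spans[1])
    ranking = rank_events(comparison, catalog)
    if "marathon" in ranking.index:
        out["marathon_rank"] = int(ranking.loc["marathon", "rank"])
    return out
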