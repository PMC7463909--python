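"""End-to-end orchestration of the six-group synthetic experiment.

For every regime preset and every replicate culture the pipeline simulates
a recording (seed = base_seed + running index), detects calcium events,
builds the thresholded correlation network and computes the three
connectivity metrics, then assembles group summaries (median, Q1-Q3),
Mann-Whitney comparisons of every group against the intact and hypoxia
groups, and optional figures.  Every seed and parameter is written to a
manifest so a run is reproducible from its config alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import events as ev
from . import network as net
from . import stats as st
from . import synthetic as syn
from .errors import IncompleteRunError, UnknownPresetError

__all__ = ["ExperimentConfig", "run_experiment", "make_report",
           "DEFAULT_PRESETS"]

DEFAULT_PRESETS = list(syn.REGIME_PRESETS)

METRIC_COLUMNS = ["percent_working", "median_duration", "median_frequency",
                  "connections_per_cell", "mean_adjacent_rho",
                  "percent_correlated"]


@dataclass
class ExperimentConfig:
    presets: list[str] = field(default_factory=lambda: list(DEFAULT_PRESETS))
    cultures_per_group: int = 6
    base_seed: int = 0
    n_cells: int | None = None
    duration: float | None = None
    threshold: float = net.CORRELATION_THRESHOLD
    epsilon_um: float = net.ADJACENCY_EPSILON_UM
    theta_on: float = ev.THETA_ON
    theta_off: float = ev.THETA_OFF
    min_duration_s: float = ev.MIN_DURATION_S
    out_dir: str = "experiment_out"
    figures: bool = True

    def validate(self) -> None:
        if not self.presets:
            raise ValueError("presets must be nonempty")
        unknown = [p for p in self.presets if p not in syn.REGIME_PRESETS]
        if unknown:
            raise UnknownPresetError(
                f"unknown preset(s) {unknown}; known: "
                + ", ".join(sorted(syn.REGIME_PRESETS)))
        if self.cultures_per_group < 1:
            raise ValueError("cultures_per_group must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys {sorted(bad)}")
        return cls(**raw)


def _sim_config(config: ExperimentConfig, preset: str,
                seed: int) -> syn.SimulationConfig:
    overrides: dict = {"seed": seed}
    if config.n_cells is not None:
        overrides["n_cells"] = config.n_cells
    if config.duration is not None:
        overrides["duration"] = config.duration
    return syn.apply_regime(preset, **overrides)


def analyse_recording(recording: syn.Recording,
                      config: ExperimentConfig) -> dict:
    """Event detection + network construction for one culture.

    Returns the per-culture metric row plus the events and pair tables.
    """
    events = ev.detect_recording(recording, theta_on=config.theta_on,
                                 theta_off=config.theta_off,
                                 min_duration_s=config.min_duration_s)
    summary = ev.summarize_activity(events, recording.n_cells,
                                    recording.duration)
    pairs = net.pairwise_correlation(recording)
    pairs = net.classify_adjacent(pairs, recording.cells,
                                  epsilon_um=config.epsilon_um)
    graph = net.build_graph(pairs, threshold=config.threshold)
    metrics = net.network_metrics(graph, pairs)
    row = {
        "percent_working": summary.percent_working,
        "median_duration": summary.median_duration,
        "median_frequency": summary.median_frequency,
        "connections_per_cell": metrics.connections_per_cell,
        "mean_adjacent_rho": metrics.mean_adjacent_rho,
        "percent_correlated": metrics.percent_correlated,
        "n_adjacent_pairs": metrics.n_adjacent_pairs,
        "n_edges": metrics.n_edges,
    }
    return {"events": events, "summary": summary, "pairs": pairs,
            "graph": graph, "metrics_row": row}


def _events_frame(events: dict, frame_rate: float) -> pd.DataFrame:
    rows = [(cid, e.onset_frame / frame_rate, e.offset_frame / frame_rate,
             e.duration, e.peak_dff)
            for cid, evs in events.items() for e in evs]
    return pd.DataFrame(rows, columns=["cell_id", "onset_s", "offset_s",
                                       "duration_s", "peak_dff"])


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full multi-group experiment; returns the report dict.

    Output layout under ``config.out_dir``::

        manifest.json
        <preset>/culture_<k>/{geometry,traces,events,pairs,summary}.csv
        group_<metric>.csv   report.json   figures/*.png (optional)
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "presets": config.presets,
        "cultures_per_group": config.cultures_per_group,
        "base_seed": config.base_seed,
        "analysis": {
            "threshold": config.threshold, "epsilon_um": config.epsilon_um,
            "theta_on": config.theta_on, "theta_off": config.theta_off,
            "min_duration_s": config.min_duration_s,
        },
        "cultures": [],
    }

    index = 0
    for preset in config.presets:
        for k in range(config.cultures_per_group):
            seed = config.base_seed + index
            index += 1
            sim = _sim_config(config, preset, seed)
            recording, _truth = syn.simulate_recording(sim, group_label=preset)
            res = analyse_recording(recording, config)

            cdir = out / preset / f"culture_{k}"
            syn.write_recording(recording, cdir)
            _events_frame(res["events"], recording.frame_rate).to_csv(
                cdir / "events.csv", index=False)
            res["pairs"].to_csv(cdir / "pairs.csv", index=False)
            pd.DataFrame([{"group": preset, "culture": k, "seed": seed,
                           **res["metrics_row"]}]).to_csv(
                cdir / "summary.csv", index=False)
            manifest["cultures"].append(
                {"group": preset, "culture": k, "seed": seed,
                 "sim_config": dataclasses.asdict(sim)})

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    report = make_report(out)
    if config.figures:
        make_figures(out)
    return report


def make_report(results_dir: str | Path) -> dict:
    """Assemble group tables, the JSON report and cross-group tests.

    Recomputes everything from the persisted per-culture CSVs; raises
    :class:`IncompleteRunError` naming any missing stage output.
    """
    out = Path(results_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise IncompleteRunError([str(manifest_path)])
    manifest = json.loads(manifest_path.read_text())

    missing = []
    rows = []
    for entry in manifest["cultures"]:
        cdir = out / entry["group"] / f"culture_{entry['culture']}"
        for name in ("summary.csv", "events.csv", "pairs.csv"):
            if not (cdir / name).exists():
                missing.append(str(cdir / name))
        if not missing:
            rows.append(pd.read_csv(cdir / "summary.csv"))
    if missing:
        raise IncompleteRunError(missing)

    cultures = pd.concat(rows, ignore_index=True)
    cultures.to_csv(out / "cultures.csv", index=False)

    presets = manifest["presets"]
    report: dict = {"groups": {}, "comparisons": {}}
    for metric in METRIC_COLUMNS:
        table = []
        for preset in presets:
            vals = cultures.loc[cultures["group"] == preset, metric].dropna()
            gs = st.median_iqr(vals, group_label=preset)
            table.append({"group": preset, "n": gs.n, "median": gs.center,
                          "q1": gs.spread[0], "q3": gs.spread[1]})
            report["groups"].setdefault(preset, {})[metric] = {
                "n": gs.n, "median": gs.center,
                "q1": gs.spread[0], "q3": gs.spread[1]}
        pd.DataFrame(table).to_csv(out / f"group_{metric}.csv", index=False)

    for baseline in ("intact", "hypoxia"):
        if baseline not in presets:
            continue
        base_vals = {m: cultures.loc[cultures["group"] == baseline, m].dropna()
                     for m in METRIC_COLUMNS}
        for preset in presets:
            if preset == baseline:
                continue
            for metric in METRIC_COLUMNS:
                vals = cultures.loc[cultures["group"] == preset,
                                    metric].dropna()
                if len(vals) == 0 or len(base_vals[metric]) == 0:
                    continue
                u, p = st.mann_whitney(vals, base_vals[metric])
                report["comparisons"].setdefault(
                    f"vs_{baseline}", {}).setdefault(preset, {})[metric] = {
                    "U": u, "p": p}

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def make_figures(results_dir: str | Path) -> list[Path]:
    """Regenerate figures from the persisted CSVs alone.

    Produces box plots of the activity triple and the network triple, the
    per-group correlation-distance scatters, and functional-graph drawings
    of the first culture of each group.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import networkx as nx

    out = Path(results_dir)
    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    cultures = pd.read_csv(out / "cultures.csv")
    manifest = json.loads((out / "manifest.json").read_text())
    presets = manifest["presets"]
    made: list[Path] = []

    triples = [
        ("activity", ["percent_working", "median_duration",
                      "median_frequency"]),
        ("network", ["connections_per_cell", "mean_adjacent_rho",
                     "percent_correlated"]),
    ]
    for name, metrics in triples:
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
        for ax, metric in zip(axes, metrics):
            data = [cultures.loc[cultures["group"] == p, metric].dropna()
                    for p in presets]
            ax.boxplot(data, tick_labels=[str(i + 1) for i in range(len(presets))])
            ax.set_title(metric.replace("_", " "))
            ax.set_xlabel("group")
        fig.tight_layout()
        path = fig_dir / f"{name}_metrics.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        made.append(path)

    fig, axes = plt.subplots(2, (len(presets) + 1) // 2,
                             figsize=(4 * ((len(presets) + 1) // 2), 7),
                             squeeze=False)
    for ax, preset in zip(axes.ravel(), presets):
        pairs = pd.read_csv(out / preset / "culture_0" / "pairs.csv")
        dist = pairs[~pairs["adjacent"]]
        adj = pairs[pairs["adjacent"]]
        ax.scatter(dist["distance"], dist["rho"], s=4, alpha=0.5,
                   color="steelblue", label="non-adjacent")
        ax.scatter(adj["distance"], adj["rho"], s=8, color="crimson",
                   label="adjacent")
        ax.axhline(0.3, ls="--", lw=0.8, color="gray")
        ax.set_title(preset, fontsize=9)
        ax.set_xlabel("distance, µm")
        ax.set_ylabel("ρ")
        ax.set_ylim(-0.4, 1.0)
    axes.ravel()[0].legend(fontsize=7)
    fig.tight_layout()
    path = fig_dir / "correlation_distance.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    made.append(path)

    fig, axes = plt.subplots(2, (len(presets) + 1) // 2,
                             figsize=(4 * ((len(presets) + 1) // 2), 7),
                             squeeze=False)
    for ax, preset in zip(axes.ravel(), presets):
        cdir = out / preset / "culture_0"
        geo = pd.read_csv(cdir / "geometry.csv")
        pairs = pd.read_csv(cdir / "pairs.csv")
        g = net.build_graph(pairs)
        pos = {int(r.cell_id): (r.x, -r.y) for r in geo.itertuples()}
        nx.draw_networkx(g, pos=pos, ax=ax, node_size=18, with_labels=False,
                         width=0.5, node_color="black", edge_color="tomato")
        ax.set_title(preset, fontsize=9)
        ax.set_axis_off()
    fig.tight_layout()
    path = fig_dir / "functional_graphs.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    made.append(path)
    return made
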