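"""Pipeline driver: configuration, staging, manifests.

Binds the stages into one reproducible run:

    simulate/load -> BGA extraction -> selectivity -> latency -> topology

Input modes: ``simulate`` (in-package generator), ``hdf5`` (a previously
written dataset container), ``supplementary-mat`` (the deposited
electrode-level matrices; raw traces are not deposited, so the BGA and
latency stages are skipped and selectivity/topology run from the stored
d', shuffles and coordinates). Every run writes the resolved configuration
and seed beside its outputs plus a manifest with a content hash per
artifact; re-running with the same config and seed reproduces the hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gammatopo import bga as bga_mod
from gammatopo import latency as lat_mod
from gammatopo import selectivity as sel_mod
from gammatopo import simulate as sim_mod
from gammatopo import topology as top_mod

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Resolved parameters for one pipeline run (YAML round-trippable)."""

    input_mode: str = "simulate"            # simulate | hdf5 | supplementary-mat
    input_path: str | None = None           # for hdf5 / supplementary-mat modes
    output_dir: str = "results/run"
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "bga", "selectivity", "latency",
                               "topology")
    simulation: dict = field(default_factory=dict)   # SimulationConfig overrides
    gamma_band_hz: tuple[float, float] = (60.0, 120.0)
    line_hz: float = 60.0
    baseline_window_s: tuple[float, float] = (-0.7, -0.2)
    analysis_window_s: tuple[float, float] = (0.1, 0.4)
    n_perm: int = 10_000
    q: float = 0.01
    latency_alpha: float = 0.05
    persistence_s: float = 0.100
    log_level: str = "INFO"

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        for k in ("gamma_band_hz", "baseline_window_s", "analysis_window_s"):
            d[k] = list(d[k])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        for k in ("gamma_band_hz", "baseline_window_s", "analysis_window_s",
                  "stages"):
            if isinstance(d.get(k), list):
                d[k] = tuple(d[k])
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", index=False, float_format="%.10g")
    tmp.replace(path)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the configured stages; return the artifact paths by name."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def register(name: str, path: Path) -> None:
        artifacts[name] = path

    stages = list(config.stages)
    if config.input_mode == "supplementary-mat":
        for skipped in ("simulate", "bga", "latency"):
            if skipped in stages:
                log.info("stage %s skipped: raw traces unavailable in "
                         "supplementary-mat mode", skipped)
                stages.remove(skipped)

    epochs = geometry = truth = None
    if config.input_mode == "simulate":
        sim_cfg = sim_mod.SimulationConfig(**{"seed": config.seed,
                                              **config.simulation})
        epochs, geometry, truth = sim_mod.simulate_dataset(sim_cfg)
        log.info("simulate: %d electrodes, %d subjects", len(epochs),
                 geometry["subject"].nunique())
        if "simulate" in stages:
            ds_path = out / "dataset.h5"
            sim_mod.write_dataset((epochs, geometry, truth), ds_path, sim_cfg)
            register("dataset", ds_path)
    elif config.input_mode == "hdf5":
        if not config.input_path:
            raise ValueError("hdf5 mode requires input_path")
        epochs, geometry, truth = sim_mod.read_dataset(config.input_path)
        log.info("load: %d electrodes from %s", len(epochs), config.input_path)
    elif config.input_mode != "supplementary-mat":
        raise ValueError(f"unknown input mode {config.input_mode!r}")

    table = None
    if config.input_mode == "supplementary-mat":
        from gammatopo import supplementary as sup_mod
        if not config.input_path:
            raise ValueError("supplementary-mat mode requires input_path")
        cohorts = {}
        for p in str(config.input_path).split(","):
            cohorts.update(sup_mod.read_supplementary(p.strip()))
        if "selectivity" in stages:
            table, summary = sup_mod.reproduce_selectivity(cohorts, q=config.q)
            _write_tsv(table, out / "selectivity.tsv")
            (out / "selectivity_summary.json").write_text(
                json.dumps(summary, indent=2))
            register("selectivity", out / "selectivity.tsv")
            register("selectivity_summary", out / "selectivity_summary.json")
        if "topology" in stages:
            screen, coeffs = sup_mod.reproduce_topology(cohorts)
            _write_tsv(screen, out / "collinearity.tsv")
            _write_tsv(coeffs, out / "topology_coefficients.tsv")
            register("collinearity", out / "collinearity.tsv")
            register("topology_coefficients", out / "topology_coefficients.tsv")
    else:
        window_means = None
        bga_series = None
        if {"bga", "selectivity", "latency"} & set(stages):
            if epochs is None:
                raise ValueError("BGA stage requires a simulate/hdf5 input "
                                 "(missing upstream dataset artifact)")
            bga_series = {}
            window_means = {}
            for ep in epochs:
                series = bga_mod.extract_bga(
                    ep, band=config.gamma_band_hz, line_hz=config.line_hz,
                    baseline_window_s=config.baseline_window_s)
                bga_series[ep.electrode_id] = series
                labels = np.asarray(series.categories)[series.retained]
                window_means[ep.electrode_id] = (
                    bga_mod.window_mean_bga(series, config.analysis_window_s),
                    labels)
            log.info("bga: extracted %d electrodes", len(bga_series))
            if "bga" in stages:
                rows = []
                for eid, series in bga_series.items():
                    rows.append(pd.DataFrame({
                        "electrode": eid, "time_s": series.time_axis,
                        "mean_pct": series.trial_mean,
                        "sd_pct": series.trial_sd}))
                _write_tsv(pd.concat(rows, ignore_index=True),
                           out / "bga_mean_traces.tsv")
                register("bga_mean_traces", out / "bga_mean_traces.tsv")

        if "selectivity" in stages:
            table = sel_mod.selectivity_table(
                window_means, geometry, categories=list(sim_mod.CATEGORIES),
                n_perm=config.n_perm, q=config.q, seed=config.seed)
            log.info("selectivity: %d rows, %d flagged", len(table),
                     int(table["fdr_flag"].sum()))
            _write_tsv(table, out / "selectivity.tsv")
            register("selectivity", out / "selectivity.tsv")

        if "latency" in stages:
            if table is None:
                raise ValueError("latency stage requires the selectivity "
                                 "stage (missing upstream artifact)")
            lat_rows = []
            flagged = table[table["fdr_flag"]]
            for _, r in flagged.iterrows():
                series = bga_series[r["electrode"]]
                res = lat_mod.onset_latency(
                    series, r["category"], alpha=config.latency_alpha,
                    persistence_s=config.persistence_s)
                lat_rows.append({
                    "electrode": r["electrode"], "region": r["region"],
                    "hemisphere": r["hemisphere"], "category": r["category"],
                    "onset_ms": res.onset_latency_ms})
            lat_table = pd.DataFrame(
                lat_rows, columns=["electrode", "region", "hemisphere",
                                   "category", "onset_ms"])
            _write_tsv(lat_table, out / "latency.tsv")
            register("latency", out / "latency.tsv")
            if len(lat_table):
                summary, pairwise = lat_mod.latency_summary(lat_table)
                _write_tsv(summary, out / "latency_summary.tsv")
                register("latency_summary", out / "latency_summary.tsv")
                if len(pairwise):
                    _write_tsv(pairwise, out / "latency_pairwise.tsv")
                    register("latency_pairwise", out / "latency_pairwise.tsv")
            log.info("latency: %d onsets detected",
                     int(lat_table["onset_ms"].notna().sum()))

        if "topology" in stages:
            if table is None:
                raise ValueError("topology stage requires the selectivity "
                                 "stage (missing upstream artifact)")
            geo = table.drop_duplicates("electrode").set_index("electrode")[
                ["subject", "hemisphere", "region", "x", "y", "z"]]
            # correlations need >= 3 electrodes; drop (and log) smaller cells
            cell_n = geo.groupby(["region", "hemisphere"])["x"].transform("size")
            if (cell_n < 3).any():
                log.warning("dropping %d electrodes in cells with < 3 "
                            "electrodes from the collinearity screen",
                            int((cell_n < 3).sum()))
            screen = top_mod.collinearity_screen(geo[cell_n >= 3])
            fits = top_mod.fit_region_models(table)
            coeffs, counts = top_mod.topology_report(fits, table)
            _write_tsv(screen, out / "collinearity.tsv")
            _write_tsv(coeffs, out / "topology_coefficients.tsv")
            _write_tsv(counts, out / "topology_counts.tsv")
            register("collinearity", out / "collinearity.tsv")
            register("topology_coefficients", out / "topology_coefficients.tsv")
            register("topology_counts", out / "topology_counts.tsv")
            log.info("topology: %d models fitted", len(fits))

    (out / "config.yaml").write_text(config.to_yaml())
    register("config", out / "config.yaml")
    manifest = {name: {"path": str(p.name), "sha256": _sha256(p)}
                for name, p in artifacts.items()}
    man_path = out / "manifest.json"
    tmp = man_path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    tmp.replace(man_path)
    artifacts["manifest"] = man_path
    return artifacts
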