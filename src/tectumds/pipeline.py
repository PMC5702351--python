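"""Stage drivers tying generation, analysis and simulation into runs.

Each function takes a RunConfig, writes its outputs plus a manifest carrying
the config hash, and returns the written paths.  These are the programmatic
entry points behind both the command-line interface and the analysis
scripts.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth, tuning, population, circuit, io, plots
from .protocol import make_protocol

log = logging.getLogger("tectumds")

__all__ = ["RunConfig", "cmd_generate", "cmd_analyze", "cmd_fit_population", "cmd_simulate",
           "cmd_battery"]


@dataclass
class RunConfig:
    """Serializable configuration for one pipeline run."""

    out_dir: str = "results"
    seed: int = 0
    # generate
    counts: dict = field(default_factory=lambda: dict(synth.SIN_COUNTS))
    subtype_peaks: tuple = synth.SIN_PEAKS_DEG
    subtype_fwhm_deg: tuple = synth.SIN_FWHM_DEG
    spread_deg: float = 15.0
    snr: float = None  # None -> noiseless
    n_repeats: int = 1
    write_traces: bool = False
    # analyze
    responses_csv: str = None
    bin_width_deg: float = 10.0
    n_components: int = 3
    # simulate
    rgc_means_deg: tuple = circuit.DEFAULT_RGC_MEANS_DEG
    rgc_fwhm_deg: tuple = circuit.DEFAULT_RGC_FWHM_DEG
    refine: bool = True
    observed_pref_deg: float = circuit.OBSERVED_P2_PREF_DEG
    direction_grid_deg: float = 1.0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("subtype_peaks", "subtype_fwhm_deg", "rgc_means_deg", "rgc_fwhm_deg"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def _prep(config: RunConfig) -> Path:
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def cmd_generate(config: RunConfig):
    """Generate a synthetic population and write responses CSV + truth JSON."""
    out = _prep(config)
    protocol = make_protocol(seed=config.seed)
    cells = synth.sample_population(config.counts, subtype_peaks=config.subtype_peaks,
                                    spread_deg=config.spread_deg, seed=config.seed,
                                    subtype_fwhm_deg=config.subtype_fwhm_deg)
    if config.snr is not None:
        cells = synth.set_noise_from_snr(cells, protocol, config.snr)
    ds = synth.make_dataset(cells, protocol, seed=config.seed, n_repeats=config.n_repeats)
    paths = list(ds.write(out))
    if config.write_traces:
        trace_dir = out / "traces"
        trace_dir.mkdir(exist_ok=True)
        for i, cell in enumerate(cells):
            tr = synth.synth_trace(cell, protocol, seed=synth._cell_seed(config.seed, i))
            paths.append(io.write_trace_h5(tr, trace_dir / f"cell_{i:04d}.h5"))
    paths.append(io.write_manifest(out, config.to_dict(), paths[:2]))
    log.info("generated %d cells -> %s", len(cells), paths[0])
    return paths


def cmd_analyze(config: RunConfig):
    """Per-cell tuning analysis of a response table."""
    out = _prep(config)
    src = config.responses_csv or (Path(config.out_dir) / "synthetic_responses.csv")
    rvs = io.read_responses(src)
    log.info("analyzing %d cells (thresholds: DSI 0.5, OSI 0.5, R^2 0.7)", len(rvs))
    profiles = {cid: tuning.analyze_response_vector(rv) for cid, rv in rvs.items()}
    results_csv = out / "cell_results.csv"
    io.write_results(profiles, results_csv)
    paths = [results_csv, io.write_manifest(out, config.to_dict(), [results_csv])]
    return paths


def cmd_fit_population(config: RunConfig):
    """Histogram + mixture decomposition of DS preferred angles, with summaries."""
    out = _prep(config)
    results_csv = Path(config.out_dir) / "cell_results.csv"
    df = pd.read_csv(results_csv)
    ds = df[df.cell_class == "DS"]
    hist = population.build_histogram(ds.preferred_deg.to_numpy() % 360.0,
                                      config.bin_width_deg)
    fit = population.fit_mixture(hist, config.n_components)
    mixture_json = out / "mixture.json"
    io.write_mixture(fit, mixture_json)
    labels = population.assign_subtypes(ds.preferred_deg.to_numpy() % 360.0, fit)
    labeled = ds.assign(subtype=labels)
    labeled_csv = out / "subtypes.csv"
    labeled.to_csv(labeled_csv, index=False)

    src = config.responses_csv or (Path(config.out_dir) / "synthetic_responses.csv")
    paths = [mixture_json, labeled_csv]
    if Path(src).exists():
        rvs = io.read_responses(src)
        members = [rvs[cid] for cid in ds.cell_id]
        profiles = [tuning.analyze_response_vector(rv) for rv in members]
        summary = population.summarize_population(members, profiles, labels)
        paths.append(plots.polar_population(summary, out / "population_polar.png"))
    paths.append(io.write_manifest(out, config.to_dict(), paths))
    log.info("mixture fit R^2=%.3f, centers %s", fit.r_squared,
             [round(c.center_deg, 1) for c in fit.components])
    return paths


def cmd_simulate(config: RunConfig):
    """Intact-circuit tuning curves for all units."""
    out = _prep(config)
    spec = circuit.default_circuit(config.rgc_means_deg, config.rgc_fwhm_deg)
    if config.refine:
        spec = spec.with_kappas(circuit.refine_kappas(spec, config.observed_pref_deg))
    sim = circuit.SimulationConfig(direction_grid_deg=config.direction_grid_deg,
                                   seed=config.seed)
    curves = circuit.tuning_curves(spec, sim)
    rows = {"direction_deg": sim.direction_grid}
    rows.update({uid: c.response for uid, c in curves.items()})
    curves_csv = out / "tuning_curves.csv"
    pd.DataFrame(rows).to_csv(curves_csv, index=False)
    png = plots.polar_tuning(sim.direction_grid,
                             {uid: curves[uid].normalized for uid in ("P1", "P2", "P3", "P4")},
                             out / "pvn_tuning_polar.png", title="PVN tuning (intact)")
    paths = [curves_csv, png, io.write_manifest(out, config.to_dict(), [curves_csv])]
    return paths


def cmd_battery(config: RunConfig):
    """The five-perturbation battery for the emergent PVN population."""
    out = _prep(config)
    spec = circuit.default_circuit(config.rgc_means_deg, config.rgc_fwhm_deg)
    if config.refine:
        spec = spec.with_kappas(circuit.refine_kappas(spec, config.observed_pref_deg))
    sim = circuit.SimulationConfig(direction_grid_deg=config.direction_grid_deg,
                                   seed=config.seed)
    table = circuit.perturbation_battery(spec, sim, observed_pref_deg=config.observed_pref_deg)
    battery_csv = out / "battery.csv"
    table.to_csv(battery_csv, index=False)
    curves = {}
    for pert in circuit.BATTERY_PERTURBATIONS:
        w = circuit.perturbed_weights(spec, pert)
        curves[pert.label] = circuit.tuning_curves(spec, sim, weights=w)["P2"].normalized
    png = plots.polar_tuning(sim.direction_grid, curves, out / "battery_polar.png",
                             title="P2 under perturbations")
    paths = [battery_csv, png, io.write_manifest(out, config.to_dict(), [battery_csv])]
    log.info("battery:\n%s", table.to_string(index=False))
    return paths
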