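"""Config-driven orchestration of the AC-vs-IC comparison grid.

One run sweeps scenario x conductivity groups x {AC, IC} x amplitudes,
computes the lesion metrics per cell, pairs each AC cell with its IC
counterpart, aggregates the paired differences, and optionally runs the
thermal protocol at the lowest amplitude.  Scenario presets map the study's
ablation-strategy targets to fiber patterns: "ostium" (circumferential
fibers around a pulmonary-vein-like hole), "roof-line" (uniform oblique
fibers), "posterior-wall" (two crossing oblique bundles) — analogues of the
targets, not replicas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .conductivity import ANISOTROPY_GROUPS, ConductivityModel
from .electrostatics import SolverSettings, solve_potential
from .errors import ConfigError
from .fibers import FiberPattern, make_fiber_field
from .geometry import (ScenarioConfig, build_ostium_scenario,
                       build_slab_scenario)
from .materials import default_materials, load_materials
from .metrics import (AblationMetrics, aggregate_stats, compute_metrics,
                      paired_difference)
from .protocol import PulseProtocol
from .thermal import build_velocity_field, run_thermal_protocol

log = logging.getLogger("pfasim")

__all__ = ["RunConfig", "ComparisonReport", "run_comparison",
           "SCENARIO_PRESETS"]

#: ablation-strategy presets: (scenario kind, fiber pattern, pattern params)
SCENARIO_PRESETS = {
    "slab": ("slab", FiberPattern.UNIFORM, {}),
    "ostium": ("ostium", FiberPattern.CIRCUMFERENTIAL, {}),
    "roof-line": ("slab", FiberPattern.UNIFORM, {"theta": np.pi / 4}),
    "posterior-wall": ("slab", FiberPattern.CROSSING_BUNDLES, {}),
}


@dataclass
class RunConfig:
    scenario: ScenarioConfig = dc_field(default_factory=ScenarioConfig)
    preset: str = "slab"
    ostium_diameter: float = 8e-3
    groups: tuple = (1, 2, 3, 4)
    modes: tuple = ("AC", "IC")
    amplitudes: tuple = (1000.0, 1500.0, 2000.0)
    protocol: PulseProtocol = dc_field(default_factory=PulseProtocol)
    solver: SolverSettings = dc_field(default_factory=SolverSettings)
    thermal_enabled: bool = False
    thermal_mode: str = "GATED"
    thermal_groups: tuple = (4,)
    velocity_profile: str = "plug"
    blood_velocity: float = 0.1
    materials: dict = dc_field(default_factory=dict)
    output_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if not self.groups or not self.modes or not self.amplitudes:
            raise ConfigError("groups, modes and amplitudes must be non-empty")
        bad = set(self.groups) - set(ANISOTROPY_GROUPS)
        if bad:
            raise ConfigError(f"unknown conductivity groups {sorted(bad)}")
        if set(self.modes) - {"AC", "IC"}:
            raise ConfigError("modes must be a subset of {AC, IC}")
        if any(a <= 0 for a in self.amplitudes):
            raise ConfigError("amplitudes must be positive")
        if self.preset not in SCENARIO_PRESETS:
            raise ConfigError(f"unknown preset {self.preset!r}; choose from "
                              f"{sorted(SCENARIO_PRESETS)}")
        self.scenario.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        kw = {}
        if "scenario" in raw:
            kw["scenario"] = ScenarioConfig(**raw.pop("scenario"))
        if "protocol" in raw:
            kw["protocol"] = PulseProtocol(**raw.pop("protocol"))
        if "solver" in raw:
            kw["solver"] = SolverSettings(**raw.pop("solver"))
        for key in ("groups", "modes", "amplitudes", "thermal_groups"):
            if key in raw:
                kw[key] = tuple(raw.pop(key))
        unknown = set(raw) - {f.name for f in
                              cls.__dataclass_fields__.values()}
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        kw.update(raw)
        cfg = cls(**kw)
        cfg.validate()
        return cfg


@dataclass
class ComparisonReport:
    cells: pd.DataFrame          # one row per (group, mode, amplitude)
    pairs: pd.DataFrame          # AC-vs-IC differences per (group, amplitude)
    aggregates: pd.DataFrame     # mean +/- SD over groups per amplitude
    thermal: pd.DataFrame | None = None
    max_T_traces: dict = dc_field(default_factory=dict)

    def write(self, output_dir) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = "%.10g"
        self.cells.to_csv(out / "metrics.csv", index=False,
                          float_format=fmt)
        self.pairs.to_csv(out / "paired_differences.csv", index=False,
                          float_format=fmt)
        self.aggregates.to_csv(out / "aggregates.csv", index=False,
                               float_format=fmt)
        if self.thermal is not None:
            self.thermal.to_csv(out / "thermal.csv", index=False,
                                float_format=fmt)
        for name, trace in self.max_T_traces.items():
            pd.DataFrame(trace, columns=["t_s", "T_max_C"]).to_csv(
                out / f"max_T_{name}.csv", index=False, float_format=fmt)


def build_scenario(config: RunConfig):
    """Mesh + fiber field for the configured preset."""
    kind, pattern, params = SCENARIO_PRESETS[config.preset]
    scen = config.scenario
    if kind == "ostium":
        mesh = build_ostium_scenario(scen, config.ostium_diameter)
        params = dict(params)
        params.setdefault(
            "center",
            (0.0, config.ostium_diameter / 2 + scen.catheter_radius
             + 2 * scen.resolution))
    else:
        mesh = build_slab_scenario(scen)
    merged = {**params, **scen.pattern_params}
    fibers = make_fiber_field(mesh, pattern, merged)
    return mesh, fibers


def _metrics_row(group, mode, amplitude, sol, m: AblationMetrics) -> dict:
    return {"group": group, "mode": mode, "amplitude_V": amplitude,
            "area_mm2": m.surface_area, "volume_mm3": m.volume,
            "extent_x_mm": m.extent_x, "extent_y_mm": m.extent_y,
            "extent_z_mm": m.extent_z,
            "picard_iterations": sol.picard_iterations,
            "residual": sol.residual}


def run_comparison(config: RunConfig) -> ComparisonReport:
    """Run the full grid and assemble the comparison report.

    IC cells do not depend on the anisotropy group (the isotropic baseline is
    the same sigma_i for every group), so one IC solve per amplitude is
    reused across groups.
    """
    config.validate()
    materials = (load_materials(config.materials) if config.materials
                 else default_materials())
    mesh, fibers = build_scenario(config)
    log.info("scenario %s: %d cells, %d nodes", config.preset,
             mesh.n_elements, mesh.n_nodes)

    rows, cell_store = [], {}
    ic_cache = {}
    for amplitude in config.amplitudes:
        for group in config.groups:
            for mode in config.modes:
                if mode == "IC" and amplitude in ic_cache:
                    sol, m = ic_cache[amplitude]
                else:
                    model = ConductivityModel.from_group(group, mode)
                    log.info("solve group=%s mode=%s amplitude=%g",
                             group, mode, amplitude)
                    sol = solve_potential(mesh, fibers, model, amplitude,
                                          config.solver, materials)
                    m = compute_metrics(mesh, sol.e_mag,
                                        keep_isosurface=False)
                    if mode == "IC":
                        ic_cache[amplitude] = (sol, m)
                cell_store[(group, mode, amplitude)] = (sol, m)
                rows.append(_metrics_row(group, mode, amplitude, sol, m))
    cells = pd.DataFrame(rows)

    pair_rows = []
    if {"AC", "IC"} <= set(config.modes):
        for amplitude in config.amplitudes:
            for group in config.groups:
                _, mac = cell_store[(group, "AC", amplitude)]
                _, mic = cell_store[(group, "IC", amplitude)]
                d_vol = paired_difference(mac.volume, mic.volume, "volume")
                d_area = paired_difference(mac.surface_area,
                                           mic.surface_area, "area")
                row = {"group": group, "amplitude_V": amplitude,
                       "volume_percent": d_vol.percent,
                       "volume_significant": d_vol.significant,
                       "area_percent": d_area.percent,
                       "area_significant": d_area.significant}
                for axis in "xyz":
                    d_ext = paired_difference(
                        getattr(mac, f"extent_{axis}"),
                        getattr(mic, f"extent_{axis}"), "extent")
                    row[f"extent_{axis}_mm_diff"] = d_ext.absolute
                    row[f"extent_{axis}_significant"] = d_ext.significant
                pair_rows.append(row)
    pairs = pd.DataFrame(pair_rows)

    agg_rows = []
    if len(config.groups) >= 2 and not pairs.empty:
        for amplitude in config.amplitudes:
            sub = pairs[pairs.amplitude_V == amplitude]
            for col in ("volume_percent", "area_percent",
                        "extent_x_mm_diff", "extent_y_mm_diff",
                        "extent_z_mm_diff"):
                mean, sd = aggregate_stats(sub[col])
                agg_rows.append({"amplitude_V": amplitude, "metric": col,
                                 "mean": mean, "sd": sd})
    aggregates = pd.DataFrame(agg_rows)

    thermal_df, traces = None, {}
    if config.thermal_enabled:
        t_rows = []
        amplitude = min(config.amplitudes)
        vel = build_velocity_field(mesh, config.velocity_profile,
                                   config.blood_velocity)
        protocol = replace(config.protocol, amplitude=amplitude)
        for group in config.thermal_groups:
            maxes = {}
            for mode in config.modes:
                sol, _ = cell_store[(group, mode, amplitude)]
                state = run_thermal_protocol(mesh, sol, protocol, materials,
                                             velocity=vel,
                                             mode=config.thermal_mode)
                maxes[mode] = state.max_myocardial_T
                traces[f"group{group}_{mode}"] = state.max_T_trace
            row = {"group": group, "amplitude_V": amplitude, **{
                f"max_T_{m}_C": v for m, v in maxes.items()}}
            if {"AC", "IC"} <= maxes.keys():
                d = paired_difference(maxes["AC"], maxes["IC"], "temperature")
                row["diff_C"] = d.absolute
                row["significant"] = d.significant
            t_rows.append(row)
        thermal_df = pd.DataFrame(t_rows)

    report = ComparisonReport(cells=cells, pairs=pairs,
                              aggregates=aggregates, thermal=thermal_df,
                              max_T_traces=traces)
    if config.output_dir:
        report.write(config.output_dir)
    return report
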