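"""End-to-end pipeline commands tying the modules together.

Each command is a plain function taking a :class:`~lvmech.config.RunConfig`
and writing regenerable artifacts (CSV series, JSON summaries, VTK meshes)
under the config's output directory. The CLI in :mod:`lvmech.cli` is a thin
wrapper over these.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .fe import FEModel
from .fibers import assign_fibers
from .geometry import build_mesh, solve_geometry
from .inverse import InverseResult, identify_cycle, summarize
from .vtkio import write_vtk
from .waveforms import ActiveElastanceRule, CycleData, generate_cycle, load_cycle_csv

__all__ = [
    "build_model",
    "load_cycle",
    "cmd_make_waveforms",
    "cmd_build_model",
    "cmd_forward",
    "cmd_identify",
    "cmd_compare",
]

log = logging.getLogger("lvmech")


def load_cycle(config: RunConfig) -> CycleData:
    if config.cycle_csv:
        return load_cycle_csv(config.cycle_csv)
    rule = ActiveElastanceRule.for_peak_pressure(
        config.cycle.p_peak, config.materials.e_active_max
    )
    return generate_cycle(config.cycle, rule)


def build_model(config: RunConfig) -> FEModel:
    """Geometry -> mesh -> fibers -> assembled FE model from one config."""
    g = config.geometry
    geom = solve_geometry(g.cavity_volume, g.wall_volume, g.aspect_ratio,
                          g.truncation_fraction)
    mesh = build_mesh(geom, g.n_circ, g.n_long, g.n_layers, calibrate=g.calibrate)
    m = config.materials
    field = assign_fibers(mesh, vf_myo=m.vf_myo, vf_collagen=m.vf_collagen)
    return FEModel(
        mesh, field,
        ogden=config.ogden(),
        constituents=config.constituents(),
        bcs=config.bcs,
        vol_form=m.vol_form,
        active_fiber_law=m.active_fiber_law,
        collagen_fiber_law=m.collagen_fiber_law,
        settings=config.solver,
    )


def _outdir(config: RunConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def cmd_make_waveforms(config: RunConfig) -> CycleData:
    """Generate the cycle waveforms and write them as CSV."""
    cycle = load_cycle(config)
    out = _outdir(config)
    cycle.to_csv(out / "cycle.csv")
    log.info("wrote %s (%d samples)", out / "cycle.csv", len(cycle.t))
    return cycle


def cmd_build_model(config: RunConfig) -> FEModel:
    """Build the FE model and export mesh + fiber field as VTK."""
    model = build_model(config)
    out = _outdir(config)
    ff = model.fibers
    mesh = model.mesh
    # face-set membership as a point marker: 1 endo, 2 epi, 3 base
    marker = np.zeros(mesh.n_nodes)
    marker[np.unique(mesh.endo_faces)] = 1
    marker[np.unique(mesh.epi_faces)] = 2
    marker[np.unique(mesh.base_faces)] = 3
    write_vtk(
        out / "model.vtk",
        mesh,
        cell_data={
            "myofiber": ff.myofiber.mean(axis=1),
            "collagen": ff.collagen.mean(axis=1),
            "helix_angle_deg": ff.beta.mean(axis=1),
            "transverse_angle_deg": ff.eta.mean(axis=1),
        },
        point_data={"face_set": marker},
    )
    log.info("wrote %s (%d elements)", out / "model.vtk", model.mesh.n_elems)
    return model


def cmd_forward(config: RunConfig, K_schedule) -> pd.DataFrame:
    """Forward simulation under a prescribed bulk-modulus schedule.

    ``K_schedule`` is a scalar or an array matching the cycle samples.
    Returns and writes the resulting volume trace.
    """
    cycle = load_cycle(config)
    K = np.broadcast_to(np.asarray(K_schedule, dtype=float), cycle.t.shape)
    if np.any(K <= 0):
        raise ValueError("bulk-modulus schedule must be positive")
    model = build_model(config)
    state = model.preload(
        model.initial_state(), float(cycle.p[0]),
        n_ramp=config.inverse.n_ramp, K=float(K[0]), c_act=cycle.rule.c_act,
    )
    rows = []
    for i, (t, p, ea, k) in enumerate(zip(cycle.t, cycle.p, cycle.e_active, K)):
        state = model.solve_step(state, float(p), float(ea), float(k))
        rows.append({"t_s": t, "p_kPa": p, "K_kPa": k, "v_ml": state.volume,
                     "e_active_kPa": ea})
        log.info("forward t=%.3f p=%.3f K=%.4g V=%.3f", t, p, k, state.volume)
    df = pd.DataFrame(rows)
    out = _outdir(config)
    df.to_csv(out / "forward.csv", index=False)
    return df


def cmd_identify(config: RunConfig) -> tuple[InverseResult, dict]:
    """The main inverse experiment: identify K(t) over the cycle."""
    cycle = load_cycle(config)
    model = build_model(config)
    result = identify_cycle(model, cycle, config.inverse)
    summary = summarize(result)
    out = _outdir(config)
    result.to_csv(out / "identified.csv")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    log.info(
        "identified cycle: K_peak=%.4g kPa, max rel err=%.3g, %d flagged",
        summary["K_peak_kPa"], summary["max_rel_err"], summary["n_flagged"],
    )
    return result, summary


def cmd_compare(configs: list[RunConfig], output_dir: str | None = None) -> pd.DataFrame:
    """Cross-dataset table of peak bulk modulus vs ejection fraction."""
    rows = []
    for i, cfg in enumerate(configs):
        _, summary = cmd_identify(cfg)
        rows.append(
            {
                "dataset": i + 1,
                "K_peak_kPa": summary["K_peak_kPa"],
                "Ef_pct": summary["Ef_pct"],
                "SV_ml": summary["SV_ml"],
                "EDV_ml": summary["EDV_ml"],
                "ESV_ml": summary["ESV_ml"],
                "incompressible_fraction_pct": summary["incompressible_fraction_pct"],
            }
        )
    df = pd.DataFrame(rows)
    out = Path(output_dir or configs[0].output_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "k_peak_vs_ef.csv", index=False)
    return df
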