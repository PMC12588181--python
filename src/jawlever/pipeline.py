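"""End-to-end pipeline driver and report assembly.

Reads a YAML run configuration, resolves the model inputs (architecture
table plus either a 3D landmark geometry or a planar angle/lever table),
runs PCSA -> forces -> equilibrium -> gape sweep -> calibration ->
sensitivity, and writes a report bundle: full-precision CSV/JSON plus a
rounded human-readable text summary.  Reports are pure functions of
(inputs, configuration): rerunning an identical configuration reproduces
byte-identical JSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import reference
from .architecture import (
    ModelConstants,
    MuscleArchitecture,
    pcsa_table,
    read_architecture_csv,
)
from .calibration import fit_muscle_stress
from .equilibrium import (
    PlanarModel,
    mechanics_from_geometry,
    mechanics_table,
    read_planar_csv,
    total_bite_force,
)
from .errors import SchemaError
from .gape import sweep_gape
from .geometry import JawGeometry, read_landmarks_csv, read_landmarks_json
from .sensitivity import run_sensitivity
from .synthetic import generate_geometry, spec_from_planar


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (see :func:`load_run_config`)."""

    constants: ModelConstants = field(default_factory=ModelConstants)
    architecture: Path | None = None
    specimen: str | None = None
    geometry: Path | None = None
    planar: Path | None = None
    d_cbp: Mapping[str, float] = field(default_factory=dict)
    openers: tuple[str, ...] = ()
    bite_points: tuple[str, ...] = ()
    gape_step: float = 0.5
    max_gape: float = 60.0
    full_sweep: bool = False
    sweep: bool = True
    synthesize_geometry: bool = True
    origin_distance: float = reference.REFERENCE_ORIGIN_DISTANCE_MM
    f_alive: Mapping[str, float] = field(default_factory=dict)
    sensitivity_fraction: float = 0.05
    sensitivity_bite_point: str | None = None
    seed: int = 0
    output_dir: Path = Path("jawlever-out")


def load_run_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    path = Path(path)
    data = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: configuration must be a mapping")
    base = path.parent

    def _path(key: str) -> Path | None:
        v = data.get(key)
        if v is None:
            return None
        p = Path(v)
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise SchemaError(f"{path}: {key} file {p} does not exist")
        return p

    constants = ModelConstants(**(data.get("constants") or {}))
    gape_cfg = data.get("gape") or {}
    sens_cfg = data.get("sensitivity") or {}
    fraction = float(sens_cfg.get("fraction", 0.05))
    if not (0.0 < fraction < 1.0):
        raise SchemaError(f"{path}: sensitivity fraction must lie in (0, 1)")
    cfg = RunConfig(
        constants=constants,
        architecture=_path("architecture"),
        specimen=data.get("specimen"),
        geometry=_path("geometry"),
        planar=_path("planar"),
        d_cbp={str(k): float(v) for k, v in (data.get("d_cbp") or {}).items()},
        openers=tuple(data.get("openers") or ()),
        bite_points=tuple(data.get("bite_points") or ()),
        gape_step=float(gape_cfg.get("step", 0.5)),
        max_gape=float(gape_cfg.get("max_gape", 60.0)),
        full_sweep=bool(gape_cfg.get("full_sweep", False)),
        sweep=bool(gape_cfg.get("enabled", True)),
        synthesize_geometry=bool(data.get("synthesize_geometry", True)),
        origin_distance=float(
            data.get("origin_distance", reference.REFERENCE_ORIGIN_DISTANCE_MM)
        ),
        f_alive={str(k): float(v) for k, v in (data.get("f_alive") or {}).items()},
        sensitivity_fraction=fraction,
        sensitivity_bite_point=sens_cfg.get("bite_point"),
        seed=int(data.get("seed", 0)),
        output_dir=base / str(data.get("output_dir", "jawlever-out")),
    )
    if cfg.geometry is not None and cfg.planar is not None:
        raise SchemaError(f"{path}: give either 'geometry' or 'planar', not both")
    return cfg


def _resolve_inputs(
    cfg: RunConfig,
) -> tuple[list[MuscleArchitecture] | None, PlanarModel | None, JawGeometry | None]:
    """(architecture records, planar model, geometry) per the configuration."""
    arch = None
    if cfg.architecture is not None:
        arch = read_architecture_csv(cfg.architecture)
    elif cfg.specimen is not None:
        arch = reference.architecture_records(cfg.specimen)

    planar = None
    geom = None
    if cfg.geometry is not None:
        reader = (
            read_landmarks_json
            if cfg.geometry.suffix.lower() == ".json"
            else read_landmarks_csv
        )
        geom = reader(cfg.geometry)
        if arch is None:
            raise SchemaError(
                "a geometry run needs an architecture table ('architecture' "
                "path or 'specimen' label)"
            )
    elif cfg.planar is not None:
        if not cfg.d_cbp:
            raise SchemaError("planar input requires 'd_cbp' out-levers")
        planar = read_planar_csv(cfg.planar, cfg.d_cbp, cfg.openers)
    elif cfg.specimen == "M2851":
        # built-in worked example: published closed-mouth model table
        planar = reference.planar_model_m2851()
    if planar is not None and cfg.synthesize_geometry:
        geom = generate_geometry(
            spec_from_planar(
                planar, origin_distance=cfg.origin_distance, seed=cfg.seed
            )
        )
    if planar is None and geom is None:
        raise SchemaError(
            "no model input: provide 'geometry', 'planar', or specimen 'M2851'"
        )
    return arch, planar, geom


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Run every stage the configuration enables; write the report bundle.

    Returns the JSON-serialisable report dictionary.
    """
    arch, planar, geom = _resolve_inputs(cfg)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "constants": {
            "muscle_stress_N_cm2": cfg.constants.muscle_stress,
            "density_g_cm3": cfg.constants.density,
            "mass_correction": cfg.constants.mass_correction,
        },
        "seed": cfg.seed,
    }
    text: list[str] = ["jawlever pipeline report", "========================", ""]
    text.append(
        f"constants: muscle stress {cfg.constants.muscle_stress:g} N/cm2, "
        f"density {cfg.constants.density:g} g/cm3, "
        f"mass correction {cfg.constants.mass_correction:g}"
    )

    # --- architecture stage -------------------------------------------------
    if arch is not None:
        tab = pcsa_table(arch, cfg.constants)
        tab.to_csv(out / "pcsa.csv", index=False)
        report["pcsa"] = {
            r.muscle: {"pcsa_cm2": r.pcsa_cm2, "f3dmax_N": r.f3dmax_N}
            for r in tab.itertuples(index=False)
        }
        text += ["", "muscle architecture (PCSA, F3Dmax)",
                 _rounded(tab, {"pcsa_cm2": 4, "f3dmax_N": 3})]

    # --- per-muscle mechanics at closed mouth -------------------------------
    if geom is not None:
        muscles_src = (
            {pm.muscle: pm.f3dmax for pm in planar.muscles}
            if planar is not None
            else arch
        )
        mech = mechanics_from_geometry(geom, muscles_src, cfg.constants)
        bite_points = cfg.bite_points or tuple(geom.bite_points)
    else:
        mech = planar.mechanics()
        bite_points = cfg.bite_points or tuple(planar.d_cbp)
    mtab = mechanics_table(mech, bite_points)
    mtab.to_csv(out / "mechanics_closed.csv", index=False)
    text += ["", "per-muscle mechanics at closed mouth",
             _rounded(mtab, {c: 3 for c in mtab.columns if c != "muscle"} | {
                 "phi_deg": 2, "theta_deg": 2})]

    # --- bite force, gape sweep, calibration --------------------------------
    summary_rows = []
    report["bite_points"] = {}
    for bp in bite_points:
        entry: dict[str, Any] = {}
        closed = total_bite_force(mech, bp)
        entry["fcalc_closed_N"] = closed.total_force
        entry["excluded_openers"] = sorted(closed.excluded)
        f_opt = None
        if cfg.sweep and geom is not None:
            sw = sweep_gape(
                geom, muscles_src, cfg.constants, bp,
                step=cfg.gape_step, max_gape=cfg.max_gape,
                full_sweep=cfg.full_sweep,
            )
            sw.to_frame().to_csv(out / f"sweep_{bp}.csv", index=False)
            entry["optimal_gape_deg"] = sw.optimal_gape
            entry["fcalc_optimal_N"] = sw.optimal_force
            f_opt = sw.optimal_force
        if bp in cfg.f_alive:
            f_ref = f_opt if f_opt is not None else closed.total_force
            cal = fit_muscle_stress(
                cfg.f_alive[bp], f_ref, cfg.constants.muscle_stress, bite_point=bp
            )
            entry["f_alive_N"] = cal.f_alive
            entry["fitted_stress_N_cm2"] = cal.fitted_stress
        report["bite_points"][bp] = entry
        summary_rows.append({"bite_point": bp, **entry})
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "bite_forces.csv", index=False)
    text += ["", "bite forces", _rounded(summary, {
        c: 3 for c in summary.columns
        if c not in ("bite_point", "excluded_openers", "optimal_gape_deg")
    } | {"optimal_gape_deg": 2})]

    # --- sensitivity --------------------------------------------------------
    sens_bp = cfg.sensitivity_bite_point
    if sens_bp is None and bite_points:
        sens_bp = bite_points[-1]
    if sens_bp is not None:
        sens_model = planar if planar is not None else _planarise(mech, geom, bite_points)
        sens = run_sensitivity(
            sens_model, sens_bp, gape=0.0, fraction=cfg.sensitivity_fraction
        )
        frame = sens.to_frame()
        frame.to_csv(out / "sensitivity.csv")
        report["sensitivity"] = {
            "bite_point": sens_bp,
            "fraction": cfg.sensitivity_fraction,
            "baseline_force_N": sens.baseline_force,
            "top3_by_mass": list(sens.top_muscles("mass", 3)),
            "entries_pct": {
                f"{m}:{p}:{d}": (None if math.isnan(v) else v)
                for (m, p, d), v in sens.entries.items()
            },
        }
        text += ["", f"sensitivity at bite point {sens_bp} "
                     f"(+/-{cfg.sensitivity_fraction:.0%} one-at-a-time)",
                 frame.round(2).to_string()]

    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    (out / "report.txt").write_text("\n".join(text) + "\n", encoding="utf-8")
    return report


def _planarise(mech, geom, bite_points) -> PlanarModel:
    """Planar view of geometry-derived mechanics (for sensitivity)."""
    from .equilibrium import PlanarMuscle
    from .geometry import distance_to_bite_point

    muscles = tuple(
        PlanarMuscle(
            muscle=m.muscle, f3dmax=m.f3dmax, phi=m.action.phi,
            theta=m.action.theta, lever=m.action.lever,
        )
        for m in mech
    )
    openers = frozenset(m.muscle for m in mech if not m.is_closer)
    d_cbp = {bp: distance_to_bite_point(geom, bp) for bp in bite_points}
    return PlanarModel(muscles=muscles, d_cbp=d_cbp, openers=openers)


def _rounded(df: pd.DataFrame, decimals: Mapping[str, int]) -> str:
    shown = df.copy()
    for col, nd in decimals.items():
        if col in shown.columns:
            shown[col] = shown[col].map(
                lambda v, nd=nd: round(v, nd) if isinstance(v, float) else v
            )
    return shown.to_string(index=False)
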