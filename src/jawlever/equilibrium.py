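"""Static moment equilibrium about the condyle and bilateral bite force.

Pipeline per muscle i (all at a fixed gape):

1. ``F2Dmax_i = F3Dmax_i * sin(phi_i)`` — discard the mediolateral force
   component (it cancels between the two sides and exerts no moment about
   the mediolateral rotation axis);
2. ``R_i = D_IC_i * sin(theta_i) * F2Dmax_i / D_CBP`` — the share of the
   muscle's moment about the condyle delivered at the bite point (in-lever
   times sagittal force component perpendicular to it, divided by the
   out-lever);
3. ``Fcalc = 2 * sum_i R_i`` over jaw-closing muscles only — both sides of
   the head contract symmetrically; muscles whose moment opens the jaw
   (identified by sign, not by name) are excluded and reported as such.

Two input pathways build the per-muscle mechanics: from a 3D landmark
geometry (angles re-derived from coordinates), or "planar" mode from
tabulated (F3Dmax, phi, theta, lever) values when no coordinates exist —
the form in which published model tables come.  Planar mode cannot compute
moment signs, so openers are declared explicitly there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .architecture import (
    ModelConstants,
    MuscleArchitecture,
    compute_f3dmax,
)
from .errors import InvalidInputError, ModelError, SchemaError
from .geometry import ActionLine, JawGeometry, derive_action_line, distance_to_bite_point

#: Bilateral symmetry factor: both sides of the head bite simultaneously.
BILATERAL_FACTOR = 2.0


def project_to_sagittal(f3dmax: float, phi: float) -> float:
    """Sagittal (2D) force component: ``F3Dmax * sin(phi)`` in N.

    Algebraically identical to subtracting the squared mediolateral
    component under the root, ``sqrt(F3D^2 - (F3D*cos(phi))^2)``.
    """
    if not (f3dmax >= 0):
        raise InvalidInputError(f"f3dmax must be >= 0 N, got {f3dmax!r}")
    if not (0.0 <= phi <= 180.0):
        raise InvalidInputError(f"phi must lie in [0, 180] deg, got {phi!r}")
    return f3dmax * math.sin(math.radians(phi))


def resultant_at_bite_point(
    f2dmax: float, theta: float, lever: float, d_cbp: float
) -> float:
    """Force (N) delivered at the bite point by one muscle's moment.

    ``R = D_IC * sin(theta) * F2Dmax / D_CBP``; lever and out-lever share
    units (mm), so the ratio is dimensionless.
    """
    if not (d_cbp > 0):
        raise InvalidInputError(f"out-lever d_cbp must be > 0 mm, got {d_cbp!r}")
    if not (lever >= 0):
        raise InvalidInputError(f"lever must be >= 0 mm, got {lever!r}")
    return lever * math.sin(math.radians(theta)) * f2dmax / d_cbp


@dataclass(frozen=True)
class MuscleMechanics:
    """All per-muscle derived quantities at one jaw configuration."""

    muscle: str
    f3dmax: float
    f2dmax: float
    action: ActionLine
    resultants: Mapping[str, float]
    moment_sign: int

    @property
    def is_closer(self) -> bool:
        return self.moment_sign < 0


@dataclass(frozen=True)
class BiteForceResult:
    """Bilateral bite force at one bite point and gape."""

    bite_point: str
    gape: float
    total_force: float
    per_muscle: Mapping[str, float]
    excluded: tuple[str, ...]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        excl = ", ".join(self.excluded) if self.excluded else "none"
        return (
            f"Fcalc({self.bite_point}) = {self.total_force:.3f} N "
            f"at gape {self.gape:g} deg (excluded openers: {excl})"
        )


ForceSource = Sequence[MuscleArchitecture] | Mapping[str, float]


def _resolve_forces(
    muscles: ForceSource, constants: ModelConstants | None
) -> tuple[dict[str, float], dict[str, str]]:
    """Per-muscle F3Dmax and anatomical roles from either input form."""
    if isinstance(muscles, Mapping):
        return {str(k): float(v) for k, v in muscles.items()}, {}
    if constants is None:
        raise InvalidInputError(
            "constants are required to derive forces from architecture records"
        )
    forces = {a.name: compute_f3dmax(a, constants) for a in muscles}
    roles = {a.name: a.role for a in muscles}
    return forces, roles


def mechanics_from_geometry(
    geom: JawGeometry,
    muscles: ForceSource,
    constants: ModelConstants | None = None,
    bite_points: Sequence[str] | None = None,
) -> list[MuscleMechanics]:
    """Per-muscle mechanics from landmarks + muscle forces.

    ``muscles`` is either a sequence of :class:`MuscleArchitecture`
    (F3Dmax computed from mass and fibre length via ``constants``) or a
    ready mapping ``muscle -> F3Dmax`` in N.  Muscles whose architecture
    ``role`` is ``"opener"`` (e.g. the digastric) keep an opening moment
    sign regardless of geometry, so they appear in the exclusion report
    rather than silently vanishing.  Muscles absent from the geometry
    raise ``KeyError``.
    """
    if bite_points is None:
        bite_points = tuple(geom.bite_points)
    forces, roles = _resolve_forces(muscles, constants)
    out = []
    for name, f3d in forces.items():
        line = derive_action_line(geom, name)
        sign = 1 if roles.get(name) == "opener" else line.moment_sign
        f2d = project_to_sagittal(f3d, line.phi)
        resultants = {
            bp: resultant_at_bite_point(
                f2d, line.theta, line.lever, distance_to_bite_point(geom, bp)
            )
            for bp in bite_points
        }
        out.append(
            MuscleMechanics(
                muscle=name,
                f3dmax=f3d,
                f2dmax=f2d,
                action=line,
                resultants=resultants,
                moment_sign=sign,
            )
        )
    return out


def total_bite_force(
    mechanics: Iterable[MuscleMechanics], bite_point: str
) -> BiteForceResult:
    """Bilateral bite force: double the summed resultants of the closers.

    Muscles with an opening (or zero) moment are excluded from the sum and
    listed in ``excluded``; an empty closer set is a model error.
    """
    mechanics = list(mechanics)
    per_muscle: dict[str, float] = {}
    excluded: list[str] = []
    gape = None
    for mech in mechanics:
        if bite_point not in mech.resultants:
            raise KeyError(
                f"muscle {mech.muscle!r} has no resultant for bite point "
                f"{bite_point!r}"
            )
        if mech.is_closer:
            per_muscle[mech.muscle] = mech.resultants[bite_point]
        else:
            excluded.append(mech.muscle)
    if not per_muscle:
        raise ModelError(
            f"no jaw-closing muscle contributes at bite point {bite_point!r}"
        )
    total = BILATERAL_FACTOR * sum(per_muscle.values())
    return BiteForceResult(
        bite_point=bite_point,
        gape=0.0,
        total_force=total,
        per_muscle=per_muscle,
        excluded=tuple(excluded),
    )


def bite_force_from_geometry(
    geom: JawGeometry,
    muscles: ForceSource,
    constants: ModelConstants | None,
    bite_point: str,
) -> BiteForceResult:
    """Convenience: mechanics + summation in one call, tagged with the gape."""
    mech = mechanics_from_geometry(geom, muscles, constants, (bite_point,))
    res = total_bite_force(mech, bite_point)
    return replace(res, gape=geom.gape)


# ---------------------------------------------------------------------------
# Planar (geometry-free) mode


@dataclass(frozen=True)
class PlanarMuscle:
    """Tabulated per-muscle inputs when no landmark coordinates exist."""

    muscle: str
    f3dmax: float
    phi: float
    theta: float
    lever: float

    def __post_init__(self) -> None:
        if not (self.f3dmax >= 0):
            raise InvalidInputError(
                f"muscle {self.muscle!r}: f3dmax must be >= 0 N"
            )
        for name, hi in (("phi", 180.0), ("theta", 180.0)):
            v = getattr(self, name)
            if not (0.0 <= v <= hi):
                raise InvalidInputError(
                    f"muscle {self.muscle!r}: {name} must lie in [0, {hi:g}] deg, "
                    f"got {v!r}"
                )
        if not (self.lever >= 0):
            raise InvalidInputError(f"muscle {self.muscle!r}: lever must be >= 0 mm")


@dataclass(frozen=True)
class PlanarModel:
    """A full geometry-free model: muscles + out-levers + declared openers.

    ``d_cbp`` maps each bite-point label to its out-lever (mm).  ``openers``
    lists muscles excluded from bite-force summation; in this mode moment
    signs cannot be computed from coordinates, so exclusion is declarative.
    Gape rotation is unavailable (it needs coordinates).
    """

    muscles: tuple[PlanarMuscle, ...]
    d_cbp: Mapping[str, float]
    openers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        names = [m.muscle for m in self.muscles]
        if len(set(names)) != len(names):
            raise InvalidInputError("duplicate muscle labels in planar model")
        for bp, d in self.d_cbp.items():
            if not (d > 0):
                raise InvalidInputError(
                    f"bite point {bp!r}: out-lever must be > 0 mm, got {d!r}"
                )
        unknown = self.openers - set(names)
        if unknown:
            raise InvalidInputError(f"declared opener(s) not in model: {sorted(unknown)}")

    def mechanics(self) -> list[MuscleMechanics]:
        out = []
        for pm in self.muscles:
            sign = 1 if pm.muscle in self.openers else -1
            f2d = project_to_sagittal(pm.f3dmax, pm.phi)
            resultants = {
                bp: resultant_at_bite_point(f2d, pm.theta, pm.lever, d)
                for bp, d in self.d_cbp.items()
            }
            line = ActionLine(pm.muscle, pm.phi, pm.theta, pm.lever, sign)
            out.append(
                MuscleMechanics(pm.muscle, pm.f3dmax, f2d, line, resultants, sign)
            )
        return out

    def bite_force(self, bite_point: str) -> BiteForceResult:
        return total_bite_force(self.mechanics(), bite_point)


def read_planar_csv(
    path: str | Path,
    d_cbp: Mapping[str, float],
    openers: Iterable[str] = (),
) -> PlanarModel:
    """Read planar inputs ``muscle,f3dmax_N,phi_deg,theta_deg,lever_mm``.

    Out-levers per bite point are scalars supplied alongside (typically
    from the run configuration), not rows of this table.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover
        raise SchemaError(f"{path}: cannot parse CSV: {exc}") from exc
    required = ("muscle", "f3dmax_N", "phi_deg", "theta_deg", "lever_mm")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    muscles = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            muscles.append(
                PlanarMuscle(
                    muscle=str(row.muscle),
                    f3dmax=float(row.f3dmax_N),
                    phi=float(row.phi_deg),
                    theta=float(row.theta_deg),
                    lever=float(row.lever_mm),
                )
            )
        except (InvalidInputError, TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from exc
    try:
        return PlanarModel(tuple(muscles), dict(d_cbp), frozenset(openers))
    except InvalidInputError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def mechanics_table(
    mechanics: Iterable[MuscleMechanics], bite_points: Sequence[str] | None = None
) -> pd.DataFrame:
    """Model-summary table: F3Dmax, phi, F2Dmax, theta and R per bite point."""
    mechanics = list(mechanics)
    if bite_points is None:
        seen: list[str] = []
        for m in mechanics:
            for bp in m.resultants:
                if bp not in seen:
                    seen.append(bp)
        bite_points = seen
    rows = []
    for m in mechanics:
        row = {
            "muscle": m.muscle,
            "f3dmax_N": m.f3dmax,
            "phi_deg": m.action.phi,
            "f2dmax_N": m.f2dmax,
            "theta_deg": m.action.theta,
            "lever_mm": m.action.lever,
            "moment_sign": m.moment_sign,
        }
        for bp in bite_points:
            row[f"r_{bp}_N"] = m.resultants.get(bp, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)
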