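"""Calibration of muscle stress (specific tension) against in vivo bite force.

The whole model chain is linear in the specific tension F_MS: doubling the
stress doubles every muscle force and hence the calculated bite force.  The
stress that makes the model reproduce a measured in vivo force therefore
has the closed form

    FMS* = FMS_ref * Falive / Fcalc(FMS_ref).

An iterative mode is also provided that mimics the operational procedure —
increase or decrease the stress and re-evaluate the model until calculated
and measured forces agree — implemented as a bisection on the stress; by
linearity it converges to the same answer and serves as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .architecture import ModelConstants
from .equilibrium import ForceSource
from .errors import InvalidInputError, ModelError
from .gape import sweep_gape
from .geometry import JawGeometry

#: Bisection bracket for the fitted stress, N/cm^2.
STRESS_BRACKET = (0.1, 200.0)
#: Absolute force tolerance (N) at which the iterative fit stops.
FORCE_TOL = 1e-3


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted specific tension matching the model to an in vivo force."""

    bite_point: str
    f_alive: float
    f_calc_ref: float
    fitted_stress: float
    reference_stress: float = 30.0

    @property
    def scale(self) -> float:
        """Multiplier applied to the reference stress."""
        return self.fitted_stress / self.reference_stress


def fit_muscle_stress(
    f_alive: float,
    f_calc_ref: float,
    reference_stress: float = 30.0,
    bite_point: str = "",
    method: str = "closed_form",
) -> CalibrationResult:
    """Fit F_MS so the model matches ``f_alive``.

    ``f_calc_ref`` is the model's bite force evaluated at
    ``reference_stress`` (conventionally at the optimal gape).
    ``method`` is ``"closed_form"`` (exact, via linearity) or
    ``"bisection"`` (iterative increase/decrease loop; agrees to
    :data:`FORCE_TOL`).
    """
    if not (f_alive > 0):
        raise InvalidInputError(f"f_alive must be > 0 N, got {f_alive!r}")
    if not (f_calc_ref > 0):
        raise InvalidInputError(f"f_calc_ref must be > 0 N, got {f_calc_ref!r}")
    if not (reference_stress > 0):
        raise InvalidInputError(
            f"reference_stress must be > 0 N/cm^2, got {reference_stress!r}"
        )

    if method == "closed_form":
        fitted = reference_stress * f_alive / f_calc_ref
    elif method == "bisection":
        fitted = _bisect_stress(
            lambda s: f_calc_ref * s / reference_stress, f_alive
        )
    else:
        raise InvalidInputError(
            f"method must be 'closed_form' or 'bisection', got {method!r}"
        )
    return CalibrationResult(
        bite_point=bite_point,
        f_alive=f_alive,
        f_calc_ref=f_calc_ref,
        fitted_stress=fitted,
        reference_stress=reference_stress,
    )


def _bisect_stress(
    fcalc_of_stress: Callable[[float], float],
    f_alive: float,
    bracket: tuple[float, float] = STRESS_BRACKET,
    tol: float = FORCE_TOL,
    max_iter: int = 200,
) -> float:
    """Bisection on the stress until |Fcalc - Falive| <= tol.

    ``fcalc_of_stress`` must be increasing in the stress (it is, the model
    being linear with positive slope).
    """
    lo, hi = bracket
    f_lo = fcalc_of_stress(lo) - f_alive
    f_hi = fcalc_of_stress(hi) - f_alive
    if f_lo > 0 or f_hi < 0:
        raise ModelError(
            f"in vivo force {f_alive:g} N is outside the reachable range "
            f"[{fcalc_of_stress(lo):g}, {fcalc_of_stress(hi):g}] N for stresses "
            f"in {bracket}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        resid = fcalc_of_stress(mid) - f_alive
        if abs(resid) <= tol:
            return mid
        if resid < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)  # pragma: no cover - tol always reached first


def calibrate_geometry(
    geom: JawGeometry,
    muscles: ForceSource,
    constants: ModelConstants,
    bite_point: str,
    f_alive: float,
    at_optimal_gape: bool = True,
    step: float = 0.5,
    max_gape: float = 60.0,
    full_sweep: bool = False,
    method: str = "closed_form",
) -> tuple[CalibrationResult, float]:
    """End-to-end calibration from a landmark geometry.

    Runs the gape sweep at the reference stress, takes the model force at
    the optimal gape (or at the current gape if ``at_optimal_gape`` is
    False) and fits the stress.  Returns the calibration record and the
    gape at which it was performed.
    """
    if at_optimal_gape:
        sweep = sweep_gape(
            geom, muscles, constants, bite_point,
            step=step, max_gape=max_gape, full_sweep=full_sweep,
        )
        f_ref, gape = sweep.optimal_force, sweep.optimal_gape
    else:
        from .equilibrium import bite_force_from_geometry

        res = bite_force_from_geometry(geom, muscles, constants, bite_point)
        f_ref, gape = res.total_force, geom.gape
    result = fit_muscle_stress(
        f_alive, f_ref, constants.muscle_stress, bite_point=bite_point,
        method=method,
    )
    return result, gape
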