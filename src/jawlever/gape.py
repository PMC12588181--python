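"""Gape sweep: bite force as a function of jaw opening angle.

Opening the jaw rotates the mandibular landmarks about the condyle, which
changes every muscle's action line (phi, theta) and lever geometry while
leaving its architecture-derived F3Dmax untouched (no force-length effect
is modelled).  Sweeping the opening angle in small steps and recomputing
the equilibrium at each step traces a force-gape profile; the optimal gape
is the opening at which the calculated bite force peaks.

By default the sweep stops at the first decrease of the force — the
classical stopping rule, valid for unimodal profiles — and reports the
angle just before the drop.  ``full_sweep=True`` scans all the way to
``max_gape`` and takes the global argmax, guarding against local maxima.
"""

from __future__ import annotations

from dataclasses import dataclass
import pandas as pd

from .architecture import ModelConstants
from .equilibrium import ForceSource, bite_force_from_geometry
from .errors import InvalidInputError
from .geometry import JawGeometry, rotate_mandible


@dataclass(frozen=True)
class GapeSweepResult:
    """Force-gape profile and its optimum for one bite point."""

    bite_point: str
    step: float
    profile: tuple[tuple[float, float], ...]  # (gape deg, Fcalc N)
    optimal_gape: float
    optimal_force: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.profile, columns=["gape_deg", "fcalc_N"])


def sweep_gape(
    geom: JawGeometry,
    muscles: ForceSource,
    constants: ModelConstants | None,
    bite_point: str,
    step: float = 0.5,
    max_gape: float = 60.0,
    full_sweep: bool = False,
) -> GapeSweepResult:
    """Sweep gape from the current opening in ``step``-degree increments.

    At each step the mandible is rotated once more by ``step`` about the
    condyle and the whole equilibrium (action lines, projections, moment
    sum) is recomputed.  The optimum reported is the smallest gape
    attaining the maximal force (deterministic tie-break on plateaus).
    """
    if not (step > 0):
        raise InvalidInputError(f"step must be > 0 deg, got {step!r}")
    if not (max_gape >= step):
        raise InvalidInputError(
            f"max_gape ({max_gape!r}) must be at least one step ({step!r})"
        )

    profile: list[tuple[float, float]] = []
    current = geom
    prev_force = None
    # walk in exact multiples of step to avoid float drift in the gape axis
    n_steps = int(round((max_gape - geom.gape) / step))
    for k in range(n_steps + 1):
        gape = geom.gape + k * step
        if k > 0:
            current = rotate_mandible(current, step)
        force = bite_force_from_geometry(
            current, muscles, constants, bite_point
        ).total_force
        profile.append((gape, force))
        if not full_sweep and prev_force is not None and force < prev_force:
            break  # first decrease: peak was the previous gape
        prev_force = force

    best_gape, best_force = profile[0]
    for gape, force in profile[1:]:
        if force > best_force:
            best_gape, best_force = gape, force
    return GapeSweepResult(
        bite_point=bite_point,
        step=step,
        profile=tuple(profile),
        optimal_gape=best_gape,
        optimal_force=best_force,
    )
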