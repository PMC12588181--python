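"""One-at-a-time parameter sensitivity of the calculated bite force.

Each of the six per-muscle model parameters — in-lever D_IC, angle theta,
muscle mass MM, fibre length FL, angle phi, and the out-lever D_CBP as it
enters that muscle's term — is scaled by (1 +/- fraction) for one muscle at
a time, the bite force is recomputed, and the percent change is recorded.

Because the model is a sum of per-muscle terms, parameters that enter a
term as a pure factor (lever, mass) shift the total by exactly
+/- fraction times that muscle's force share; pure denominators (fibre
length, per-muscle out-lever) shift it by the share times (1/(1 -/+ f) - 1),
which is why those two columns of a sensitivity table are always
identical.  Angles act through sin(), so their effect depends on where on
the sine curve the muscle sits and can flip sign past 90 degrees.

Mass and fibre length act on F3Dmax multiplicatively (F3Dmax is
proportional to MM/FL), so the analysis runs on the geometry-free planar
model without needing the raw architecture table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .equilibrium import (
    PlanarModel,
    PlanarMuscle,
    project_to_sagittal,
    resultant_at_bite_point,
)
from .errors import InvalidInputError

#: The six perturbable per-muscle parameters.
PARAMETERS = ("lever", "theta", "mass", "fibre_length", "phi", "d_cbp")
DIRECTIONS = ("-", "+")


@dataclass(frozen=True)
class SensitivityTable:
    """Percent change of Fcalc for every (muscle, parameter, direction).

    ``entries[(muscle, parameter, direction)]`` is
    ``100 * (Fcalc' - Fcalc) / Fcalc``; ``direction`` is ``"-"`` or
    ``"+"``.  Perturbations that push an angle out of its [0, 180] degree
    domain are flagged (entry NaN, reason in ``flags``) rather than raised.
    """

    bite_point: str
    gape: float
    fraction: float
    baseline_force: float
    entries: Mapping[tuple[str, str, str], float]
    flags: Mapping[tuple[str, str, str], str]

    def to_frame(self) -> pd.DataFrame:
        """Rows = muscles, columns = (parameter, direction)."""
        muscles = []
        for m, _, _ in self.entries:
            if m not in muscles:
                muscles.append(m)
        cols = pd.MultiIndex.from_tuples(
            [(p, f"{d}{self.fraction:.0%}") for p in PARAMETERS for d in DIRECTIONS],
            names=["parameter", "direction"],
        )
        data = [
            [self.entries[(m, p, d)] for p in PARAMETERS for d in DIRECTIONS]
            for m in muscles
        ]
        return pd.DataFrame(data, index=pd.Index(muscles, name="muscle"), columns=cols)

    def top_muscles(self, parameter: str = "mass", n: int = 3) -> tuple[str, ...]:
        """Muscles ranked by |percent change| for one parameter (+ direction)."""
        scored = sorted(
            (
                (abs(v), m)
                for (m, p, d), v in self.entries.items()
                if p == parameter and d == "+" and not math.isnan(v)
            ),
            reverse=True,
        )
        return tuple(m for _, m in scored[:n])


def _perturbed_term(
    pm: PlanarMuscle, d_cbp: float, parameter: str, factor: float
) -> float | None:
    """One muscle's resultant with one parameter scaled; None if invalid."""
    f3d, phi, theta, lever, d = pm.f3dmax, pm.phi, pm.theta, pm.lever, d_cbp
    if parameter == "lever":
        lever *= factor
    elif parameter == "theta":
        theta *= factor
    elif parameter == "mass":
        f3d *= factor  # F3Dmax proportional to mass
    elif parameter == "fibre_length":
        f3d /= factor  # F3Dmax inversely proportional to fibre length
    elif parameter == "phi":
        phi *= factor
    elif parameter == "d_cbp":
        d *= factor  # scaled only within this muscle's term
    else:
        raise InvalidInputError(
            f"unknown parameter {parameter!r}; expected one of {PARAMETERS}"
        )
    if not (0.0 <= phi <= 180.0) or not (0.0 <= theta <= 180.0):
        return None
    return resultant_at_bite_point(project_to_sagittal(f3d, phi), theta, lever, d)


def run_sensitivity(
    model: PlanarModel,
    bite_point: str,
    gape: float = 0.0,
    fraction: float = 0.05,
) -> SensitivityTable:
    """Full one-at-a-time sensitivity table at one jaw configuration.

    ``model`` is the planar model at the configuration of interest (build
    it from a rotated geometry to evaluate at an open gape); openers are
    excluded both from the baseline and from the rows.
    """
    if not (0.0 < fraction < 1.0):
        raise InvalidInputError(f"fraction must lie in (0, 1), got {fraction!r}")
    baseline = model.bite_force(bite_point)
    f0 = baseline.total_force
    d_cbp = model.d_cbp[bite_point]

    entries: dict[tuple[str, str, str], float] = {}
    flags: dict[tuple[str, str, str], str] = {}
    closers = [pm for pm in model.muscles if pm.muscle not in model.openers]
    for pm in closers:
        base_term = resultant_at_bite_point(
            project_to_sagittal(pm.f3dmax, pm.phi), pm.theta, pm.lever, d_cbp
        )
        for parameter in PARAMETERS:
            for direction, factor in zip(DIRECTIONS, (1 - fraction, 1 + fraction)):
                key = (pm.muscle, parameter, direction)
                term = _perturbed_term(pm, d_cbp, parameter, factor)
                if term is None:
                    entries[key] = float("nan")
                    flags[key] = (
                        f"{parameter} x {factor:g} leaves the [0, 180] degree domain"
                    )
                    continue
                # only this muscle's term changes; the factor 2 cancels in
                # the ratio but is kept for clarity
                f_new = f0 + 2.0 * (term - base_term)
                entries[key] = 100.0 * (f_new - f0) / f0
    return SensitivityTable(
        bite_point=bite_point,
        gape=gape,
        fraction=fraction,
        baseline_force=f0,
        entries=entries,
        flags=flags,
    )
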