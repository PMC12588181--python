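"""Synthetic specimens: landmark geometries and architecture tables.

No landmark coordinates are ever published alongside jaw-model tables —
only the derived angles and force columns.  This module inverts that
derivation: given per-muscle targets (phi, theta, in-lever) and out-levers
per bite point, it constructs an explicit 3D landmark set whose derived
action lines reproduce the targets exactly (at zero noise), so every
downstream stage — rotation, equilibrium, gape sweep, calibration — can be
exercised and round-trip-tested without a real specimen.

Construction: each insertion centroid is placed in the sagittal plane at
its in-lever distance anterior to the condyle.  The sagittal action
direction is the in-lever direction rotated by theta — towards closing for
closers, towards opening for declared openers — and the mediolateral
component is then set by phi.  The origin is placed a fixed distance along
that unit vector (the distance is unconstrained by the model: only the
direction enters).  Landmark noise, when requested, jitters every
non-condyle landmark with isotropic Gaussian noise whose standard
deviation is ``noise_sd`` times the geometry scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .architecture import DEFAULT_ROSTER
from .errors import InvalidInputError
from .geometry import JawGeometry


@dataclass(frozen=True)
class MuscleTarget:
    """Prescribed action-line values for one synthetic muscle."""

    phi: float
    theta: float
    lever: float
    opener: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.phi < 180.0):
            raise InvalidInputError(
                f"target phi must lie in (0, 180) deg, got {self.phi!r}"
            )
        if not (0.0 < self.theta < 180.0):
            raise InvalidInputError(
                f"target theta must lie in (0, 180) deg, got {self.theta!r}"
            )
        if not (self.lever > 0):
            raise InvalidInputError(
                f"target lever must be > 0 mm (theta is undefined on a zero "
                f"lever), got {self.lever!r}"
            )


@dataclass(frozen=True)
class GeometrySpec:
    """Recipe for a synthetic jaw geometry.

    ``muscles`` maps labels to :class:`MuscleTarget`; ``d_cbp`` maps bite
    point labels to out-lever distances (mm).  ``origin_distance`` is the
    (unconstrained) insertion-to-origin distance along the action line.
    ``noise_sd`` is relative landmark jitter; all randomness derives from
    ``seed``.
    """

    muscles: Mapping[str, MuscleTarget]
    d_cbp: Mapping[str, float]
    condyle: tuple[float, float, float] = (0.0, 0.0, 0.0)
    origin_distance: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.muscles:
            raise InvalidInputError("spec must contain at least one muscle")
        if not self.d_cbp:
            raise InvalidInputError("spec must contain at least one bite point")
        for bp, d in self.d_cbp.items():
            if not (d > 0):
                raise InvalidInputError(
                    f"bite point {bp!r}: out-lever must be > 0 mm, got {d!r}"
                )
        if not (self.origin_distance > 0):
            raise InvalidInputError("origin_distance must be > 0 mm")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")


def generate_geometry(spec: GeometrySpec) -> JawGeometry:
    """Build a landmark set realising the spec's angle and lever targets.

    At ``noise_sd == 0`` the round trip through action-line derivation
    recovers every (phi, theta, lever, d_cbp) target to floating-point
    accuracy, with closing moment signs for non-opener muscles.
    """
    condyle = np.asarray(spec.condyle, dtype=float)
    rng = np.random.default_rng(spec.seed)

    bite_points = {
        bp: condyle + np.array([d, 0.0, 0.0]) for bp, d in spec.d_cbp.items()
    }
    origins: dict[str, np.ndarray] = {}
    insertions: dict[str, np.ndarray] = {}
    for name, tgt in spec.muscles.items():
        # insertion: in-lever along +x (anterior) from the condyle
        insertion = condyle + np.array([tgt.lever, 0.0, 0.0])
        # sagittal action direction: +x rotated by theta; dorsally (closing
        # moment, since the moment convention is opening-positive) for
        # closers, ventrally for openers
        th = math.radians(tgt.theta)
        s = np.array([math.cos(th), math.sin(th)])
        if tgt.opener:
            s = np.array([math.cos(th), -math.sin(th)])
        ph = math.radians(tgt.phi)
        unit = np.array([s[0] * math.sin(ph), s[1] * math.sin(ph), math.cos(ph)])
        origins[name] = insertion + spec.origin_distance * unit
        insertions[name] = insertion

    if spec.noise_sd > 0:
        scale = float(
            np.mean([t.lever for t in spec.muscles.values()] + list(spec.d_cbp.values()))
        )
        sd = spec.noise_sd * scale
        for mapping in (origins, insertions, bite_points):
            for key in mapping:
                mapping[key] = mapping[key] + rng.normal(0.0, sd, size=3)

    return JawGeometry(
        condyle=condyle,
        origins=origins,
        insertions=insertions,
        bite_points=bite_points,
        gape=0.0,
    )


def spec_from_planar(
    model,
    condyle: tuple[float, float, float] = (0.0, 0.0, 0.0),
    origin_distance: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> GeometrySpec:
    """Geometry spec whose targets reproduce a planar model's table.

    Lifts a geometry-free :class:`~jawlever.equilibrium.PlanarModel` into
    an explicit landmark geometry (declared openers become opening-moment
    muscles), which makes gape rotation available for data that were
    published only as angle/lever tables.  The lift is not unique — origin
    distances are unconstrained — so opened-jaw results depend on
    ``origin_distance``; closed-mouth results do not.
    """
    targets = {
        pm.muscle: MuscleTarget(
            phi=pm.phi,
            theta=pm.theta,
            lever=pm.lever,
            opener=pm.muscle in model.openers,
        )
        for pm in model.muscles
    }
    return GeometrySpec(
        muscles=targets,
        d_cbp=dict(model.d_cbp),
        condyle=condyle,
        origin_distance=origin_distance,
        noise_sd=noise_sd,
        seed=seed,
    )


def generate_architecture(
    n_muscles: int = 13,
    median_mass: float = 0.02,
    sigma_mass: float = 0.6,
    median_fibre_length: float = 3.5,
    sigma_fibre_length: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Random but reproducible architecture table of a small-mammal jaw.

    Masses (g) and fibre lengths (mm) are log-normal; the defaults centre
    the draws on a mouse-opossum-sized masticatory apparatus (muscle
    masses a few tens of milligrams, fibres a few millimetres) so derived
    PCSAs land in the realistic 0.01-0.15 cm^2 band.  When ``n_muscles``
    is 13 the standard didelphid labels are used (with the digastric
    marked as opener); otherwise muscles are labelled ``m01``…
    """
    if n_muscles < 1:
        raise InvalidInputError("n_muscles must be >= 1")
    for name, v in (
        ("median_mass", median_mass),
        ("sigma_mass", sigma_mass),
        ("median_fibre_length", median_fibre_length),
        ("sigma_fibre_length", sigma_fibre_length),
    ):
        if not (v > 0):
            raise InvalidInputError(f"{name} must be > 0, got {v!r}")
    rng = np.random.default_rng(seed)
    masses = median_mass * np.exp(rng.normal(0.0, sigma_mass, n_muscles))
    fls = median_fibre_length * np.exp(rng.normal(0.0, sigma_fibre_length, n_muscles))
    if n_muscles == len(DEFAULT_ROSTER):
        names = list(DEFAULT_ROSTER)
        roles = ["opener" if n == "Di" else "closer" for n in names]
    else:
        names = [f"m{i + 1:02d}" for i in range(n_muscles)]
        roles = ["closer"] * n_muscles
    return pd.DataFrame(
        {
            "muscle": names,
            "mass_g": masses,
            "fibre_length_mm": fls,
            "role": roles,
        }
    )
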