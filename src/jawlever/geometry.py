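"""Jaw landmark geometry: action lines, angles, lever arms, gape rotation.

Coordinate frame (skull-fixed, right mandible):

* x — anteroposterior, positive towards the incisors (anterior);
* y — dorsoventral, positive dorsal;
* z — mediolateral.

The sagittal plane is x-y.  The mandible rotates rigidly about the
mediolateral axis through the centre of the condylar process; positive
rotation opens the jaw (anterior points move ventrally).

For every muscle the line of action is the vector from its mandibular
insertion centroid towards its cranial origin centroid — the direction in
which it pulls the mandible.  Two angles summarise it:

* ``phi`` — angle between the 3D action vector and the mediolateral axis.
  ``sin(phi)`` is the fraction of muscle force remaining after the
  mediolateral component is discounted (it cancels in bilateral biting).
* ``theta`` — angle, within the sagittal plane, between the lever vector
  (condyle -> insertion) and the sagittal projection of the action vector.
  ``sin(theta)`` scales the moment the sagittal force exerts about the
  condyle.

Moments about the condyle are signed with jaw-closing negative, so a
muscle with a positive moment is an opener and is excluded from bite-force
summation downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, InvalidInputError, SchemaError

#: Relative tolerance below which a projected vector counts as zero.
_DEGENERATE_RTOL = 1e-12


@dataclass(frozen=True)
class ActionLine:
    """Derived mechanics of one muscle's pull on the mandible.

    ``phi`` and ``theta`` in degrees within [0, 180]; ``lever`` is the
    sagittal-plane distance from condyle to insertion centroid in mm;
    ``moment_sign`` is +1 for an opening moment, -1 for closing, 0 if the
    sagittal action line passes through the condyle.
    """

    muscle: str
    phi: float
    theta: float
    lever: float
    moment_sign: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi <= 180.0):
            raise InvalidInputError(
                f"muscle {self.muscle!r}: phi must lie in [0, 180] deg, got {self.phi!r}"
            )
        if not (0.0 <= self.theta <= 180.0):
            raise InvalidInputError(
                f"muscle {self.muscle!r}: theta must lie in [0, 180] deg, "
                f"got {self.theta!r}"
            )
        if not (self.lever >= 0):
            raise InvalidInputError(
                f"muscle {self.muscle!r}: lever must be >= 0 mm, got {self.lever!r}"
            )
        if self.moment_sign not in (-1, 0, 1):
            raise InvalidInputError(
                f"muscle {self.muscle!r}: moment_sign must be -1, 0 or +1"
            )


def _as_point(p, what: str) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise InvalidInputError(f"{what}: expected a 3D point, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise InvalidInputError(f"{what}: coordinates must be finite, got {a}")
    return a


@dataclass(frozen=True)
class JawGeometry:
    """Landmark set of one specimen in the skull-fixed frame (mm).

    ``condyle`` is the rotation centre; ``origins``/``insertions`` map each
    muscle to its cranial origin / mandibular insertion centroid;
    ``bite_points`` maps tooth labels (at least ``"incisor"`` and ``"m4"``)
    to occlusal positions.  ``gape`` is the current opening angle in
    degrees (0 = closed, as dissected).
    """

    condyle: np.ndarray
    origins: Mapping[str, np.ndarray]
    insertions: Mapping[str, np.ndarray]
    bite_points: Mapping[str, np.ndarray]
    gape: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "condyle", _as_point(self.condyle, "condyle"))
        for attr in ("origins", "insertions", "bite_points"):
            mapping = {
                str(k): _as_point(v, f"{attr}[{k!r}]")
                for k, v in getattr(self, attr).items()
            }
            object.__setattr__(self, attr, mapping)
        if set(self.origins) != set(self.insertions):
            only_o = sorted(set(self.origins) - set(self.insertions))
            only_i = sorted(set(self.insertions) - set(self.origins))
            raise InvalidInputError(
                "origins and insertions must cover the same muscles "
                f"(origin-only: {only_o}, insertion-only: {only_i})"
            )
        for m in self.origins:
            if np.array_equal(self.origins[m], self.insertions[m]):
                raise InvalidInputError(
                    f"muscle {m!r}: origin and insertion centroids coincide"
                )
        for label, p in self.bite_points.items():
            if np.array_equal(p, self.condyle):
                raise InvalidInputError(
                    f"bite point {label!r} coincides with the condyle"
                )
        if not math.isfinite(self.gape):
            raise InvalidInputError(f"gape must be finite, got {self.gape!r}")

    @property
    def muscles(self) -> tuple[str, ...]:
        return tuple(self.origins)


def _sagittal(v: np.ndarray) -> np.ndarray:
    """Project a 3D vector onto the sagittal (x-y) plane."""
    return v[:2]


def derive_action_line(geom: JawGeometry, muscle: str) -> ActionLine:
    """Derive (phi, theta, lever, moment sign) for one muscle from landmarks.

    Raises
    ------
    KeyError
        If the muscle is absent from the geometry.
    DegenerateGeometryError
        If the action vector has no sagittal component (purely mediolateral
        pull) or the insertion sits on the condyle in the sagittal plane.
    """
    if muscle not in geom.origins:
        raise KeyError(f"muscle {muscle!r} not present in geometry")
    origin = geom.origins[muscle]
    insertion = geom.insertions[muscle]
    action = origin - insertion  # pull direction: insertion -> origin
    norm3 = float(np.linalg.norm(action))
    if norm3 <= 0.0:
        raise DegenerateGeometryError(muscle, "zero-length action vector", geom.gape)

    phi = math.degrees(math.acos(np.clip(action[2] / norm3, -1.0, 1.0)))
    # fold to [0, 90]-symmetric convention? No: phi measured from the
    # mediolateral axis spans [0, 180]; sin(phi) >= 0 either way.

    a_sag = _sagittal(action)
    norm2 = float(np.linalg.norm(a_sag))
    if norm2 <= _DEGENERATE_RTOL * norm3:
        raise DegenerateGeometryError(
            muscle, "action vector has no sagittal component (phi ~ 0 or 180)",
            geom.gape,
        )

    lever_vec = _sagittal(insertion - geom.condyle)
    lever = float(np.linalg.norm(lever_vec))
    if lever <= _DEGENERATE_RTOL * max(norm3, 1.0):
        raise DegenerateGeometryError(
            muscle, "insertion coincides with condyle in the sagittal plane",
            geom.gape,
        )

    cos_t = float(np.dot(lever_vec, a_sag)) / (lever * norm2)
    theta = math.degrees(math.acos(np.clip(cos_t, -1.0, 1.0)))

    # Moment about the mediolateral axis, opening-positive: with opening
    # defined as (x, y) -> (y, -x) rotation, the opening-sense moment of a
    # sagittal force a applied at lever L is L_y*a_x - L_x*a_y.
    moment = lever_vec[1] * a_sag[0] - lever_vec[0] * a_sag[1]
    scale = lever * norm2
    if abs(moment) <= 1e-12 * scale:
        sign = 0
    else:
        sign = 1 if moment > 0 else -1
    return ActionLine(muscle=muscle, phi=phi, theta=theta, lever=lever,
                      moment_sign=sign)


def rotate_mandible(geom: JawGeometry, delta: float) -> JawGeometry:
    """Rigidly rotate the mandibular landmarks by ``delta`` degrees.

    Insertion centroids and bite points rotate about the mediolateral axis
    through the condyle; positive ``delta`` opens the jaw (a point anterior
    to the condyle moves ventrally).  Cranial landmarks (origins, condyle)
    are fixed.  Returns a new geometry with ``gape`` incremented.
    """
    if not math.isfinite(delta):
        raise InvalidInputError(f"rotation angle must be finite, got {delta!r}")
    rad = math.radians(delta)
    c, s = math.cos(rad), math.sin(rad)
    # opening sense: (x, y) -> (x*cos + y*sin, -x*sin + y*cos)
    rot = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])

    def _rot(p: np.ndarray) -> np.ndarray:
        return geom.condyle + rot @ (p - geom.condyle)

    return JawGeometry(
        condyle=geom.condyle,
        origins=geom.origins,
        insertions={m: _rot(p) for m, p in geom.insertions.items()},
        bite_points={b: _rot(p) for b, p in geom.bite_points.items()},
        gape=geom.gape + delta,
    )


def distance_to_bite_point(geom: JawGeometry, bite: str) -> float:
    """Sagittal-plane distance (mm) from the condyle to a bite point (out-lever)."""
    if bite not in geom.bite_points:
        raise KeyError(
            f"unknown bite point {bite!r}; available: {sorted(geom.bite_points)}"
        )
    return float(np.linalg.norm(_sagittal(geom.bite_points[bite] - geom.condyle)))


# ---------------------------------------------------------------------------
# I/O


def read_landmarks_csv(path: str | Path) -> JawGeometry:
    """Read a landmark table ``landmark,role,x_mm,y_mm,z_mm``.

    ``role`` is one of ``condyle``, ``origin:<muscle>``,
    ``insertion:<muscle>``, ``bite:<label>``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover
        raise SchemaError(f"{path}: cannot parse CSV: {exc}") from exc
    required = ("landmark", "role", "x_mm", "y_mm", "z_mm")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")

    condyle = None
    origins: dict[str, np.ndarray] = {}
    insertions: dict[str, np.ndarray] = {}
    bites: dict[str, np.ndarray] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            point = np.array([float(row.x_mm), float(row.y_mm), float(row.z_mm)])
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: row {i + 2}: non-numeric coordinate") from exc
        role = str(row.role).strip()
        if role == "condyle":
            if condyle is not None:
                raise SchemaError(f"{path}: row {i + 2}: duplicate condyle")
            condyle = point
        elif role.startswith("origin:"):
            origins[role.split(":", 1)[1]] = point
        elif role.startswith("insertion:"):
            insertions[role.split(":", 1)[1]] = point
        elif role.startswith("bite:"):
            bites[role.split(":", 1)[1]] = point
        else:
            raise SchemaError(
                f"{path}: row {i + 2}: unrecognised role {role!r} "
                "(expected condyle, origin:<m>, insertion:<m> or bite:<label>)"
            )
    if condyle is None:
        raise SchemaError(f"{path}: no condyle landmark")
    try:
        return JawGeometry(condyle, origins, insertions, bites)
    except InvalidInputError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def read_landmarks_json(path: str | Path) -> JawGeometry:
    """JSON equivalent of the landmark CSV: keys ``condyle``, ``origins``,
    ``insertions``, ``bite_points`` (and optional ``gape``)."""
    path = Path(path)
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    try:
        return JawGeometry(
            condyle=data["condyle"],
            origins=data.get("origins", {}),
            insertions=data.get("insertions", {}),
            bite_points=data.get("bite_points", {}),
            gape=float(data.get("gape", 0.0)),
        )
    except KeyError as exc:
        raise SchemaError(f"{path}: missing key {exc}") from exc
    except InvalidInputError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_landmarks_csv(geom: JawGeometry, path: str | Path) -> None:
    """Inverse of :func:`read_landmarks_csv`."""
    rows = [("condyle", "condyle", *geom.condyle)]
    for m, p in geom.origins.items():
        rows.append((f"{m}_origin", f"origin:{m}", *p))
    for m, p in geom.insertions.items():
        rows.append((f"{m}_insertion", f"insertion:{m}", *p))
    for b, p in geom.bite_points.items():
        rows.append((b, f"bite:{b}", *p))
    pd.DataFrame(
        rows, columns=["landmark", "role", "x_mm", "y_mm", "z_mm"]
    ).to_csv(path, index=False)
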