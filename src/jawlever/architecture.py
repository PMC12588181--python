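"""Muscle architecture: masses, fibre lengths, PCSA and maximum 3D force.

The force a muscle can exert scales with its physiological cross-sectional
area (PCSA), the ratio of muscle volume to mean fibre length.  For dissected
museum specimens the measured mass underestimates fresh mass because of
formalin fixation and long-term ethanol storage, so the force computation
applies a preserved-to-fresh mass correction; the PCSA itself is reported
from the preserved mass, matching how dissection tables are conventionally
published.

Units follow dissection practice: masses in grams, fibre lengths in
millimetres, densities in g/cm^3, muscle stress (specific tension) in
N/cm^2.  Lengths are converted to centimetres inside the formulas so that
areas come out in cm^2 and forces in newtons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .errors import InvalidInputError, SchemaError

#: Muscle labels of the didelphid masticatory roster used throughout the
#: worked example: masseter (superficial / intermediate ant+post / profound),
#: zygomaticomandibularis (ant/post), temporalis (suprazygomatic /
#: superficial / profound lat+med), pterygoids and the digastric opener.
DEFAULT_ROSTER: tuple[str, ...] = (
    "Di",
    "MS",
    "MIant",
    "MIpos",
    "MP",
    "ZMant",
    "ZMpos",
    "TZ",
    "TS",
    "TPlat",
    "TPmed",
    "PtLat",
    "PtMed",
)

#: Muscles that act as jaw openers by anatomy (used when no geometry is
#: available to compute moment signs).
DEFAULT_OPENERS: frozenset[str] = frozenset({"Di"})


@dataclass(frozen=True)
class MuscleArchitecture:
    """One dissected muscle: preserved mass and mean fibre length.

    Parameters
    ----------
    name
        Muscle label, e.g. ``"MS"`` for M. masseter superficialis.
    mass
        Preserved muscle mass in grams.
    fibre_length
        Mean fibre length in millimetres.
    role
        ``"closer"`` or ``"opener"``.  Openers (the digastric, and any
        muscle whose computed moment opens the jaw) never contribute to
        bite force.
    """

    name: str
    mass: float
    fibre_length: float
    role: str = "closer"

    def __post_init__(self) -> None:
        if not self.name:
            raise InvalidInputError("muscle name must be non-empty")
        if not (self.mass > 0):
            raise InvalidInputError(
                f"muscle {self.name!r}: mass must be > 0 g, got {self.mass!r}"
            )
        if not (self.fibre_length > 0):
            raise InvalidInputError(
                f"muscle {self.name!r}: fibre length must be > 0 mm, "
                f"got {self.fibre_length!r}"
            )
        if self.role not in ("closer", "opener"):
            raise InvalidInputError(
                f"muscle {self.name!r}: role must be 'closer' or 'opener', "
                f"got {self.role!r}"
            )


@dataclass(frozen=True)
class ModelConstants:
    """Physical constants of the bite model.

    muscle_stress
        Specific tension F_MS in N/cm^2.  Default 30, the classical
        mammalian skeletal-muscle value; calibration against in vivo bite
        force refits it.
    density
        Muscle density d_M in g/cm^3.  Default 1.0518, the head-muscle
        value; alternative published densities are 1.0597, 1.0564 (limb
        muscle) and 1.0582 (masseter-specific).
    mass_correction
        Dimensionless preserved-to-fresh mass factor.  Default 1.692,
        compensating the average 40.91 % mass loss from formalin fixation
        followed by ethanol storage.
    """

    muscle_stress: float = 30.0
    density: float = 1.0518
    mass_correction: float = 1.692

    def __post_init__(self) -> None:
        for name in ("muscle_stress", "density", "mass_correction"):
            v = getattr(self, name)
            if not (v > 0):
                raise InvalidInputError(f"{name} must be > 0, got {v!r}")

    def with_stress(self, muscle_stress: float) -> "ModelConstants":
        """Copy of these constants with a different specific tension."""
        return ModelConstants(muscle_stress, self.density, self.mass_correction)


def compute_pcsa(arch: MuscleArchitecture, constants: ModelConstants) -> float:
    """Physiological cross-sectional area in cm^2.

    PCSA = MM / (FL * d_M) with the fibre length converted from mm to cm.
    The preserved->fresh mass correction is deliberately NOT applied here:
    PCSA is reported on the preserved mass, as in dissection tables; the
    correction enters only the force computation.
    """
    return arch.mass / (_mm_to_cm(arch.fibre_length) * constants.density)


def compute_f3dmax(arch: MuscleArchitecture, constants: ModelConstants) -> float:
    """Maximum tetanic force along the muscle's 3D line of action, in N.

    F3Dmax = F_MS * MM * c_mass / (FL * d_M)
           = F_MS * c_mass * PCSA,

    i.e. the specific tension applied to the fresh-mass PCSA.
    """
    return (
        constants.muscle_stress
        * arch.mass
        * constants.mass_correction
        / (_mm_to_cm(arch.fibre_length) * constants.density)
    )


def _mm_to_cm(length_mm: float) -> float:
    return length_mm / 10.0


# ---------------------------------------------------------------------------
# Tabular interface


_ARCH_COLUMNS = ("muscle", "mass_g", "fibre_length_mm")


def architecture_from_frame(
    df: pd.DataFrame,
    roster: Sequence[str] | None = None,
    source: str = "<frame>",
) -> list[MuscleArchitecture]:
    """Validate a muscle-architecture table and return typed records.

    Expected columns: ``muscle, mass_g, fibre_length_mm`` and optionally
    ``role``.  ``roster``, when given, is the set of admissible muscle
    labels; pass :data:`DEFAULT_ROSTER` to enforce the didelphid roster.
    """
    missing = [c for c in _ARCH_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing column(s) {', '.join(missing)}")
    names = df["muscle"].astype(str)
    dupes = names[names.duplicated()].tolist()
    if dupes:
        raise SchemaError(f"{source}: duplicate muscle label(s) {dupes}")
    if roster is not None:
        unknown = sorted(set(names) - set(roster))
        if unknown:
            raise SchemaError(
                f"{source}: muscle label(s) {unknown} not in roster {list(roster)}"
            )
    muscles = []
    for i, row in enumerate(df.itertuples(index=False)):
        role = getattr(row, "role", "closer")
        if role is None or (isinstance(role, float) and pd.isna(role)):
            role = "closer"
        try:
            muscles.append(
                MuscleArchitecture(
                    name=str(row.muscle),
                    mass=float(row.mass_g),
                    fibre_length=float(row.fibre_length_mm),
                    role=str(role),
                )
            )
        except (InvalidInputError, TypeError, ValueError) as exc:
            raise SchemaError(f"{source}: row {i + 2}: {exc}") from exc
    if not muscles:
        raise SchemaError(f"{source}: architecture table is empty")
    return muscles


def read_architecture_csv(
    path: str | Path, roster: Sequence[str] | None = None
) -> list[MuscleArchitecture]:
    """Read a muscle-architecture CSV (``muscle,mass_g,fibre_length_mm[,role]``)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise SchemaError(f"{path}: cannot parse CSV: {exc}") from exc
    return architecture_from_frame(df, roster=roster, source=str(path))


def architecture_to_frame(muscles: Iterable[MuscleArchitecture]) -> pd.DataFrame:
    """Inverse of :func:`architecture_from_frame`."""
    return pd.DataFrame(
        [
            {
                "muscle": m.name,
                "mass_g": m.mass,
                "fibre_length_mm": m.fibre_length,
                "role": m.role,
            }
            for m in muscles
        ]
    )


def pcsa_table(
    muscles: Iterable[MuscleArchitecture], constants: ModelConstants
) -> pd.DataFrame:
    """Dissection-style summary: mass, fibre length, PCSA and F3Dmax per muscle."""
    rows = []
    for m in muscles:
        rows.append(
            {
                "muscle": m.name,
                "mass_g": m.mass,
                "fibre_length_mm": m.fibre_length,
                "pcsa_cm2": compute_pcsa(m, constants),
                "f3dmax_N": compute_f3dmax(m, constants),
                "role": m.role,
            }
        )
    return pd.DataFrame(rows)


def load_constants(path: str | Path) -> ModelConstants:
    """Read :class:`ModelConstants` from a YAML or JSON mapping.

    Recognised keys: ``muscle_stress``, ``density``, ``mass_correction``;
    absent keys keep their defaults.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: expected a mapping of constant names")
    known = {"muscle_stress", "density", "mass_correction"}
    unknown = sorted(set(data) - known)
    if unknown:
        raise SchemaError(f"{path}: unknown constant(s) {unknown}")
    try:
        return ModelConstants(**{k: float(v) for k, v in data.items()})
    except InvalidInputError:
        raise
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: non-numeric constant: {exc}") from exc
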