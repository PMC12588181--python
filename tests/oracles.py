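"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's equilibrium and sweep code paths:
forces are assembled as explicit 3D vectors, moments as explicit cross
products, rotations as hand-written rotation matrices, and optima by
dense grid search.
"""

import math

import numpy as np


def oracle_bite_force(geom, forces: dict[str, float], bite_point: str) -> float:
    """Bilateral bite force by explicit cross-product moment balance.

    For each muscle build the full 3D force vector along insertion->origin,
    drop its mediolateral component, take the z-component of the torque
    about the condyle, keep jaw-closing torques only, and balance the
    summed moment against the bite force times the out-lever.
    """
    condyle = geom.condyle
    closing_moment = 0.0
    for name in geom.muscles:
        u = geom.origins[name] - geom.insertions[name]
        fvec = forces[name] * u / np.linalg.norm(u)
        fvec = np.array([fvec[0], fvec[1], 0.0])  # discard mediolateral
        lever = geom.insertions[name] - condyle
        lever = np.array([lever[0], lever[1], 0.0])
        tau_z = float(np.cross(lever, fvec)[2])
        # closing torque is +z here: opening sends anterior points ventral,
        # i.e. is the -z rotation sense
        if tau_z > 0:
            closing_moment += tau_z
    out_lever = geom.bite_points[bite_point] - condyle
    d = float(np.hypot(out_lever[0], out_lever[1]))
    return 2.0 * closing_moment / d


def rotate_opening(points: dict[str, np.ndarray], condyle, delta_deg: float):
    """Hand-rolled opening rotation of mandibular points about the condyle."""
    a = math.radians(delta_deg)
    c, s = math.cos(a), math.sin(a)
    out = {}
    for k, p in points.items():
        rel = p - condyle
        out[k] = condyle + np.array(
            [c * rel[0] + s * rel[1], -s * rel[0] + c * rel[1], rel[2]]
        )
    return out


def oracle_optimal_gape(
    geom, forces: dict[str, float], bite_point: str,
    max_gape: float = 20.0, step: float = 0.01,
) -> tuple[float, float]:
    """Dense-grid argmax of the force-gape profile (smallest gape wins ties)."""
    from jawlever import JawGeometry

    best_gape, best_force = 0.0, -math.inf
    n = int(round(max_gape / step))
    for k in range(n + 1):
        gape = k * step
        rotated = JawGeometry(
            condyle=geom.condyle,
            origins=geom.origins,
            insertions=rotate_opening(geom.insertions, geom.condyle, gape),
            bite_points=rotate_opening(geom.bite_points, geom.condyle, gape),
            gape=gape,
        )
        f = oracle_bite_force(rotated, forces, bite_point)
        if f > best_force + 1e-12:
            best_gape, best_force = gape, f
    return best_gape, best_force
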