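"""Internal coordinates of the isomerizing double bond.

The photoisomerization of a C1-C2=C3-C4 ethylenic fragment is tracked through
a small set of dihedral angles (all in degrees, unwrapped along the time
axis) and one stretching coordinate:

``alpha``
    C1-C2-C3-C4 skeletal twist: the reaction coordinate.  A counterclockwise
    rotation runs 0 (cis reactant) -> -90 (conical-intersection region) ->
    -180 (trans product).
``beta``
    R1-C2-C3-R4 substituent dihedral: the wag of the ethylenic substituents
    relative to the conjugated backbone.
``delta_op``
    Out-of-plane wag coordinate, ``alpha - beta``.
``tau``
    Orbital-overlap dihedral ``alpha - 0.5 * delta_op`` = (alpha + beta) / 2.
    tau = 0 at the planar cis reactant, -90 where the p-orbital overlap
    vanishes (decay region), -180 at the trans product.  Its velocity at the
    S1->S0 hop is the central reactivity predictor of the analysis.
``rho``, ``gamma``
    Optional five-membered-ring inversion dihedrals (pyrroline N-C2-C3-C4 and
    indanylidene C1'-C2'-C3'-C4') used for promoter-mode analysis.
``bla``
    Bond-length alternation: mean formal single-bond length minus mean formal
    double-bond length along the mapped conjugated path (Angstrom).

Velocities are forward finite differences over the actual frame spacing
(deg/fs, Angstrom/fs); the last frame's velocity is NaN.  The linear relation
``d(tau)/dt = d(alpha)/dt - 0.5 d(delta_op)/dt`` then holds identically at
every frame, which downstream statistics rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, UndefinedDihedralError
from .trajectory_io import Trajectory

ANGLE_SERIES = ("alpha", "beta", "delta_op", "tau", "rho", "gamma")


@dataclass
class GeometrySeries:
    """One named internal-coordinate time series with finite-difference velocities."""

    name: str
    times: np.ndarray
    values: np.ndarray
    velocities: np.ndarray  # forward difference; NaN on the last frame

    def __len__(self) -> int:
        return len(self.values)


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, range (-180, 180].

    Standard two-plane/atan2 construction; positive when the far bond is
    rotated clockwise relative to the near bond viewed along p2->p3 (IUPAC).
    Raises :class:`UndefinedDihedralError` when either bonded triple is
    collinear.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    nb1 = np.linalg.norm(b1)
    if nb1 == 0.0:
        raise UndefinedDihedralError("central atoms coincide")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < 1e-10 * max(np.linalg.norm(b0), 1.0) or np.linalg.norm(
        w
    ) < 1e-10 * max(np.linalg.norm(b2), 1.0):
        raise UndefinedDihedralError("collinear bonded triple")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang <= -180.0 else float(ang)


def dihedral_series(coords: np.ndarray, quad: tuple[int, int, int, int]) -> np.ndarray:
    """Per-frame dihedral (degrees, wrapped) for one atom-index quadruple."""
    i, j, k, l = quad
    p1, p2, p3, p4 = coords[:, i], coords[:, j], coords[:, k], coords[:, l]
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    b1 = b1 / np.linalg.norm(b1, axis=1, keepdims=True)
    v = b0 - np.sum(b0 * b1, axis=1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=1, keepdims=True) * b1
    x = np.sum(v * w, axis=1)
    y = np.sum(np.cross(b1, v) * w, axis=1)
    return np.degrees(np.arctan2(y, x))


def unwrap(series) -> np.ndarray:
    """Remove 360-degree jumps so consecutive differences are < 180 in magnitude.

    The first value is unchanged; later values are shifted by multiples of
    360 degrees.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("cannot unwrap an empty series")
    return np.unwrap(series, period=360.0)


def _forward_velocity(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    vel = np.full_like(values, np.nan)
    if len(values) > 1:
        vel[:-1] = np.diff(values) / np.diff(times)
    return vel


def _bla_series(coords: np.ndarray, single_bonds, double_bonds) -> np.ndarray:
    def mean_length(bonds):
        ls = [np.linalg.norm(coords[:, i] - coords[:, j], axis=1) for i, j in bonds]
        return np.mean(ls, axis=0)

    return mean_length(single_bonds) - mean_length(double_bonds)


def derive_series(traj: Trajectory, dihedral_map: dict) -> dict[str, GeometrySeries]:
    """Compute all mapped internal-coordinate series for one trajectory.

    ``dihedral_map`` must contain atom-index quadruples for ``alpha`` and
    ``beta``; ``rho``, ``gamma`` and the BLA bond lists
    (``bla_single``/``bla_double``, each a list of index pairs) are optional.
    All indices are 0-based positions in the XYZ atom order.

    Derived series: ``delta_op = alpha - beta`` and
    ``tau = alpha - 0.5 * delta_op``, computed from the unwrapped alpha and
    beta so the velocity identity holds exactly.
    """
    for required in ("alpha", "beta"):
        if required not in dihedral_map:
            raise ConfigurationError(f"dihedral_map lacks required quadruple {required!r}")
    n_atoms = traj.n_atoms
    out: dict[str, GeometrySeries] = {}

    def check(quad):
        if any(not 0 <= i < n_atoms for i in quad):
            raise ConfigurationError(f"dihedral_map indices {quad} outside 0..{n_atoms - 1}")
        return tuple(quad)

    raw: dict[str, np.ndarray] = {}
    for name in ("alpha", "beta", "rho", "gamma"):
        if name in dihedral_map:
            raw[name] = unwrap(dihedral_series(traj.coords, check(dihedral_map[name])))
    raw["delta_op"] = raw["alpha"] - raw["beta"]
    raw["tau"] = raw["alpha"] - 0.5 * raw["delta_op"]
    if "bla_single" in dihedral_map and "bla_double" in dihedral_map:
        for bonds in (dihedral_map["bla_single"], dihedral_map["bla_double"]):
            for i, j in bonds:
                if not (0 <= i < n_atoms and 0 <= j < n_atoms):
                    raise ConfigurationError(f"BLA bond ({i},{j}) outside 0..{n_atoms - 1}")
        raw["bla"] = _bla_series(
            traj.coords, dihedral_map["bla_single"], dihedral_map["bla_double"]
        )
    for name, values in raw.items():
        out[name] = GeometrySeries(
            name=name,
            times=traj.times,
            values=values,
            velocities=_forward_velocity(traj.times, values),
        )
    return out
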