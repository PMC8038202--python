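"""Cremer–Pople ring puckering for six-membered (pyranose) rings.

The puckering state of a six-membered ring is described in a spherical-polar
coordinate system (Q, theta, phi): Q is the total puckering amplitude (the
root-sum-square of the six out-of-plane displacements, in Å), theta in
[0, 180]° selects the conformer family (theta = 0 is the 4C1 chair of
D-pyranoses with the ring atoms ordered O5, C1, C2, C3, C4, C5; theta = 180
is 1C4) and phi in [0, 360)° is the pseudorotation phase on the equator
(boats and twist-boats).

The module also provides the inverse construction (a ring with prescribed
puckering), classification onto the 38 canonical pyranose conformers, and
least-squares rigid-body superposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PuckerCoordinates",
    "ConformerLabel",
    "compute_cp",
    "build_ring",
    "classify_conformer",
    "superpose",
    "CANONICAL_CONFORMERS",
]

PLANAR_Q = 1e-6  # Å; below this amplitude the ring is reported planar
RING_CONVENTION = ("O5", "C1", "C2", "C3", "C4", "C5")


class GeometryError(ValueError):
    """Degenerate geometry (collinear ring, too few atoms, ...)."""


@dataclass(frozen=True)
class PuckerCoordinates:
    """Cremer–Pople coordinates of one six-membered ring."""

    Q: float          # total amplitude, Å
    theta: float      # polar angle, degrees in [0, 180]
    phi: float        # azimuthal phase, degrees in [0, 360)
    q2: float         # equatorial component amplitude, Å
    q3: float         # chair component amplitude (signed by convention q3 = Q cos θ)
    z: np.ndarray     # six signed displacements from the mean plane, Å
    planar: bool = False

    def __post_init__(self):
        object.__setattr__(self, "z", np.asarray(self.z, dtype=float))


@dataclass(frozen=True)
class ConformerLabel:
    """Canonical conformer assignment with angular distance to its pole/region."""

    label: str
    distance: float  # great-circle distance on the CP sphere, degrees


def _as_ring(coords) -> np.ndarray:
    xyz = np.asarray(coords, dtype=float)
    if xyz.shape != (6, 3):
        raise GeometryError(f"expected six 3-D positions, got shape {xyz.shape}")
    if not np.all(np.isfinite(xyz)):
        raise GeometryError("non-finite ring coordinates")
    return xyz


def compute_cp(coords: Sequence[Sequence[float]]) -> PuckerCoordinates:
    """Cremer–Pople coordinates of a six-membered ring.

    ``coords`` are the Cartesian positions in ring order, first atom O5 by
    the package convention.  The mean plane is the Cremer–Pople plane: the
    displacements z_j sum to zero exactly and sum-of-squares to Q^2.
    """
    xyz = _as_ring(coords)
    center = xyz.mean(axis=0)
    rp = xyz - center

    j = np.arange(6)
    # in-plane basis defining the normal of the CP mean plane
    r1 = (rp * np.sin(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    r2 = (rp * np.cos(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    n = np.cross(r1, r2)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise GeometryError("degenerate (collinear) ring geometry")
    n /= norm
    z = rp @ n

    q2c = np.sqrt(1.0 / 3.0) * (z * np.cos(4 * np.pi * j / 6)).sum()
    q2s = -np.sqrt(1.0 / 3.0) * (z * np.sin(4 * np.pi * j / 6)).sum()
    q3 = np.sqrt(1.0 / 6.0) * ((-1.0) ** j * z).sum()
    q2 = float(np.hypot(q2c, q2s))
    Q = float(np.sqrt(q2 * q2 + q3 * q3))

    if Q < PLANAR_Q:
        return PuckerCoordinates(Q=Q, theta=0.0, phi=0.0, q2=q2, q3=float(q3),
                                 z=z, planar=True)

    theta = float(np.degrees(np.arctan2(q2, q3)))
    phi = float(np.degrees(np.arctan2(q2s, q2c))) % 360.0
    if theta in (0.0, 180.0):
        phi = 0.0
    return PuckerCoordinates(Q=Q, theta=theta, phi=phi, q2=q2, q3=float(q3), z=z)


def _displacements(Q: float, theta_deg: float, phi_deg: float) -> np.ndarray:
    th = np.radians(theta_deg)
    ph = np.radians(phi_deg)
    q2 = Q * np.sin(th)
    q3 = Q * np.cos(th)
    j = np.arange(6)
    return (np.sqrt(1.0 / 3.0) * q2 * np.cos(ph + 2 * np.pi * j / 3)
            + np.sqrt(1.0 / 6.0) * q3 * (-1.0) ** j)


def build_ring(Q: float, theta: float, phi: float,
               bond_length: float = 1.54) -> np.ndarray:
    """Six Cartesian positions of a ring with prescribed (Q, theta, phi).

    Inverse of :func:`compute_cp`: the in-plane projection is a regular
    hexagon whose radius is chosen so adjacent atoms sit near
    ``bond_length`` apart, and the out-of-plane displacements are the exact
    CP displacements.  Round-trips through :func:`compute_cp` to 1e-6.
    """
    if Q < 0:
        raise ValueError("puckering amplitude Q must be non-negative")
    z = _displacements(Q, theta, phi)
    dz2 = np.mean(np.diff(np.append(z, z[0])) ** 2)
    rho2 = bond_length ** 2 - dz2
    rho = np.sqrt(rho2) if rho2 > 0.25 else bond_length
    j = np.arange(6)
    # clockwise placement keeps the CP normal along +z (theta=0 -> 4C1)
    x = rho * np.sin(2 * np.pi * j / 6)
    y = rho * np.cos(2 * np.pi * j / 6)
    return np.column_stack([x, y, z])


# --- canonical conformer classification -----------------------------------
#
# The 38 canonical pyranose conformers on the CP sphere (atom order
# O5, C1, C2, C3, C4, C5; superscripts = atoms above the mean plane,
# subscripts = below).  Poles: chairs.  Equator (theta=90): boats at even
# multiples of 60° in phi, twist-boats (S) between them.  Tropics
# (theta = 54.7°/125.3°): envelopes (E) and half-chairs (H) alternating
# every 30°.  Positions follow from the displacement formula above.

_TROPIC = float(np.degrees(np.arctan(np.sqrt(2.0))))  # 54.735…°


def _name_from_pattern(theta: float, phi: float) -> str:
    """Derive the canonical name from the sign pattern of the displacements."""
    names = ["O", "1", "2", "3", "4", "5"]
    z = _displacements(1.0, theta, phi)
    amax = np.abs(z).max()
    up = [names[i] for i in range(6) if z[i] > 0.6 * amax]
    dn = [names[i] for i in range(6) if z[i] < -0.6 * amax]

    def fmt(atoms):
        return ",".join(atoms)

    if abs(theta - 90.0) < 1e-9:
        if len(up) == 2:
            return f"{fmt(up)}B"
        return f"B{fmt(dn)}"
    # tropics: envelope (single dominant atom) or half-chair (adjacent pair)
    big_up = [names[i] for i in range(6) if z[i] > 0.82 * amax]
    big_dn = [names[i] for i in range(6) if z[i] < -0.82 * amax]
    if len(big_up) == 1 and len(big_dn) == 1:
        return f"{fmt(big_up)}H{fmt(big_dn)}"
    if len(big_up) == 1 and not big_dn:
        return f"{fmt(big_up)}E"
    if len(big_dn) == 1 and not big_up:
        return f"E{fmt(big_dn)}"
    raise RuntimeError(f"ambiguous canonical pattern at theta={theta}, phi={phi}")


# twist-boat names follow the standard Stoddart itinerary on the equator;
# the boat names are re-derived from the displacement pattern and checked.
_EQUATOR = ["O,3B", "3S1", "B1,4", "5S1", "2,5B", "2SO",
            "BO,3", "1S3", "1,4B", "1S5", "B2,5", "OS2"]


def _canonical_positions() -> dict[str, tuple[float, float]]:
    pos: dict[str, tuple[float, float]] = {}
    pos["4C1"] = (0.0, 0.0)
    pos["1C4"] = (180.0, 0.0)
    for k, name in enumerate(_EQUATOR):
        phi = 30.0 * k
        if "B" in name:  # boats are unambiguous from the sign pattern
            assert _name_from_pattern(90.0, phi) == name
        pos[name] = (90.0, phi)
    for theta in (_TROPIC, 180.0 - _TROPIC):
        for k in range(12):
            phi = 30.0 * k
            pos[_name_from_pattern(theta, phi)] = (theta, phi)
    return pos


CANONICAL_CONFORMERS: dict[str, tuple[float, float]] = _canonical_positions()
assert len(CANONICAL_CONFORMERS) == 38


def _sphere_distance(t1, p1, t2, p2) -> float:
    t1, p1, t2, p2 = map(np.radians, (t1, p1, t2, p2))
    c = (np.sin(t1) * np.sin(t2) * np.cos(p1 - p2) + np.cos(t1) * np.cos(t2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def classify_conformer(theta: float, phi: float,
                       chair_threshold: float = 45.0) -> ConformerLabel:
    """Assign the nearest canonical conformer name.

    theta within ``chair_threshold`` of a pole is a chair (4C1 / 1C4);
    otherwise the nearest equatorial or tropical canonical form on the
    CP sphere is reported with its great-circle distance.
    """
    if not (0.0 <= theta <= 180.0):
        raise ValueError("theta outside [0, 180]")
    phi = phi % 360.0
    if theta <= chair_threshold:
        return ConformerLabel("4C1", _sphere_distance(theta, phi, 0.0, 0.0))
    if theta >= 180.0 - chair_threshold:
        return ConformerLabel("1C4", _sphere_distance(theta, phi, 180.0, 0.0))
    best, dist = None, np.inf
    for name, (t0, p0) in sorted(CANONICAL_CONFORMERS.items()):
        if name in ("4C1", "1C4"):
            continue
        d = _sphere_distance(theta, phi, t0, p0)
        if d < dist - 1e-12:
            best, dist = name, d
    return ConformerLabel(best, dist)


# --- rigid superposition ---------------------------------------------------

def superpose(ref, mobile):
    """Least-squares rigid superposition of ``mobile`` onto ``ref`` (Kabsch).

    Returns ``(rmsd, (rotation, translation))`` such that
    ``mobile @ rotation.T + translation`` best fits ``ref``.
    """
    ref = np.asarray(ref, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise GeometryError("coordinate sets must be matched (n, 3) arrays")
    n = ref.shape[0]
    if n < 3:
        raise GeometryError("need at least three atoms to superpose")
    rc, mc = ref.mean(axis=0), mob.mean(axis=0)
    A, B = ref - rc, mob - mc
    if np.linalg.matrix_rank(A, tol=1e-9) < 2:
        raise GeometryError("collinear reference coordinates")
    H = B.T @ A
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    fitted = mob @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return rmsd, (R, t)
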