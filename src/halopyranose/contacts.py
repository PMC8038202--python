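"""Crystal environments, hydrogen bonds, packing indices, H normalization.

Symmetry expansion generates atom images ``x' = R x + t + n`` (operator plus
lattice translation) around a chosen central molecule.  Hydrogen bonds are
identified geometrically — donor-acceptor distance and D-H···A angle cutoffs
— with defaults wide enough to cover O-H···O, C-H···O and the O/C-H···halogen
interactions seen in halogenated sugar crystals.  The Kitaigorodskii packing
index is the fraction of the unit-cell volume occupied by the molecular van
der Waals volume, evaluated on a voxel grid (overlaps counted once).

X-ray refinement places H nuclei too close to their carrier atom (0.97 Å
C-H vs the 1.083 Å neutron value); :func:`normalize_h` extends each X-H
bond to the standard neutron distance, the usual convention before
Hirshfeld-surface analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structio import AtomSite, Crystal, SymOp

__all__ = [
    "ContactRecord", "PackingIndex", "AtomImage",
    "COVALENT_RADII", "BONDI_RADII", "NEUTRON_XH",
    "molecules", "expand_environment", "find_hbonds", "packing_index",
    "normalize_h", "normalize_h_cartesian",
]

COVALENT_RADII: Mapping[str, float] = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Na": 1.66, "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}
BOND_TOLERANCE = 0.40  # Å added to the covalent-radius sum

BONDI_RADII: Mapping[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}

# neutron-diffraction X-H reference distances, Å
NEUTRON_XH: Mapping[str, float] = {"C": 1.083, "O": 0.983, "N": 1.009, "B": 1.185}

HALOGENS = frozenset({"F", "Cl", "Br", "I"})
DEFAULT_MAX_DA: Mapping[str, float] = {"O": 3.6, "N": 3.6, "F": 3.6,
                                       "Cl": 3.9, "Br": 3.9, "I": 3.9}
DEFAULT_MIN_ANGLE = 120.0  # degrees


@dataclass(frozen=True)
class AtomImage:
    """Symmetry image of an asymmetric-unit site."""

    site_index: int
    op_index: int
    lattice: tuple          # integer lattice translation
    label: str
    element: str
    cart: np.ndarray

    def key(self):
        return (self.site_index, self.op_index, self.lattice)


@dataclass
class ContactRecord:
    donor: str
    hydrogen: str
    acceptor: str
    d_DA: float
    angle_DHA: float
    symop: str              # generating operator triplet + lattice translation
    kind: str

    def __post_init__(self):
        if self.d_DA <= 0:
            raise ValueError("non-positive donor-acceptor distance")
        if not (0.0 <= self.angle_DHA <= 180.0):
            raise ValueError("D-H...A angle outside [0, 180]")


@dataclass(frozen=True)
class PackingIndex:
    value: float            # fraction of the cell volume, in (0, 1)
    method: str

    def __post_init__(self):
        if not (0.0 < self.value < 1.0):
            raise ValueError("packing index must lie in (0, 1)")


def _bonded(elem_a: str, elem_b: str, dist: float) -> bool:
    ra = COVALENT_RADII.get(elem_a, 0.8)
    rb = COVALENT_RADII.get(elem_b, 0.8)
    return dist <= ra + rb + BOND_TOLERANCE


def molecules(crystal: Crystal) -> list[list[int]]:
    """Connected components of the asymmetric unit under covalent bonding."""
    cart = crystal.cart_coords()
    n = len(cart)
    elems = [s.element for s in crystal.sites]
    adj: list[list[int]] = [[] for _ in range(n)]
    if n > 1:
        tree = cKDTree(cart)
        for i, j in tree.query_pairs(r=4.0):
            d = float(np.linalg.norm(cart[i] - cart[j]))
            if _bonded(elems[i], elems[j], d):
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    comps: list[list[int]] = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in adj[i]:
                if not seen[j]:
                    seen[j] = True
                    stack.append(j)
        comps.append(sorted(comp))
    return comps


def _perpendicular_widths(crystal: Crystal) -> np.ndarray:
    """Distance between opposite cell faces along each axis."""
    M = crystal.orthogonalization
    a, b, c = M[:, 0], M[:, 1], M[:, 2]
    V = abs(np.dot(a, np.cross(b, c)))
    return np.array([V / np.linalg.norm(np.cross(b, c)),
                     V / np.linalg.norm(np.cross(c, a)),
                     V / np.linalg.norm(np.cross(a, b))])


def expand_environment(crystal: Crystal, center: int = 0,
                       radius: float = 6.0) -> list[AtomImage]:
    """Symmetry-generated atom images within ``radius`` of a central molecule.

    ``center`` indexes the molecules of the asymmetric unit (see
    :func:`molecules`).  The closed ball is used: an atom exactly at
    ``radius`` is included.  The identity image of the central molecule is
    part of the returned environment.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    comps = molecules(crystal)
    central = crystal.cart_coords()[comps[center]]
    tree = cKDTree(central)

    widths = _perpendicular_widths(crystal)
    extent = np.ptp(central, axis=0).max() if len(central) > 1 else 0.0
    nmax = np.ceil((radius + extent + 2.0) / widths).astype(int) + 1

    frac = np.array([s.frac_xyz for s in crystal.sites])
    M = crystal.orthogonalization
    out: list[AtomImage] = []
    seen = set()
    for oi, op in enumerate(crystal.symmetry_ops):
        base = frac @ op.rot_array.T + np.array([float(t) for t in op.tran])
        for na in range(-nmax[0], nmax[0] + 1):
            for nb in range(-nmax[1], nmax[1] + 1):
                for nc in range(-nmax[2], nmax[2] + 1):
                    shift = np.array([na, nb, nc], dtype=float)
                    cart = (base + shift) @ M.T
                    dists, _ = tree.query(cart)
                    for si in np.flatnonzero(dists <= radius + 1e-9):
                        key = (int(si), oi, (na, nb, nc))
                        if key in seen:
                            continue
                        seen.add(key)
                        s = crystal.sites[si]
                        out.append(AtomImage(site_index=int(si), op_index=oi,
                                             lattice=(na, nb, nc),
                                             label=s.label, element=s.element,
                                             cart=cart[si]))
    return out


def _h_attachments(crystal: Crystal):
    """(h_index, heavy_index) pairs for every bonded hydrogen."""
    cart = crystal.cart_coords()
    elems = [s.element for s in crystal.sites]
    pairs = []
    for i, e in enumerate(elems):
        if e != "H":
            continue
        best, best_d = None, np.inf
        for j, ej in enumerate(elems):
            if ej == "H":
                continue
            d = float(np.linalg.norm(cart[i] - cart[j]))
            if d < best_d:
                best, best_d = j, d
        if best is not None and _bonded("H", elems[best], best_d):
            pairs.append((i, best))
        else:
            pairs.append((i, None))
    return pairs, cart


def _contact_kind(donor_elem: str, acceptor_elem: str) -> str:
    d = donor_elem if donor_elem in ("O", "C", "N") else None
    if acceptor_elem == "O":
        a = "O"
    elif acceptor_elem in HALOGENS:
        a = "X"
    else:
        a = None
    if d and a:
        return f"{d}-H...{a}"
    return "other"


def find_hbonds(crystal: Crystal,
                max_da: Mapping[str, float] | float = None,
                min_angle: float = DEFAULT_MIN_ANGLE,
                include_intramolecular: bool = False) -> list[ContactRecord]:
    """Hydrogen bonds / short contacts satisfying the geometric criteria.

    Donors are O/N/C atoms carrying a hydrogen; acceptors O/N and halogens.
    Each bond appears once per unique symmetry relation (donor kept in the
    asymmetric unit), sorted by donor-acceptor distance.
    """
    if max_da is None:
        max_da = dict(DEFAULT_MAX_DA)
    if isinstance(max_da, (int, float)):
        max_da = {e: float(max_da) for e in DEFAULT_MAX_DA}

    attach, cart = _h_attachments(crystal)
    h_pairs = [(h, d) for h, d in attach if d is not None]
    if not any(s.element == "H" for s in crystal.sites):
        warnings.warn("no hydrogen atoms present; returning no contacts")
        return []

    comps = molecules(crystal)
    mol_of = {}
    for mi, comp in enumerate(comps):
        for i in comp:
            mol_of[i] = mi

    acceptor_elems = set(DEFAULT_MAX_DA) & set(max_da)
    cutoff = max(max_da.values())
    records: list[ContactRecord] = []
    seen = set()
    for h_idx, d_idx in h_pairs:
        donor = crystal.sites[d_idx]
        if donor.element not in ("O", "N", "C"):
            continue
        # acceptor images around this donor's molecule
        env = expand_environment(crystal, center=mol_of[d_idx],
                                 radius=cutoff + 2.0)
        for img in env:
            if img.element not in acceptor_elems:
                continue
            same_image = img.op_index == 0 and img.lattice == (0, 0, 0)
            if same_image and img.site_index == d_idx:
                continue
            if (same_image and not include_intramolecular
                    and mol_of[img.site_index] == mol_of[d_idx]):
                continue
            dda = float(np.linalg.norm(img.cart - cart[d_idx]))
            if dda < 0.5 or dda > max_da.get(img.element, 0.0):
                continue
            v1 = cart[d_idx] - cart[h_idx]
            v2 = img.cart - cart[h_idx]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if ang < min_angle:
                continue
            key = (d_idx, img.key())
            if key in seen:
                continue
            seen.add(key)
            op = crystal.symmetry_ops[img.op_index]
            records.append(ContactRecord(
                donor=donor.label, hydrogen=crystal.sites[h_idx].label,
                acceptor=img.label, d_DA=dda, angle_DHA=ang,
                symop=f"{op.triplet()} + {list(img.lattice)}",
                kind=_contact_kind(donor.element, img.element)))
    records.sort(key=lambda r: (r.d_DA, r.donor, r.acceptor, r.symop))
    return records


def molecular_volume(elements: Sequence[str], coords, voxel: float = 0.1,
                     radii: Mapping[str, float] | None = None) -> float:
    """Volume (Å^3) of the union of vdW spheres, on a voxel grid."""
    if voxel <= 0:
        raise ValueError("voxel size must be positive")
    radii = dict(BONDI_RADII if radii is None else radii)
    coords = np.asarray(coords, dtype=float)
    rlist = []
    for e in elements:
        if e not in radii:
            raise KeyError(f"no van der Waals radius for element {e!r}")
        rlist.append(radii[e])
    rmax = max(rlist)
    lo = coords.min(axis=0) - rmax - voxel
    hi = coords.max(axis=0) + rmax + voxel
    shape = np.ceil((hi - lo) / voxel).astype(int)
    occ = np.zeros(shape, dtype=bool)
    axes = [lo[k] + (np.arange(shape[k]) + 0.5) * voxel for k in range(3)]
    for xyz, r in zip(coords, rlist):
        i0 = np.maximum(((xyz - r - lo) / voxel).astype(int) - 1, 0)
        i1 = np.minimum(((xyz + r - lo) / voxel).astype(int) + 2, shape)
        ax = axes[0][i0[0]:i1[0]] - xyz[0]
        ay = axes[1][i0[1]:i1[1]] - xyz[1]
        az = axes[2][i0[2]:i1[2]] - xyz[2]
        d2 = (ax[:, None, None] ** 2 + ay[None, :, None] ** 2
              + az[None, None, :] ** 2)
        occ[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= d2 <= r * r
    return float(occ.sum()) * voxel ** 3


def packing_index(crystal: Crystal, voxel: float = 0.1,
                  radii: Mapping[str, float] | None = None) -> PackingIndex:
    """Kitaigorodskii packing index: Z * V_vdW(asymmetric unit) / V_cell."""
    elems = [s.element for s in crystal.sites]
    vol = molecular_volume(elems, crystal.cart_coords(), voxel=voxel,
                           radii=radii)
    value = crystal.z_value * vol / crystal.volume
    radii_name = "bondi" if radii is None else "custom"
    return PackingIndex(value=value,
                        method=f"radii={radii_name}, voxel={voxel} A")


def normalize_h_cartesian(elements: Sequence[str], coords) -> np.ndarray:
    """Move each H along its existing X-H vector to the neutron distance."""
    coords = np.array(coords, dtype=float)
    n = len(coords)
    for i, e in enumerate(elements):
        if e != "H":
            continue
        best, best_d = None, np.inf
        for j in range(n):
            if elements[j] == "H":
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d < best_d:
                best, best_d = j, d
        if best is None or not _bonded("H", elements[best], best_d):
            warnings.warn(f"orphan hydrogen at index {i}; left in place")
            continue
        target = NEUTRON_XH.get(elements[best])
        if target is None:
            continue
        direction = (coords[i] - coords[best]) / best_d
        coords[i] = coords[best] + direction * target
    return coords


def normalize_h(crystal: Crystal) -> Crystal:
    """Return a copy of the crystal with X-H distances set to neutron values."""
    elems = [s.element for s in crystal.sites]
    cart = normalize_h_cartesian(elems, crystal.cart_coords())
    Minv = np.linalg.inv(crystal.orthogonalization)
    new_sites = []
    for s, xyz in zip(crystal.sites, cart @ Minv.T):
        new_sites.append(AtomSite(label=s.label, element=s.element,
                                  frac_xyz=xyz, occupancy=s.occupancy))
    return Crystal(cell=crystal.cell, symmetry_ops=list(crystal.symmetry_ops),
                   sites=new_sites, z_value=crystal.z_value)
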