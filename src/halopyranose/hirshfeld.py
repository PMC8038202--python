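"""Hirshfeld surfaces, fingerprint histograms and contact enrichment ratios.

The Hirshfeld surface of a molecule in a crystal is the locus where the
promolecule (the sum of spherical free-atom densities of that molecule)
contributes exactly half of the procrystal density: the 0.5 isosurface of
the weight ``w = rho_promolecule / (rho_promolecule + rho_environment)``.
Each surface point carries d_i and d_e — the distances to the nearest
nucleus inside and outside the surface — whose joint, area-weighted 2-D
histogram is the fingerprint plot.  Collapsing the surface area onto
element pairs gives contact contributions C_XY, per-element surface
proportions ``S_X = C_XX + 1/2 sum_{Y!=X} C_XY``, random-mixing
expectations ``R_XY = 2 S_X S_Y`` (``S_X^2`` on the diagonal) and
enrichment ratios ``E_XY = C_XY / R_XY``; E > 1 marks favoured contacts.

Free-atom densities are a self-contained single-zeta Slater-type-orbital
model with Slater's-rules exponents (sums of ``c r^p exp(-a r)`` terms per
occupied shell); each atom's density integrates exactly to its electron
count and is monotonically decreasing beyond ~0.35 Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import gamma, pi
from typing import Mapping, Sequence

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .contacts import expand_environment, molecules, normalize_h
from .structio import Crystal

__all__ = [
    "SphericalAtomDensity", "HirshfeldSurface", "FingerprintHistogram",
    "ContactTable", "atom_density", "promolecule_density",
    "build_surface", "build_surface_from_atoms",
    "fingerprint", "contact_contributions", "enrichment", "ResolutionError",
]

BOHR = 0.529177210903  # Å

# electron configurations (n, l, occupancy) of the supported elements
_CONFIGS = {
    "H": [(1, 0, 1)],
    "C": [(1, 0, 2), (2, 0, 2), (2, 1, 2)],
    "N": [(1, 0, 2), (2, 0, 2), (2, 1, 3)],
    "O": [(1, 0, 2), (2, 0, 2), (2, 1, 4)],
    "F": [(1, 0, 2), (2, 0, 2), (2, 1, 5)],
    "P": [(1, 0, 2), (2, 0, 2), (2, 1, 6), (3, 0, 2), (3, 1, 3)],
    "S": [(1, 0, 2), (2, 0, 2), (2, 1, 6), (3, 0, 2), (3, 1, 4)],
    "Cl": [(1, 0, 2), (2, 0, 2), (2, 1, 6), (3, 0, 2), (3, 1, 5)],
    "Br": [(1, 0, 2), (2, 0, 2), (2, 1, 6), (3, 0, 2), (3, 1, 6),
           (3, 2, 10), (4, 0, 2), (4, 1, 5)],
    "I": [(1, 0, 2), (2, 0, 2), (2, 1, 6), (3, 0, 2), (3, 1, 6),
          (3, 2, 10), (4, 0, 2), (4, 1, 6), (4, 2, 10), (5, 0, 2), (5, 1, 5)],
}
_Z = {"H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15, "S": 16, "Cl": 17,
      "Br": 35, "I": 53}
_NSTAR = {1: 1.0, 2: 2.0, 3: 3.0, 4: 3.7, 5: 4.0}


class ResolutionError(RuntimeError):
    """The extracted isosurface failed to close at the requested grid."""


def _slater_shells(element: str):
    """Per shell group: (n, zeta_bohr, occupancy) by Slater's screening rules."""
    cfg = _CONFIGS[element]
    groups: dict[tuple, int] = {}
    for n, l, occ in cfg:
        key = (n, "d") if l == 2 else (n, "sp")
        groups[key] = groups.get(key, 0) + occ
    out = []
    for (n, kind), occ in sorted(groups.items()):
        s = 0.0
        for (n2, kind2), occ2 in groups.items():
            if (n2, kind2) == (n, kind):
                s += (occ - 1) * (0.30 if n == 1 else 0.35)
            elif kind == "sp":
                if n2 == n - 1:
                    s += occ2 * 0.85
                elif n2 <= n - 2 or (n2 == n and kind2 == "d"):
                    s += occ2 * 1.00
            else:  # d electron: every inner or same-n sp electron screens fully
                if n2 < n or (n2 == n and kind2 == "sp"):
                    s += occ2 * 1.00
        out.append((n, (_Z[element] - s) / _NSTAR[n], occ))
    return out


@dataclass(frozen=True)
class SphericalAtomDensity:
    """Spherically averaged free-atom density rho(r) = sum c r^p exp(-a r).

    ``r`` in Å, ``rho`` in e/Å^3; integrates to the atomic electron count.
    """

    element: str
    terms: tuple            # (c [e/Å^3], p, a [1/Å]) per occupied shell
    cutoff: float           # Å; rho below ~1e-9 e/Å^3 beyond this

    def rho(self, r):
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        inside = r <= self.cutoff
        rr = np.where(inside, r, 1.0)
        for c, p, a in self.terms:
            out += np.where(inside, c * rr ** p * np.exp(-a * rr), 0.0)
        return out

    @property
    def electrons(self) -> float:
        # analytic: int 4 pi r^2 c r^p e^(-a r) dr = 4 pi c Gamma(p+3)/a^(p+3)
        return float(sum(4 * pi * c * gamma(p + 3) / a ** (p + 3)
                         for c, p, a in self.terms))


def _build_density(element: str) -> SphericalAtomDensity:
    terms = []
    for n, zeta, occ in _slater_shells(element):
        ns = _NSTAR[n]
        norm2 = (2 * zeta) ** (2 * ns + 1) / gamma(2 * ns + 1)  # bohr units
        c_bohr = occ * norm2 / (4 * pi)           # coeff of r^p e^(-2 zeta r)
        p = 2 * ns - 2
        c = c_bohr / BOHR ** 3 / BOHR ** p        # convert to Å
        a = 2 * zeta / BOHR
        terms.append((c, p, a))
    dens = SphericalAtomDensity(element=element, terms=tuple(terms), cutoff=np.inf)
    r = np.linspace(0.5, 12.0, 2000)
    rho = dens.rho(r)
    above = np.flatnonzero(rho > 1e-9)
    cutoff = float(r[above[-1]]) if len(above) else 0.5
    return SphericalAtomDensity(element=element, terms=tuple(terms),
                                cutoff=cutoff)


DENSITIES: Mapping[str, SphericalAtomDensity] = {
    e: _build_density(e) for e in _CONFIGS
}


def atom_density(element: str) -> SphericalAtomDensity:
    try:
        return DENSITIES[element]
    except KeyError:
        raise KeyError(f"no spherical atomic density for element {element!r}")


def promolecule_density(points, elements: Sequence[str], coords) -> np.ndarray:
    """Summed spherical-atom density (e/Å^3) at ``points`` (n, 3)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    out = np.zeros(len(pts))
    for elem, xyz in zip(elements, coords):
        dens = atom_density(elem)
        r = np.linalg.norm(pts - xyz, axis=1)
        out += dens.rho(r)
    return out


@dataclass
class HirshfeldSurface:
    """Triangulated 0.5-weight isosurface with per-point contact metadata."""

    vertices: np.ndarray          # (nv, 3), Å
    faces: np.ndarray             # (nf, 3) vertex indices
    area: float                   # Å^2
    volume: float                 # Å^3
    d_i: np.ndarray               # per-vertex distance to nearest internal nucleus
    d_e: np.ndarray
    vertex_areas: np.ndarray      # per-vertex area share, sums to `area`
    vertex_internal_elem: list
    vertex_external_elem: list
    face_areas: np.ndarray
    face_internal_elem: list      # nearest internal element at face centroid
    face_external_elem: list


def _add_density_grid(grid_shape, origin, spacing, elements, coords):
    """Accumulate promolecule density on a regular grid, per-atom subboxes."""
    total = np.zeros(grid_shape)
    axes = [origin[k] + np.arange(grid_shape[k]) * spacing for k in range(3)]
    for elem, xyz in zip(elements, coords):
        dens = atom_density(elem)
        rc = dens.cutoff
        i0 = np.maximum(((xyz - rc - origin) / spacing).astype(int), 0)
        i1 = np.minimum(((xyz + rc - origin) / spacing).astype(int) + 2,
                        grid_shape)
        if np.any(i0 >= i1):
            continue
        ax = axes[0][i0[0]:i1[0]] - xyz[0]
        ay = axes[1][i0[1]:i1[1]] - xyz[1]
        az = axes[2][i0[2]:i1[2]] - xyz[2]
        r = np.sqrt(ax[:, None, None] ** 2 + ay[None, :, None] ** 2
                    + az[None, None, :] ** 2)
        total[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] += dens.rho(r)
    return total


def build_surface_from_atoms(internal_elements, internal_coords,
                             external_elements, external_coords,
                             grid: float = 0.15, padding: float = 3.0,
                             require_closed: bool = True) -> HirshfeldSurface:
    """Hirshfeld surface of an explicit internal/external atom partition.

    With ``require_closed=False`` an open surface patch (e.g. the bisecting
    plane between two lone atoms) is returned with NaN volume instead of
    raising :class:`ResolutionError`.
    """
    int_xyz = np.atleast_2d(np.asarray(internal_coords, dtype=float))
    ext_xyz = np.atleast_2d(np.asarray(external_coords, dtype=float))
    if ext_xyz.size == 0:
        raise ValueError("no external atoms: the Hirshfeld surface is open")
    if grid <= 0:
        raise ValueError("grid spacing must be positive")

    origin = int_xyz.min(axis=0) - padding
    top = int_xyz.max(axis=0) + padding
    shape = tuple(np.ceil((top - origin) / grid).astype(int) + 1)

    rho_pro = _add_density_grid(shape, origin, grid, internal_elements, int_xyz)
    rho_env = _add_density_grid(shape, origin, grid, external_elements, ext_xyz)
    w = rho_pro / (rho_pro + rho_env + 1e-300)

    if w.max() <= 0.5:
        raise ResolutionError("weight never exceeds 0.5: no interior region "
                              "(check the internal atom selection)")
    try:
        verts, faces, _, _ = marching_cubes(w, level=0.5,
                                            spacing=(grid, grid, grid))
    except (ValueError, RuntimeError) as exc:
        raise ResolutionError(f"isosurface extraction failed: {exc}; "
                              "refine the grid or enlarge the padding")
    verts = verts + origin
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    closed = mesh.is_watertight
    if require_closed and not closed:
        raise ResolutionError(
            "extracted surface is not closed; refine the grid, enlarge the "
            "padding, or include more environment atoms")
    verts = np.asarray(mesh.vertices)
    faces = np.asarray(mesh.faces)

    tree_i = cKDTree(int_xyz)
    tree_e = cKDTree(ext_xyz)
    d_i, idx_i = tree_i.query(verts)
    d_e, idx_e = tree_e.query(verts)
    v_int = [internal_elements[k] for k in idx_i]
    v_ext = [external_elements[k] for k in idx_e]

    face_areas = mesh.area_faces
    vertex_areas = np.zeros(len(verts))
    for col in range(3):
        np.add.at(vertex_areas, faces[:, col], face_areas / 3.0)
    centroids = verts[faces].mean(axis=1)
    _, ci = tree_i.query(centroids)
    _, ce = tree_e.query(centroids)
    f_int = [internal_elements[k] for k in ci]
    f_ext = [external_elements[k] for k in ce]

    return HirshfeldSurface(
        vertices=verts, faces=faces, area=float(mesh.area),
        volume=float(abs(mesh.volume)) if closed else float("nan"),
        d_i=np.asarray(d_i),
        d_e=np.asarray(d_e), vertex_areas=vertex_areas,
        vertex_internal_elem=v_int, vertex_external_elem=v_ext,
        face_areas=np.asarray(face_areas), face_internal_elem=f_int,
        face_external_elem=f_ext)


def build_surface(crystal: Crystal, molecule: int = 0, grid: float = 0.15,
                  padding: float = 3.0, env_radius: float = 6.0,
                  h_normalization: bool = True) -> HirshfeldSurface:
    """Hirshfeld surface of one molecule of the crystal.

    The environment contains every symmetry image with an atom within
    ``env_radius`` of the central molecule (whole molecules, as generated
    by symmetry expansion), excluding the central image itself.  X-H bond
    lengths are normalized to neutron values by default, the standard
    convention for Hirshfeld analysis.
    """
    if h_normalization:
        crystal = normalize_h(crystal)
    comps = molecules(crystal)
    central_idx = comps[molecule]
    cart = crystal.cart_coords()
    elems = [s.element for s in crystal.sites]
    central_set = set(central_idx)
    images = expand_environment(crystal, center=molecule, radius=env_radius)
    ext_elems, ext_xyz = [], []
    for img in images:
        if (img.op_index == 0 and img.lattice == (0, 0, 0)
                and img.site_index in central_set):
            continue
        ext_elems.append(img.element)
        ext_xyz.append(img.cart)
    if not ext_xyz:
        raise ValueError("no environment atoms within env_radius")
    return build_surface_from_atoms(
        [elems[i] for i in central_idx], cart[central_idx],
        ext_elems, np.array(ext_xyz), grid=grid, padding=padding)


@dataclass
class FingerprintHistogram:
    """Area-fraction histogram over (d_i, d_e), percentages summing to 100."""

    counts: np.ndarray           # (nbins, nbins) percentages of surface area
    bin_width: float
    range: tuple

    @property
    def edges(self) -> np.ndarray:
        lo, hi = self.range
        return np.arange(lo, hi + self.bin_width / 2, self.bin_width)


def fingerprint(surface: HirshfeldSurface, bin_width: float = 0.01,
                d_range: tuple = (0.4, 3.0)) -> FingerprintHistogram:
    """Area-weighted 2-D histogram of (d_i, d_e); out-of-range points are
    clamped into the edge bins so the histogram always totals 100%."""
    lo, hi = d_range
    eps = bin_width * 1e-6
    di = np.clip(surface.d_i, lo + eps, hi - eps)
    de = np.clip(surface.d_e, lo + eps, hi - eps)
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    H, _, _ = np.histogram2d(di, de, bins=[edges, edges],
                             weights=surface.vertex_areas)
    H = 100.0 * H / surface.vertex_areas.sum()
    return FingerprintHistogram(counts=H, bin_width=bin_width, range=d_range)


@dataclass
class ContactTable:
    """Contact-area fractions and enrichment quantities by element pair."""

    C: dict                      # {(X, Y) sorted: area fraction}, sums to 1
    S: dict = field(default_factory=dict)   # per-element surface proportion
    R: dict = field(default_factory=dict)   # random-contact expectation
    E: dict = field(default_factory=dict)   # enrichment ratio (may be missing)


def contact_contributions(surface: HirshfeldSurface) -> ContactTable:
    """Area fraction of each unordered element-pair contact (per-triangle)."""
    C: dict[tuple, float] = {}
    for area, ei, ee in zip(surface.face_areas, surface.face_internal_elem,
                            surface.face_external_elem):
        key = tuple(sorted((ei, ee)))
        C[key] = C.get(key, 0.0) + float(area)
    total = sum(C.values())
    return ContactTable(C={k: v / total for k, v in sorted(C.items())})


def enrichment(table: ContactTable, floor: float = 1e-4) -> ContactTable:
    """Fill S_X, R_XY and E_XY = C_XY / R_XY into the contact table.

    ``R_XX = S_X^2`` (the standard convention for the diagonal).  Ratios
    with ``R_XY < floor`` are reported as missing (NaN) rather than huge.
    """
    total = sum(table.C.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError("contact contributions must sum to 1")
    elements = sorted({e for pair in table.C for e in pair})
    S = {}
    for x in elements:
        s = table.C.get((x, x), 0.0)
        for y in elements:
            if y != x:
                s += 0.5 * table.C.get(tuple(sorted((x, y))), 0.0)
        S[x] = s
    R, E = {}, {}
    for i, x in enumerate(elements):
        for y in elements[i:]:
            key = (x, y)
            R[key] = S[x] * S[y] if x == y else 2.0 * S[x] * S[y]
            if R[key] < floor:
                E[key] = float("nan")
            else:
                E[key] = table.C.get(key, 0.0) / R[key]
    table.S, table.R, table.E = S, R, E
    return table
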