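"""Ligand-in-pocket characterization: binding site, fingerprints, electrostatics.

The binding site of a ligand (e.g. the 2-fluoro sugar G2F in pyranose
2-oxidase) is the set of residues with any atom within a cutoff of the
ligand; 4.5 Å is the conventional near-field boundary.  Ligand Hirshfeld
fingerprints reuse the crystal machinery with the ligand as promolecule and
the protein as environment.  Electrostatic interaction energies use a
point-multipole model (charge, optional dipole and traceless quadrupole per
site) with explicit near/far bookkeeping against the same 4.5 Å cutoff.
The model accepts any user-supplied population-analysis charges; it is a
simplified point-multipole electrostatics, so absolute energies against
full aspherical-density treatments are comparable only qualitatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hirshfeld import ContactTable, FingerprintHistogram, \
    build_surface_from_atoms, contact_contributions, fingerprint
from .ring_pucker import superpose
from .structio import ProteinStructure, Residue

__all__ = [
    "BindingSite", "MultipoleSite", "InteractionEnergy",
    "COULOMB_KJ_PER_MOL", "IONIZED_RESIDUES",
    "extract_site", "ligand_fingerprint", "multipole_energy",
    "compare_ligand_geometries",
]

# e^2 / (4 pi eps0 * 1 Å) * N_A, in kJ/mol
COULOMB_KJ_PER_MOL = 1389.35458

# residues carrying formal charges at physiological pH
IONIZED_RESIDUES = {"ARG": +1, "LYS": +1, "ASP": -1, "GLU": -1}

NEAR_CUTOFF_DEFAULT = 4.5  # Å


@dataclass
class BindingSite:
    ligand_code: str
    ligand_atoms: list
    residues: list                   # (chain, Residue, closest approach Å)
    cutoff: float


@dataclass
class MultipoleSite:
    """Point multipole: charge (e), optional dipole (e Å), quadrupole (e Å^2)."""

    position: np.ndarray
    charge: float = 0.0
    dipole: np.ndarray | None = None
    quadrupole: np.ndarray | None = None   # traceless 3x3

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.dipole is not None:
            self.dipole = np.asarray(self.dipole, dtype=float)
        if self.quadrupole is not None:
            self.quadrupole = np.asarray(self.quadrupole, dtype=float)
            if abs(np.trace(self.quadrupole)) > 1e-8:
                raise ValueError("quadrupole must be traceless")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("non-finite site position")


@dataclass
class InteractionEnergy:
    total: float                     # kJ/mol
    near: float                      # pairs with r < near_cutoff
    far: float
    n_near: int
    n_far: int
    per_pair: list = field(default_factory=list)


def extract_site(structure: ProteinStructure, ligand_code: str,
                 cutoff: float = NEAR_CUTOFF_DEFAULT) -> BindingSite:
    """Residues with any atom within ``cutoff`` of the ligand.

    Residues are sorted by closest approach.  Waters survive only if they
    were kept at parsing time.
    """
    ligands = structure.ligands(ligand_code)
    if not ligands:
        avail = structure.ligand_codes()
        raise ValueError(f"no ligand {ligand_code!r}; available: {avail}")
    lig_xyz = np.vstack([res.coords() for res in ligands])
    residues = []
    for chain, res in structure.all_residues():
        if res.is_ligand and res.name == ligand_code:
            continue
        d = np.min(np.linalg.norm(
            res.coords()[:, None, :] - lig_xyz[None, :, :], axis=2))
        if d <= cutoff:
            residues.append((chain, res, float(d)))
    residues.sort(key=lambda t: (t[2], t[0], t[1].number))
    lig_atoms = [a for res in ligands for a in res.atoms]
    return BindingSite(ligand_code=ligand_code, ligand_atoms=lig_atoms,
                       residues=residues, cutoff=cutoff)


def ligand_fingerprint(structure: ProteinStructure, ligand_code: str,
                       env_radius: float = 6.0, grid: float = 0.2,
                       bin_width: float = 0.01,
                       ) -> tuple[FingerprintHistogram, ContactTable]:
    """Hirshfeld fingerprint of the ligand against its protein surroundings."""
    site = extract_site(structure, ligand_code, cutoff=env_radius)
    int_elems = [a.element for a in site.ligand_atoms]
    int_xyz = np.array([a.xyz for a in site.ligand_atoms])
    ext_elems, ext_xyz = [], []
    for _, res, _ in site.residues:
        for a in res.atoms:
            ext_elems.append(a.element)
            ext_xyz.append(a.xyz)
    if not ext_xyz:
        raise ValueError("ligand has no environment atoms: surface is open")
    surface = build_surface_from_atoms(int_elems, int_xyz, ext_elems,
                                       np.array(ext_xyz), grid=grid)
    table = contact_contributions(surface)
    return fingerprint(surface, bin_width=bin_width), table


# --- point-multipole electrostatics ---------------------------------------

def _pair_energy(a: MultipoleSite, b: MultipoleSite, rvec: np.ndarray,
                 r: float) -> float:
    """Interaction energy (kJ/mol) of two point-multipole sites."""
    k = COULOMB_KJ_PER_MOL
    u = rvec / r                      # unit vector from a to b
    e = a.charge * b.charge / r
    if b.dipole is not None:
        # dipole at b in the field of charge a
        e += -a.charge * np.dot(b.dipole, u) / r ** 2
    if a.dipole is not None:
        e += b.charge * np.dot(a.dipole, u) / r ** 2
    if a.dipole is not None and b.dipole is not None:
        e += (np.dot(a.dipole, b.dipole)
              - 3.0 * np.dot(a.dipole, u) * np.dot(b.dipole, u)) / r ** 3
    # charge-quadrupole (Buckingham convention, traceless theta)
    for q, site in ((a.charge, b), (b.charge, a)):
        if site.quadrupole is not None and q != 0.0:
            e += q * 0.5 * (3.0 * u @ site.quadrupole @ u) / r ** 3
    return k * e


def multipole_energy(set_a: Sequence[MultipoleSite],
                     set_b: Sequence[MultipoleSite],
                     near_cutoff: float = NEAR_CUTOFF_DEFAULT,
                     keep_pairs: bool = False) -> InteractionEnergy:
    """Pairwise electrostatic energy between two disjoint multipole sets.

    Terms through dipole-dipole plus charge-quadrupole are summed for every
    pair; each pair is booked as near (r < ``near_cutoff``) or far.  The
    result is symmetric in the two sets and linear in each set's moments.
    """
    near = far = 0.0
    n_near = n_far = 0
    pairs = []
    for a in set_a:
        for b in set_b:
            rvec = b.position - a.position
            r = float(np.linalg.norm(rvec))
            if r < 1e-6:
                raise ValueError("coincident multipole sites (r < 1e-6 Å)")
            e = _pair_energy(a, b, rvec, r)
            if r < near_cutoff:
                near += e
                n_near += 1
            else:
                far += e
                n_far += 1
            if keep_pairs:
                pairs.append((r, e))
    return InteractionEnergy(total=near + far, near=near, far=far,
                             n_near=n_near, n_far=n_far, per_pair=pairs)


def residue_energies(ligand_sites: Sequence[MultipoleSite],
                     residue_sites: dict,
                     near_cutoff: float = NEAR_CUTOFF_DEFAULT) -> dict:
    """Per-residue electrostatic energies; keys as in ``residue_sites``."""
    return {key: multipole_energy(ligand_sites, sites, near_cutoff).total
            for key, sites in residue_sites.items()}


def compare_ligand_geometries(ligands: Sequence[Residue]) -> np.ndarray:
    """Pairwise RMSD matrix of ligand copies, matched by atom name."""
    names = [tuple(a.name for a in lig.atoms) for lig in ligands]
    ref = set(names[0])
    for i, nm in enumerate(names[1:], start=1):
        if set(nm) != ref:
            raise ValueError(f"atom-name mismatch between ligand 0 and {i}")
    n = len(ligands)
    out = np.zeros((n, n))
    for i in range(n):
        ci = {a.name: a.xyz for a in ligands[i].atoms}
        xi = np.array([ci[k] for k in sorted(ref)])
        for j in range(i + 1, n):
            cj = {a.name: a.xyz for a in ligands[j].atoms}
            xj = np.array([cj[k] for k in sorted(ref)])
            rmsd, _ = superpose(xi, xj)
            out[i, j] = out[j, i] = rmsd
    return out
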