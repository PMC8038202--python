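"""Synthetic ground-truth generators for every stage of the pipeline.

Each generator is driven by an explicit integer seed through
``numpy.random.default_rng``; the same (parameters, seed) pair reproduces
the output bit-for-bit, and in the noiseless limit every planted truth is
recovered exactly by the corresponding analysis operation.  Default noise
levels emulate the precision of the experimental procedures being mimicked:
Gaussian SD 0.2 Hz on scalar couplings (1D line fitting / 2D peak-position
reads) and 2% of the maximum intensity on NOESY buildup points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from . import nmr
from .contacts import expand_environment
from .nmr import CouplingSet, KarplusParams, NOEBuildup
from .ring_pucker import build_ring
from .structio import AtomSite, Crystal, parse_symop

__all__ = [
    "SyntheticSpec", "GenerationError", "SPACE_GROUPS",
    "gen_ring", "gen_crystal", "gen_hbond_dimer", "gen_couplings",
    "gen_noesy", "gen_multipoles", "DEFAULT_MIXING_TIMES",
    "COUPLING_NOISE_SD", "INTENSITY_NOISE_FRAC",
]

COUPLING_NOISE_SD = 0.2        # Hz
INTENSITY_NOISE_FRAC = 0.02    # fraction of the maximum buildup intensity
DEFAULT_MIXING_TIMES = np.array([0.100, 0.200, 0.350, 0.500, 0.600, 0.750])

SPACE_GROUPS = {
    "P1": ["x,y,z"],
    "P21": ["x,y,z", "-x,y+1/2,-z"],
    "P212121": ["x,y,z", "x+1/2,-y+1/2,-z", "-x,y+1/2,-z+1/2",
                "-x+1/2,-y,z+1/2"],
}


class GenerationError(RuntimeError):
    """The requested synthetic system cannot be built (e.g. steric clash)."""


@dataclass
class SyntheticSpec:
    """Declarative description of one synthetic dataset."""

    kind: str                    # ring | crystal | couplings | noesy | multipoles
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    def generate(self):
        try:
            fn = {"ring": gen_ring, "crystal": gen_crystal,
                  "couplings": gen_couplings, "noesy": gen_noesy,
                  "multipoles": gen_multipoles}[self.kind]
        except KeyError:
            raise ValueError(f"unknown synthetic kind {self.kind!r}")
        return fn(seed=self.seed, **self.parameters)


def gen_ring(Q: float = 0.55, theta: float = 0.0, phi: float = 0.0,
             bond_length: float = 1.54, noise_sd: float = 0.0,
             seed: int = 0) -> np.ndarray:
    """Six ring-atom positions at a chosen pucker, optionally with
    Gaussian coordinate noise (Å)."""
    coords = build_ring(Q, theta, phi, bond_length=bond_length)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, noise_sd, size=coords.shape)
    return coords


_DEFAULT_MOLECULE = (
    ("O", "H", "H"),
    np.array([[0.0, 0.0, 0.0], [0.96, 0.0, 0.0],
              [-0.24, 0.93, 0.0]]),
)


def gen_crystal(spacegroup: str = "P212121", molecule=None,
                cell=(6.0, 7.0, 8.0, 90.0, 90.0, 90.0),
                origin_frac=(0.13, 0.17, 0.11), min_separation: float = 1.5,
                seed: int = 0) -> Crystal:
    """Toy molecular crystal in P1, P2_1 or P2_1 2_1 2_1.

    ``molecule`` is ``(elements, cartesian coordinates)``; the default is a
    bent water-like molecule.  The asymmetric unit is placed with its
    centroid at ``origin_frac`` (a general position).  A steric check
    requires all intermolecular contacts to exceed ``min_separation``.
    """
    if spacegroup not in SPACE_GROUPS:
        raise ValueError(f"unsupported space group {spacegroup!r}")
    elements, coords = molecule if molecule is not None else _DEFAULT_MOLECULE
    coords = np.asarray(coords, dtype=float)
    ops = [parse_symop(s) for s in SPACE_GROUPS[spacegroup]]

    crystal_probe = Crystal(cell=tuple(cell), symmetry_ops=ops, sites=[
        AtomSite(label=f"{e}{i+1}", element=e, frac_xyz=(0, 0, 0))
        for i, e in enumerate(elements)])
    M = crystal_probe.orthogonalization
    frac = (coords - coords.mean(axis=0)) @ np.linalg.inv(M).T \
        + np.asarray(origin_frac)
    sites = [AtomSite(label=f"{e}{i+1}", element=e, frac_xyz=f)
             for i, (e, f) in enumerate(zip(elements, frac))]
    crystal = Crystal(cell=tuple(cell), symmetry_ops=ops, sites=sites)

    central = crystal.cart_coords()
    for img in expand_environment(crystal, center=0,
                                  radius=max(min_separation + 1.0, 3.0)):
        if img.op_index == 0 and img.lattice == (0, 0, 0):
            continue
        d = np.min(np.linalg.norm(central - img.cart, axis=1))
        if d < min_separation:
            raise GenerationError(
                f"steric clash: intermolecular contact {d:.2f} Å < "
                f"{min_separation} Å; enlarge the cell")
    return crystal


def gen_hbond_dimer(d_DA: float = 2.70, angle_DHA: float = 165.0,
                    d_OH: float = 0.97,
                    cell=(20.0, 21.0, 22.0, 90.0, 90.0, 90.0)) -> Crystal:
    """P1 crystal holding an O-H donor and an O acceptor at a planted
    hydrogen-bond geometry (exact d(D···A) and D-H···A angle)."""
    a = np.radians(angle_DHA)
    D = np.zeros(3)
    H = np.array([d_OH, 0.0, 0.0])
    u = np.array([-np.cos(a), np.sin(a), 0.0])     # direction H -> A
    hu = float(H @ u)
    t = -hu + np.sqrt(hu * hu - d_OH ** 2 + d_DA ** 2)
    A = H + t * u
    crystal = Crystal(
        cell=tuple(cell), symmetry_ops=[parse_symop("x,y,z")],
        sites=[], z_value=1)
    Minv = np.linalg.inv(crystal.orthogonalization)
    shift = np.array([0.25, 0.25, 0.25])
    sites = []
    for label, elem, xyz in (("O1", "O", D), ("H1", "H", H), ("O2", "O", A)):
        sites.append(AtomSite(label=label, element=elem,
                              frac_xyz=xyz @ Minv.T + shift))
    crystal.sites = sites
    return crystal


def gen_couplings(torsions: dict | None = None,
                  rotamers: tuple = (1.0, 0.0, 0.0),
                  params: KarplusParams | None = None,
                  gauche_fraction: float | None = None,
                  noise_sd: float = COUPLING_NOISE_SD,
                  seed: int = 0) -> CouplingSet:
    """Coupling set generated from known torsions and rotamer fractions.

    Ring couplings come from the Karplus curve at the given torsions,
    J_56R/J_56S from the C5-C6 limiting-value model, and (optionally) the
    apparent geminal coupling from a known C6-O6 gauche fraction.
    Noiseless output inverts exactly through the analysis operations.
    """
    A, B, C = rotamers
    if not np.isclose(A + B + C, 1.0):
        raise ValueError("rotamer fractions must sum to 1")
    rng = np.random.default_rng(seed)
    params = params or nmr.haasnoot_altona_params()
    ring = {}
    for name, phi in (torsions or {}).items():
        ring[name] = float(nmr.karplus_forward(phi, params)
                           + (rng.normal(0.0, noise_sd) if noise_sd else 0.0))
    JR, JS = nmr.c5c6_forward(A, B, C)
    if noise_sd:
        JR += rng.normal(0.0, noise_sd)
        JS += rng.normal(0.0, noise_sd)
    J_app = None
    if gauche_fraction is not None:
        Jg, Jt = nmr.c6o6_gauche_trans(A, B, C)
        J_app = gauche_fraction * Jg + (1.0 - gauche_fraction) * Jt
        if noise_sd:
            J_app += rng.normal(0.0, noise_sd)
        J_app = float(J_app)
    return CouplingSet(ring=ring, J_56R=float(JR), J_56S=float(JS),
                       J_6R6S=J_app)


def gen_noesy(distances: dict | None = None, sigma_ref: float = 0.05,
              r_ref: float = nmr.NOE_R_REF, mixing_times=None,
              noise_frac: float = INTENSITY_NOISE_FRAC,
              seed: int = 0) -> list[NOEBuildup]:
    """NOESY buildup curves with slopes sigma = sigma_ref (r/r_ref)^-6.

    ``distances`` maps proton-pair names to distances (Å).  Intensity noise
    is Gaussian with SD ``noise_frac`` of each curve's maximum intensity.
    """
    distances = distances or {"H1-H3": 2.5, "H1-H5": 2.4}
    t = np.asarray(DEFAULT_MIXING_TIMES if mixing_times is None
                   else mixing_times, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for pair, r in distances.items():
        if r <= 0:
            raise ValueError(f"non-positive distance for {pair}")
        sigma = sigma_ref * (r / r_ref) ** -6
        intensities = sigma * t
        if noise_frac:
            intensities = intensities + rng.normal(
                0.0, noise_frac * intensities.max(), size=t.shape)
        out.append(NOEBuildup(pair=tuple(pair.split("-")), mixing_times=t,
                              intensities=intensities, sigma_ref=sigma_ref,
                              r_ref=r_ref))
    return out


def gen_multipoles(n_a: int = 4, n_b: int = 4, with_dipoles: bool = False,
                   separation: float = 8.0, seed: int = 0):
    """Two random, spatially disjoint multipole-site sets for energy tests."""
    from .ligand_env import MultipoleSite
    rng = np.random.default_rng(seed)

    def sample(n, offset):
        sites = []
        for _ in range(n):
            pos = rng.uniform(-1.5, 1.5, 3) + offset
            dip = rng.uniform(-0.3, 0.3, 3) if with_dipoles else None
            sites.append(MultipoleSite(position=pos,
                                       charge=float(rng.uniform(-1, 1)),
                                       dipole=dip))
        return sites

    return sample(n_a, np.zeros(3)), sample(n_b, np.array([separation, 0, 0]))
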