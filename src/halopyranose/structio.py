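"""Structure and table I/O: small-molecule CIF, PDB, symmetry operators, CSV/JSON.

Conventions
-----------
* Fractional coordinates are the internal crystallographic representation;
  Cartesian conversion uses the standard orthogonalization with ``a`` along
  x and ``b`` in the xy-plane.
* Symmetry-operator translations are exact rationals (1/2, 1/4, ...) —
  gemmi's integer/24 representation is preserved as :class:`fractions.Fraction`.
* Atom-site labels are case-preserved; the element comes from the CIF type
  symbol, falling back to the leading alphabetic characters of the label.
* Missing occupancy means 1.0; disordered sites (occupancy < 1) are accepted
  but flagged so downstream analysis can keep the major conformer.
* PDB parsing: 1-based residue numbers, Å, altloc 'A' preferred.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomSite", "SymOp", "Crystal", "ProteinAtom", "Residue", "Chain",
    "ProteinStructure", "CifFormatError", "SymOpParseError",
    "parse_symop", "read_cif", "write_crystal", "read_pdb", "write_pdb",
    "write_table", "WATER_CODES",
]

WATER_CODES = frozenset({"HOH", "WAT", "DOD", "H2O"})

_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn".split())


class CifFormatError(ValueError):
    """A required CIF item is missing or malformed."""


class SymOpParseError(ValueError):
    """A symmetry-operator triplet string could not be parsed."""


def _normalize_element(sym: str) -> str:
    s = re.sub(r"[^A-Za-z]", "", sym)
    cand = s[:2].capitalize()
    if cand in _ELEMENTS:
        return cand
    cand = s[:1].upper()
    if cand in _ELEMENTS:
        return cand
    raise ValueError(f"unrecognized element symbol {sym!r}")


@dataclass
class AtomSite:
    """One atom of the asymmetric unit, in fractional coordinates."""

    label: str
    element: str
    frac_xyz: np.ndarray
    occupancy: float = 1.0
    disordered: bool = field(default=False, compare=False)

    def __post_init__(self):
        self.element = _normalize_element(self.element)
        self.frac_xyz = np.asarray(self.frac_xyz, dtype=float)
        if self.frac_xyz.shape != (3,) or not np.all(np.isfinite(self.frac_xyz)):
            raise ValueError(f"bad fractional coordinates for {self.label}")
        if not (0.0 < self.occupancy <= 1.0):
            raise ValueError(f"occupancy of {self.label} outside (0, 1]")
        if self.occupancy < 1.0:
            self.disordered = True


@dataclass(frozen=True)
class SymOp:
    """Affine symmetry operator in fractional space, exact translations."""

    rot: tuple                 # 3x3 of int
    tran: tuple                # 3 of Fraction

    def apply(self, frac) -> np.ndarray:
        R = np.array(self.rot, dtype=float)
        t = np.array([float(x) for x in self.tran])
        return R @ np.asarray(frac, dtype=float) + t

    @property
    def rot_array(self) -> np.ndarray:
        return np.array(self.rot, dtype=float)

    def triplet(self) -> str:
        out = []
        for row, t in zip(self.rot, self.tran):
            terms = []
            for coef, var in zip(row, "xyz"):
                if coef == 1:
                    terms.append(f"+{var}")
                elif coef == -1:
                    terms.append(f"-{var}")
                elif coef != 0:
                    terms.append(f"{coef:+d}*{var}")
            if t != 0:
                terms.append(f"{'+' if t > 0 else '-'}{abs(t)}")
            out.append("".join(terms).lstrip("+") or "0")
        return ",".join(out)


IDENTITY_OP = SymOp(rot=((1, 0, 0), (0, 1, 0), (0, 0, 1)),
                    tran=(Fraction(0), Fraction(0), Fraction(0)))


def parse_symop(text: str) -> SymOp:
    """Parse a triplet like ``-x+1/2, -y, z+1/2`` into an exact affine op."""
    try:
        op = gemmi.Op(text)
    except (RuntimeError, ValueError) as exc:
        raise SymOpParseError(f"cannot parse symmetry operator {text!r}: {exc}")
    den = gemmi.Op.DEN
    rot = tuple(tuple(v // den for v in row) for row in op.rot)
    for row, orig in zip(rot, op.rot):
        if any(r * den != o for r, o in zip(row, orig)):
            raise SymOpParseError(f"non-integer rotation part in {text!r}")
    tran = tuple(Fraction(v, den) for v in op.tran)
    return SymOp(rot=rot, tran=tran)


@dataclass
class Crystal:
    """Cell, symmetry and asymmetric-unit sites of a molecular crystal."""

    cell: tuple                  # (a, b, c, alpha, beta, gamma); Å / degrees
    symmetry_ops: list
    sites: list
    z_value: int | None = None

    def __post_init__(self):
        a, b, c, al, be, ga = self.cell
        if min(a, b, c) <= 0:
            raise ValueError("cell lengths must be positive")
        if not all(0.0 < x < 180.0 for x in (al, be, ga)):
            raise ValueError("cell angles must lie in (0, 180)")
        if not self.symmetry_ops:
            self.symmetry_ops = [IDENTITY_OP]
        if self.z_value is None:
            self.z_value = len(self.symmetry_ops)

    @property
    def orthogonalization(self) -> np.ndarray:
        """Matrix M with cartesian = M @ fractional (a along x, b in xy)."""
        a, b, c, al, be, ga = self.cell
        al, be, ga = np.radians([al, be, ga])
        cv = (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
        v = np.sqrt(max(np.sin(be) ** 2 - cv ** 2, 0.0))
        return np.array([
            [a, b * np.cos(ga), c * np.cos(be)],
            [0.0, b * np.sin(ga), c * cv],
            [0.0, 0.0, c * v],
        ])

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.orthogonalization)))

    def frac_to_cart(self, frac) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.orthogonalization.T

    def cart_coords(self) -> np.ndarray:
        return self.frac_to_cart(np.array([s.frac_xyz for s in self.sites]))


# --- CIF -------------------------------------------------------------------

_CELL_ITEMS = {
    "_cell_length_a": 0, "_cell_length_b": 1, "_cell_length_c": 2,
    "_cell_angle_alpha": 3, "_cell_angle_beta": 4, "_cell_angle_gamma": 5,
}
_SYMM_TAGS = ("_symmetry_equiv_pos_as_xyz", "_space_group_symop_operation_xyz")


def _cif_number(text: str) -> float:
    return float(re.sub(r"\(\d*\)$", "", text))


def read_cif(path) -> Crystal:
    """Read a small-molecule CIF (single data block) into a :class:`Crystal`."""
    path = Path(path)
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()

    cell = [None] * 6
    for item, idx in _CELL_ITEMS.items():
        val = block.find_value(item)
        if val is None:
            raise CifFormatError(f"{path.name}: missing cell item {item}")
        cell[idx] = _cif_number(val)

    ops: list[SymOp] = []
    for tag in _SYMM_TAGS:
        col = block.find_loop(tag)
        strings = list(col) if col else []
        if not strings:
            val = block.find_value(tag)
            if val is not None:
                strings = [val]
        for s in strings:
            ops.append(parse_symop(gemmi.cif.as_string(s)))
        if ops:
            break
    if not ops:
        ops = [IDENTITY_OP]

    labels = block.find_loop("_atom_site_label")
    if not labels:
        raise CifFormatError(f"{path.name}: missing _atom_site_ loop")
    table = block.find("_atom_site_", ["label", "?type_symbol", "fract_x",
                                       "fract_y", "fract_z", "?occupancy"])
    sites: list[AtomSite] = []
    for row in table:
        label = row[0]
        type_symbol = row[1] if row.has(1) else ""
        try:
            element = _normalize_element(type_symbol or label)
        except ValueError:
            element = _normalize_element(label)
        frac = [_cif_number(row[i]) for i in (2, 3, 4)]
        occ = _cif_number(row[5]) if row.has(5) and row[5] not in ".?" else 1.0
        sites.append(AtomSite(label=label, element=element,
                              frac_xyz=np.array(frac), occupancy=occ))
    if not sites:
        raise CifFormatError(f"{path.name}: empty _atom_site_ loop")

    zval = block.find_value("_cell_formula_units_Z")
    z = int(_cif_number(zval)) if zval is not None else None
    return Crystal(cell=tuple(cell), symmetry_ops=ops, sites=sites, z_value=z)


def write_crystal(crystal: Crystal, path, precision: int = 6) -> Path:
    """Write a minimal small-molecule CIF; round-trips through read_cif."""
    path = Path(path)
    p = precision
    lines = ["data_halopyranose", ""]
    names = ("a", "b", "c", "alpha", "beta", "gamma")
    for name, val in zip(names, crystal.cell):
        tag = f"_cell_length_{name}" if name in "abc" else f"_cell_angle_{name}"
        lines.append(f"{tag} {val:.{p}f}")
    lines.append(f"_cell_formula_units_Z {crystal.z_value}")
    lines += ["", "loop_", "_space_group_symop_operation_xyz"]
    lines += [f"'{op.triplet()}'" for op in crystal.symmetry_ops]
    lines += ["", "loop_", "_atom_site_label", "_atom_site_type_symbol",
              "_atom_site_fract_x", "_atom_site_fract_y", "_atom_site_fract_z",
              "_atom_site_occupancy"]
    for s in crystal.sites:
        x, y, z = s.frac_xyz
        lines.append(f"{s.label} {s.element} {x:.{p}f} {y:.{p}f} {z:.{p}f} "
                     f"{s.occupancy:.4f}")
    path.write_text("\n".join(lines) + "\n")
    return path


# --- PDB -------------------------------------------------------------------

@dataclass
class ProteinAtom:
    name: str
    element: str
    xyz: np.ndarray

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    name: str
    number: int
    atoms: list
    is_ligand: bool = False
    is_water: bool = False

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])


@dataclass
class Chain:
    name: str
    residues: list


@dataclass
class ProteinStructure:
    chains: list

    def all_residues(self) -> Iterable[tuple[str, Residue]]:
        for ch in self.chains:
            for res in ch.residues:
                yield ch.name, res

    def ligands(self, code: str | None = None) -> list:
        out = [r for _, r in self.all_residues()
               if r.is_ligand and (code is None or r.name == code)]
        return out

    def ligand_codes(self) -> list:
        return sorted({r.name for _, r in self.all_residues() if r.is_ligand})


def read_pdb(path, remove_waters: bool = False,
             ligand_codes: Sequence[str] = ()) -> ProteinStructure:
    """Read a PDB coordinate file.

    Residues appearing as HETATM (or whose name is in ``ligand_codes``) and
    that are not water are flagged as ligands.  With ``remove_waters`` the
    water residues are dropped, mirroring structure preparation for
    binding-site analysis.
    """
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no ATOM/HETATM records")
    model = st[0]
    chains: list[Chain] = []
    n_atoms = 0
    for ch in model:
        residues: list[Residue] = []
        seen_numbers = set()
        for res in ch:
            num = res.seqid.num
            if num in seen_numbers:
                raise ValueError(f"duplicate residue number {num} in chain {ch.name}")
            seen_numbers.add(num)
            is_water = res.name in WATER_CODES
            if remove_waters and is_water:
                continue
            atoms = []
            for at in res:
                if at.altloc not in ("", " ", "\x00", "A"):
                    continue
                atoms.append(ProteinAtom(
                    name=at.name, element=at.element.name or at.name[0],
                    xyz=np.array([at.pos.x, at.pos.y, at.pos.z])))
            if not atoms:
                continue
            is_ligand = ((res.het_flag == "H" and not is_water)
                         or res.name in ligand_codes)
            residues.append(Residue(name=res.name, number=num, atoms=atoms,
                                    is_ligand=is_ligand, is_water=is_water))
            n_atoms += len(atoms)
        if residues:
            chains.append(Chain(name=ch.name, residues=residues))
    if n_atoms == 0:
        raise ValueError(f"{path}: no ATOM/HETATM records")
    return ProteinStructure(chains=chains)


def write_pdb(structure: ProteinStructure, path) -> Path:
    """Write a minimal PDB coordinate file (ATOM/HETATM + END)."""
    path = Path(path)
    lines = []
    serial = 1
    for ch in structure.chains:
        for res in ch.residues:
            record = "HETATM" if (res.is_ligand or res.is_water) else "ATOM  "
            for at in res.atoms:
                name = at.name if len(at.name) >= 4 else f" {at.name:<3s}"
                x, y, z = at.xyz
                lines.append(
                    f"{record}{serial:5d} {name:<4s} {res.name:<3s} "
                    f"{ch.name[:1]}{res.number:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {at.element:>2s}")
                serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


# --- result tables ---------------------------------------------------------

def write_table(records: Sequence, path, fmt: str = "csv",
                precision: int = 6, columns: Sequence[str] | None = None) -> Path:
    """Write result rows (mappings or dataclass-likes) as CSV or JSON.

    Column order is the field order of the first record (or ``columns`` for
    an empty record list, yielding a header-only file); numbers are written
    with ``precision`` significant digits.
    """
    path = Path(path)
    rows = []
    for rec in records:
        if hasattr(rec, "__dataclass_fields__"):
            rows.append({k: getattr(rec, k) for k in rec.__dataclass_fields__})
        else:
            rows.append(dict(rec))
    df = pd.DataFrame(rows, columns=list(rows[0].keys()) if rows else columns)
    try:
        if fmt == "csv":
            df.to_csv(path, index=False, float_format=f"%.{precision}g")
        elif fmt == "json":
            path.write_text(json.dumps(
                json.loads(df.to_json(orient="records", double_precision=10)),
                indent=1))
        else:
            raise ValueError(f"unknown table format {fmt!r}")
    except OSError as exc:
        raise OSError(f"cannot write table to {path}: {exc}")
    return path
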