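import numpy as np
import pytest

import halopyranose as hp

TOY_CIF = """\
data_toy
_cell_length_a 7.0
_cell_length_b 9.0
_cell_length_c 11.0
_cell_angle_alpha 90.0
_cell_angle_beta 90.0
_cell_angle_gamma 90.0
_cell_formula_units_Z 4
loop_
_space_group_symop_operation_xyz
'x,y,z'
'x+1/2,-y+1/2,-z'
'-x,y+1/2,-z+1/2'
'-x+1/2,-y,z+1/2'
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
_atom_site_occupancy
O5 O 0.100 0.120 0.110 1.0
C1 C 0.210 0.160 0.150 1.0
C2 C 0.300 0.110 0.230 1.0
C3 C 0.260 0.120 0.340 1.0
C4 C 0.140 0.090 0.350 1.0
C5 C 0.060 0.140 0.260 1.0
O1 O 0.290 0.250 0.120 1.0
H1 H 0.220 0.070 0.100 1.0
H2 H 0.390 0.140 0.220 1.0
H3 H 0.270 0.210 0.360 1.0
H4 H 0.120 0.000 0.360 1.0
HO1 H 0.350 0.260 0.170 1.0
"""

TOY_PDB = """\
ATOM      1  N   ALA A   1      10.000  10.000  10.000  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.200  10.600  10.400  1.00  0.00           C
ATOM      3  C   ALA A   1      12.300   9.700  10.900  1.00  0.00           C
ATOM      4  O   ALA A   1      12.200   8.500  10.800  1.00  0.00           O
ATOM      5  CB  ALA A   1      11.700  11.500   9.300  1.00  0.00           C
ATOM      6  N   GLY A   2      20.000  20.000  20.000  1.00  0.00           N
ATOM      7  CA  GLY A   2      21.200  20.700  20.300  1.00  0.00           C
ATOM      8  C   GLY A   2      22.300  19.800  20.800  1.00  0.00           C
ATOM      9  O   GLY A   2      22.100  18.600  20.900  1.00  0.00           O
HETATM   10  C1  LIG A 101      13.500  11.500  11.500  1.00  0.00           C
HETATM   11  O1  LIG A 101      14.400  12.300  11.200  1.00  0.00           O
HETATM   12  C2  LIG A 101      13.800  10.400  12.400  1.00  0.00           C
HETATM   13  O   HOH A 201      15.000  15.000  15.000  1.00  0.00           O
HETATM   14  O   HOH A 202      16.000  16.000  16.000  1.00  0.00           O
HETATM   15  O   HOH A 203      17.000  17.000  17.000  1.00  0.00           O
END
"""


@pytest.fixture
def toy_cif(tmp_path):
    p = tmp_path / "toy.cif"
    p.write_text(TOY_CIF)
    return p


@pytest.fixture
def toy_pdb(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return p


def quaternion_rmsd(ref, mob):
    """Independent optimal-superposition RMSD via Horn's quaternion method."""
    ref = np.asarray(ref, float)
    mob = np.asarray(mob, float)
    a = ref - ref.mean(axis=0)
    b = mob - mob.mean(axis=0)
    M = b.T @ a
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz]])
    lam = np.linalg.eigvalsh(K)[-1]
    e = float((a ** 2).sum() + (b ** 2).sum() - 2.0 * lam)
    return np.sqrt(max(e, 0.0) / len(ref))


@pytest.fixture
def single_atom_crystal():
    """Dense P2_1 2_1 2_1 packing of lone O atoms (Z = 4)."""
    mol = (("O",), np.array([[0.0, 0.0, 0.0]]))
    return hp.gen_crystal("P212121", molecule=mol,
                          cell=(4.2, 4.4, 4.6, 90, 90, 90))
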