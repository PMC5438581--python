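"""Hydrogen bonds, salt bridges, hydrophobic contacts, metal/site/lid
geometry."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lipdyn.core import Selection, Trajectory
from lipdyn.interactions import (
    active_site_geometry,
    assign_hydrophobic_types,
    count_hydrophobic_contacts,
    count_salt_bridges,
    find_hbonds,
    hbond_energy,
    lid_metrics,
    metal_coordination,
)
from lipdyn.selection import select
from lipdyn.synthetic import (
    make_catalytic_triad_fixture,
    make_interaction_fixture,
    make_toy_protein,
)
from tests.conftest import make_atoms


def all_atoms(structure) -> Selection:
    return Selection.from_indices(range(len(structure.atoms)))


class TestHbondEnergy:
    def test_ideal_geometry_is_25(self):
        assert hbond_energy(2.1, 180, 180) == pytest.approx(25.0)
        # distances below the 2.1 plateau do not raise the energy further
        assert hbond_energy(1.8, 180, 180) == pytest.approx(25.0)

    def test_vanishes_at_2p6_regardless_of_angles(self):
        for th in (0, 90, 180):
            assert hbond_energy(2.6, th, th) == 0.0
            assert hbond_energy(3.5, th, th) == 0.0

    def test_midpoint_value(self):
        assert hbond_energy(2.35, 180, 180) == pytest.approx(12.5)

    def test_monotone_nonincreasing_in_distance(self):
        ds = np.linspace(0.5, 3.5, 100)
        es = [hbond_energy(d, 150, 150) for d in ds]
        assert all(e1 >= e2 - 1e-12 for e1, e2 in zip(es, es[1:]))

    def test_continuity_at_kinks(self):
        for d0 in (2.1, 2.6):
            lo = hbond_energy(d0 - 1e-9, 170, 170)
            hi = hbond_energy(d0 + 1e-9, 170, 170)
            assert lo == pytest.approx(hi, abs=1e-6)

    def test_scale_factors_bounded(self):
        assert hbond_energy(2.1, 100, 180) == 0.0      # DHA ramp floor
        assert hbond_energy(2.1, 140, 180) == pytest.approx(12.5)
        assert hbond_energy(2.1, 180, 80) == 0.0       # HAX ramp floor


class TestFindHbonds:
    def test_collinear_fixture_energy_25(self):
        s = make_interaction_fixture("hbond", d_ha=2.0)
        bonds, count = find_hbonds(s, all_atoms(s), all_atoms(s), mode="energy")
        assert count == 1
        assert bonds[0].energy == pytest.approx(25.0)

    def test_far_acceptor_no_bond_either_mode(self):
        s = make_interaction_fixture("hbond", d_ha=4.0)
        for mode in ("energy", "distance"):
            _, count = find_hbonds(s, all_atoms(s), all_atoms(s), mode=mode)
            assert count == 0

    def test_heavy_atom_rule_without_hydrogens(self):
        """Donor N to acceptor O at 3.4 A counts under the <3.5 rule."""
        s = make_atoms([
            ("N", "N", "GLY", 1, (0, 0, 0)),
            ("C", "C", "GLY", 3, (3.4 + 1.23, 0, 0)),
            ("O", "O", "GLY", 3, (3.4, 0, 0)),
        ])
        _, count = find_hbonds(s, all_atoms(s), all_atoms(s), mode="distance")
        assert count == 1
        s2 = make_atoms([
            ("N", "N", "GLY", 1, (0, 0, 0)),
            ("C", "C", "GLY", 3, (3.6 + 1.23, 0, 0)),
            ("O", "O", "GLY", 3, (3.6, 0, 0)),
        ])
        _, count2 = find_hbonds(s2, all_atoms(s2), all_atoms(s2), mode="distance")
        assert count2 == 0

    def test_energy_mode_falls_back_without_hydrogens(self, helix12):
        sel = all_atoms(helix12)
        _, n_energy = find_hbonds(helix12, sel, sel, mode="energy")
        _, n_dist = find_hbonds(helix12, sel, sel, mode="distance")
        assert n_energy == n_dist


class TestSaltBridges:
    def test_lys_inside_cutoff(self):
        s = make_interaction_fixture("salt_bridge", d=3.9)
        count, records = count_salt_bridges(s)
        assert count == 1
        assert records[0].contact_class == "salt_bridge"

    def test_lys_boundary_excluded(self):
        s = make_interaction_fixture("salt_bridge", d=4.01)
        assert count_salt_bridges(s)[0] == 0
        # exactly at 4.0 the strict < excludes
        s_eq = make_interaction_fixture("salt_bridge", d=4.0)
        assert count_salt_bridges(s_eq)[0] == 0

    def test_arg_tighter_cutoff(self):
        s = make_interaction_fixture("salt_bridge", d=3.6, basic="ARG")
        assert count_salt_bridges(s)[0] == 0
        s2 = make_interaction_fixture("salt_bridge", d=3.4, basic="ARG")
        assert count_salt_bridges(s2)[0] == 1

    def test_no_charged_residues(self, helix12):
        assert count_salt_bridges(helix12)[0] == 0

    def test_residue_pair_deduplication(self):
        """Two qualifying oxygens of one Glu count a single bridge."""
        s = make_atoms([
            ("NZ", "N", "LYS", 1, (0, 0, 0)),
            ("OE1", "O", "GLU", 5, (3.0, 0, 0)),
            ("OE2", "O", "GLU", 5, (3.0, 1.5, 0)),
        ])
        assert count_salt_bridges(s)[0] == 1

    def test_monotone_in_cutoff(self):
        s = make_atoms([
            ("NZ", "N", "LYS", 1, (0, 0, 0)),
            ("OD1", "O", "ASP", 5, (4.5, 0, 0)),
            ("NE", "N", "ARG", 9, (0, 8, 0)),
            ("OE1", "O", "GLU", 12, (3.7, 8, 0)),
        ])
        counts = [count_salt_bridges(s, lys_cutoff=c, arg_cutoff=c - 0.5)[0]
                  for c in (3.0, 4.0, 5.0, 6.0)]
        assert counts == sorted(counts)


class TestHydrophobicTyping:
    def test_ala_cb_with_explicit_hydrogens_is_type1(self):
        s = make_interaction_fixture("hydrophobic_pair")
        types = assign_hydrophobic_types(s)
        cb_types = [t for a, t in zip(s.atoms, types) if a.name == "CB"]
        assert cb_types == [1, 1]

    def test_template_typing_without_hydrogens(self):
        """A hydrogen-less Leu side chain types from residue templates:
        CB (2H) -> 2, CG (1H + 3C) -> 2, CD1/CD2 (3H) -> 1."""
        s = make_atoms([
            ("CB", "C", "LEU", 1, (0.0, 0, 0)),
            ("CG", "C", "LEU", 1, (1.5, 0, 0)),
            ("CD1", "C", "LEU", 1, (2.3, 1.2, 0)),
            ("CD2", "C", "LEU", 1, (2.3, -1.2, 0)),
        ])
        types = assign_hydrophobic_types(s)
        assert types == [2, 2, 1, 1]

    def test_aromatic_ring_and_polar_none(self):
        s = make_atoms([
            ("CG", "C", "PHE", 1, (0, 0, 0)),
            ("OG", "O", "SER", 2, (10, 0, 0)),
            ("CB", "C", "SER", 2, (11.5, 0, 0)),
        ])
        types = assign_hydrophobic_types(s)
        assert types[0] == 3          # Phe ring carbon
        assert types[1] is None       # oxygen never typed
        assert types[2] == 2          # Ser CB: 2 implicit H


class TestHydrophobicContacts:
    def test_pair_below_5A_counts(self):
        s = make_interaction_fixture("hydrophobic_pair", d=4.9)
        count, _ = count_hydrophobic_contacts(s, "intra_protein")
        assert count >= 1

    def test_pair_above_5A_zero_carbon_pairs(self):
        s = make_interaction_fixture("hydrophobic_pair", d=5.1)
        count, records = count_hydrophobic_contacts(s, "intra_protein")
        carbon_pairs = [
            r for r in records
            if s.atoms[r.atom_i].element == "C" and s.atoms[r.atom_j].element == "C"
        ]
        assert carbon_pairs == []

    def test_matches_bruteforce_oracle(self):
        """Spatial-tree counting equals the O(n^2) double loop on a
        50-atom random fixture."""
        rng = np.random.default_rng(5)
        specs = []
        for k in range(25):
            xyz = rng.uniform(0, 18, 3)
            specs.append(("CB", "C", "ALA", k + 1, tuple(xyz)))
            for h in range(3):
                specs.append((f"HB{h+1}", "H", "ALA", k + 1,
                              tuple(xyz + [0.3 * (h + 1), 0.3, 0.5])))
        s = make_atoms(specs)
        count, records = count_hydrophobic_contacts(s, "intra_protein", cutoff=5.0)
        types = assign_hydrophobic_types(s)
        brute = 0
        for i, j in itertools.combinations(range(len(s.atoms)), 2):
            ai, aj = s.atoms[i], s.atoms[j]
            if types[i] is None or types[j] is None:
                continue
            if ai.resid == aj.resid:
                continue
            if np.linalg.norm(ai.coords - aj.coords) < 5.0:
                brute += 1
        assert count == brute

    def test_protein_to_hetgroup_mode(self):
        specs = [("CB", "C", "ALA", 1, (0.0, 0, 0))]
        for h in range(3):
            specs.append((f"HB{h+1}", "H", "ALA", 1, (0.3, 0.3 * h, 0.9)))
        # a methanol-like carbon 4 A away
        specs.append(("C1", "C", "MOH", 2, (4.0, 0, 0)))
        for h in range(3):
            specs.append((f"H{h+1}", "H", "MOH", 2, (4.3, 0.3 * h, 0.9)))
        s = make_atoms(specs)
        count, _ = count_hydrophobic_contacts(s, "protein_to_hetgroup")
        assert count == 1
        intra, _ = count_hydrophobic_contacts(s, "intra_protein")
        assert intra == 0


class TestMetalCoordination:
    def test_synthetic_probe_distance(self):
        s = make_interaction_fixture(
            "metal_site", element="CA", shell=[(1, "GLU", "OE2", 2.0)]
        )
        ion = next(i for i, a in enumerate(s.atoms) if a.category == "ion")
        dists = metal_coordination(s, ion, [(1, "GLU", "OE2")])
        assert dists == [pytest.approx(2.0, abs=1e-9)]

    def test_shell_order_preserved(self):
        shell_spec = [(286, "GLY", "O", 2.2), (360, "GLU", "OE2", 2.32),
                      (365, "ASP", "OD2", 2.44), (366, "PRO", "O", 2.37)]
        s = make_interaction_fixture("metal_site", element="CA", shell=shell_spec)
        ion = next(i for i, a in enumerate(s.atoms) if a.category == "ion")
        dists = metal_coordination(s, ion, [t[:3] for t in shell_spec])
        assert dists == [pytest.approx(d, abs=1e-9) for *_, d in shell_spec]

    def test_missing_shell_atom_named(self):
        s = make_interaction_fixture("metal_site")
        ion = next(i for i, a in enumerate(s.atoms) if a.category == "ion")
        with pytest.raises(KeyError, match="ASP999"):
            metal_coordination(s, ion, [(999, "ASP", "OD2")])


class TestActiveSite:
    def test_constructed_angle_and_flags(self):
        s = make_catalytic_triad_fixture(ca_angle=43.16, d_asp_his=2.8,
                                         d_ser_his=3.1)
        g = active_site_geometry(s)
        assert g.ca_angle == pytest.approx(43.16, abs=1e-9)
        assert g.d_asp_od2_his_nd1 == pytest.approx(2.8, abs=1e-9)
        assert g.hbond_asp_his and g.hbond_ser_his

    def test_collinear_triad_180(self):
        s = make_catalytic_triad_fixture(ca_angle=180.0)
        assert active_site_geometry(s).ca_angle == pytest.approx(180.0)

    def test_flag_threshold(self):
        s = make_catalytic_triad_fixture(d_ser_his=3.6)
        g = active_site_geometry(s)
        assert not g.hbond_ser_his

    def test_missing_residue_raises(self, helix12):
        with pytest.raises(KeyError):
            active_site_geometry(helix12)


class TestLidMetrics:
    def test_distance_trivial_and_static_rmsd_zero(self):
        lid = make_toy_protein(56, "lid_like", resid_offset=175)
        frames = np.stack([lid.coords] * 3)
        traj = Trajectory(lid, frames, np.arange(3.0) * 30)
        dist_s, rmsd_s = lid_metrics(traj, (175, 230), lid)
        i_lo = lid.find_atom(175, "CA")
        i_hi = lid.find_atom(230, "CA")
        expected = float(np.linalg.norm(lid.coords[i_lo] - lid.coords[i_hi]))
        assert np.allclose(dist_s.values, expected)
        assert np.allclose(rmsd_s.values, 0.0, atol=1e-9)

    def test_rigid_lid_displacement_recovered(self):
        """Displace only resid 200-230 by 2 A: lid RMSD reports the
        displacement magnitude over lid backbone atoms."""
        prot = make_toy_protein(120, "extended", resid_offset=150)
        coords = prot.coords.copy()
        lid_idx = [i for i, a in enumerate(prot.atoms) if 200 <= a.resid <= 230]
        coords[lid_idx] += np.array([0.0, 0.0, 2.0])
        frames = np.stack([coords])
        traj = Trajectory(prot, frames, np.array([0.0]))
        _, rmsd_s = lid_metrics(traj, (200, 230), prot)
        # core is unchanged -> fit is identity -> lid rmsd = 2 A
        assert rmsd_s.values[0] == pytest.approx(2.0, abs=0.01)

    def test_missing_lid_residue_raises(self, helix12):
        frames = np.stack([helix12.coords])
        traj = Trajectory(helix12, frames, np.array([0.0]))
        with pytest.raises(KeyError):
            lid_metrics(traj, (175, 230), helix12)


class TestRigidMotionInvariance:
    @pytest.mark.parametrize("seed", [1, 2])
    def test_census_counts_invariant(self, seed):
        s = make_interaction_fixture("salt_bridge", d=3.5)
        rot = Rotation.from_euler("xyz", [11 * seed, -23, 41], degrees=True).as_matrix()
        moved = s.with_coords(s.coords @ rot.T + np.array([3.0, -7, 2]))
        assert count_salt_bridges(moved)[0] == count_salt_bridges(s)[0]
        hp = make_interaction_fixture("hydrophobic_pair", d=4.2)
        hp_m = hp.with_coords(hp.coords @ rot.T + 5.0)
        assert (count_hydrophobic_contacts(hp_m, "intra_protein")[0]
                == count_hydrophobic_contacts(hp, "intra_protein")[0])
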