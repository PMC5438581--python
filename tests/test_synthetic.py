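"""The synthetic-data generators themselves."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from lipdyn.core import Selection
from lipdyn.correlations import dccm
from lipdyn.errors import PlacementError
from lipdyn.solvent import BUILTIN_SPECIES
from lipdyn.synthetic import (
    SyntheticSpec,
    make_catalytic_triad_fixture,
    make_gaussian_trajectory,
    make_interaction_fixture,
    make_solvated_box,
    make_toy_protein,
)


class TestToyProtein:
    @pytest.mark.parametrize("geometry", ["alpha_helix", "extended", "lid_like"])
    def test_backbone_bond_lengths_sane(self, geometry):
        s = make_toy_protein(20, geometry)
        res = {}
        for a in s.atoms:
            res.setdefault(a.resid, {})[a.name] = a.coords
        for r in range(1, 21):
            assert np.linalg.norm(res[r]["CA"] - res[r]["N"]) == pytest.approx(1.458, abs=0.01)
            assert np.linalg.norm(res[r]["C"] - res[r]["CA"]) == pytest.approx(1.525, abs=0.01)
            if r < 20:
                assert np.linalg.norm(res[r + 1]["N"] - res[r]["C"]) == pytest.approx(1.329, abs=0.01)

    def test_lid_like_offset_contains_lid_termini(self):
        s = make_toy_protein(56, "lid_like", resid_offset=175)
        assert s.find_atom(175, "CA") >= 0
        assert s.find_atom(230, "CA") >= 0

    def test_too_few_residues_rejected(self):
        with pytest.raises(ValueError):
            make_toy_protein(2, "alpha_helix")

    def test_structure_invariants_hold(self):
        make_toy_protein(10, "lid_like").validate()


class TestGaussianTrajectory:
    def test_zero_variance_equals_reference(self, helix12):
        spec = SyntheticSpec(n_atoms=len(helix12.atoms), variances=0.0,
                             n_frames=4, seed=1)
        traj = make_gaussian_trajectory(spec, helix12)
        assert np.allclose(traj.frames, helix12.coords[None])

    def test_bit_reproducible_per_seed(self, helix12):
        spec = SyntheticSpec(n_atoms=len(helix12.atoms), variances=0.25,
                             n_frames=20, seed=42)
        t1 = make_gaussian_trajectory(spec, helix12)
        t2 = make_gaussian_trajectory(spec, helix12)
        assert np.array_equal(t1.frames, t2.frames)
        spec_other = SyntheticSpec(n_atoms=len(helix12.atoms), variances=0.25,
                                   n_frames=20, seed=43)
        t3 = make_gaussian_trajectory(spec_other, helix12)
        assert not np.array_equal(t1.frames, t3.frames)

    def test_non_psd_covariance_refused(self, helix12):
        # three atoms pairwise correlated at -0.9 cannot coexist
        spec = SyntheticSpec(
            n_atoms=len(helix12.atoms), variances=0.25,
            correlation_blocks=[([0, 1, 2], -0.9)], n_frames=10, seed=0,
        )
        with pytest.raises(ValueError, match="semi-definite"):
            make_gaussian_trajectory(spec, helix12)

    def test_perfectly_anticorrelated_pair(self, helix12):
        spec = SyntheticSpec(
            n_atoms=len(helix12.atoms), variances=0.25,
            correlation_blocks=[([0, 1], -1.0)], n_frames=400, seed=7,
        )
        traj = make_gaussian_trajectory(spec, helix12)
        m = dccm(traj, selection=Selection.from_indices([0, 1]),
                 last_fraction=1.0, fit_selection=Selection.from_indices([0]))
        assert m.matrix[0, 1] == pytest.approx(-1.0, abs=1e-6)

    def test_empirical_covariance_converges(self, helix12):
        """Frobenius relative error of the displacement covariance
        against the prescription stays under 10% at 5000 frames."""
        blocks = [([0, 1, 2, 3], 0.5)]
        spec = SyntheticSpec(n_atoms=len(helix12.atoms), variances=0.25,
                             correlation_blocks=blocks, n_frames=5000, seed=3)
        traj = make_gaussian_trajectory(spec, helix12)
        disp = traj.frames - helix12.coords[None]
        # pool the three axes (independent, same covariance)
        pooled = np.concatenate([disp[:, :, c] for c in range(3)], axis=0)
        emp = np.cov(pooled.T, bias=True)
        target = spec.covariance()
        rel = np.linalg.norm(emp - target) / np.linalg.norm(target)
        assert rel < 0.10

    def test_atom_count_mismatch(self, helix12, extended8):
        spec = SyntheticSpec(n_atoms=len(helix12.atoms), n_frames=4)
        with pytest.raises(ValueError):
            make_gaussian_trajectory(spec, extended8)


class TestSolvatedBox:
    def test_zero_molecules_protein_unchanged(self, helix12):
        box = make_solvated_box(helix12, BUILTIN_SPECIES["water"], 0, seed=0)
        assert len(box.atoms) == len(helix12.atoms)
        assert np.allclose(box.coords, helix12.coords)

    def test_deterministic_per_seed(self, helix12):
        b1 = make_solvated_box(helix12, BUILTIN_SPECIES["water"], 40,
                               box_margin=7.0, seed=9)
        b2 = make_solvated_box(helix12, BUILTIN_SPECIES["water"], 40,
                               box_margin=7.0, seed=9)
        assert np.array_equal(b1.coords, b2.coords)

    def test_min_heavy_distance_bruteforce(self, helix12):
        box = make_solvated_box(helix12, BUILTIN_SPECIES["ethanol"], 15,
                                box_margin=6.0, seed=2)
        heavy = [i for i, a in enumerate(box.atoms) if a.element != "H"]
        n_protein_heavy = sum(1 for a in helix12.atoms if a.element != "H")
        coords = box.coords
        solvent_heavy = heavy[n_protein_heavy:]
        for i in solvent_heavy:
            for j in heavy:
                if i == j:
                    continue
                same_mol = (box.atoms[i].resid == box.atoms[j].resid
                            and box.atoms[i].chain == box.atoms[j].chain)
                if not same_mol:
                    assert np.linalg.norm(coords[i] - coords[j]) >= 2.2 - 1e-9

    def test_atoms_per_molecule_matches_species(self, helix12):
        for name in ("water", "methanol", "pentanol"):
            sp = BUILTIN_SPECIES[name]
            box = make_solvated_box(helix12, sp, 3, box_margin=8.0, seed=1)
            added = len(box.atoms) - len(helix12.atoms)
            assert added == 3 * sp.atoms_per_molecule

    def test_impossible_box_reports_achieved(self, helix12):
        with pytest.raises(PlacementError) as err:
            make_solvated_box(helix12, BUILTIN_SPECIES["pentanol"], 5000,
                              box_margin=1.0, seed=0, max_tries=10)
        assert 0 <= err.value.achieved < 5000


class TestFixtures:
    def test_hbond_fixture_geometry_exact(self):
        s = make_interaction_fixture("hbond", d_ha=2.1)
        h = next(a for a in s.atoms if a.name == "H")
        o = next(a for a in s.atoms if a.name == "O")
        assert np.linalg.norm(h.coords - o.coords) == pytest.approx(2.1, abs=1e-6)

    def test_salt_bridge_boundary_pair(self):
        from lipdyn.interactions import count_salt_bridges

        assert count_salt_bridges(make_interaction_fixture("salt_bridge", d=3.99))[0] == 1
        assert count_salt_bridges(make_interaction_fixture("salt_bridge", d=4.01))[0] == 0

    def test_metal_fixture_distance(self):
        from lipdyn.interactions import metal_coordination

        s = make_interaction_fixture("metal_site",
                                     shell=[(5, "GLU", "OE2", 2.32)])
        ion = next(i for i, a in enumerate(s.atoms) if a.category == "ion")
        assert metal_coordination(s, ion, [(5, "GLU", "OE2")])[0] == pytest.approx(2.32, abs=1e-6)

    def test_triad_fixture_validates(self):
        make_catalytic_triad_fixture().validate()

    def test_unknown_kind_raises(self):
        with pytest.raises(ValueError):
            make_interaction_fixture("wormhole")
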