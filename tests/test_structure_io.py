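"""Structure parsing, selection grammar, primitive geometry, tables."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipdyn.core import Trajectory, categorize_resname
from lipdyn.errors import ParseError, SelectionSyntaxError, TopologyError
from lipdyn.geometry import angle, distance
from lipdyn.pdbio import (
    read_structure,
    read_trajectory,
    write_structure,
    write_trajectory,
)
from lipdyn.selection import select
from lipdyn.synthetic import SyntheticSpec, make_gaussian_trajectory, make_toy_protein
from lipdyn.tables import read_table, write_table

finite_coord = st.floats(-500, 500, allow_nan=False, allow_infinity=False)
vec3 = st.tuples(finite_coord, finite_coord, finite_coord)


class TestReadStructure:
    def test_identity_parse_preserves_atoms(self, tiny_pdb_text, tmp_path):
        path = tmp_path / "tiny.pdb"
        path.write_text(tiny_pdb_text)
        s = read_structure(path)
        assert [a.name for a in s.atoms] == ["N", "CA", "C", "CA"]
        assert [a.resid for a in s.atoms] == [1, 1, 1, 400]
        assert s.atoms[0].bfactor == pytest.approx(10.0)

    def test_calcium_hetatm_categorized_as_ion(self, tiny_pdb_text, tmp_path):
        path = tmp_path / "tiny.pdb"
        path.write_text(tiny_pdb_text)
        s = read_structure(path)
        assert s.atoms[3].category == "ion"
        assert s.atoms[3].element == "CA"
        # the alpha carbon of residue 1 is NOT an ion
        assert s.atoms[1].category == "protein"
        assert s.atoms[1].element == "C"

    def test_water_and_organic_categories(self):
        assert categorize_resname("HOH") == "water"
        assert categorize_resname("MOH") == "organic_solvent"
        assert categorize_resname("XYZ", extra_organic={"XYZ"}) == "organic_solvent"
        assert categorize_resname("GLU") == "protein"

    def test_malformed_coordinate_names_line(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text("ATOM      1  N   ALA A   1       x.000   0.000   0.000\n")
        with pytest.raises(ParseError, match="line 1"):
            read_structure(path)

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(ParseError):
            read_structure(path)

    def test_roundtrip_preserves_order_names_resids(self, tmp_path):
        s = make_toy_protein(6, "alpha_helix", resid_offset=40)
        path = tmp_path / "toy.pdb"
        write_structure(s, path)
        s2 = read_structure(path)
        assert [a.name for a in s2.atoms] == [a.name for a in s.atoms]
        assert [a.resid for a in s2.atoms] == [a.resid for a in s.atoms]
        assert [a.resname for a in s2.atoms] == [a.resname for a in s.atoms]


class TestReadTrajectory:
    def test_two_identical_models(self, tmp_path, helix12):
        traj = Trajectory(helix12, np.stack([helix12.coords] * 2),
                          np.array([0.0, 30.0]))
        path = tmp_path / "t.pdb"
        write_trajectory(traj, path)
        back = read_trajectory(helix12, path)
        assert back.n_frames == 2
        assert np.allclose(back.frames[0], back.frames[1])
        # default spacing is 30 ps
        assert np.allclose(back.times, [0.0, 30.0])

    def test_roundtrip_to_pdb_precision(self, tmp_path, helix12):
        spec = SyntheticSpec(n_atoms=len(helix12.atoms), variances=0.1,
                             n_frames=5, seed=3)
        traj = make_gaussian_trajectory(spec, helix12)
        path = tmp_path / "t.pdb"
        write_trajectory(traj, path)
        back = read_trajectory(helix12, path)
        assert back.frames.shape == traj.frames.shape
        assert np.max(np.abs(back.frames - traj.frames)) <= 1e-3 + 1e-12

    def test_atom_count_mismatch_reports_counts(self, tmp_path, helix12, extended8):
        traj = Trajectory(helix12, helix12.coords[None], np.array([0.0]))
        path = tmp_path / "t.pdb"
        write_trajectory(traj, path)
        with pytest.raises(TopologyError, match="48"):
            read_trajectory(extended8, path)


class TestSelection:
    def test_resid_range_and_name(self):
        s = make_toy_protein(300, "extended", resid_offset=1)
        sel = select(s, "resid 175:230 and name CA")
        assert len(sel) == 56
        assert all(175 <= s.atoms[i].resid <= 230 for i in sel)

    def test_empty_selection_allowed(self, helix12):
        assert len(select(helix12, "resname HOH")) == 0

    def test_whitespace_invariance(self, helix12):
        a = select(helix12, "resid 3:7 and name CA")
        b = select(helix12, "  resid   3:7   and   name  CA ")
        assert a.indices == b.indices

    def test_not_and_or_parentheses(self, helix12):
        full = select(helix12, "category protein")
        cas = select(helix12, "name CA")
        rest = select(helix12, "category protein and not name CA")
        assert set(full) == set(cas) | set(rest)
        either = select(helix12, "(name CA or name N) and resid 1:3")
        assert len(either) == 6

    def test_syntax_error_reports_position(self, helix12):
        with pytest.raises(SelectionSyntaxError) as err:
            select(helix12, "resid 1:3 and")
        assert err.value.position >= 10
        with pytest.raises(SelectionSyntaxError):
            select(helix12, "bogus 5")


class TestPrimitives:
    def test_distance_345(self):
        assert distance((0, 0, 0), (3, 4, 0)) == pytest.approx(5.0)
        assert distance((1, 2, 3), (1, 2, 3)) == 0.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=vec3, b=vec3)
    def test_distance_matches_componentwise_oracle(self, a, b):
        oracle = sum((ai - bi) ** 2 for ai, bi in zip(a, b)) ** 0.5
        assert distance(a, b) == pytest.approx(oracle, abs=1e-12, rel=1e-12)
        assert distance(b, a) == pytest.approx(distance(a, b), abs=0)

    def test_angle_collinear_and_perpendicular(self):
        assert angle((1, 0, 0), (0, 0, 0), (-1, 0, 0)) == pytest.approx(180.0)
        assert angle((1, 0, 0), (0, 0, 0), (0, 1, 0)) == pytest.approx(90.0)

    def test_angle_zero_arm_raises(self):
        from lipdyn.errors import DegenerateGeometryError

        with pytest.raises(DegenerateGeometryError):
            angle((0, 0, 0), (0, 0, 0), (1, 0, 0))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=vec3, v=vec3, c=vec3)
    def test_angle_matches_arccos_oracle(self, a, v, c):
        u1 = np.array(a) - np.array(v)
        u2 = np.array(c) - np.array(v)
        n1, n2 = np.linalg.norm(u1), np.linalg.norm(u2)
        if n1 < 1e-6 or n2 < 1e-6:
            return
        oracle = np.degrees(np.arccos(np.clip(u1 @ u2 / (n1 * n2), -1, 1)))
        assert angle(a, v, c) == pytest.approx(oracle, abs=1e-9)


class TestTables:
    def test_empty_records_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_table([], path, columns=["metric", "mean", "sd", "se"])
        assert path.read_text().strip() == "metric,mean,sd,se"

    def test_one_row_roundtrip(self, tmp_path):
        path = tmp_path / "row.jsonl"
        write_table([{"metric": "rmsd", "value": 1.25}], path, format="jsonl")
        back = read_table(path, format="jsonl")
        assert back == [{"metric": "rmsd", "value": "1.25"}]

    def test_summary_schema_four_columns(self, tmp_path):
        rows = [{"metric": "rmsd", "mean": 0.723, "sd": 0.03, "se": 0.02}]
        path = tmp_path / "summary.csv"
        write_table(rows, path)
        header = path.read_text().splitlines()[0]
        assert header.split(",") == ["metric", "mean", "sd", "se"]

    def test_bit_stable_output(self, tmp_path):
        rows = [{"a": 1 / 3, "b": 2.0}]
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_table(rows, p1)
        write_table(rows, p2)
        assert p1.read_bytes() == p2.read_bytes()
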