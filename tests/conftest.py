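"""Shared fixtures: small synthetic structures and trajectories."""

from __future__ import annotations

import numpy as np
import pytest

from lipdyn.core import Atom, Structure
from lipdyn.synthetic import SyntheticSpec, make_gaussian_trajectory, make_toy_protein


@pytest.fixture(scope="session")
def helix12() -> Structure:
    return make_toy_protein(12, "alpha_helix")


@pytest.fixture(scope="session")
def extended8() -> Structure:
    return make_toy_protein(8, "extended")


@pytest.fixture()
def tiny_pdb_text() -> str:
    """Three backbone atoms of one residue plus one calcium ion."""
    return (
        "TITLE     tiny fixture\n"
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N\n"
        "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 11.00           C\n"
        "ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00 12.00           C\n"
        "HETATM    4 CA    CA A 400       8.000   8.000   8.000  1.00 20.00          CA\n"
        "END\n"
    )


def make_atoms(specs) -> Structure:
    """Compact helper: specs = [(name, element, resname, resid, xyz), ...]."""
    atoms = []
    from lipdyn.core import categorize_resname

    for i, (name, element, resname, resid, xyz) in enumerate(specs, start=1):
        atoms.append(Atom(
            serial=i, name=name, element=element, resname=resname,
            resid=resid, chain="A", coords=np.asarray(xyz, dtype=float),
            category=categorize_resname(resname),
        ))
    return Structure(atoms=atoms, title="test fixture", source="test")


@pytest.fixture()
def gaussian_traj(helix12):
    """Factory for isotropic Gaussian trajectories around the helix."""

    def _make(variance=0.25, n_frames=500, seed=0, blocks=()):
        spec = SyntheticSpec(
            n_atoms=len(helix12.atoms), variances=variance,
            correlation_blocks=list(blocks), n_frames=n_frames, seed=seed,
        )
        return make_gaussian_trajectory(spec, helix12)

    return _make
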