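"""Synthetic inputs for every pipeline stage.

This module generates, without any MD engine: toy peptide backbones at
prescribed dihedrals, Gaussian trajectories with a prescribed per-atom
variance/correlation structure, geometrically packed solvent boxes, and
small interaction fixtures that instantiate each census criterion at a
chosen geometry.  All generators are bit-reproducible given a seed.

The Gaussian trajectory is the stand-in for an equilibrated MD run: for
an isotropic per-axis variance v the expected per-atom RMSF is
``sqrt(3 v)``, and a correlation block with coefficient rho appears in
the cross-correlation map as entries converging to rho.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_FRAME_SPACING_PS
from .core import Atom, Structure, Trajectory
from .errors import DegenerateGeometryError, PlacementError
from .solvent import BUILTIN_SPECIES, SolventSpecies

_MIN_PLACEMENT_DIST = 2.2      # heavy-atom clash floor in solvated boxes


# --- covariance-prescribed Gaussian trajectories ----------------------------

@dataclass
class SyntheticSpec:
    """Prescription for a Gaussian trajectory.

    ``variances`` is the per-atom displacement variance per Cartesian
    axis (A^2); a scalar applies to every atom.  ``correlation_blocks``
    lists ``(member_indices, rho)`` groups whose members share pairwise
    displacement correlation rho; the implied atom covariance matrix
    must be positive semi-definite (it is validated, never repaired).
    """

    n_atoms: int
    variances: float | np.ndarray = 0.25
    correlation_blocks: list[tuple[list[int], float]] = field(default_factory=list)
    n_frames: int = 2000
    frame_spacing_ps: float = DEFAULT_FRAME_SPACING_PS
    seed: int = 0

    def variance_vector(self) -> np.ndarray:
        v = np.asarray(self.variances, dtype=float)
        if v.ndim == 0:
            v = np.full(self.n_atoms, float(v))
        if v.shape != (self.n_atoms,):
            raise ValueError("variances must be scalar or length n_atoms")
        if np.any(v < 0):
            raise ValueError("variances must be non-negative")
        return v

    def covariance(self) -> np.ndarray:
        """The per-axis atom-displacement covariance matrix implied by
        the prescription; raises if not positive semi-definite."""
        v = self.variance_vector()
        sd = np.sqrt(v)
        cov = np.diag(v)
        for members, rho in self.correlation_blocks:
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"correlation {rho} outside [-1, 1]")
            m = np.asarray(members, dtype=int)
            if np.any(m < 0) or np.any(m >= self.n_atoms):
                raise ValueError("correlation block member out of range")
            if len(set(m.tolist())) != len(m):
                raise ValueError("correlation block repeats members")
            for a in range(len(m)):
                for b in range(a + 1, len(m)):
                    cov[m[a], m[b]] = rho * sd[m[a]] * sd[m[b]]
                    cov[m[b], m[a]] = cov[m[a], m[b]]
        eigmin = float(np.linalg.eigvalsh(cov).min()) if self.n_atoms else 0.0
        if eigmin < -1e-10 * max(1.0, float(v.max(initial=0.0))):
            raise ValueError(
                f"prescribed covariance is not positive semi-definite "
                f"(min eigenvalue {eigmin:.3g}); refusing to repair it"
            )
        return cov

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        self.covariance()


def make_gaussian_trajectory(spec: SyntheticSpec, reference: Structure) -> Trajectory:
    """Frames = reference + zero-mean Gaussian displacements with the
    spec's per-axis covariance (axes independent, identically
    distributed)."""
    spec.validate()
    if len(reference.atoms) != spec.n_atoms:
        raise ValueError(
            f"reference has {len(reference.atoms)} atoms, spec says {spec.n_atoms}"
        )
    cov = spec.covariance()
    w, vecs = np.linalg.eigh(cov)
    factor = vecs * np.sqrt(np.clip(w, 0.0, None))        # cov = factor @ factor.T
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal(size=(spec.n_frames, 3, spec.n_atoms))
    disp = np.einsum("af,kcf->kca", factor, z)            # (F, 3, A)
    frames = reference.coords[None, :, :] + np.transpose(disp, (0, 2, 1))
    times = np.arange(spec.n_frames, dtype=float) * spec.frame_spacing_ps
    return Trajectory(topology=reference, frames=frames, times=times)


# --- toy peptides -----------------------------------------------------------

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.8

_PHI_PSI = {
    "alpha_helix": (-57.0, -47.0),
    "extended": (-139.0, 135.0),
}


def _nerf(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d from three predecessors with internal coordinates."""
    ang = np.radians(angle_deg)
    dih = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(dih),
        bond * np.sin(ang) * np.sin(dih),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def make_toy_protein(n_residues: int, geometry: str = "alpha_helix",
                     resid_offset: int = 1, resname: str = "ALA",
                     chain: str = "A") -> Structure:
    """A poly-residue backbone (N, CA, C, O per residue) at ideal
    dihedrals.

    ``alpha_helix`` uses phi/psi = (-57, -47); ``extended`` a beta-like
    (-139, 135); ``lid_like`` builds a helix / extended-loop / helix
    motif (the two-helix lid shape) and is conventionally numbered from
    ``resid_offset=175`` so that resids 175 and 230 exist.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    if geometry == "lid_like":
        n1 = max(3, n_residues * 2 // 5)
        n3 = max(3, n_residues * 2 // 5)
        n2 = n_residues - n1 - n3
        per_res = (["alpha_helix"] * n1 + ["extended"] * max(0, n2)
                   + ["alpha_helix"] * n3)[:n_residues]
    elif geometry in _PHI_PSI:
        per_res = [geometry] * n_residues
    else:
        raise ValueError(f"unknown geometry {geometry!r}")

    # seed the first residue by hand
    coords: list[tuple[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - _ANGLE_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    backbone: list[dict[str, np.ndarray]] = [{"N": n0, "CA": ca0, "C": c0}]
    for k in range(1, n_residues):
        prev = backbone[-1]
        phi_k, psi_prev = _PHI_PSI[per_res[k]][0], _PHI_PSI[per_res[k - 1]][1]
        n_k = _nerf(prev["N"], prev["CA"], prev["C"], _BOND_C_N,
                    _ANGLE_CA_C_N, psi_prev)
        ca_k = _nerf(prev["CA"], prev["C"], n_k, _BOND_N_CA,
                     _ANGLE_C_N_CA, 180.0)                     # omega trans
        c_k = _nerf(prev["C"], n_k, ca_k, _BOND_CA_C, _ANGLE_N_CA_C, phi_k)
        backbone.append({"N": n_k, "CA": ca_k, "C": c_k})
    # carbonyl O: in the peptide plane, anti to the next N
    for k, res in enumerate(backbone):
        if k + 1 < len(backbone):
            psi_k = _PHI_PSI[per_res[k]][1]
            res["O"] = _nerf(res["N"], res["CA"], res["C"], _BOND_C_O,
                             _ANGLE_CA_C_O, psi_k + 180.0)
        else:
            res["O"] = _nerf(res["N"], res["CA"], res["C"], _BOND_C_O,
                             _ANGLE_CA_C_O, 0.0)
    atoms = []
    serial = 1
    for k, res in enumerate(backbone):
        for name in ("N", "CA", "C", "O"):
            atoms.append(Atom(
                serial=serial, name=name, element=name[0], resname=resname,
                resid=resid_offset + k, chain=chain, coords=res[name],
                category="protein",
            ))
            serial += 1
    return Structure(atoms=atoms, title=f"toy {geometry} x{n_residues}",
                     source="synthetic")


# --- solvated boxes ---------------------------------------------------------

def _molecule_template(species: SolventSpecies) -> list[tuple[str, str, np.ndarray]]:
    """(atom name, element, coords) for one solvent molecule.

    Idealized geometry: zig-zag carbon chain, terminal hydroxyl, and
    hydrogens placed off-axis — chemically simplified but correctly
    countable and typeable (terminal CH3, interior CH2, O-H).
    """
    name = species.name.lower()
    if name == "water":
        return [
            ("O", "O", np.array([0.0, 0.0, 0.0])),
            ("H1", "H", np.array([0.96, 0.0, 0.0])),
            ("H2", "H", np.array([-0.24, 0.93, 0.0])),
        ]
    n_carbons = {"methanol": 1, "ethanol": 2, "propanol": 3,
                 "butanol": 4, "pentanol": 5}.get(name)
    if n_carbons is None:
        raise ValueError(f"no molecule template for species {species.name!r}")
    out: list[tuple[str, str, np.ndarray]] = []
    # zig-zag carbons in the xy plane
    for c in range(n_carbons):
        pos = np.array([1.53 * c * 0.83, 0.87 * (c % 2), 0.0])
        out.append((f"C{c + 1}", "C", pos))
    o_pos = out[-1][2] + np.array([1.18, 0.80 * (1 if n_carbons % 2 == 0 else -1), 0.0])
    out.append(("O", "O", o_pos))
    out.append(("HO", "H", o_pos + np.array([0.65, 0.0, 0.70])))
    # hydrogens: terminal carbon C1 gets 3, interior carbons 2 each
    h_serial = 1
    for c in range(n_carbons):
        n_h = 3 if c == 0 else 2
        base = out[c][2]
        for h in range(n_h):
            ang = 2.0 * np.pi * h / 3.0
            off = np.array([0.36 * np.cos(ang), 0.36 * np.sin(ang),
                            1.04 if h % 2 == 0 else -1.04])
            out.append((f"H{h_serial}", "H", base + off))
            h_serial += 1
    if len(out) != species.atoms_per_molecule:
        raise AssertionError(
            f"template for {species.name} has {len(out)} atoms, "
            f"species says {species.atoms_per_molecule}"
        )
    return out


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a random unit quaternion."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def make_solvated_box(protein: Structure, species: SolventSpecies,
                      n_molecules: int, box_margin: float = 5.0,
                      seed: int = 0, max_tries: int = 500) -> Structure:
    """Protein centered in a rectangular box, plus ``n_molecules`` copies
    of one solvent species at random non-clashing poses.

    Placement is rejection sampling with a 2.2 A heavy-atom clash floor;
    if a molecule cannot be placed within ``max_tries`` attempts a
    :class:`PlacementError` reports the achieved count.  Deterministic
    per seed.
    """
    rng = np.random.default_rng(seed)
    template = _molecule_template(species)
    heavy_template = [t for t in template if t[1] != "H"]
    atoms = list(protein.atoms)
    if atoms:
        center = protein.coords.mean(axis=0)
        lo = protein.coords.min(axis=0) - box_margin
        hi = protein.coords.max(axis=0) + box_margin
    else:
        center = np.zeros(3)
        side = max(6.0, 2.0 * box_margin) * max(1.0, n_molecules ** (1 / 3))
        lo, hi = -0.5 * side * np.ones(3), 0.5 * side * np.ones(3)
    placed_heavy = [a.coords for a in atoms if a.element.upper() != "H"]
    serial = len(atoms) + 1
    next_resid = (max((a.resid for a in atoms), default=0)) + 1
    for mol in range(n_molecules):
        ok = False
        for _ in range(max_tries):
            pos = lo + rng.random(3) * (hi - lo)
            rot = _random_rotation(rng)
            heavy_xyz = [pos + rot @ t[2] for t in heavy_template]
            if placed_heavy:
                arr = np.asarray(placed_heavy)
                dmin = min(
                    float(np.min(np.linalg.norm(arr - h, axis=1))) for h in heavy_xyz
                )
                if dmin < _MIN_PLACEMENT_DIST:
                    continue
            for name, element, t_xyz in template:
                atoms.append(Atom(
                    serial=serial, name=name, element=element,
                    resname=species.resname, resid=next_resid, chain="S",
                    coords=pos + rot @ t_xyz,
                    category="water" if species.name == "water" else "organic_solvent",
                ))
                serial += 1
            placed_heavy.extend(heavy_xyz)
            next_resid += 1
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"could not place molecule {mol + 1}/{n_molecules} of "
                f"{species.name} without clashes", achieved=mol,
            )
    return Structure(atoms=atoms, title=f"{protein.title} + {n_molecules} {species.name}",
                     source="synthetic")


# --- interaction fixtures ---------------------------------------------------

def _atom(serial, name, element, resname, resid, xyz, category="protein") -> Atom:
    return Atom(serial=serial, name=name, element=element, resname=resname,
                resid=resid, chain="A", coords=np.asarray(xyz, dtype=float),
                category=category)


def make_interaction_fixture(kind: str, **params) -> Structure:
    """Minimal synthetic structures instantiating one census criterion.

    * ``hbond``: N-H donor and C=O acceptor, collinear, with
      ``d_ha`` the H...O distance (default 2.1) — both angular scale
      factors are 1 at this geometry.
    * ``salt_bridge``: Lys NZ and Glu OE1 separated by ``d`` (default 3.9).
    * ``hydrophobic_pair``: two CH3 carbons (different residues)
      separated by ``d`` (default 4.9).
    * ``metal_site``: a metal ion (``element``, default CA) with ligand
      shell atoms at prescribed distances
      ``shell=[(resid, resname, atom_name, distance), ...]``.
    """
    if kind == "hbond":
        d_ha = float(params.get("d_ha", 2.1))
        theta_dha = float(params.get("theta_dha", 180.0))
        if d_ha <= 0:
            raise DegenerateGeometryError("d_ha must be positive")
        n = np.array([0.0, 0.0, 0.0])
        h = np.array([1.0, 0.0, 0.0])
        ang = np.radians(180.0 - theta_dha)
        o = h + d_ha * np.array([np.cos(ang), np.sin(ang), 0.0])
        c = o + 1.23 * np.array([np.cos(ang), np.sin(ang), 0.0])
        return Structure(atoms=[
            _atom(1, "N", "N", "GLY", 1, n),
            _atom(2, "H", "H", "GLY", 1, h),
            _atom(3, "C", "C", "GLY", 3, c),
            _atom(4, "O", "O", "GLY", 3, o),
        ], title="synthetic hbond fixture", source="synthetic")
    if kind == "salt_bridge":
        d = float(params.get("d", 3.9))
        basic_res = params.get("basic", "LYS")
        basic_atom = {"LYS": "NZ", "ARG": params.get("arg_atom", "NE")}[basic_res]
        return Structure(atoms=[
            _atom(1, "CA", "C", basic_res, 1, [-1.5, 0, 0]),
            _atom(2, basic_atom, "N", basic_res, 1, [0, 0, 0]),
            _atom(3, "CA", "C", "GLU", 5, [d + 1.5, 0, 0]),
            _atom(4, "OE1", "O", "GLU", 5, [d, 0, 0]),
        ], title="synthetic salt-bridge fixture", source="synthetic")
    if kind == "hydrophobic_pair":
        d = float(params.get("d", 4.9))
        atoms = []
        serial = 1
        for resid, x0 in ((1, 0.0), (2, d)):
            cb = np.array([x0, 0.0, 0.0])
            atoms.append(_atom(serial, "CB", "C", "ALA", resid, cb)); serial += 1
            for h in range(3):
                ang = 2 * np.pi * h / 3
                off = np.array([0.36 * np.cos(ang), 0.36 * np.sin(ang), 1.04])
                atoms.append(_atom(serial, f"HB{h + 1}", "H", "ALA", resid, cb + off))
                serial += 1
        return Structure(atoms=atoms, title="synthetic hydrophobic fixture",
                         source="synthetic")
    if kind == "metal_site":
        element = str(params.get("element", "CA")).upper()
        shell = params.get("shell", [(1, "GLU", "OE2", 2.0)])
        atoms = [_atom(1, element, element, element, 900, [0, 0, 0], category="ion")]
        serial = 2
        directions = _shell_directions(len(shell))
        for (resid, resname, atom_name, dist), u in zip(shell, directions):
            atoms.append(_atom(serial, atom_name, atom_name[0], resname, resid,
                               dist * u))
            serial += 1
        # ion record last so residue contiguity holds trivially
        atoms = atoms[1:] + atoms[:1]
        return Structure(atoms=atoms, title="synthetic metal-site fixture",
                         source="synthetic")
    raise ValueError(f"unknown fixture kind {kind!r}")


def _shell_directions(n: int) -> np.ndarray:
    """n well-separated unit vectors (octahedral-ish directions first)."""
    base = np.array([
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
        [1, 1, 1], [-1, -1, 1],
    ], dtype=float)
    if n > len(base):
        raise ValueError("too many shell atoms")
    out = base[:n]
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def make_beta_sheet_fixture(n_per_strand: int = 5, period: float = 3.4,
                            separation: float = 4.13) -> Structure:
    """Synthetic two-strand antiparallel sheet fixture.

    Two flat strands (chains A and B, the second running in the reverse
    direction at ``separation`` along y) with carbonyl oxygens
    alternating up/down so that the central residues of the two strands
    donate backbone hydrogen bonds to each other — the bridge pattern a
    sheet assignment must detect.  Geometry is idealized, not a real
    beta sheet.
    """
    if n_per_strand < 5:
        raise ValueError("need at least 5 residues per strand")
    p = period
    atoms: list[Atom] = []
    serial = 1

    def add(name, element, resname, resid, chain, xyz):
        nonlocal serial
        atoms.append(Atom(serial=serial, name=name, element=element,
                          resname=resname, resid=resid, chain=chain,
                          coords=np.asarray(xyz, dtype=float),
                          category="protein"))
        serial += 1

    # strand A along +x at y=0; O up for even residues
    for k in range(n_per_strand):
        x = p * k
        add("N", "N", "ALA", k + 1, "A", [x, 0.0, 0.0])
        add("CA", "C", "ALA", k + 1, "A", [x + 1.1, -1.0, 0.0])
        add("C", "C", "ALA", k + 1, "A", [x + 2.2, 0.0, 0.0])
        o_sign = 1.0 if k % 2 == 0 else -1.0
        add("O", "O", "ALA", k + 1, "A", [x + 2.2, 1.23 * o_sign, 0.0])
    # strand B along -x at y=separation; O down for even residues
    x0 = 4.0 * p + 2.2
    d = separation
    for m in range(n_per_strand):
        x = x0 - p * m
        add("N", "N", "ALA", m + 11, "B", [x, d, 0.0])
        add("CA", "C", "ALA", m + 11, "B", [x - 1.1, d + 1.0, 0.0])
        add("C", "C", "ALA", m + 11, "B", [x - 2.2, d, 0.0])
        o_sign = -1.0 if m % 2 == 0 else 1.0
        add("O", "O", "ALA", m + 11, "B", [x - 2.2, d + 1.23 * o_sign, 0.0])
    return Structure(atoms=atoms, title="synthetic antiparallel sheet fixture",
                     source="synthetic")


def make_catalytic_triad_fixture(ca_angle: float = 43.16,
                                 d_asp_his: float = 2.8,
                                 d_ser_his: float = 3.1) -> Structure:
    """Synthetic stand-in for a lipase catalytic triad.

    Places Ser113/Asp317/His358 marker atoms so that the Calpha angle at
    the Asp and the two catalytic heavy-atom distances equal the
    requested values exactly.  This is a constructed fixture for
    validating the measurement path, not crystal coordinates.
    """
    arm = 7.0
    asp_ca = np.array([0.0, 0.0, 0.0])
    ser_ca = asp_ca + arm * np.array([1.0, 0.0, 0.0])
    ang = np.radians(ca_angle)
    his_ca = asp_ca + arm * np.array([np.cos(ang), np.sin(ang), 0.0])
    od2 = asp_ca + np.array([1.5, 0.8, 0.0])
    nd1 = od2 + d_asp_his * np.array([np.cos(ang / 2), np.sin(ang / 2), 0.0])
    ne2 = nd1 + np.array([1.4, 1.4, 0.0])
    og = ne2 + d_ser_his * np.array([0.0, 0.0, 1.0])
    return Structure(atoms=[
        _atom(1, "CA", "C", "SER", 113, ser_ca),
        _atom(2, "OG", "O", "SER", 113, og),
        _atom(3, "CA", "C", "ASP", 317, asp_ca),
        _atom(4, "OD2", "O", "ASP", 317, od2),
        _atom(5, "CA", "C", "HIS", 358, his_ca),
        _atom(6, "ND1", "N", "HIS", 358, nd1),
        _atom(7, "NE2", "N", "HIS", 358, ne2),
    ], title="synthetic catalytic-triad fixture", source="synthetic")
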