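"""Superposition, deviation, fluctuation and compactness metrics.

Conventions
-----------
* RMSD between two conformations is the root of the mean squared
  per-atom displacement: ``sqrt(sum |r_i|^2 / n)``.
* RMSF of atom *i* is the root of the summed per-Cartesian-component
  variances of its position over the trajectory, taken after removing
  rigid-body motion by superposing every frame onto a reference
  conformation (the trajectory mean by default, refined over two fit
  passes; the first frame is available as an alternative reference).
* The crystallographic temperature factor follows
  ``B_i = (8/3) * (pi * RMSF_i)^2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Selection, Structure, Trajectory
from .errors import DegenerateGeometryError

BFACTOR_PREFACTOR = 8.0 * np.pi**2 / 3.0

#: Atom names comprising the peptide backbone for "backbone RMSD".
BACKBONE_ATOM_NAMES = ("N", "CA", "C", "O")


@dataclass
class MetricSeries:
    """A per-frame scalar time series (RMSD, lid distance, SASA...)."""

    label: str
    units: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")

    def time_mean(self) -> float:
        return float(np.mean(self.values))


@dataclass
class PerAtomProfile:
    """Per-atom scalars over a selection (RMSF, B-factor, SASA...)."""

    selection: Selection
    values: np.ndarray
    units: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.selection):
            raise ValueError("values length must equal selection length")


# --- primitives -------------------------------------------------------------

def distance(a, b) -> float:
    """Euclidean distance between two points in Angstrom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.linalg.norm(a - b))


def angle(a, vertex, c) -> float:
    """Angle a-vertex-c in degrees, in [0, 180]."""
    a = np.asarray(a, dtype=float)
    vertex = np.asarray(vertex, dtype=float)
    c = np.asarray(c, dtype=float)
    u = a - vertex
    v = c - vertex
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("angle arm has zero length")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None):
    """Optimal rigid-body superposition (Kabsch, via SVD).

    Returns ``(rotation, translation, post_fit_rmsd)`` such that
    ``mobile @ rotation.T + translation`` best matches ``reference`` in the
    (weighted) least-squares sense.  The rotation is always proper
    (det = +1); reflections are never returned.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superposition needs >= 3 atom pairs")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()
    mob_c = mobile - (w[:, None] * mobile).sum(axis=0)
    ref_c = reference - (w[:, None] * reference).sum(axis=0)
    # collinearity check: rank of the centered mobile cloud
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise DegenerateGeometryError("collinear or degenerate atom set")
    h = (w[:, None] * mob_c).T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = (w[:, None] * reference).sum(axis=0) - rotation @ (
        (w[:, None] * mobile).sum(axis=0)
    )
    fitted = mobile @ rotation.T + translation
    post_fit_rmsd = float(np.sqrt((w * np.sum((fitted - reference) ** 2, axis=1)).sum()))
    return rotation, translation, post_fit_rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ rotation.T + translation


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation over corresponding atom pairs (no
    fitting)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate sets differ in shape: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[0] < 1:
        raise ValueError("need at least one atom pair")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(traj: Trajectory, selection: Selection,
                reference: Structure | None = None,
                fit: bool = True, label: str = "rmsd") -> MetricSeries:
    """Per-frame RMSD of a selection from a reference structure.

    Each frame is first superposed onto the reference over the same
    selection (the standard prerequisite for deviation-from-crystal
    curves) unless ``fit=False``.
    """
    ref = reference if reference is not None else traj.topology
    idx = selection.as_array()
    ref_xyz = ref.coords[idx]
    values = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        frame_xyz = traj.frames[k][idx]
        if fit:
            rot, trans, fitted_rmsd = kabsch_superpose(frame_xyz, ref_xyz)
            values[k] = fitted_rmsd
        else:
            values[k] = rmsd(frame_xyz, ref_xyz)
    return MetricSeries(label=label, units="A", times=traj.times.copy(), values=values)


def rmsf(traj: Trajectory, selection: Selection,
         fit_selection: Selection | None = None,
         reference: str = "mean", fit_passes: int = 2) -> PerAtomProfile:
    """Per-atom root-mean-square fluctuation in Angstrom.

    Every frame is superposed (over ``fit_selection``, defaulting to the
    analysis selection) onto a reference conformation before variances
    are accumulated.  ``reference='mean'`` iterates fitting against the
    running mean conformation (``fit_passes`` rounds); ``'first'`` fits
    against frame 0.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if reference not in ("mean", "first"):
        raise ValueError("reference must be 'mean' or 'first'")
    idx = selection.as_array()
    fit_idx = fit_selection.as_array() if fit_selection is not None else idx
    frames = traj.frames
    if len(fit_idx) >= 3:
        ref_fit = frames[0][fit_idx] if reference == "first" else None
        passes = 1 if reference == "first" else max(1, fit_passes)
        work_fit = frames[:, fit_idx, :].copy()
        work_sel = frames[:, idx, :].copy()
        for _ in range(passes):
            target = ref_fit if reference == "first" else work_fit.mean(axis=0)
            for k in range(traj.n_frames):
                rot, trans, _ = kabsch_superpose(work_fit[k], target)
                work_fit[k] = apply_transform(work_fit[k], rot, trans)
                work_sel[k] = apply_transform(work_sel[k], rot, trans)
        fitted = work_sel
    else:
        # too few atoms to define a rigid fit: use raw coordinates
        fitted = frames[:, idx, :]
    mean_pos = fitted.mean(axis=0)
    var_per_axis = np.mean((fitted - mean_pos) ** 2, axis=0)  # (n_sel, 3)
    values = np.sqrt(var_per_axis.sum(axis=1))
    return PerAtomProfile(selection=selection, values=values, units="A")


def bfactor_from_rmsf(profile: PerAtomProfile) -> PerAtomProfile:
    """Convert an RMSF profile (A) to B-factors (A^2): B = (8 pi^2/3) rmsf^2."""
    if np.any(profile.values < 0):
        raise ValueError("RMSF values must be non-negative")
    return PerAtomProfile(
        selection=profile.selection,
        values=BFACTOR_PREFACTOR * profile.values**2,
        units="A^2",
    )


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted RMS distance from the center of mass, in Angstrom."""
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if coords.ndim != 2 or coords.shape[0] == 0:
        raise ValueError("need at least one atom")
    if masses.shape != (coords.shape[0],):
        raise ValueError("masses must match atom count")
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (masses[:, None] * coords).sum(axis=0) / total
    sq = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt((masses * sq).sum() / total))


def radius_of_gyration_series(traj: Trajectory, selection: Selection) -> MetricSeries:
    idx = selection.as_array()
    masses = np.array([traj.topology.atoms[i].mass for i in idx])
    values = np.array(
        [radius_of_gyration(traj.frames[k][idx], masses) for k in range(traj.n_frames)]
    )
    return MetricSeries(label="rgyr", units="A", times=traj.times.copy(), values=values)
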