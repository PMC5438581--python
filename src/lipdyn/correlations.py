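"""Dynamic cross-correlation matrices of atomic motions.

Entry (i, j) is the normalized covariance of the 3-D displacement
vectors of atoms i and j about their trajectory-mean positions,

    DCCM_ij = <d_i . d_j> / sqrt(<d_i^2> <d_j^2>),

computed after superposing every window frame onto the window-mean
conformation (otherwise global tumbling dominates the map).  Values lie
in [-1, +1]; the diagonal is +1 wherever an atom moves at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Selection, Structure, Trajectory
from .geometry import apply_transform, kabsch_superpose
from .tables import write_table

#: trailing fraction of frames analysed by default (the equilibrated tail).
DEFAULT_WINDOW_FRACTION = 0.25


@dataclass
class DCCMatrix:
    selection: Selection
    matrix: np.ndarray
    window: tuple[float, float]            # (t_min, t_max) in ps
    resids: list[int] = field(default_factory=list)
    zero_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.selection), len(self.selection)):
            raise ValueError("matrix shape must match selection length")
        self.matrix = m

    def to_csv(self, path) -> None:
        labels = self.resids or list(range(len(self.selection)))
        rows = []
        for i, li in enumerate(labels):
            row = {"resid": li}
            row.update({str(lj): float(self.matrix[i, j]) for j, lj in enumerate(labels)})
            rows.append(row)
        write_table(rows, path, format="csv")

    def to_long_format(self, path) -> None:
        labels = self.resids or list(range(len(self.selection)))
        rows = [
            {"resid_i": labels[i], "resid_j": labels[j],
             "correlation": float(self.matrix[i, j])}
            for i in range(len(labels)) for j in range(len(labels))
        ]
        write_table(rows, path, format="csv")


def ca_selection(structure: Structure) -> Selection:
    """One Calpha per protein residue, in residue order (the default
    atom set for residue-indexed correlation maps)."""
    idx = [i for i, a in enumerate(structure.atoms)
           if a.category == "protein" and a.name == "CA"]
    return Selection.from_indices(idx, n_atoms=len(structure.atoms))


def dccm(traj: Trajectory, selection: Selection | None = None,
         window: tuple[float, float] | None = None,
         last_fraction: float | None = None,
         fit_selection: Selection | None = None) -> DCCMatrix:
    """Dynamic cross-correlation matrix over a frame window.

    ``window=(t_min, t_max)`` selects frames by time; ``last_fraction``
    selects a trailing fraction instead (default 0.25 when neither is
    given).  Fitting uses ``fit_selection`` (default: the analysis
    selection).  Zero-variance atoms yield rows/columns of 0, flagged in
    ``zero_variance``; their diagonal entry is set to +1 only when the
    atom genuinely moves.
    """
    if selection is None:
        selection = ca_selection(traj.topology)
    if len(selection) == 0:
        raise ValueError("empty selection")
    if window is not None:
        sub = traj.window(t_min=window[0], t_max=window[1])
    else:
        sub = traj.window(last_fraction=last_fraction if last_fraction is not None
                          else DEFAULT_WINDOW_FRACTION)
    if sub.n_frames < 2:
        raise ValueError("window must contain at least 2 frames")
    idx = selection.as_array()
    fit_idx = fit_selection.as_array() if fit_selection is not None else idx
    frames_fit = sub.frames[:, fit_idx, :].copy()
    frames_sel = sub.frames[:, idx, :].copy()
    if len(fit_idx) >= 3:
        for _ in range(2):
            target = frames_fit.mean(axis=0)
            for k in range(sub.n_frames):
                rot, trans, _ = kabsch_superpose(frames_fit[k], target)
                frames_fit[k] = apply_transform(frames_fit[k], rot, trans)
                frames_sel[k] = apply_transform(frames_sel[k], rot, trans)
    disp = frames_sel - frames_sel.mean(axis=0)          # (F, n, 3)
    f, n, _ = disp.shape
    # <d_i . d_j> via a single gemm over the flattened component axis
    cov = np.einsum("fik,fjk->ij", disp, disp) / f
    var = np.diag(cov).copy()
    zero = var <= 1e-300
    denom = np.sqrt(np.outer(np.where(zero, 1.0, var), np.where(zero, 1.0, var)))
    matrix = cov / denom
    matrix[zero, :] = 0.0
    matrix[:, zero] = 0.0
    moving = np.flatnonzero(~zero)
    matrix[moving, moving] = 1.0
    matrix = 0.5 * (matrix + matrix.T)                   # exact symmetry
    resids = [traj.topology.atoms[i].resid for i in idx]
    return DCCMatrix(
        selection=selection,
        matrix=matrix,
        window=(float(sub.times[0]), float(sub.times[-1])),
        resids=resids,
        zero_variance=zero,
    )


def block_summary(matrix: DCCMatrix,
                  regions: dict[str, tuple[int, int]]) -> dict[tuple[str, str], float]:
    """Mean correlation between every pair of named resid ranges.

    Symmetric in region order; a region whose resids are absent from the
    matrix selection raises.
    """
    resids = np.array(matrix.resids)
    members: dict[str, np.ndarray] = {}
    for name, (lo, hi) in regions.items():
        idx = np.flatnonzero((resids >= lo) & (resids <= hi))
        if len(idx) == 0:
            raise KeyError(f"region {name!r} ({lo}:{hi}) matches no atoms in the matrix")
        members[name] = idx
    out: dict[tuple[str, str], float] = {}
    names = list(regions)
    for a in names:
        for b in names:
            block = matrix.matrix[np.ix_(members[a], members[b])]
            out[(a, b)] = float(block.mean())
    return out
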