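"""Config-driven orchestration over replicate trajectories.

``run_analysis`` executes the full metric stack for each replicate and
writes per-metric CSV series, first/last-frame interaction censuses,
per-replicate correlation matrices plus their mean, a Table-style
replicate summary (mean / sample s.d. / s.e. of the per-replicate time
means) and a manifest sufficient to reproduce every number.

Outputs are byte-stable: identical config + inputs produce identical
files (fixed float formatting, no timestamps in outputs).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .constants import VDW_RADII
from .core import Selection, Structure, Trajectory
from .correlations import ca_selection, dccm
from .errors import LipdynError
from .geometry import (
    BACKBONE_ATOM_NAMES,
    MetricSeries,
    bfactor_from_rmsf,
    radius_of_gyration_series,
    rmsd_series,
    rmsf,
)
from .interactions import (
    active_site_geometry,
    count_hydrophobic_contacts,
    count_salt_bridges,
    find_hbonds,
    lid_metrics,
)
from .pdbio import read_structure, read_trajectory
from .secondary import ss_content
from .selection import select
from .tables import write_table

logger = logging.getLogger(__name__)


class StageError(LipdynError):
    """A pipeline stage failed; message names the stage and input."""

    def __init__(self, stage: str, source: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for {source}: {cause}")
        self.stage = stage


@dataclass
class ReplicateSummary:
    """Across-replicate statistics of one metric's per-replicate
    time-means (sample s.d., s.e. = s.d./sqrt(n); reported for n >= 2)."""

    label: str
    n: int
    mean: float
    sd: float | None = None
    se: float | None = None


def aggregate_replicates(series_per_replicate: list[MetricSeries],
                         statistic: str = "time_mean") -> ReplicateSummary:
    """Collapse each replicate's series to its time mean, then summarize
    across replicates."""
    if statistic not in ("time_mean", "last_frame"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if not series_per_replicate:
        raise ValueError("need at least one replicate")
    labels = {s.label for s in series_per_replicate}
    if len(labels) != 1:
        raise ValueError(f"replicate series have mismatched labels: {sorted(labels)}")
    if statistic == "time_mean":
        values = np.array([s.time_mean() for s in series_per_replicate])
    else:
        values = np.array([float(s.values[-1]) for s in series_per_replicate])
    n = len(values)
    mean = float(values.mean())
    if n >= 2:
        sd = float(values.std(ddof=1))
        se = sd / np.sqrt(n)
        return ReplicateSummary(series_per_replicate[0].label, n, mean, sd, float(se))
    return ReplicateSummary(series_per_replicate[0].label, n, mean)


@dataclass
class RunConfig:
    """Everything a run needs; loadable from a YAML mapping."""

    topology: str
    trajectories: list[str]
    out_dir: str
    lid_range: tuple[int, int] = (175, 230)
    active_site: tuple[int, int, int] = (113, 317, 358)
    metal_shells: dict = field(default_factory=dict)
    window_last_fraction: float = 0.25
    sasa_probe: float = 1.4
    sasa_points: int = 960
    hbond_mode: str = "distance"
    hbond_distance_cutoff: float = 3.5
    hbond_energy_threshold: float = 6.25
    salt_bridge_lys_cutoff: float = 4.0
    salt_bridge_arg_cutoff: float = 3.5
    hydrophobic_cutoff: float = 5.0
    burial_threshold: float = 20.0
    organic_resnames: list[str] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in [self.topology, *self.trajectories]:
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        for name, value in (
            ("hbond_distance_cutoff", self.hbond_distance_cutoff),
            ("salt_bridge_lys_cutoff", self.salt_bridge_lys_cutoff),
            ("salt_bridge_arg_cutoff", self.salt_bridge_arg_cutoff),
            ("hydrophobic_cutoff", self.hydrophobic_cutoff),
            ("burial_threshold", self.burial_threshold),
            ("sasa_probe", self.sasa_probe),
        ):
            if value <= 0:
                raise ValueError(f"threshold {name} must be positive, got {value}")
        self.lid_range = tuple(self.lid_range)           # type: ignore[assignment]
        self.active_site = tuple(self.active_site)       # type: ignore[assignment]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _series_rows(series: MetricSeries) -> list[dict]:
    return [{"time_ps": float(t), series.label: float(v)}
            for t, v in zip(series.times, series.values)]


def _census(structure: Structure, config: RunConfig) -> dict:
    protein_sel = select(structure, "category protein")
    _, n_hb_dist = find_hbonds(structure, protein_sel, protein_sel,
                               mode="distance",
                               distance_cutoff=config.hbond_distance_cutoff)
    _, n_hb_energy = find_hbonds(structure, protein_sel, protein_sel,
                                 mode="energy",
                                 energy_threshold=config.hbond_energy_threshold)
    n_sb, _ = count_salt_bridges(structure,
                                 lys_cutoff=config.salt_bridge_lys_cutoff,
                                 arg_cutoff=config.salt_bridge_arg_cutoff)
    n_hydro, _ = count_hydrophobic_contacts(structure, "intra_protein",
                                            cutoff=config.hydrophobic_cutoff)
    out = {
        "hbonds_distance_mode": n_hb_dist,
        "hbonds_energy_mode": n_hb_energy,
        "salt_bridges": n_sb,
        "hydrophobic_contacts": n_hydro,
    }
    resids = {a.resid for a in structure.atoms if a.category == "protein"}
    if set(config.active_site) <= resids:
        try:
            geom = active_site_geometry(structure, *config.active_site)
            out.update({
                "active_site_angle_deg": geom.ca_angle,
                "d_asp_his_A": geom.d_asp_od2_his_nd1,
                "d_ser_his_A": geom.d_ser_og_his_ne2,
            })
        except KeyError:
            pass
    return out


def run_analysis(config: RunConfig) -> dict:
    """Run the metric stack over all replicates; returns the manifest.

    On any stage failure the partial outputs written so far are removed
    and a :class:`StageError` naming the stage is raised.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "load_topology"

    def emit(rows, name, columns=None):
        path = out_dir / name
        write_table(rows, path, format="csv", columns=columns)
        written.append(path)
        return path

    try:
        topology = read_structure(config.topology,
                                  extra_organic_resnames=config.organic_resnames)
        backbone_sel = Selection.from_indices(
            [i for i, a in enumerate(topology.atoms)
             if a.category == "protein" and a.name in BACKBONE_ATOM_NAMES],
            n_atoms=len(topology.atoms))
        protein_sel = select(topology, "category protein")
        resids = {a.resid for a in topology.atoms if a.category == "protein"}
        has_lid = config.lid_range[0] in resids and config.lid_range[1] in resids
        summaries: dict[str, list[MetricSeries]] = {}
        matrices = []
        for r, traj_path in enumerate(config.trajectories, start=1):
            stage = f"replicate_{r}"
            traj = read_trajectory(topology, traj_path, format="pdb")
            series_list = [
                rmsd_series(traj, backbone_sel, reference=topology, label="rmsd"),
                radius_of_gyration_series(traj, protein_sel),
            ]
            if has_lid:
                dist_s, lrmsd_s = lid_metrics(traj, config.lid_range, topology)
                series_list += [dist_s, lrmsd_s]
            if traj.n_frames >= 2:
                prof = rmsf(traj, backbone_sel)
                bf = bfactor_from_rmsf(prof)
                emit([
                    {"atom_index": int(i), "rmsf_A": float(v), "bfactor_A2": float(b)}
                    for i, v, b in zip(backbone_sel, prof.values, bf.values)
                ], f"replicate{r}_rmsf.csv")
                series_list.append(MetricSeries(
                    "bfactor", "A^2", np.array([0.0]),
                    np.array([float(bf.values.mean())])))
            for s in series_list:
                if s.label not in ("bfactor",):
                    emit(_series_rows(s), f"replicate{r}_{s.label}.csv")
                summaries.setdefault(s.label, []).append(s)
            stage = f"replicate_{r}_dccm"
            if traj.n_frames >= 8 and len(ca_selection(topology)) >= 2:
                m = dccm(traj, last_fraction=config.window_last_fraction)
                m.to_csv(out_dir / f"replicate{r}_dccm.csv")
                written.append(out_dir / f"replicate{r}_dccm.csv")
                matrices.append(m)
            stage = f"replicate_{r}_census"
            for tag, k in (("first", 0), ("last", traj.n_frames - 1)):
                census = _census(traj.frame_structure(k), config)
                emit([{"metric": key, "value": float(val)}
                      for key, val in census.items()],
                     f"replicate{r}_census_{tag}.csv")
            stage = f"replicate_{r}_ss"
            rows = ss_content(traj)
            emit([{"time_ps": row["time"],
                   **{f"fraction_{c}": row[c] for c in "HGETC"}}
                  for row in rows], f"replicate{r}_ss.csv")
        stage = "aggregate"
        summary_rows = []
        for label in sorted(summaries):
            summ = aggregate_replicates(summaries[label])
            summary_rows.append({
                "metric": label, "n": summ.n, "mean": summ.mean,
                "sd": "" if summ.sd is None else format(summ.sd, ".6g"),
                "se": "" if summ.se is None else format(summ.se, ".6g"),
            })
        emit(summary_rows, "summary.csv",
             columns=["metric", "n", "mean", "sd", "se"])
        if matrices:
            mean_matrix = matrices[0]
            if len(matrices) > 1:
                stacked = np.mean([m.matrix for m in matrices], axis=0)
                mean_matrix = matrices[0]
                mean_matrix = type(matrices[0])(
                    selection=matrices[0].selection, matrix=stacked,
                    window=matrices[0].window, resids=matrices[0].resids)
            mean_matrix.to_csv(out_dir / "dccm_mean.csv")
            written.append(out_dir / "dccm_mean.csv")
        stage = "manifest"
        manifest = {
            "package": "lipdyn",
            "version": __version__,
            "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
            "inputs": {p: _sha256(p) for p in [config.topology, *config.trajectories]},
            "vdw_radii": VDW_RADII,
            "outputs": sorted(str(p.name) for p in written),
        }
        manifest_path = out_dir / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=list)
            fh.write("\n")
        logger.info("run complete: %d replicates, %d output files",
                    len(config.trajectories), len(written) + 1)
        return manifest
    except Exception as exc:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, config.topology, exc) from exc
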