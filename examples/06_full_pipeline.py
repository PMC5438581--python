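"""End-to-end replicate analysis.

Builds three synthetic replicate trajectories of a lid-like toy protein
(resids 175-230), runs the full metric stack and prints the
across-replicate summary (mean / s.d. / s.e. of per-replicate time
means) — the aggregation layout used for simulation property tables.
"""

import tempfile
from pathlib import Path

from lipdyn import (
    RunConfig,
    SyntheticSpec,
    make_gaussian_trajectory,
    make_toy_protein,
    read_table,
    run_analysis,
    write_structure,
    write_trajectory,
)

work = Path(tempfile.mkdtemp(prefix="lipdyn_example_"))
ref = make_toy_protein(56, "lid_like", resid_offset=175)
topo = work / "topology.pdb"
write_structure(ref, topo)

traj_paths = []
for r in range(3):
    spec = SyntheticSpec(n_atoms=len(ref.atoms), variances=0.09,
                         n_frames=20, seed=100 + r)
    path = work / f"replicate{r + 1}.pdb"
    write_trajectory(make_gaussian_trajectory(spec, ref), path)
    traj_paths.append(str(path))

cfg = RunConfig(topology=str(topo), trajectories=traj_paths,
                out_dir=str(work / "out"))
cfg.validate()
manifest = run_analysis(cfg)

print(f"outputs in {cfg.out_dir}: {len(manifest['outputs'])} files")
print(f"{'metric':<14}{'n':>3}{'mean':>12}{'sd':>12}{'se':>12}")
for row in read_table(Path(cfg.out_dir) / "summary.csv"):
    print(f"{row['metric']:<14}{row['n']:>3}{row['mean']:>12}{row['sd']:>12}{row['se']:>12}")
print()
print("Lid distance is the Calpha 175-230 separation; lid rmsd the lid-only")
print("backbone deviation after fitting on the non-lid core; rmsd/rgyr are")
print("global deviation and compactness. s.e. = s.d./sqrt(3 replicates).")
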