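"""Build a synthetic nucleosome and simulate both regimes.

Generates the pseudo-atomic model (146 bp DNA superhelix around eight
histone chains plus a docked CENP-C fragment) and a planted-dynamics
trajectory for the unmodified and acetylated regimes, writing PDB/.trj/YAML
outputs plus a replayable manifest.
"""

from pathlib import Path

from nucleodyn import run_simulation
from nucleodyn.io import read_pdb, read_trajectory

outroot = Path("scratch/example_runs")
for preset in ("unmodified", "acetyl"):
    res = run_simulation(outroot / preset, preset=preset, seed=7, n_frames=500)
    model = read_pdb(res.model_path)
    traj = read_trajectory(res.trajectory_path, model)
    print(f"{preset:>10s}: {model.n_atoms} pseudo-atoms, {traj.n_frames} frames, "
          f"chains {''.join(model.chains)}")
print("Each run is byte-identical for the same seed and replayable from its "
      "manifest.json; the acetyl regime plants tighter jitter, stronger entry-end "
      "DNA breathing, dimer compaction and CENP-C detachment.")
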