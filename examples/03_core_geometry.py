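"""Histone-core geometry: RMSF with blocked errors and dimer COM distances.

The per-atom RMSF quantifies local flexibility about the time-averaged
structure (blocked thirds give an error bar); the mass-weighted
center-of-mass distance between the CENP-A/H4 and CENP-A'/H4' dimers tracks
core compaction, which the acetyl regime plants as a 2 A shift together
with reduced jitter.
"""

from nucleodyn import AnalysisConfig, Selection, com_distance_series, rmsf, superpose
from nucleodyn.synth import build_nucleosome_model, make_preset, simulate_trajectory

no_equil = AnalysisConfig(equilibration_fraction=0.0)
core = Selection(
    roles=("CENP-A", "CENP-A'", "H4", "H4'", "H2A", "H2A'", "H2B", "H2B'"),
    atom_names=("CA",),
)
dimer_a = Selection(roles=("CENP-A", "H4"), atom_names=("CA",))
dimer_b = Selection(roles=("CENP-A'", "H4'"), atom_names=("CA",))

for preset in ("unmodified", "acetyl"):
    params = make_preset(preset, n_frames=1200, seed=7)
    model, topo = build_nucleosome_model(params)
    traj = simulate_trajectory(model, topo, params)

    fitted = superpose(traj, core, topo)
    res = rmsf(fitted, core, no_equil, topo)
    _, summary = com_distance_series(traj, topo, dimer_a, dimer_b)
    print(f"{preset:>10s}: mean core RMSF {res.values.mean():.3f} A "
          f"(block SD {res.block_sd.mean():.3f}); dimer COM distance "
          f"{summary.mean:.2f} A, variance {summary.variance:.4f}")
print("Lower RMSF and a shorter dimer COM distance in the acetyl regime "
      "reflect the planted rigidification/compaction of the histone core.")
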