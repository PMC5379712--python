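"""DNA-end breathing, groove widths and scissoring/groove coherence.

Measures the distance from each terminal base pair to the pseudo-dyad (its
variance reports how much that end unwraps), the cross-strand minor-groove
width at the planted site, and the alpha2-alpha3 scissoring angle of the
4-helix bundle.  In the acetyl regime the entry end breathes with 5 A
amplitude versus 1 A at the exit end, and the scissoring and groove series
share a latent oscillation with correlation 0.82.
"""

from nucleodyn import (
    dna_end_to_dyad_series,
    groove_width_series,
    scissoring_series,
    series_correlation,
)
from nucleodyn.synth import build_nucleosome_model, make_preset, simulate_trajectory

params = make_preset("acetyl", n_frames=4000, seed=7)
model, topo = build_nucleosome_model(params)
traj = simulate_trajectory(model, topo, params)

for end in ("entry", "exit"):
    series, summary = dna_end_to_dyad_series(traj, topo, end)
    print(f"{end:>6s} end: mean distance to dyad {summary.mean:.2f} A, "
          f"variance {summary.variance:.2f} A^2")

scissor = scissoring_series(traj, topo)
groove = groove_width_series(traj, topo, "minor", params.resolved_groove_site())
r = series_correlation(scissor, groove)
print(f"scissoring angle: mean {scissor.values.mean():.1f} deg, "
      f"SD {scissor.values.std():.1f} deg")
print(f"minor-groove width at residue {params.resolved_groove_site()}: "
      f"mean {groove.values.mean():.1f} A")
print(f"Pearson r(scissor, groove) = {r:.3f} (planted rho = "
      f"{params.scissor_groove_rho}); the larger entry-end variance is the "
      f"asymmetric-unwrapping signature.")
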