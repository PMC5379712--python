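# nucleodyn

Trajectory analysis for nucleosome dynamics, built around a synthetic
pseudo-atomic nucleosome generator with planted, analytically known motions.

## Who this is for

Centromeric chromatin is organized by CENP-A, the histone H3 variant that
replaces H3 in centromeric nucleosomes. Modifications buried in the CENP-A
histone fold — acetylation or monomethylation of K124 near the pseudo-dyad —
can rigidify the histone core, occlude the CENP-A C-terminus that the inner
kinetochore protein CENP-C docks onto, and change how the nucleosomal DNA
ends unwrap. Probing such effects computationally requires a battery of
trajectory observables; `nucleodyn` implements that battery as a tested,
reusable library:

* **contacts** — residue×residue contact occupancy between representative
  atoms (Cα for protein, P for DNA; cutoff 8 Å, occupancy = fraction of
  frames with distance ≤ cutoff), interface retention and stable-contact
  bookkeeping (retained / lost / gained) between two simulations;
* **geometry** — Kabsch superposition onto the time-averaged structure,
  per-atom RMSF with blocked (thirds) error bars, mass-weighted dimer
  center-of-mass distance distributions, DNA end-to-pseudo-dyad distances,
  cross-strand groove widths, the α2–α3 scissoring angle of the 4-helix
  bundle, and Pearson correlation between series;
* **essential dynamics** — PCA of the positional covariance over the histone
  core (`scope="core"`) or the whole nucleosome with 10 bp truncated per DNA
  end (`scope="nuc"`), free-energy landscapes F = −kT·ln(P/P_max) over two
  mode projections, and 5×-amplified multi-MODEL PDB mode animations;
* **fragment ions** — theoretical b/y series, precursor m/z and spectrum
  annotation for modified peptides such as VTLFPK(acetyl)DVQLAR, the tryptic
  CENP-A peptide diagnostic of K124 acetylation/methylation;
* **cell scoring** — chromatin-fiber co-localization counting (positive when
  ≥ 50 % of foci co-localize), pooled EdU⁺/CENP-B⁺ replication-timing
  fractions, and four-category mitotic-defect binning.

Because real microsecond all-atom trajectories are not shippable, the
`synth` module generates a 146-bp DNA superhelix wrapped around eight
histone bead chains with *planted* dynamics (Gaussian jitter, asymmetric
DNA-end breathing, a coupled scissoring–groove oscillation with tunable
correlation, dimer compaction, CENP-C detachment). Every analysis stage is
validated by recovering those planted parameters.

## Worked example

```python
from nucleodyn import (AnalysisConfig, series_correlation,
                       dna_end_to_dyad_series, groove_width_series,
                       scissoring_series)
from nucleodyn.synth import build_nucleosome_model, make_preset, simulate_trajectory

params = make_preset("acetyl", n_frames=4000, seed=7)   # rho = 0.82 planted
model, topo = build_nucleosome_model(params)
traj = simulate_trajectory(model, topo, params)

entry, es = dna_end_to_dyad_series(traj, topo, "entry")
exit_, xs = dna_end_to_dyad_series(traj, topo, "exit")
scissor = scissoring_series(traj, topo)
groove = groove_width_series(traj, topo, "minor", params.resolved_groove_site())
print(es.variance, xs.variance, series_correlation(scissor, groove))
```

This prints (see `examples/04_dna_unwrapping_coherence.py` for the narrated
version):

```
 entry end: mean distance to dyad 49.16 A, variance 12.56 A^2
  exit end: mean distance to dyad 46.56 A, variance 0.57 A^2
scissoring angle: mean 20.0 deg, SD 9.6 deg
Pearson r(scissor, groove) = 0.810 (planted rho = 0.82)
```

The entry-end variance exceeds the exit-end variance because the acetyl
regime plants 5 Å versus 1 Å breathing amplitudes (asymmetric unwrapping),
and the measured scissoring/groove coherence recovers the planted
correlation of 0.82 up to the small attenuation from bead jitter.

The `examples/` directory has one short script per capability:
simulation & reproducible runs, contact maps, core geometry (RMSF/COM),
DNA unwrapping & coherence, essential dynamics & landscapes, fragment ions,
and cell scoring. All write any bulky output under `scratch/`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full analysis battery from scratch: it simulates the
unmodified and acetyl regimes from the given seed, runs contact,
COM-distance, RMSF, unwrapping, coherence, PCA/landscape, fragment-ion and
cell-scoring stages, and prints a summary of what each stage measured. The
JSON written to `--out` maps registered numeric target identifiers to
measured values; this package registers none, so the file contains `{}` and
the printed summary is the product.
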