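# Methods

## Data model and conventions

Coordinates are in Å, times in ns. Frames are 0-based; residue indices are
kept exactly as in the input (1-based in PDB files) and never renumbered, so
residue labels like K124 or K79 survive every stage. The native trajectory
format is plain text (header with atom/frame counts, one coordinate triple
per atom per frame, `#`-prefixed metadata lines); adapters to binary MD
formats would have to produce the same in-memory contract and are out of
scope. PDB files carry no masses, so per-element average atomic masses are
attached at read time; the synthetic generator gives its pseudo-atoms those
same element masses (C for protein beads, P for DNA beads) so a PDB round
trip is exactly mass-preserving. Within any center-of-mass group the beads
are of a single element, so this choice does not bias COM geometry.

Analysis functions that take an `AnalysisConfig` discard the leading
`equilibration_fraction` of frames internally (default 0.6, i.e. the final
400 ns of a 1 µs run) before computing anything. A caller who has already
truncated the trajectory passes `equilibration_fraction=0`.

## The synthetic nucleosome: a stated world, not a physics simulator

`synth.build_nucleosome_model` lays out two antiparallel strands of n_bp
(default 146) P beads on a superhelix (radius 41.8 Å, 1.7 turns, 25.9 Å
pitch per turn, 10 Å radial strand separation) around eight histone chains
of Cα beads: CENP-A and CENP-A′ with explicit α2/α3 helix rods crossing at
20° near the center (the 4-helix bundle), an explicit C-terminal rod, and
blob-shaped H4/H2A/H2B chains, plus an optional CENP-C fragment rod docked
4.5 Å off the CENP-A C-terminus. The base-pair map is i ↔ n_bp+1−i
(1-based, antiparallel) with the central pair as pseudo-dyad.

`simulate_trajectory` adds four planted, analytically known motions to the
reference:

1. **Bead jitter** — i.i.d. isotropic Gaussian displacement per bead per
   frame, SD `core_sigma` (0.35 Å unmodified, giving per-bead RMSF
   √3·σ ≈ 0.61 Å, a realistic core fluctuation scale; 0.25 Å in the acetyl
   regime, emulating the rigidified core).
2. **DNA-end breathing** — the terminal 10 bp of each end move as a rigid
   unit along the dyad→end direction, sinusoidally with period 10 ns.
   Amplitudes: unmodified 2 Å (entry) / 1 Å (exit); acetyl 5 / 1 Å, the
   stronger and more asymmetric unwrapping of the acetylated particle.
   Rigid sinusoidal motion along that axis makes the end-to-dyad distance
   series exactly `D0 + A·sin(ωt)` plus jitter noise, so A is recoverable
   in closed form (we use the discrete Fourier amplitude at the dominant
   frequency, which white jitter barely perturbs — a plain √2·std estimator
   would be biased ~12 % at the 1 Å amplitude).
3. **Coupled scissoring/groove oscillation** — one latent standard-normal
   series z_t rotates α2 and α3 (both CENP-A chains) by ±φ_t/2 about the
   bundle normal (φ_t = amp·z_t, so the α2–α3 angle is exactly 20° + φ_t),
   while a second series g_t = ρ·z_t + √(1−ρ²)·w_t displaces a 5-bead
   strand-J window along the cross-strand direction at the planted groove
   site (default strand-I residue max(16, n_bp/3)). The bivariate-Gaussian
   mixing makes corr(φ, g) = ρ exactly. Acetyl regime: ρ = 0.82, scissor SD
   10°, groove SD 3 Å; unmodified: ρ = 0, 3°, 1 Å. Amplitudes were chosen
   once, before any test was run, from an error budget: with σ = 0.25 Å
   jitter the measurement noise on the scissoring angle (~0.5°) and on the
   single-P-pair groove width (~0.35 Å) attenuates the measured Pearson r
   by < 2 %, so the full-pipeline estimate at 5000 frames lands near 0.80.
4. **Constant offsets** — `dimer_com_shift` (2 Å, acetyl) translates
   CENP-A′/H4′ toward CENP-A/H4, making the difference of mean dimer-COM
   distances between regimes equal the shift; `cenpc_offset` (6 Å, acetyl)
   pushes the CENP-C fragment off the C-terminal rod, taking its docking
   contacts from ~4.5 Å (occupancy ≈ 1) to ~10.5 Å (occupancy ≈ 0 at the
   8 Å cutoff).

All randomness comes from one `numpy.random.default_rng(seed)` (PCG64) with
a fixed draw order, so a run is bit-reproducible from its seed; the seed and
the planted series are stored in the trajectory metadata.

**What a green test does and does not establish.** The generator emulates
the *statistical signatures* of the phenomena (occupancy contrasts, variance
asymmetry, coherence, compaction), not their physics: there is no solvent,
no sequence-dependent DNA mechanics, no energetics, and the bead jitter is
temporally white where real trajectories are autocorrelated. Parameter
recovery therefore validates the estimators and the pipeline plumbing, not
any claim about real CENP-A nucleosomes.

## Analysis choices

* **Contacts**: one representative atom per residue (Cα protein, P DNA);
  a distance exactly equal to the cutoff counts as a contact (≤). "Stable
  contact" means occupancy ≥ 0.5 by default (configurable). The occupancy
  loop is a vectorized per-frame distance matrix; tests pin it against an
  O(n²) per-pair brute force exactly.
* **Superposition**: each frame is rigid-body least-squares fitted
  (Kabsch via SVD, reflections excluded) onto the time-averaged coordinates
  of the reference selection, iterated to self-consistency — standard
  essential-dynamics practice, mass-unweighted.
* **RMSF**: about the time-averaged position over the analysis window;
  blocked estimate splits the window into `block_count` (default 3)
  contiguous blocks, each about its own mean, reporting the per-atom SD of
  block values. Deviations are taken relative to frame 0 before centering so
  a static trajectory yields exactly 0. A per-base-pair variant averages
  the two strands' P values.
* **Groove width**: distance between P_I(i) and P_J(basepair(i)+k), k = 3
  (minor) / 7 (major), minus a 5.8 Å phosphate-exclusion diameter, floored
  at 0. This is a documented package convention — no published algorithm is
  reproduced — and all groove statements in the tests are relative to it.
* **Scissoring**: angle between the dominant principal axes of the α2 and
  α3 Cα sets, axis signs fixed by continuity with the previous frame (acute
  at frame 0). "Coherence" is the Pearson correlation of the raw series —
  no smoothing, detrending or lag.
* **DNA ends**: the entry end is the strand-I 5′ terminus side (recorded in
  the topology, overridable); the end observable uses the terminal base
  pair's P-bead COM versus the dyad base pair's P-bead COM.
* **PCA**: mass-unweighted covariance with 1/n normalization of the
  superposed selection; `scope="nuc"` drops `end_truncation_bp` (default 10)
  base pairs per DNA end so end motions do not dominate the leading modes.
  When 3N exceeds the frame count the decomposition runs in frame space
  (Gram matrix), which spans the sampled subspace exactly; eigenvector signs
  are fixed by making the largest-magnitude component positive. Free-energy
  landscapes are F = −kT·ln(count/count_max) with kT = 1 by default
  (landscape in kT units; no physical temperature is ever needed); unsampled
  bins are NaN and flagged, never 0. Mode animations displace the mean by
  `animation_scale`·√λ·sin(2πk/n_interp) along the mode (default scale 5).
* **Fragment ions**: monoisotopic residue masses to ≥ 5 decimals, proton
  1.007276 Da, water 18.010565 Da; b_i = prefix + proton, y_i = suffix +
  water + proton, multi-charge m/z = (neutral + z·proton)/z. Only b/y are
  produced (CID regime); neutral losses and a/c/z series are out of scope.
  The default annotation tolerance is 0.4 Da (ion-trap CID). Note the
  theoretical 2+/3+ precursors of the acetyl/methyl K124 peptides are
  714.914 and 467.614; spectrum labels in the literature that round or
  shift from these are reported as observed values, not forced to match.
* **Cell scoring**: the fiber threshold is inclusive (≥ 50 %) by default
  with a strict (>) flag, because the operational figure-legend wording is
  inclusive while narrative text uses ">50 %"; replication fractions pool
  aggregate counts over cells rather than averaging per-cell ratios.

## Degenerate inputs and numerical notes

Zero-variance series refuse to correlate; collinear superposition references
are rejected; selections that resolve to nothing raise instead of returning
an empty list; equilibration refuses to leave fewer than two frames; PCA
eigenvalues are clipped at 0 against rounding; landscape minima are exactly
0 by construction (log of the max count is subtracted, not divided).

## Known limitations

No binary trajectory readers (plain-text only). No helicoidal DNA
parameters (roll/twist/slide) or Curves-style groove algorithm. No
hydrogen-bond or atom-chemistry contact definitions. The cell-scoring module
does no image analysis — inputs are pre-scored tables. The generator's
whiteness in time means autocorrelation-sensitive estimators (e.g.
statistical inefficiency) cannot be exercised against it.
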