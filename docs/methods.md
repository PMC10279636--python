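# Methods

This note documents the models, conventions and design choices behind
`plvnet`, and what the synthetic testbed does and does not establish about
real EEG data.

## Synthetic phase-coupling generator

**Model.**  Every parcel oscillates at a common carrier frequency
(default 10 Hz, the centre of the 8–12 Hz alpha band).  Phase coupling is
planted hierarchically: node *i* in group *g* has instantaneous phase

    φ_i(t) = 2π f t + ψ + η_g(t) + ε_i(t),

where ψ is a uniform per-epoch phase, η_g is group-level von Mises jitter
(concentration κ_g) and ε_i node-level von Mises jitter (κ_i), both drawn
independently at every sample.  ψ cancels in every pairwise phase
difference, so the expected phase-locking value is

    PLV_ij = ρ_i ρ_j                    (same group),
    PLV_ij = r_g r_h ρ_i ρ_j           (groups g ≠ h),

with ρ = I₁(κ)/I₀(κ) the mean resultant length (`plv_to_kappa` inverts
this Bessel ratio to 1e-6).  Target matrices are decomposed by a rank-one
fit per within-group block in the log domain (exact for block-constant
targets and for node-scaled targets of the form `w·u_i·u_j`) plus a
rank-one fit of the between-group factors; arbitrary targets are honoured
approximately, block-structured ones exactly in expectation.  Signals are
`amplitude · cos(φ_i(t))` plus Gaussian noise (default SD 0.1 in units of
the unit amplitude).

**Why white jitter.**  The PLV estimator averages unit phasors of the
phase difference over time within an epoch.  Jitter that is independent
across samples gives the estimator ~T effective samples per epoch
(T = 205 in the default 0–0.8 s window), keeping the small-sample modulus
bias (≈ √((1−r²)/T)) well below the calibration tolerance.  Smooth jitter
would be kinder to the Hilbert transform but collapses the effective
sample count and inflates low-PLV estimates several-fold.

**Estimator fidelity.**  The true phases realise the planted PLV exactly
in expectation (`generate_phases` exposes them).  The signal path adds two
distortions: (i) analytic-signal phase extraction of a broadband-jittered
cosine biases pairwise PLV by up to ≈ ±0.04 over targets 0.1–0.9
(measured; within the ±0.05 calibration band at 200 epochs × 205 samples);
(ii) strong *group* jitter — needed when between-group coupling is much
weaker than within — is common to all group members, and its loss through
the nonlinear phase extraction attenuates within-group PLV by up to
≈ 0.08 at within 0.8 / between 0.1.  Consequently block-level round trips
are asserted on the true phases, pairwise calibration on the full signal
path.

**Design emulation.**  `ExperimentDesign` defaults to 52 subjects,
overt/covert × fear/sad/happy/neutral, 100 trials per cell (400 stimuli
per task over 4 emotions, ~98% retained in the study this emulates).
Subject random effects act on the coupling scale (all analysed metrics are
coupling-derived), as a Gaussian intercept added to every off-diagonal
target and clipped to [0, 1).  Planted condition × emotion effects
increment the cross-subsystem (between-block) couplings of the affected
cells.  The pipeline additionally draws per-subject node factors
`u_i ~ U(0.75, 1)` and scales targets by `u_i u_j`: real connectivity
matrices have graded connection strengths, and without this heterogeneity
proportional thresholding is degenerate (all within-block edges tie and no
boosted between-block edge can ever out-rank a within edge, hiding any
planted effect).

**Epoch conventions.**  −0.5…0.8 s at 256 Hz; epoch length is
`floor((tmax − tmin)·fs) + 1` samples with the first sample at
`round(tmin·fs)` (333 samples), inclusive endpoints.  Identical
`(design_cell, seed)` pairs give bit-identical output; all randomness
derives from `numpy` `SeedSequence`s keyed by the seed and stable hashes
of the cell labels.

## Preprocessing

Deterministic conditioning for sensor data: polyphase resampling (512 →
256 Hz default) with proportional event remapping; average reference;
zero-phase forward–backward Butterworth band-pass (order 4; zero phase
because the output feeds phase estimation; band 8–12 Hz following the
convention that the narrower stated alpha definition governs, configurable);
moving-window peak-to-peak rejection (reject iff any channel exceeds
100 µV max−min inside any 200 ms window advanced by 20 ms, trailing
partial window included); bad channels by maximal inter-channel
correlation < 0.85 (all channels stand in for the neighbourhood when no
montage is given) or high/low-frequency power ratio above the channel mean
+ 4 SD.  ICA-based artifact classification and source modelling are out of
scope; the analysis enters at parcel signals, with the generator standing
in for source reconstruction.

**Known limitation — filter ringing in short epochs.**  The 4 Hz-wide
alpha filter rings for several hundred ms.  On 1.3 s epochs,
epoch-then-filter and filter-then-epoch differ by ~8% RMS even in the
epoch centre; the two orders agree to < 1% only when epochs are long
relative to the ringing (~0.4% on 4 s epochs, where the property test
runs).  For PLV purposes the pipeline prefers filtering the continuous
record (or analysis-ready narrowband synthetic signals) and additionally
trims 100 ms from each epoch border before estimation.

## Connectivity

Instantaneous phase is the angle of the analytic (Hilbert) signal per
epoch and node; constant traces are rejected as degenerate.  The default
estimator computes PLV over time within each epoch and averages the
resulting matrices across epochs (`mode="time"`); a cross-trial variant
(PLV across epochs at each time point, averaged over time,
`mode="trials"`) is provided since the original toolchain's normalisation
is not pinned down.  Defaults: post-stimulus window 0–0.8 s (with the full
−0.5–0.8 s a config switch away) and 100 ms edge trim.  Plain PLV is used
deliberately — no volume-conduction correction — matching the analysis
this package reimplements.  For independent phases the estimator's null
bias is ≈ √(π/(4T)), verified by simulation.

## Graph metrics

Connectivity matrices are proportionally thresholded: the
`round(density · n(n−1)/2)` largest off-diagonal weights are kept *with
their weights* (the printed modularity formula uses weights and weighted
degree; a binary mode is not provided).  Round-half-up edge count; ties at
the cutoff are broken by lowest node index and logged.  Edge length is
`1/weight` — the standard transform for affinity weights in [0, 1] — and
all-pairs shortest paths use Floyd–Warshall.  Global efficiency averages
inverse shortest path lengths over ordered pairs with `1/∞ = 0`.  The
routing matrix stores inverse shortest path lengths (0 for unreachable
pairs, 1 on the diagonal); routing efficiency is its maximum over
core × extended parcel pairs.  Modularity is maximised by Louvain
(resolution γ = 1, 100 restarts by default, best Q kept, fixed seeds);
the reported Q is always re-evaluated from the weighted formula on the
returned partition, so it matches the definition to 1e-12.

The default core/extended table maps the face-network region lists onto
Destrieux labels (core: inferior occipital gyrus/sulcus, lateral
fusiform, superior temporal sulcus; extended: superior and inferior
frontal gyri, temporal pole, insula, subcentral region; both
hemispheres).  The exact parcel membership is configuration, not code —
pass any two-column CSV (`parcel_label, system`).

## Statistics

Each metric is modelled as `value ~ condition * emotion + (1 | subject)`
with sum-coded factors, fit by REML.  The random-intercept covariance
(σ²I + τ²J per subject) admits an exact profiled likelihood, so the fit
is a bounded one-dimensional search over τ²/σ² (boundary τ² = 0
included); estimates are deterministic and reproducible to < 1e-8, and the
suite cross-validates them against statsmodels' MixedLM and R's
lmerTest.  Type-III F tests use Satterthwaite denominator degrees of
freedom computed by the delta method on the REML information
(finite-difference gradient and Hessian of the closed-form likelihood);
multi-df terms pool eigencontrast dfs as in lmerTest.  In the balanced
design the denominator df reduce to the classical `N − p − (s − 1)`
(e.g. 357 for 52 subjects × 8 cells).  Pairwise emotion contrasts within
each condition (6 pairs × 2 conditions) are tested on estimated marginal
means with per-contrast Satterthwaite df; the 12 contrasts per metric form
one Benjamini–Hochberg family (recorded in the run manifest).
Kenward–Roger is not implemented; Satterthwaite is the stated method.

**Calibration and power.**  Under a metric-level null simulation (subject
intercept + residual noise, 10 subjects) the interaction test's type-I
error stays within [0.02, 0.10] at α = .05 over 500 replicates.  The
documented power condition plants a shift of 1.25 residual SDs on the two
overt-negative cells with 20 subjects: the interaction noncentrality is
λ = n·δ²/2 ≈ 15.6, theoretical power ≈ 0.93, and the measured rate over
100 replicates exceeds 0.8.

## Problem sizes used in validation

Oracle comparisons (exhaustive path enumeration, exhaustive partition
search) run on ≤ 8-node graphs where brute force is exact.  Generator
calibration uses 2 nodes × 200 epochs × 205 samples × 20 seeds per
target.  Community recovery uses 20 nodes in four 5-node modules (within
0.8 / between 0.1, 20% density) — the aligned design in which the
threshold budget (38 edges) matches the within-module capacity (40); with
two 10-node modules the same threshold cannot cover the 90 within pairs
and node-correlated estimation noise leaves isolated parcels, a knife-edge
property of homogeneous planted blocks rather than of the detector.  The
directional-pattern experiments use 6 subjects × 20 nodes × 30 epochs per
cell with +0.3 planted cross-subsystem coupling in overt-fear/sad.

## What passing tests do and do not show

The generator produces stationary, single-frequency, noise-perturbed
oscillations with exactly exchangeable epochs.  Real source-reconstructed
EEG adds volume conduction and signal leakage, non-stationary amplitude
and frequency dynamics, heterogeneous per-parcel SNR and artifact
residue — none of which are modelled.  Passing tests therefore establish
that the *analysis chain* is correct and well calibrated (estimators match
their definitions, planted effects of known size are recovered with the
expected error rates), not that the scientific findings would replicate
on new EEG recordings; the original study's exact F and t values are not
reproducible without its raw data.
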