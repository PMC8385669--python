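# Methods notes

This note records the modelling choices behind `dfcprint`: what each stage
computes, which conventions were fixed where several were defensible, what
the synthetic generators do and do not emulate, and the package's known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Index spaces and conventions

The parcellation is categorical: 11 region names, each present in both
hemispheres, ordered FP, FM, FL, CM, CL, TA, TP, PL, PM, PO, OC with the
left-hemisphere block first (indices 0–10) and the right block second
(11–21). No ordering is canonical on scientific grounds; one must be fixed
so that vector indices are bit-stable across runs, and this is it.

Edges enumerate the row-major upper triangle of the 22 × 22 region matrix
(231 edges: 55 LL, 55 RR, 121 LR); DFC coefficients enumerate the row-major
upper triangle of the 231 × 231 edge matrix (26,565 per band; 132,825 over
the five bands in the fixed order δ, θ, α₁, α₂, β). Each coefficient
involves 3 regions (its two edges share one region; 4,620 cases) or 4
regions (21,945), and one of four lateralization categories:

| category | edge types | count |
| --- | --- | --- |
| unilateral within-hemispheric | LL·LL or RR·RR | 2 · C(55,2) = 2,970 |
| unilateral between-hemispheric | LL·RR | 55 · 55 = 3,025 |
| bilateral-unilateral | LR·LL or LR·RR | 121 · 110 = 13,310 |
| bilateral-bilateral | LR·LR | C(121,2) = 7,260 |

The within/between counts are forced by the edge-laterality counts; some
published tabulations of this taxonomy swap the two labels' numbers
(printing 3,025 within / 2,970 between), which is combinatorially
impossible, so the package reports the forced values.

The mirror map swaps L↔R on both endpoint regions of each edge and induces
a permutation of coefficients. Both permutations are involutions;
cross-hemisphere homolog edges (L.X–R.X) are fixed points; the taxonomy is
invariant under the map. Mirror symmetry of a profile is the Pearson
correlation between the vector and its mirrored copy.

## Signal processing

**Band-pass.** Per band, a linear-phase windowed-sinc (Hamming) FIR with
transition width min(2 Hz, low edge) and length at least 3 cycles of the
low edge, applied by centred convolution (zero-phase; boundary effects span
half the kernel). α₂ is implemented as 10–13 Hz, the conventional
upper-alpha band abutting β at 13 Hz. An optional acquisition-style
front-end (least-squares FIR 0.5–70 Hz of order 4.8 × sampling rate plus a
50 Hz notch) is provided but off by default — it models a recording chain,
not the per-band analysis filter, and synthetic data do not need it.

**Phase.** The analytic-signal phase is computed on 250 ms windows with
50 % overlap; each window contributes its central half to the stitched
series (the first and last windows also contribute their outer halves, and
an end-aligned window covers any remainder). This keeps the Hilbert
transform's edge artifacts out of the output; the stitched phase agrees
with the whole-signal Hilbert phase to well under 0.05 rad RMS on
stationary narrowband signals (asserted in the tests). The exact stitching
rule is a package convention — any rule with the same overlap that excises
window edges would do.

**Epochs** are non-overlapping, aligned to the recording start, with a
trailing partial epoch dropped: N = ⌊duration / epoch length⌋, so 15 min at
250 ms gives N = 3,600.

## Connectivity and DFC

PLI uses sign(0) = 0 exactly: numerically equal phases contribute nothing.
(Phase differences of exactly π are not representable in floating point;
sin returns ~1e-16 there, and no special-casing is attempted.)
Electrode-to-region reduction is the unweighted mean over cross-region
electrode pairs. DFC is the product-moment (Pearson) correlation in double
precision; a constant edge time series has undefined correlations, which
are stored as 0 with a warning naming the edge, keeping the vector length
fixed. N ≥ 3 epochs are required.

## Statistics

* **Identification**: Pearson similarity between all session-1/session-2
  profile pairs; argmax assignment in both directions; ties broken toward
  the lowest subject index (deterministic) and logged. The reported rate is
  the mean of the two directions. The permutation test relabels one
  database uniformly at random (default 10,000 iterations); its expected
  rate is 1/n.
* **Mass t-tests**: Welch's unequal-variance test by default (pooled
  optional), one per coefficient; the Bonferroni threshold is α/m over the
  coefficients actually tested. Constant-in-both-groups coefficients get
  p = 1. Deltas are stored as first-level-minus-second (F − M, HC − PD).
  With matched subsets, the significant count is additionally averaged over
  the subsets; full-cohort delta/t/p are always reported.
* **Age matching**: 5-year bins; within each bin the larger level is
  randomly down-sampled to the smaller's count; bins with one level absent
  are dropped with a warning. This is the simplest reproducible reading of
  "matched for age by random exclusion".
* **Percentile tails** use the nearest-rank convention: the bottom set
  holds the smallest ⌈p·n/100⌉ values, the top set the largest, ties at the
  cut included (a constant vector degenerates to the whole index set, with
  a warning).
* **Classifier**: lasso on 0/1 labels (squared-error objective — the
  simplest reading of "a regression model" with binary coding; a logistic
  variant was considered and not needed). Features are standardized with
  training-split statistics only; the penalty is chosen by internal 5-fold
  CV over the path; ROC analysis uses the raw continuous scores. Each
  Monte-Carlo repeat draws a random 80/20 split, age-matches the training
  classes with one matched draw, and records held-out AUC and selected
  indices; single-class test splits are redrawn and logged. External
  cohorts are scored by every per-repeat model (mean ± SD of AUC) and by
  the averaged model.
* **Sweeps** reuse the cached filter+phase stage; only epoching and
  downstream stages are recomputed, which also pins where randomness
  enters. Test–retest error is the per-coefficient mean absolute difference
  between sessions (primary), with an RMSE variant alongside.

## Synthetic data

Three generator levels, because no single model can both hit an exact DFC
target and exercise the raw-EEG path:

* **Profile level** (`simulate_profile_cohort`): coefficient vectors =
  base + i.i.d. Gaussian noise, optional planted mean shifts on chosen
  coefficients for one factor level. Default noise SD 0.05 — the scale of
  between-session DFC variability that the edge-level generator produces at
  a few hundred epochs. Used wherever effect size and noise must be exact
  (mass-test power, family-wise control, classifier suites).
* **Edge level** (`simulate_cohort`): per-epoch edge values drawn from a
  Gaussian copula with a prescribed 231 × 231 correlation matrix and
  Beta(2, 5) marginals (right-skewed on [0, 1], a plausible PLI shape;
  parameters configurable). A subject's target is the shared blueprint plus
  a symmetric random deviation (scale 0.2 by default) whose session-to-
  session correlation is the stability ρ (default 0.9: stable
  individual profiles); white latent noise (default 0.1) attenuates all
  correlations by 1 − ν². Targets are clipped/projected to valid
  correlation matrices (logged); the monotone marginal transform slightly
  attenuates linear correlations, so *rank* correlation is the exact
  recovery target. Ground-truth targets are stored with the cohort.
  The default blueprint sets 3-region coefficients (0.35) above 4-region
  ones (0.10), mimicking the empirical regularity that edge pairs sharing a
  region co-fluctuate more, then projects to the nearest correlation
  matrix.
* **Channel level** (`simulate_eeg_cohort`): each region oscillates at the
  band's centre frequency while "locked" and detunes by a fixed
  region-specific offset (0.5–0.9 of the band half-width, random sign)
  while "unlocked"; lock states flip every 0.5 s with the sign of the
  region's mixture of latent factors. Locked pairs hold their phase
  difference across a 250 ms epoch (PLI → 1); a detuned member sweeps it
  through sign changes (PLI low), so edge series fluctuate with the lock
  states and inherit the latent correlation structure. A subject's factor
  loadings are √(1−w)·common + √w·private (w = 0.85), giving a shared
  blueprint plus a session-stable fingerprint. Electrodes add independent
  sensor noise (SD 0.3 of the unit oscillation). The default band is β:
  its 8.5 Hz half-width leaves room for detunes that sweep several radians
  per 250 ms epoch; in 2 Hz-wide bands the mechanism still works but with
  less dynamic range. This generator is for end-to-end pipeline coverage —
  it cannot hit an arbitrary DFC target exactly.

None of the generators emulate volume conduction, 1/f broadband spectra,
artifacts, or inter-regional anatomical constraints; passing tests
demonstrate that the *computations* are correct and that the analyses
recover structure the generators genuinely contain, not that real EEG has
that structure.

## Problem sizes

The shipped suites run at desk scale, chosen to keep every statistical
check comfortably powered: edge-level fingerprint cohorts of 20 subjects at
400 epochs; channel-level cohorts of 8 subjects, 120 s at 250 Hz, one
electrode per region; mass-test suites at the full 26,565 coefficients with
60/60 subjects (planted) and 200 null cohorts of 40; classifier suites at
1,000 features and 40 Monte-Carlo repeats; test–retest scaling over
N ∈ {240, 600, 1500, 3600} epochs. Parameters such as cohort size, epochs,
repeats and feature counts are arguments throughout, so full-scale runs
(105–144 subjects, 500 repeats, 132,825 features) use the same code paths.

## Known limitations

* Only PLI is implemented (no wPLI, coherence, or amplitude-envelope
  correlation), and only Pearson DFC (no rank-based variant).
* The region scheme is categorical; there is no electrode geometry, source
  model, or 170 × 170 electrode-level DFC.
* Bonferroni is the only multiplicity correction, by design.
* The channel-level generator's lock/detune dynamics are a caricature of
  narrowband phase coupling; quantitative DFC magnitudes from it should not
  be compared with real data.
* EDF reading is optional and read-only; native storage is a flat binary
  matrix + JSON header.
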