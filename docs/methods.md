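# Methods

This note documents the models and procedures gazesal implements, the
parameters that matter, the numerical choices, and what the synthetic
cohort does and does not emulate.

## Synthetic cohort model

Each trial (one subject freely viewing one stimulus for
`trial_duration_ms`, default 5000 ms, on a 3840×2160 screen) is generated
as:

**Fixation count.** `K = max(1, round(N(n_fix_mean, n_fix_sd)))`, capped
so cumulative duration stays within the trial. A rounded truncated normal
is the minimal assumption when only a mean/SD pair is available.
Defaults: SCHZ 8.92 (SD 1.28), HC 9.22 (SD 0.75). The SD is applied at
the trial level; in the source summaries it more plausibly describes
between-subject variation of per-subject means — only the means are
calibration targets, so this choice affects dispersion bookkeeping, not
recovered means.

**Durations.** Fixation `k` lasts
`curve(k) + u_subject + ε`, floored at `min_duration_ms` (60 ms), with
`ε ~ N(0, dur_noise_sd_ms²)` (default 50 ms) and a per-subject curve
shift `u_subject ~ N(0, dur_subject_sd_ms²)` (default 20 ms, giving the
subject-level variance that subject-level t-tests operate on).
`curve(k)` is piecewise linear: baseline at index 1, peak at
`dur_peak_index`, linear decay to `dur_converge_ms` at
`dur_converge_index`, constant after. The default shapes (HC 240→290 ms
peaking at index 5, then flat; SCHZ 300→380 ms peaking at index 5 and
converging to the HC level at index 15) encode the qualitative group
dynamics — patients start with prolonged fixations that normalize by
mid-trial — and were chosen piecewise-linear for closed-form
recoverability. `calibrate_duration_curve` rescales a curve
multiplicatively so its expected per-fixation mean,
`Σ_k P(K≥k)·curve(k) / E[K]` (exact under the count model), equals a
target mean; the shipped defaults are calibrated to 326.12 ms (SCHZ) and
254.83 ms (HC).

**Locations.** Fixation `k` samples a lattice cell from
`(1−c)·[w_k·BU + (1−w_k)·OP] + c·CB`, then adds uniform within-cell
jitter (lattice default 240×135, so jitter adds ≤ cell²/12 ≈ 21 px² per
axis — negligible against spreads of ~500 px). `BU` is a bottom-up map,
`OP` the object-prior map, `CB` a fixed central Gaussian (per-axis SD =
1/4 of each screen dimension, weight `c = 0.2` — a mild center bias kept
deliberately even though the emulated protocol counters it with
off-center start crosses). `w_k` switches from `w_bottomup_early` to
`w_bottomup_late` at `w_switch_index` (defaults 0.6 → 0.3 at index 6),
emulating early stimulus-driven and later semantically driven viewing.
Inside the generator, `BU` is a cheap analytic proxy (uniform floor plus
a blob at the physically salient region); the graph-based model below is
what gets *scored*, never the sampling proxy.

**Spatial spread calibration.** For gaze sampled from a centered
isotropic Gaussian with per-axis SD σ, `E[SDD] = σ√2` — but only while
the screen borders are far away. At the spreads being emulated
(SDD ≈ 700 px on a 2160-px-tall screen) the vertical half-extent is
≈ 2.1σ and border truncation shrinks the SDD by ≈ 5%, far more than the
2% band the calibration aims for. `sigma_for_target_sdd` therefore
inverts the truncated-normal relation
`SDD(σ)² = Var_trunc,x(σ) + Var_trunc,y(σ)` (closed form per axis,
Brent root-finding); the naive `σ = SDD/√2` is recovered when no screen
geometry is supplied. Defaults are calibrated to SDD 678.28 px (SCHZ)
and 727.56 px (HC).

**Protocol furniture.** Every trial is preceded by a tagged start-cross
fixation at one of the eight off-center cross positions of the emulated
protocol (cross size 183 px, stroke 7 px), so the cleaning stage has a
ground-truth row to remove. RNG: the trial of subject *i* on stimulus
*j* uses `SeedSequence(seed, spawn_key=(i, j))`, making any subset
reproducible in isolation.

**What the generator does not emulate.** Saccade kinematics, blinks,
drift, calibration error; photo-realistic stimuli (object regions are
hue-distinct disks, physically salient regions high-contrast texture
patches); between-subject variation in spatial spread and fixation-count
means (both are fixed per group); any dependence of durations on
location. Passing recovery tests therefore shows the *analysis pipeline*
is correct and well-calibrated, not that real scanpaths follow this
generative model.

## Cleaning and periods

Off-monitor fixations are dropped. Within each trial, only the first
fixation is eligible for cross-removal: it is dropped iff it falls
within a disk of radius `0.75 × (cross_size/2) ≈ 69 px` around the
trial's cross center (the overlap criterion is a package choice; the
protocol specifies cross geometry but no criterion — the radius is
configurable). `fix_index` is re-ranked consecutively; trials left empty
are excluded and counted. Cleaning is idempotent unless a trial's second
fixation also lands on the cross (rare and visible in the counts).
Periods: indices 1–5 are `early`, 6+ are `late`; the split partitions
the cleaned table.

## Graph-based bottom-up saliency

Channels: intensity, red–green and blue–yellow opponency, four
orientation energies from quadrature Gabor pairs (frequency 0.2
cycles/px at working resolution; the real lobe is DC-removed so flat
patches carry no energy). Orientation 0° = horizontal structure, angles
counterclockwise. Each channel is computed at `n_scales = 2` dyadic
working resolutions and downsampled to a 32×18 lattice (preserving the
16:9 screen aspect), then epsilon-floored at 1e−6.

Activation: a fully connected Markov chain over lattice nodes with
weights `(|log M_i/M_j| + ε)·exp(−d²/2σ²)`, σ = 0.15 × lattice diagonal;
its stationary distribution concentrates on nodes dissimilar from their
surround. A constant map yields the uniform distribution by definition.
Conspicuity: a second chain with weights `G̃_ij · A_j`, where `G̃` is the
distance kernel balanced to doubly stochastic (Sinkhorn, cached per
lattice). Balancing is required on a bounded lattice: the raw kernel
gives border nodes lower degree, which would center-bias the output and
break the fixed-point property that uniform activation maps to itself.

Stationary distributions come from power iteration of the lazy chain
`(P+I)/2` (same stationary vector; plain iteration oscillates on the
near-bipartite chains that two-level images induce), tolerance 1e−9 on
the L1 sweep change, hard failure with the residual reported otherwise.
Channel maps are summed with equal default weights, upsampled, blurred
(σ = 2% of image width) and unit-sum normalized. Numerical parity with
any specific published implementation is not a goal; the construction
and its invariants (oracle-checked equilibria, intensity-scale
invariance up to epsilon-floor effects, translation equivariance) are.

## Scoring

NSS z-normalizes the map with the population SD and averages it at
fixated pixels (nearest-pixel lookup, no interpolation — binary-map
semantics). When map and screen resolutions differ, coordinates are
scaled onto the map grid, which is exactly nearest-neighbour upsampling.
A zero-variance map scores 0 with a counted warning. Negative NSS passes
through the signed square root `sign(x)√|x|` (monotone, defined
everywhere); a strict mode raises instead. Ground-truth density maps sum
truncated Gaussian kernels (default σ = 64 px ≈ 1° of visual angle at
the emulated 70-cm/163-PPI geometry), weighted by duration by default,
each kernel renormalized over its on-image support so border clipping
conserves total weight; they serve visualization and export, not NSS.

## Inference

**Mixed model.** `sqrt_nss ~ group × category + (1|subject) +
(1|category)`, treatment coding, reference HC/congruent, REML. With
`V = σ²I + τ_s Z_s Z_sᵀ + τ_c Z_c Z_cᵀ`, the residual variance and fixed
effects are profiled out, leaving a criterion in the two variance ratios
evaluated in O(q³) per step via the Woodbury identity on precomputed
cross-products (q = subjects + categories); Nelder–Mead from three
starts. Satterthwaite df per coefficient:
`df = 2·Var(c'β̂)² / (gᵀA g)` with `g` the finite-difference gradient of
`Var(c'β̂)` in `(σ², τ…)` and `A` the inverse finite-difference observed
information of the unprofiled REML log-likelihood. CIs and p-values use
the t distribution on those df. ICC = Στ/(Στ+σ²); marginal/conditional
R² follow the variance-partition formulation for mixed models.

A structural caveat this model carries by design: with category both a
fixed effect and a random intercept, the category indicators lie inside
the fixed-effect column space and the REML criterion is *exactly flat*
in τ_c. The fit detects this by a projection check, pins the component
at zero, flags the fit singular, and excludes the component from the
Satterthwaite parameterization — the conventional "τ00 = 0" report,
made explicit. Estimates and the group/interaction tests are unaffected
by the choice of point on the flat ridge.

**Sequential closed testing.** Per fixation index, in ascending order,
a two-sample test (Welch by default; pooled available) on per-subject
mean durations at that index — subject-level aggregation avoids
pseudo-replication. Index k is *declared* significant iff tests 1..k all
rejected at α = 0.05; raw t/p are still reported past the first failure.
Any declaration requires test 1 to reject, so the familywise error under
the global null equals the single-test level. The testable range ends
when either group has fewer than two subjects at an index.

**Summaries and correlations.** Welch t with Welch–Satterthwaite df for
two-sample summaries (a pooled-df convention is not recoverable for the
emulated design, so Welch is reported). Pearson correlations between
oculomotor metrics and clinical variables at α = 0.001 (conservative
against the many cells), pairwise deletion with missing counts, cells
with < 3 complete pairs or constant columns reported unavailable. No
further multiplicity correction is applied beyond these conventions.

## Problem sizes and reproducibility

Recovery checks simulate 28 + 25 subjects × 50 stimuli (the full
stimulus set is 250; 50 per cohort estimates group means to ~1% while
keeping each check under a minute); the null calibration of the
sequential procedure uses 2000 replicates via the duration-only fast
path (durations are independent of spatial sampling by construction).
The acceptance test of the printed oculomotor summaries pools three
replicate cohorts so the ±2-SE comparison tests calibration rather than
single-draw luck. Pipeline runs are deterministic at the byte level
given config + seed; stages are cached by config-subtree hash, so
stats-only changes never recompute saliency maps.
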