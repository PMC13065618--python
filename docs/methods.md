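# Methods

This note documents the models, conventions, and numerical choices behind
`leukoflow`, and what the synthetic validation does and does not establish.

## Trajectory model and kinematics

A recording is a set of per-cell trajectories, ordered `(t, x, y)` samples
in seconds and micrometres inside a 600 × 480 µm observation window
(calibrated against a 327 µm reference); `x` is the flow axis. Velocity and
acceleration are forward differences,

    v[i] = (x[i+1] − x[i]) / (t[i+1] − t[i])
    a[i] = (v[i+1] − v[i]) / (t[i+1] − t[i]),

each difference using its own Δt, so irregular sampling is supported. The
acceleration series is indexed to the earlier interval. Only the flow axis
enters the descriptors: in a laminar parallel-plate chamber transverse and
out-of-plane motion is negligible, and transverse coordinates are carried
only for rendering and spatial (ROI, stationarity) tests. Tracks with
non-monotone timestamps are rejected rather than re-sorted — silent
re-sorting would mask tracking/linking errors upstream.

## Descriptor suite

Each recording is condensed to 3 classical parameters and 45 descriptors.

**Aggregation convention.** Summaries are per-leukocyte first: each usable
track (≥ 3 points) contributes its mean |v|, mean |a|, mean signed a, and
its rolling-event counts; population statistics are then taken across
cells. The alternative — pooling all per-frame samples — is available via
`per_leukocyte=False` for sensitivity analysis, but the per-cell form is
the default because the count variables are defined as *numbers of
leukocytes* per range, which forces a per-cell assignment. Each cell is
assigned to exactly one velocity bin by its mean |v| and one acceleration
bin by its mean signed a (signed, because the acceleration ranges span
negative values); a value exactly on an edge belongs to the upper bin
(half-open bins, no gaps or overlaps).

**Families.** Velocity: mean and median of per-cell mean |v|, and the mean
per-cell velocity inside each of the four ranges (0–500, 500–1000,
1000–1500, 1500–∞ µm/s). Acceleration: mean |a|, median signed a, the four
range means (edges ±5000 µm/s², in µm/s² throughout — the printed
"µm² s⁻¹" unit in the source table is dimensionally inconsistent with
Δv/Δt and is treated as a typographical slip), and the
ratio/product combinations with velocity. Rolling events: a positive event
is a frame-to-frame velocity increase Δv > ε, a negative event Δv < −ε
(ε = 0 by default; the threshold exists to suppress tracking noise on real
data). Standard deviations: SD (ddof 1) across cells of the per-cell mean
|v| and of the per-cell mean signed a, plus their ratio, product, and the
signal-to-variability ratios. Interaction products: all six pairwise
products of the four velocity-range means and likewise for acceleration.
Counts: cells per velocity bin and per acceleration bin (they sum to the
number of usable tracks — a conservation law the tests enforce).

**Missing-value conventions.** An empty bin contributes feature value 0
(its count distinguishes emptiness, and zeros keep the LDA design matrix
complete); R⁺/R⁻ with zero denominators, SDs of a single cell, and ratios
with zero denominators are NaN and are imputed as 0 (with a logged count)
only at model-fitting time.

**Classical parameters.** Rolling velocity: mean of (100 µm / crossing
time) over the first up to 53 tracks that traverse a fixed 100 µm segment
centred on the flow axis (crossing times linearly interpolated). Rolling
flux: the ROI criterion — a 100 µm² endothelial area occupied for more
than a minute — is ambiguous between dwell and traversal; it is implemented
as a dwell-overlap count — distinct tracks whose cumulative time inside a
fixed central 10 × 10 µm square exceeds 60 s — and flagged as interpretive.
Adhesion: cells staying within a 5 µm radius (≈ one cell radius) of a
point for ≥ 30 s, counted in randomly placed sub-fields and extrapolated
to the 8.77 mm² dish. Sub-fields default to the full 0.288 mm² window, in
which case the ten placements coincide and the estimate is
count × 8.77/0.288; smaller sub-fields are supported when a recording
covers more area.

## Synthetic cohort generator

The generator reproduces the statistical structure the analysis assumes,
not the imaging physics. Cells enter the window at Poisson times
(`entry_rate`, default 0.3 s⁻¹ ≈ 90 cells per 5-min field) and evolve
through a three-state Markov chain — free flow → rolling (capture),
rolling → arrest, arrest → rolling (release) — with per-second rates
converted by the frame interval (default 0.033 s; the acquisition frame
rate of the original hardware is not documented, so a standard ~30 fps
video rate is assumed). Per frame the x-increment is drawn from the
state's speed distribution: free flow ~N(1000, 150²) µm/s, rolling
group-dependent, arrest exactly 0. While rolling, jerk events arrive as
per-frame Bernoulli trials (`jerk_rate`) and add a velocity step of
`jerk_amplitude_um_s` (default 150 µm/s) with alternating sign, emulating
the transient accelerations/decelerations of adhesion-molecule engagement
and driving the rolling-event descriptors. The chain as specified needs a
capture transition; `capture_rate` (default 2 s⁻¹, making rolling the
dominant observed regime, as in an adhesion assay where freely flying
cells are barely trackable) is a package addition.

Group presets encode the qualitative contrasts the descriptors target —
Healthy: fast rolling (600 µm/s), rare arrest; T1D: slow (200 µm/s),
strongly jerky rolling; T2D: moderate rolling (400 µm/s) with frequent,
long arrests; TNF-activation slows rolling and raises arrest in every
group. No quantitative per-group velocity distributions are published
(only box plots), so these are scenario parameters chosen once to be
physiologically plausible, not estimates of clinical data.

Biomarker columns are attached at the individual level (serum assays are
per subject, not per cell) by a Gaussian copula: the named descriptor is
standardized to z, and the biomarker is mean + sd·(ρ·z + √(1−ρ²)·ε).

**What passing tests show — and don't.** The simulator produces exactly
the independence/effect structure the statistics assume: Gaussian
state-speed noise, exchangeable individuals, exactly linear biomarker
links. Recovery of planted contrasts therefore validates the *machinery*
(descriptor arithmetic, selection calibration, classifier correctness),
not clinical performance. Known unrealism: no pulsatile flow, no
cell–cell interactions or crowding, no endothelial geometry, no tracking
noise in the default path (the optional renderer closes that loop
coarsely), and the extreme bins (|a| > 5000 µm/s², v > 1500 µm/s) are
rarely populated by per-cell means under the presets, so the corresponding
range/product descriptors are uninformative (constant 0) in simulated
cohorts and are dropped automatically when a fixed model list includes
them.

The optional `render_and_track` closes the video loop: cells are painted
as Gaussian blobs (point-spread σ default 3 µm) on noisy frames, local
maxima re-detected and linked by nearest neighbour within a gate (default
60 µm/frame, with a warning when the gate is below the maximum true
displacement). Positions are quantized to the pixel grid, which is the
dominant re-tracking error at zero noise.

## Statistics

ANOVA is the textbook one-way decomposition; Tukey HSD p-values come from
the studentized-range distribution with the pooled within-group df and the
Tukey–Kramer standard error √(MSW/2·(1/nᵢ+1/nⱼ)) (equivalent to the
harmonic-mean group size; for the balanced n = 10 design the distinction
is moot). Pearson p-values use the t transform, Spearman uses average
ranks; pairs with fewer than 4 complete observations or a constant column
are NaN. Raw p-values are reported by default — the original analysis did
not correct its 990 correlation comparisons — with an optional
Benjamini–Hochberg switch. Age-adjusted (ANCOVA) comparisons are out of
scope: individual ages are not modelled.

## Discriminant analysis

Written from first principles (scikit-learn is used only as an independent
cross-check in the tests). Wilks' λ = det(W)/det(T) is computed via
sign-aware log-determinants and clipped to [0, 1]; a singular T raises an
error naming the aliased columns. Stepwise selection enters, at each step,
the candidate minimizing the new λ if its partial F

    F = ((n − g − p)/(g − 1)) · (λ_p/λ_{p+1} − 1)

meets F_in = 3.84, then removes any included variable whose F-to-remove
falls below F_out = 2.71 (worst first); ties break by column order,
F_out ≥ F_in is rejected to prevent cycling, and revisited variable sets
halt the loop. For the first entry this partial F reduces exactly to the
one-way ANOVA F, and for two groups and one variable λ = 1/(1 + t²/(n−2))
— both identities are asserted in the tests at 1e-9/1e-10.

Canonical functions are eigenvectors of W⁻¹B scaled to unit pooled
within-group variance; standardized coefficients multiply by the pooled
within-group SDs (the SPSS convention; total-SD standardization is the
other defensible reading and differs only by a per-variable factor).
Classification uses Fisher linear functions Σ⁻¹μ_g with constant
−½μ_g'Σ⁻¹μ_g + log prior. Priors default to equal — the study design is
balanced — with proportional priors available. VIF is 1/(1−R²) of each
selected variable regressed on the others (computed on standardized
columns).

Leave-one-out validation keeps the variable list FIXED across folds,
which mirrors the original SPSS workflow and is optimistic because
selection saw the held-out point; an honest `nested_loo_cv` that re-runs
selection inside every fold is provided and clearly labelled. Folds whose
removal empties a group, or makes a near-constant selected variable
singular, are skipped with a warning.

PCA operates on the correlation matrix of internally standardized columns
(constant columns dropped with a warning); components with eigenvalue > 1
are retained, and varimax rotation uses Kaiser row normalization with
iterative pairwise planar rotations to 1e-6 convergence. An independent
SVD-based varimax in the tests confirms the rotations to 1e-5 up to column
order and sign.

## Pipeline and reproducibility

Every operation is a pure function of (inputs, seed); per-recording seeds
are spawned from the master seed via `SeedSequence`, and identical
configurations produce byte-identical written artifacts (verified in the
tests). The default model roster mirrors the study's comparisons — six
binary models, the Healthy/T1D/T2D ternary family at 6/5/4/3 variables,
the TNF-activated ternary, and the six-condition model — each runnable in
"discover" mode (fresh stepwise selection) or "reproduce" mode (the fixed
published variable lists). In reproduce mode, variables that are constant
or aliased on the given cohort are dropped with a warning rather than
failing the model.

## Problem sizes used in validation

Test and acceptance runs scale the study design down where the checked
property does not depend on size: cohort simulations use 120 s recordings
(the full 300 s design is the generator default and is used by the
analysis scripts), the stepwise calibration uses the 6 × 10 / 10-variable
null design and a 3-SD planted contrast at n = 10 + 10 over 100 seeds, the
preset T1D/T2D recovery uses 20 seeds at n = 10 per group, and the ANOVA
type-I error uses 1000 (tests) / 2000 (acceptance script) null 3 × 10
tables. The expected stepwise null-admission rate under the 10-variable
design is 1 − (1 − P(F₅,₅₄ > 3.84))¹⁰ ≈ 4.7%; with the full 45-descriptor
candidate set the same multiplicity argument bounds admission at ≈ 19%
(less under correlation), which is what the identical-kinetics cohort
test asserts.

## Known limitations

* The Tracker export column layout is a defined convention of this
  package (header with t/x/y or time synonyms, one file per cell or a
  `track_id` column), not a claim about the original software's files.
* Rolling-flux ROI semantics are interpretive (dwell-overlap); see above.
* The simulator's presets are scenario parameters; absolute descriptor
  values in simulated cohorts should not be compared to clinical tables.
* Only X-axis kinematics are computed; angular, path-length, dwell-time
  and shape descriptors are deliberately out of scope.
* With equal priors and heavily unbalanced real data, Fisher-function
  accuracies can mislead; use proportional priors in that regime.
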