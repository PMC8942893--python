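# Methods

This note documents the statistical model behind `libetbind`, the choices
made where the conventional analysis leaves room, and what the synthetic
generator does and does not emulate.

## The measurement model

A Libet-clock trial yields a reported clock position (0–`n_units`, 60 by
default) for a judged event — a self-paced key-press or a tone. With clock
period *P* ms/revolution the report converts to a phase
`position × P / n_units`, and the judgment error is the signed circular
difference

    e = wrap(reported_phase − actual_event_ms),   wrap: → (−P/2, +P/2]

with the boundary tie at exactly +P/2 assigned to the positive side. The
symmetric interval is the only defensible choice: errors in this paradigm
are below ~150 ms, two orders of magnitude from the boundary, so the
tie-break is never consequential but keeps the map deterministic. Reported
positions are accepted as fractional units — participants say whole numbers,
but the analysis must not force integers; quantization is a property of the
data source and lives in the generator. Marking scheme, hand length and face
diameter are metadata only: experimental evidence indicates they do not
modulate binding, and they never enter computation.

**Binding scores.** For each participant × condition, action binding is the
mean operant-action error minus the mean baseline-action error; tone binding
likewise for tone blocks. Positive action binding and negative tone binding
are the signature of temporal binding. When every participant contributes
equal trial counts, the group mean of per-participant shifts equals the
difference of per-block grand means; with unequal counts after trimming the
two differ slightly (participant means weight cells equally) — the
participant-mean route is the one reported.

## Trimming and screening

Trial-level outliers are removed in **one pass** per
(participant, condition, block) cell: keep trials with
`|e − mean| ≤ k·SD`, `k = 2.5`, sample SD (n−1), boundary kept. The rule is
deliberately not iterated: re-estimating moments after exclusion changes the
nominal rule into a different (stricter) one. Cells with fewer than two
trials are kept whole with a warning. Exclusion percentages are reported
pooled across the four blocks per condition, the convention in this
literature. Whether the historical rule pooled blocks or conditions when
computing M and SD is not documented anywhere we know of; the per-cell
choice is recorded in the trim report so alternatives can be compared.

Group-level participant screening in this literature is part formula, part
boxplot inspection. The package operationalizes it deterministically: for
each binding measure (action/tone × condition), participants beyond the
outer Tukey fence (3 × IQR past the quartiles) are excluded outright;
participants beyond the inner fence (1.5 × IQR) are excluded only when the
measure's group skewness or excess kurtosis (bias-corrected, the values
mainstream statistics packages print) exceeds ±2 before any exclusion —
otherwise they are flagged but retained. Excluded ⊆ flagged always holds,
and every exclusion carries a machine-readable reason.

## Repeated-measures inference

The dependent variable is always the participant's **mean** baseline-corrected
judgment error per cell; trials never enter the linear model. The ANOVA is
the classical univariate within-subject decomposition: each effect is tested
against its own participant × effect interaction term. For every effect with
≥ 3 levels, the per-participant effect scores are transformed by an
orthonormal (Helmert) contrast basis — the Kronecker product of the factor
bases for the interaction — and the d × d covariance S of the transformed
scores gives

    Mauchly W = det(S) / (tr(S)/d)^d,
    χ² ≈ −(n−1)·[1 − (2d² + d + 2)/(6d(n−1))]·ln W,  df = d(d+1)/2 − 1,
    GG ε = tr(S)² / (d·tr(S²)),  clipped to [1/d, 1].

Both the uncorrected and GG-corrected p are always reported;
`correction_applied` marks effects with Mauchly p < 0.05, following the
convention of correcting only demonstrably non-spherical effects. A remark
worth knowing: the GG correction is guaranteed conservative only in the
rejection-relevant region (uncorrected p below ≈ 0.22 for these designs);
deep inside the null bulk (F ≪ 1) shrinking both dfs can *lower* the
p-value. This is a property of the F distribution, not an implementation
artifact, and the test suite asserts conservativeness only where it holds.
With ε = 1 the corrected p equals the uncorrected p exactly, and for
two-level effects F equals the squared paired t. The implementation is
cross-checked in the tests against an independently coded sums-of-squares
oracle and against `pingouin`.

Pairwise contrasts are paired t-tests on participant cell means with
Bonferroni multiplication (capped at 1). Cohen's d is reported in **two**
flavors — dz = M/SD(differences) and pooled = M/√((SD₁²+SD₂²)/2) — because
published d values in this literature are not reliably reproducible from
either formula; neither variant is privileged.

Cousineau within-subject CIs re-centre each observation as
`y − participant mean + grand mean` and take half-width
`t(n−1)·SD(normalized)/√n` per condition. The Morey inflation `√(J/(J−1))`
is available behind a flag but **off** by default, matching the original
Cousineau procedure that the figures in this literature cite.

## Bayes factors and prior derivation

Evidence for a directional effect summarized by (M, SE) is quantified as

    BF = ∫₀^∞ N(M; θ, SE²)·HN(θ; 0, sd²) dθ / N(M; 0, SE²)

with a half-normal prior whose scale `sd` is the magnitude of the same
effect in a donor experiment. The numerator is evaluated in closed form
(Gaussian product rule plus a normal CDF) in log space; by default every
call is cross-checked against adaptive quadrature (integrated in
prior-standardised units so any sd/SE ratio is well-conditioned) at 1e−6
relative tolerance. BF > 3 counts as moderate evidence for H1, BF < 0.33
for H0, boundaries as insensitive.

The donor priors come from splitting a 3 (speed) × 2 (event) interaction
into three subsidiary 1-df effects. For speeds (fast, slow) the omnibus
effect is

    [action(fast) − action(slow)] + [|tone(fast)| − |tone(slow)|]

— the change in action binding plus the change in tone-binding *magnitude*
(tone shifts are negative; more negative = more binding). The combination
rule is not uniquely pinned down by its verbal description; of the four
plausible sign conventions exactly one reproduces all three published prior
scales simultaneously, and that one is hard-coded with the uniqueness check
kept as a test. The tone-only prior is the tone-magnitude change between the
extreme speeds. A non-positive derived magnitude is an error (a half-normal
prior with zero or negative scale is undefined), not silently clamped.

M is signed with positive = the predicted direction; an observation opposing
prediction is evaluated at its signed value (lowering the BF) and flagged.
For replicating printed analyses, SE is recovered from a reported 1-df
contrast as |M|/√F; for pipeline use it comes from the paired-difference
SD/√n. Both constructors are exposed on `EffectSummary`.

## The synthetic generator

Each simulated judgment error is `μ_{condition,block} + u + ε` with
participant intercept `u ~ N(0, τ)` and trial noise `ε ~ N(0, σ_trial)`.
Event times follow the paradigm's timeline: self-paced actions uniform in
(2560, 7680) ms after clock onset — the distribution of spontaneous presses
is not documented, and a window spanning at least one revolution of every
clock speed avoids phase bias — operant tones exactly 250 ms after the
action, baseline tones uniform in (2500, 5000) ms. Reports are the true
phase plus the error, by default rounded to the nearest whole clock unit
(quantization bias is bounded by half a unit, P/120 ms).

Default parameters come from the bundled published group tables: μ is the
printed block mean, and τ is back-solved from the printed between-participant
SD as `τ = √(SD² − σ_trial²/30)` so that simulated group summaries match the
tables. Trial-level noise is **not recoverable** from group summaries; the
default `σ_trial = 70 ms` is a modeling choice of realistic single-trial
scatter for this task, recorded in the fixture file. Intercepts are drawn
independently per condition × block because the published tables constrain
only per-block SDs: consequently simulated per-block SDs match the tables,
but simulated *shift* SDs exceed the printed ones (real baseline and operant
block means are positively correlated within participants; that correlation
is not recoverable from the published summaries). Passing tests on synthetic
data therefore validate the pipeline's arithmetic and calibration, not the
correlation structure of real Libet-clock data; the generator also omits
sequential effects, drifts, and any dependence of binding on markings or
hand length (no such effects are supported by the evidence).

`recovery_experiment` replicates simulate → trim → bind → ANOVA with seeds
spawned from a single `SeedSequence`, reporting rejection rates per effect
(type-I error under null parameters — calibrated at 0.05 within Monte-Carlo
error over 200 replicates — or power otherwise) and recovered shifts with
Monte-Carlo SEs.

## Problem sizes and numerics

The shipped calibration runs use the study's natural scale — 40 participants
× 3 conditions × 4 blocks × 30 trials — with 200 replicates for error-rate
calibration and 50 for recovery averaging; one replicate of the full
pipeline takes ~40 ms, so the complete acceptance run stays around ten
seconds. Degenerate inputs are handled explicitly: zero within-cell SD keeps
all trials (deviations 0 ≤ 0); singleton cells skip trimming with a warning;
Mauchly's test is reported as undefined (no correction applied) when n − 1 ≤
effect df makes the contrast covariance singular; a BF request with
non-finite M/SE or non-positive prior scale is rejected rather than
coerced. All human-readable tables round to 2 decimals; JSON reports carry
full precision.

## Known limitations

- The generator's independence of baseline and operant intercepts (above)
  makes shift variances conservative relative to real data.
- Participant screening is a deterministic stand-in for a partly subjective
  published procedure; it reproduces the *kind* of exclusions made, not any
  specific participant count.
- Published omnibus-interaction BFs cannot be recomputed exactly because the
  SE construction for summed effects is not documented; the package exposes
  both SE routes and asserts only the prior scales and the tone-only BF.
- One-way and two-way fully-within designs only; no between-subject factors,
  no mixed models, no multivariate sphericity alternatives.
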