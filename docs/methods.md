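# Methods

This note documents the models, estimators, conventions and numerical
choices behind `eegretest`, and what the synthetic cohorts can and cannot
say about real EEG.

## MVAR model and estimation

All interaction measures derive from the linear model
x(t) = Σ_{k=1..p} A_k x(t−k) + ε(t) with innovation covariance V, fitted
to the concatenated artifact-free 500 ms segments of one session.

The default estimator (`nuttall_strand_unbiased`) is a multichannel
lattice: forward and backward prediction errors are propagated through a
Levinson recursion, and at each stage the reflection matrices are formed
from the cross-covariance of the two error processes normalized by the
running error covariances. Every covariance is divided by its actual
product count N−k rather than N (the "unbiased" normalization), which
matters at high order relative to the sample count. `least_squares`
(lagged multivariate regression) is kept as an independent cross-check;
the two agree within 10 % on long, well-conditioned simulations, and the
tests assert this.

Segment boundaries: by default the concatenated signal is fitted as if
continuous, discontinuities included. `fit_mvar(...,
segment_length=250)` (pipeline flag `respect_boundaries`) instead
excludes every lag product that straddles a segment boundary, in both
estimators. On continuous data both modes agree; on truly independent
segments the boundary-aware mode removes the contamination from the
artificial jumps.

The model order is configurable; an order of 250 at 500 Hz (one full
segment, one cycle of the lowest analyzed frequency) is supported but
the test suite works at m ≤ 6, p ≤ 12, where estimation error against
ground-truth coefficients can be measured directly. A warning is issued
when the sample count is below ten times the order. Stability of a
fitted model is recorded (companion spectral radius) but not enforced;
estimated models may legitimately be near-unstable.

## Frequency transform and the 14 measures

On the integer grid f = 2..125 Hz (1 Hz steps, strictly below Nyquist):
Ā(f) = I − Σ_k A_k e^(−i2πfk/fs), H(f) = Ā(f)⁻¹, and the two-sided
spectral density S(f) = H V Hᴴ / fs in µV²/Hz. The 1/fs scaling is a
convention; every normalized measure and every rank-based statistic
downstream is invariant to it.

Conventions that were genuinely open and are fixed here:

* **Spectrum (S)** is reported as the magnitude |S_ij(f)| so that cross-
  spectra (complex) and autospectra (real) live in one real tensor that
  rank correlation can consume.
* **pCOH** uses the partial-correlation sign convention
  Re(−G_ij/√(G_ii G_jj)) with G = S⁻¹ and diagonal set to 1.
* **dDTF** multiplies ffDTF by |pCOH| so it stays in [0, 1]; the signed
  variant is available (`pcoh_magnitude=False`).
* **Direct causality (DC)** is the lag-summed squared coefficient
  DC_ij = Σ_k A_k[i,j]², the only frequency-independent measure. This is
  the principal formula-level assumption of the package: the name and
  the frequency-independence are standard, the exact formula is not
  printed in the literature the package follows.
* **GGC** uses pairwise bivariate refits at the full model order:
  GGC_{j→i}(f) = ln(S_ii / (S_ii − (V_jj − V_ij²/V_ii)|H_ij|²)) from the
  bivariate model of channels (i, j). Non-positive denominators from
  numerical noise are clipped at eps·S_ii (eps = 1e−12) with a warning.

Directed orientation is `value[i, j]` = influence j → i everywhere: PDC
and its relatives are column-normalized in Ā, DTF and its relatives
row-normalized in H. The normalization identities Σ_i PDC_ij² = 1,
Σ_j DTF_ij² = 1 and Σ_{f,j} ffDTF_ij² = 1 hold to machine precision and
are asserted to 1e−10 over random stable models.

Band averages are unweighted arithmetic means over the integer
frequencies inside each inclusive range (delta 2–4, theta 5–7, alpha
8–13, beta 14–30, gamma 31–80, high gamma 81–125 Hz); DC passes through
without a frequency axis.

## Preprocessing

Filtering is zero-phase: a 4th-order Butterworth high-pass at 1 Hz run
forward-backward (≈48 dB/oct combined) and a second-order IIR notch at
50 Hz of 2 Hz bandwidth, also forward-backward. Exact vendor filter
coefficients are unknowable, so the roll-off and zero-phase properties
are the design targets; the tests measure DC rejection, 50 Hz
attenuation, passband flatness (2 %) and zero lag directly.

Artifact rules operate per channel on every sample/window, each flagged
region dilated by a closed margin interval clipped at the edges:
"voltage step per sampling point" is the first difference of consecutive
samples; "absolute difference on an interval" is peak-to-peak (max−min)
in a per-sample sliding window. The margin of the 200 µV rule is not
specified anywhere authoritative and is set to ±100 ms like the step
rule (configurable). The vectorized detector is tested sample-for-sample
against a literal loop-over-every-window implementation.

Segmentation starts at sample 0, uses non-overlapping 500 ms segments,
drops a segment if any sample of any channel is flagged, discards the
trailing partial segment, and keeps temporal order in the concatenation.
Recordings with fewer than 8 clean segments fail the quality gate and
are excluded with a reason in the run summary. Visual review has no
automated counterpart; an optional user-supplied override mask can be
OR-ed with the automatic detection.

## Synthetic cohorts: what they emulate, and what they do not

Each channel of a template is an AR(2) resonance. The pole angle is
placed so the analytic spectral *peak* (not the pole) sits at the
requested band center — for a pole radius ρ the closed-form relation is
cos θ_pole = cos θ_peak · 2ρ/(1+ρ²); without this correction a 10 Hz
pole at ρ = 0.9 peaks near 5.5 Hz. Directed interactions are written
into off-diagonal coefficients at chosen lags. Optional symmetric,
diagonally dominant neighbour mixing stands in for volume conduction;
because it is instantaneous and invertible, the mixed signal is still an
exact MVAR process. The reference template (6 channels, three weak
directed edges, leakage 0.25) is the default study condition for the
reliability experiments.

Innovation covariances are calibrated so every channel sits near
10 µV RMS — realistic resting-EEG scale, safely inside the amplitude
artifact thresholds. The stationary variances come from companion-form
discrete Lyapunov equations; per-channel innovation scales are fitted by
fixed-point iteration with a floor (each channel's own drive alone must
produce at least a third of the target RMS, so no channel degenerates
into a deterministic function of its drivers) and a global cap (loudest
channel at twice the target). Calibration is re-run per session, i.e.
amplitudes are treated as homeostatically regulated; the jitter between
sessions changes the interaction *structure*, not the overall scale,
which matches the construct under study (stability of the network, not
of signal power).

Subject- and session-level variation is *structural*: band centers and
coupling strengths are scaled by 1 + N(0, sd), pole radii get additive
N(0, 0.3·sd) noise clipped to [0.6, 0.95], with sd = `subject_sd` for
subjects and sd = η·`subject_sd` for session 2 around the subject's
parameters. η = 0 reproduces session 1's coefficients exactly; η = 1
makes session 2 as different from session 1 as subjects are from each
other. A naive entrywise Gaussian perturbation of the coefficient stack
was evaluated and rejected: the companion matrix of a resonant template
is so non-normal that even 0.01-scale entrywise noise pushes the
spectral radius far past 1, and after any re-stabilization the effective
perturbation size is dictated by the stability margin rather than by η,
which destroys the monotone link between the knob and downstream
reliability. Entrywise perturbation (with shrinkage of the perturbation
only) remains available for bare coefficient templates.

Injected artifacts (DC steps, half-sine slow waves, flatlines) come with
exact ground-truth flag windows derived from the rule semantics;
overlapping injections are rejected so the ground truth stays
unambiguous. Sub-threshold injections contribute no window.

What the generator does **not** emulate: 1/f background spectra,
non-stationarity (drowsiness, state drift), non-Gaussian transients, eye
or muscle artifacts with realistic morphology, or a biophysical head
model. Passing tests therefore show the *pipeline* is correct and that
reliability responds to ground-truth structural stability; they do not
show how reliable any measure is on clinical EEG.

## Reliability

Per subject: Spearman ρ (midrank ties) between the two sessions'
concatenated vectors, ordering band-major then sink then source.
Diagonal cells are included by default (the spectrum's diagonal is its
autospectrum, a listed measure component) and can be dropped
(`include_diagonal=False`). "Frequency" means the six bands by default;
a per-1-Hz variant correlates the unaveraged 124-point tensors
(`per_hz_reliability`). Identical orderings short-circuit to exactly
ρ = 1, so duplicated sessions give 1.0 without floating-point residue.
Constant vectors have undefined ρ: the subject is flagged NaN with a
warning and excluded downstream. Negative ρ values are retained
unchanged.

Per edge: for each (band, sink, source) cell, Spearman across the
subjects of one group between session-1 and session-2 values; cells that
are constant across subjects (e.g. the coherence diagonal, which is 1
by definition) are recorded as missing and counted.

## Group inference

Relative effects use pooled midranks: p̂_g = (R̄_g − ½)/N, the estimated
probability that a random group member exceeds a random member of the
pooled sample; Σ_g (n_g/N)·p̂_g = ½ holds exactly on any input.

The multivariate group comparison midranks each response column over all
N subjects and forms the ANOVA-type statistic T = tr(H)/tr(G) from the
between-group (H) and pooled within-group (G) rank covariance matrices.
T is referred to F(f1, f2) with trace moment matching:
f1 = (a−1)(tr G)²/tr(G²) and
f2 = [Σ_i (n_i−1) tr Ψ_i]²/[Σ_i (n_i−1) tr(Ψ_i²)] over per-group rank
covariances Ψ_i — fractional degrees of freedom, heterogeneity-aware in
the denominator. A label-permutation p-value of the same statistic
(vectorized, seeded) is the finite-sample cross-check; the two agree
within 0.03 across null simulations, and the type-I error at α = 0.05
sits inside [0.03, 0.07] in the calibration tests. The closed testing
procedure tests every subset of ≥ 2 groups and rejects a subset only if
it and all its supersets reject at α (plain closure, family-wise level
α).

Edge-wise comparisons use Fisher's transform z = atanh(ρ) and
Z = (z1 − z2)/√(1/(n1−3) + 1/(n2−3)), two-sided normal p-values, with
|ρ| ≥ 1 clipped to 1 − 1e−7 under a warning. All raw p-values across
group pairs, measures, bands and edges are pooled and Holm-corrected
jointly (step-down, adjusted p_(k) = max_{j≤k} min(1, (m−j+1)p_(j)));
per-measure pooling is available (`pool_scope="per_measure"`). The most
stringent per-test threshold applied (α divided by the family size) is
reported alongside, since it is the single "critical p-value" sometimes
quoted for such analyses. Non-significant Z values are zeroed in the
exported significance maps.

## Problem sizes and numerical choices

* Test and validation runs use m ≤ 6 channels, orders ≤ 12, sessions of
  10–30 s at 500 Hz, and cohorts of 8–20 subjects per condition; these
  sizes make ground-truth recovery measurable while keeping the full
  suite around a minute.
* The reliability-vs-η experiment uses the reference template, 20
  subjects, 30 s sessions, order 8, subject_sd 0.25, η ∈ {0, 0.2, 0.5, 1}.
* Stabilization: templates are shrunk uniformly (×0.95 per step, ≤ 50
  steps) below a companion spectral radius of 0.97; the margin to 1
  bounds process variance so clean synthetic data cannot trip the
  amplitude rules.
* EDF output uses plain 16-bit EDF with a symmetric digital range
  (±32767) and per-channel symmetric physical ranges, giving an exact
  linear mapping and a quantization step of 2·max|x|/65534 µV; reading
  goes through MNE.
* Ties are midranked everywhere (scipy `rankdata`); Spearman via scipy
  with the exact-ordering short-circuit noted above.
* Seeds: all generators run on `numpy.random.SeedSequence` spawning, so
  cohorts and analyses are bitwise reproducible from (config, seed).

## Known limitations

* The estimator is a standard multichannel partial-correlation lattice;
  other unbiased-covariance variants (e.g. geometric-mean
  normalizations) exist and can differ at very high order on short data.
* The ANOVA-type degrees of freedom follow trace moment matching as
  described above; published rank-MANOVA software may use slightly
  different denominator-df formulas, so fractional dfs need not match
  such software digit-for-digit (the permutation p-value is the
  distribution-free reference).
* GGC is bivariate by construction and inherits the usual caveat that
  it does not separate direct from indirect influence.
* Reliability conclusions from synthetic cohorts transfer to real EEG
  only to the extent that session-to-session drift is structural, which
  is an assumption, not a finding.
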