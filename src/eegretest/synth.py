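"""Synthetic two-session EEG cohorts from ground-truth MVAR processes.

Every downstream stage of the package (preprocessing, model fitting,
spectral connectivity, reliability, group inference) is exercised on data
from this module, because the clinical recordings the pipeline is designed
for are not publicly available.  The generator emulates their essential
structure:

* each channel carries a band-tuned oscillation (an AR(2) resonance whose
  spectral peak sits at the requested band center);
* a directed coupling graph is written into the off-diagonal MVAR
  coefficients at chosen lags;
* optional instantaneous mixing stands in for volume conduction;
* subjects are jittered copies of a group template — the jitter acts on
  the generative structure (resonance frequencies, pole radii, coupling
  strengths) — and the two sessions of a subject differ by a second,
  smaller jitter of scale ``eta * subject_sd``: the knob that sets
  expected test-retest reliability (``eta = 0``: identical interaction
  structure across sessions; ``eta = 1``: session 2 is as far from
  session 1 as subjects are from each other);
* amplitude artifacts (voltage steps, high-amplitude slow waves, flat
  segments) can be injected with exact ground-truth flag windows.

All randomness flows through :class:`numpy.random.SeedSequence` spawning,
so a cohort is a pure, bitwise-reproducible function of its spec.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import Recording
from .mvar import companion_spectral_radius

#: Target per-channel signal RMS, µV: realistic resting-EEG amplitude
#: (a few tens of µV peak-to-peak), comfortably inside the clinical
#: amplitude-artifact thresholds.
DEFAULT_TARGET_RMS = 10.0

#: Band centers cycled over channels when none are given (Hz): alpha,
#: theta, beta, alpha, delta, gamma — a crude mix of resting rhythms.
DEFAULT_BAND_CENTERS = (10.0, 6.0, 21.0, 8.0, 3.0, 35.0)

# perturbation draws are re-stabilized below this companion spectral
# radius; the margin to 1 keeps the process variance bounded so clean
# synthetic sessions stay inside the amplitude-based artifact rules
_STABILITY_RADIUS = 0.97
_SHRINK_FACTOR = 0.95
_MAX_SHRINK_ITER = 50


class StabilizationError(RuntimeError):
    """Raised when a coefficient stack cannot be shrunk into stability."""


@dataclass
class MVARTemplate:
    """Ground-truth generative MVAR process for one group.

    ``A`` has shape (p_sim, m, m); ``V`` is the innovation covariance in
    µV²; ``mixing`` (optional m x m) is applied instantaneously to the
    simulated signal as a volume-conduction surrogate.

    Templates built by :func:`make_template` also carry their structural
    parameters (band centers, pole radius, coupling edges); subject- and
    session-level variation perturbs those parameters, which keeps the
    perturbed processes well inside the stability region.
    """

    A: np.ndarray
    V: np.ndarray
    fs: float
    mixing: np.ndarray | None = None
    band_centers: list[float] | None = None
    pole_radius: float | None = None
    coupling_edges: list[tuple[int, int, int, float]] | None = None
    peak_correction: bool = True
    target_rms: float = DEFAULT_TARGET_RMS
    innovation_correlation: float = 0.0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.A.ndim != 3 or self.A.shape[1] != self.A.shape[2]:
            raise ValueError("A must have shape (p_sim, m, m)")
        if not np.allclose(self.V, self.V.T):
            raise ValueError("V must be symmetric")
        if np.any(np.linalg.eigvalsh(self.V) <= 0):
            raise ValueError("V must be positive definite")
        rad = companion_spectral_radius(self.A)
        if rad >= 1.0:
            raise ValueError(f"template is unstable (spectral radius {rad:.3f})")
        if self.mixing is not None:
            self.mixing = np.asarray(self.mixing, dtype=float)
            if self.mixing.shape != self.V.shape:
                raise ValueError("mixing must be m x m")

    @property
    def m(self) -> int:
        return self.A.shape[1]

    @property
    def p_sim(self) -> int:
        return self.A.shape[0]


def stabilize(A: np.ndarray, radius: float = _STABILITY_RADIUS) -> np.ndarray:
    """Shrink all coefficient matrices uniformly until the stack is stable.

    Multiplies every A_k by 0.95 per iteration (at most 50); raises
    :class:`StabilizationError` if the spectral radius still exceeds the
    target afterwards.
    """
    A = np.array(A, dtype=float)
    for _ in range(_MAX_SHRINK_ITER):
        if companion_spectral_radius(A) < radius:
            return A
        A *= _SHRINK_FACTOR
    if companion_spectral_radius(A) < radius:
        return A
    raise StabilizationError(
        f"could not stabilize coefficients within {_MAX_SHRINK_ITER} shrink steps"
    )


def ar2_coefficients(
    center_hz: float, fs: float, pole_radius: float, peak_correction: bool = True
) -> tuple[float, float]:
    """AR(2) coefficients producing a resonance at ``center_hz``.

    With ``peak_correction`` (default) the pole angle is chosen so that
    the analytic AR(2) spectral *peak* falls at ``center_hz``; the
    closed-form relation is cos(θ_pole) = cos(θ_peak)·2ρ/(1+ρ²).  Without
    it the pole angle is put directly at ``center_hz`` (the textbook map
    a1 = 2ρcos(2πf0/fs), a2 = −ρ²), whose peak sits below the pole
    frequency for ρ < 1.
    """
    if not 0 < pole_radius < 1:
        raise ValueError("pole_radius must be in (0, 1)")
    theta = 2 * np.pi * center_hz / fs
    if peak_correction:
        c = np.cos(theta) * 2 * pole_radius / (1 + pole_radius**2)
        theta = np.arccos(np.clip(c, -1.0, 1.0))
    a1 = 2 * pole_radius * np.cos(theta)
    a2 = -(pole_radius**2)
    return float(a1), float(a2)


def make_template(
    m: int,
    coupling_edges: Sequence[tuple[int, int, int, float]] = (),
    band_centers: Sequence[float] | None = None,
    fs: float = 500.0,
    pole_radius: float = 0.9,
    p_sim: int = 6,
    target_rms: float = DEFAULT_TARGET_RMS,
    innovation_correlation: float = 0.0,
    mixing: np.ndarray | None = None,
    peak_correction: bool = True,
) -> MVARTemplate:
    """Build a stable group-level MVAR template.

    Parameters
    ----------
    m
        Channel count.
    coupling_edges
        Directed couplings ``(source, sink, lag, strength)`` with 0-based
        channel indices and 1-based lag <= ``p_sim``; each writes
        ``A[lag-1][sink, source] = strength``.
    band_centers
        Per-channel resonance frequency in Hz; cycled from
        :data:`DEFAULT_BAND_CENTERS` when omitted.
    pole_radius
        Resonance sharpness, < 1; 0.9 gives clearly peaked but broadband
        spectra like resting EEG rhythms.
    p_sim
        Simulation model order (>= 2 for the resonance, >= max lag).
    target_rms
        Per-channel signal RMS the innovations are calibrated to, µV.
    innovation_correlation
        Exponential cross-correlation of the innovations (common-drive
        surrogate); 0 gives independent drives.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if p_sim < 2:
        raise ValueError("p_sim must be >= 2 to host an AR(2) resonance")
    if band_centers is None:
        band_centers = [DEFAULT_BAND_CENTERS[i % len(DEFAULT_BAND_CENTERS)] for i in range(m)]
    if len(band_centers) != m:
        raise ValueError("need one band center per channel")
    A = np.zeros((p_sim, m, m))
    for ch, f0 in enumerate(band_centers):
        a1, a2 = ar2_coefficients(f0, fs, pole_radius, peak_correction)
        A[0, ch, ch] = a1
        A[1, ch, ch] = a2
    for source, sink, lag, strength in coupling_edges:
        if not 1 <= lag <= p_sim:
            raise ValueError(f"edge lag {lag} exceeds p_sim={p_sim}")
        A[lag - 1, sink, source] = strength
    A = stabilize(A)
    V = _calibrated_innovations(A, innovation_correlation, target_rms=target_rms)
    return MVARTemplate(
        A=A, V=V, fs=fs, mixing=mixing,
        band_centers=[float(f) for f in band_centers],
        pole_radius=float(pole_radius),
        coupling_edges=[tuple(e) for e in coupling_edges],
        peak_correction=peak_correction,
        target_rms=target_rms,
        innovation_correlation=innovation_correlation,
    )


def _coefficients_from_structure(
    band_centers: np.ndarray,
    pole_radii: np.ndarray,
    edges: list[tuple[int, int, int, float]],
    fs: float,
    p_sim: int,
    peak_correction: bool,
) -> np.ndarray:
    m = len(band_centers)
    A = np.zeros((p_sim, m, m))
    for ch in range(m):
        a1, a2 = ar2_coefficients(band_centers[ch], fs, pole_radii[ch], peak_correction)
        A[0, ch, ch] = a1
        A[1, ch, ch] = a2
    for source, sink, lag, strength in edges:
        A[lag - 1, sink, source] = strength
    return stabilize(A)


def _jitter_params(
    centers: np.ndarray,
    radii: np.ndarray,
    edges: list[tuple[int, int, int, float]],
    scale: float,
    rng: np.random.Generator,
    fs: float,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int, int, float]]]:
    """Gaussian jitter of the structural parameters.

    Band centers and coupling strengths are scaled by 1 + N(0, scale);
    pole radii get additive N(0, 0.3*scale) noise.  Clipping keeps the
    resonances inside (0.6, 0.95) and the centers on the analyzable
    grid, so stability never saturates the jitter.
    """
    m = len(centers)
    centers = np.clip(
        centers * (1 + scale * rng.standard_normal(m)), 2.0, 0.45 * fs
    )
    radii = np.clip(radii + 0.3 * scale * rng.standard_normal(m), 0.6, 0.95)
    edges = [
        (src, snk, lag, s * (1 + scale * rng.standard_normal()))
        for src, snk, lag, s in edges
    ]
    return centers, radii, edges


def _calibrated_innovations(
    A: np.ndarray,
    correlation: float,
    target_rms: float,
    n_iter: int = 8,
) -> np.ndarray:
    """Innovation covariance giving every channel ~target_rms µV RMS.

    The innovations carry an exponential cross-correlation
    ``correlation**|i-j|`` — a crude common-drive/volume-conduction
    surrogate that makes the true coherence nonzero and heterogeneous
    across all channel pairs, as in scalp EEG.  Resonances and couplings
    amplify the innovations very unevenly, and uncalibrated signals can
    stray across the clinical amplitude-artifact thresholds (too loud
    for the 200 µV peak-to-peak rule, or too quiet for the 0.5 µV
    flatline rule); per-channel innovation scales are therefore fitted
    by fixed-point iteration on the stationary variances, which come
    from companion-form discrete Lyapunov equations.
    """
    from scipy.linalg import solve_discrete_lyapunov

    from .mvar import companion_matrix

    p, m, _ = A.shape
    idx = np.arange(m)
    C = correlation ** np.abs(np.subtract.outer(idx, idx)).astype(float)
    F = companion_matrix(A)
    # own-innovation gain per channel: variance of channel i driven only
    # by its own unit-variance innovation
    own_gain = np.empty(m)
    for j in range(m):
        Q = np.zeros_like(F)
        Q[j, j] = 1.0
        own_gain[j] = np.diag(solve_discrete_lyapunov(F, Q))[j]
    # floor: every channel's own drive alone yields >= target/3 RMS, so
    # no channel degenerates into a deterministic function of its
    # drivers (coupled sinks may end up somewhat louder than target)
    s_min = (target_rms / 3.0) / np.sqrt(own_gain)
    s = np.full(m, 1.0)
    for _ in range(n_iter):
        V = C * np.outer(s, s)
        Q = np.zeros_like(F)
        Q[:m, :m] = V
        P = solve_discrete_lyapunov(F, Q)
        stds = np.sqrt(np.diag(P)[:m])
        s = np.maximum(s * target_rms / stds, s_min)
    V = C * np.outer(s, s)
    # strongly driven sinks can exceed the target despite the fixed
    # point (their own drive is already at the floor); a uniform rescale
    # caps the loudest channel at twice the target so no clean signal
    # approaches the amplitude-artifact thresholds
    Q = np.zeros_like(F)
    Q[:m, :m] = V
    stds = np.sqrt(np.diag(solve_discrete_lyapunov(F, Q))[:m])
    if stds.max() > 2 * target_rms:
        V *= (2 * target_rms / stds.max()) ** 2
    return V


#: Directed couplings of the reference cohort: weak lagged influences
#: between three channel pairs, leaving directed null pairs to test
#: specificity.
REFERENCE_EDGES = [(0, 1, 1, 0.15), (2, 3, 2, 0.15), (4, 5, 1, 0.12)]


def reference_template(m: int = 6, mixing_leakage: float = 0.25) -> MVARTemplate:
    """The package's reference ground truth: a 6-channel resting cohort.

    Band-tuned channels (alpha/theta/beta/alpha/delta/gamma mix), three
    weak directed couplings, and neighbour volume-conduction mixing.
    Used as the default study condition for reliability experiments.
    """
    edges = [e for e in REFERENCE_EDGES if e[0] < m and e[1] < m]
    mixing = neighbor_mixing(m, mixing_leakage) if mixing_leakage > 0 else None
    return make_template(m, coupling_edges=edges, mixing=mixing)


def neighbor_mixing(m: int, leakage: float = 0.25, decay: float = 0.5) -> np.ndarray:
    """Symmetric, diagonally dominant volume-conduction surrogate.

    Each channel leaks a fraction ``leakage`` of its amplitude into its
    neighbours with exponential fall-off ``decay**distance``.  Because
    the mixing is instantaneous and invertible, the observed signal
    x = M z of a VAR process z is itself an exact VAR process (A_k ->
    M A_k M^-1, V -> M V M^T); it gives every channel pair nonzero,
    heterogeneous zero-lag coherence, as volume conduction does in
    scalp EEG.
    """
    idx = np.arange(m)
    dist = np.abs(np.subtract.outer(idx, idx)).astype(float)
    K = decay ** (dist - 1)
    np.fill_diagonal(K, 0.0)
    rowsum = K.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    return np.eye(m) + leakage * K / rowsum


def simulate_var(
    A: np.ndarray,
    V: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
    burn_in: int = 500,
    mixing: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate a stationary VAR path; returns channels x samples (µV)."""
    p, m, _ = A.shape
    L = np.linalg.cholesky(V)
    total = n_samples + burn_in + p
    e = rng.standard_normal((total, m)) @ L.T
    x = np.zeros((total, m))
    for t in range(p, total):
        acc = e[t].copy()
        for k in range(p):
            acc += A[k] @ x[t - 1 - k]
        x[t] = acc
    out = x[burn_in + p :].T
    if mixing is not None:
        out = mixing @ out
    return np.ascontiguousarray(out)


def perturb_coefficients(
    A: np.ndarray,
    scale: float,
    rng: np.random.Generator,
    max_retries: int = 5,
) -> np.ndarray:
    """Base stack + i.i.d. Gaussian(0, scale²) on every coefficient, restabilized.

    Restabilization shrinks only the *perturbation* (not the whole
    stack), so the base model's resonance structure is preserved; a draw
    that cannot be tamed is resampled with a warning, up to
    ``max_retries`` times.
    """
    if scale == 0:
        return np.array(A, dtype=float)
    A = np.asarray(A, dtype=float)
    for attempt in range(max_retries + 1):
        E = scale * rng.standard_normal(A.shape)
        gamma = 1.0
        for _ in range(_MAX_SHRINK_ITER):
            candidate = A + gamma * E
            if companion_spectral_radius(candidate) < _STABILITY_RADIUS:
                return candidate
            gamma *= 0.7  # shrink the perturbation, converging to the stable base
        if attempt == max_retries:
            raise StabilizationError(
                "coefficient perturbation could not be stabilized"
            )
        warnings.warn(
            "coefficient perturbation destabilized the model; resampling",
            stacklevel=2,
        )
    raise AssertionError("unreachable")


def sample_subject_sessions(
    template: MVARTemplate,
    subject_sd: float,
    eta: float,
    n_samples: int,
    seed: int | np.random.SeedSequence,
    channel_labels: Sequence[str] | None = None,
    burn_in: int = 500,
    noise_seeds: tuple[int, int] | None = None,
) -> tuple[Recording, Recording]:
    """Draw one subject's two sessions from a group template.

    The subject is a Gaussian-jittered copy of the template: for
    structural templates (built by :func:`make_template`) the jitter of
    scale ``subject_sd`` acts on band centers, pole radii and coupling
    strengths; for bare coefficient templates it acts entrywise on the
    stack, with restabilization.  Session 1 uses the subject's
    parameters; session 2 re-jitters them with scale ``eta *
    subject_sd``.  ``eta = 0`` therefore makes the two sessions share
    identical ground-truth coefficients (their innovation realizations
    still differ unless ``noise_seeds`` forces both sessions onto the
    same innovation stream).
    """
    if not 0 <= eta <= 1:
        raise ValueError("eta must be in [0, 1]")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    s_subj, s_sess2, s_noise1, s_noise2 = ss.spawn(4)
    if noise_seeds is not None:
        s_noise1, s_noise2 = noise_seeds
    if template.band_centers is not None:
        # structural route: jitter resonance centers/sharpness and couplings
        centers = np.asarray(template.band_centers, dtype=float)
        radii = np.full(centers.size, template.pole_radius, dtype=float)
        edges = list(template.coupling_edges or [])
        rng_subj = np.random.default_rng(s_subj)
        if subject_sd > 0:
            centers, radii, edges = _jitter_params(
                centers, radii, edges, subject_sd, rng_subj, template.fs
            )
        A_subj = _coefficients_from_structure(
            centers, radii, edges, template.fs, template.p_sim,
            template.peak_correction,
        )
        if eta > 0 and subject_sd > 0:
            c2, r2, e2 = _jitter_params(
                centers, radii, edges, eta * subject_sd,
                np.random.default_rng(s_sess2), template.fs,
            )
            A_sess2 = _coefficients_from_structure(
                c2, r2, e2, template.fs, template.p_sim, template.peak_correction
            )
        else:
            A_sess2 = A_subj
    else:
        # bare-coefficient template: entrywise Gaussian perturbation with
        # perturbation-only shrinkage
        A_subj = perturb_coefficients(
            template.A, subject_sd, np.random.default_rng(s_subj)
        )
        if eta > 0 and subject_sd > 0:
            A_sess2 = perturb_coefficients(
                A_subj, eta * subject_sd, np.random.default_rng(s_sess2)
            )
        else:
            A_sess2 = A_subj
    if channel_labels is None:
        channel_labels = [f"ch{i}" for i in range(template.m)]
    if template.band_centers is not None:
        # amplitudes are homeostatically regulated per recording: the
        # innovations of each session are recalibrated to the session's
        # own coefficients, so jitter changes the interaction structure,
        # not the overall signal scale
        V_subj = _calibrated_innovations(
            A_subj, template.innovation_correlation, template.target_rms
        )
        V_sess2 = (
            V_subj
            if A_sess2 is A_subj
            else _calibrated_innovations(
                A_sess2, template.innovation_correlation, template.target_rms
            )
        )
    else:
        V_subj = V_sess2 = template.V
    recs = []
    for A, V, s_noise in ((A_subj, V_subj, s_noise1), (A_sess2, V_sess2, s_noise2)):
        data = simulate_var(
            A,
            V,
            n_samples,
            np.random.default_rng(s_noise),
            burn_in=burn_in,
            mixing=template.mixing,
        )
        recs.append(
            Recording(data=data, fs=template.fs, channel_labels=list(channel_labels))
        )
    return recs[0], recs[1]


# ---------------------------------------------------------------------------
# artifact injection
# ---------------------------------------------------------------------------

@dataclass
class ArtifactSpec:
    """One injected artifact.

    kind
        ``step`` (DC jump of ``magnitude`` µV from ``onset`` on),
        ``slow_wave`` (half-sine bump, amplitude ``magnitude`` µV over
        ``duration`` s) or ``flatline`` (constant value for ``duration``
        s).
    """

    kind: str
    onset: int
    magnitude: float = 0.0
    duration: float = 0.0
    channel: int = 0


# thresholds/margins mirrored from the preprocessing rules so ground
# truth and detector stay in step (see preprocess.ArtifactRules)
_STEP_THRESH = 50.0
_DIFF_MAX = 200.0
_DIFF_MIN = 0.5
_STEP_MARGIN_S = 0.1
_DIFF_MARGIN_S = 0.1
_FLAT_MARGIN_S = 0.5
_DIFF_WIN_S = 0.2
_FLAT_WIN_S = 0.1


def _waveform(spec: ArtifactSpec, fs: float) -> np.ndarray:
    if spec.kind == "step":
        return np.array([])  # handled additively from onset onwards
    n = int(round(spec.duration * fs))
    if n < 1:
        raise ValueError(f"{spec.kind} duration too short at fs={fs}")
    if spec.kind == "slow_wave":
        return spec.magnitude * np.sin(np.pi * np.arange(n) / (n - 1 if n > 1 else 1))
    if spec.kind == "flatline":
        return np.zeros(n)
    raise ValueError(f"unknown artifact kind {spec.kind!r}")


def _ground_truth_window(spec: ArtifactSpec, fs: float, n: int) -> tuple[int, int] | None:
    """Exact sample window a correct rule-based detector must flag, or None."""
    if spec.kind == "step":
        if abs(spec.magnitude) <= _STEP_THRESH:
            return None
        mg = int(round(_STEP_MARGIN_S * fs))
        return (max(0, spec.onset - mg), min(n - 1, spec.onset + mg))
    if spec.kind == "flatline":
        wlen = int(round(_FLAT_WIN_S * fs))
        dur = int(round(spec.duration * fs))
        if dur < wlen:
            return None  # too short to contain a fully flat 100 ms window
        mg = int(round(_FLAT_MARGIN_S * fs))
        return (max(0, spec.onset - mg), min(n - 1, spec.onset + dur - 1 + mg))
    if spec.kind == "slow_wave":
        # evaluate the max-diff rule on the artifact waveform itself
        wave = _waveform(spec, fs)
        wlen = int(round(_DIFF_WIN_S * fs))
        mg = int(round(_DIFF_MARGIN_S * fs))
        lo = hi = None
        for start in range(-wlen + 1, len(wave)):
            seg = wave[max(0, start) : start + wlen]
            if seg.size and np.ptp(seg) > _DIFF_MAX:
                a = spec.onset + start - mg
                b = spec.onset + start + wlen - 1 + mg
                lo = a if lo is None else min(lo, a)
                hi = b if hi is None else max(hi, b)
        if lo is None:
            return None
        return (max(0, lo), min(n - 1, hi))
    raise ValueError(f"unknown artifact kind {spec.kind!r}")


def inject_artifacts(
    rec: Recording, plan: Sequence[ArtifactSpec]
) -> tuple[Recording, list[tuple[int, int]]]:
    """Add artifacts to a copy of ``rec``; return it plus ground-truth windows.

    Ground-truth windows are the exact closed sample intervals (inclusive)
    that a correct implementation of the amplitude rules must flag for
    each injection; sub-threshold injections contribute no window.
    Overlapping injections (including their margins) raise, so the ground
    truth stays unambiguous.
    """
    out = rec.copy()
    n = out.n_samples
    fs = out.fs
    spans: list[tuple[int, int]] = []
    windows: list[tuple[int, int]] = []
    for spec in plan:
        if not 0 <= spec.onset < n:
            raise ValueError(f"onset {spec.onset} outside recording of {n} samples")
        if spec.kind == "step":
            out.data[spec.channel, spec.onset :] += spec.magnitude
            extent = (spec.onset - int(_STEP_MARGIN_S * fs), spec.onset + int(_STEP_MARGIN_S * fs))
        else:
            wave = _waveform(spec, fs)
            stop = spec.onset + len(wave)
            if stop > n:
                raise ValueError("artifact extends past end of recording")
            if spec.kind == "flatline":
                out.data[spec.channel, spec.onset : stop] = out.data[spec.channel, spec.onset]
            else:
                out.data[spec.channel, spec.onset : stop] += wave
            mg = int(_FLAT_MARGIN_S * fs) if spec.kind == "flatline" else int(_DIFF_MARGIN_S * fs)
            extent = (spec.onset - mg, stop - 1 + mg)
        for a, b in spans:
            if extent[0] <= b and a <= extent[1]:
                raise ValueError("overlapping artifact injections are not allowed")
        spans.append(extent)
        gt = _ground_truth_window(spec, fs, n)
        if gt is not None:
            windows.append(gt)
    return out, windows


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    """One group of a synthetic cohort."""

    label: str
    n_subjects: int
    subject_sd: float = 0.2  # relative scale of structural jitter
    session_jitter: float = 0.2  # eta in [0, 1]
    artifact_plan: list[ArtifactSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0 <= self.session_jitter <= 1:
            raise ValueError("session_jitter must be in [0, 1]")


@dataclass
class CohortSpec:
    """Full recipe for a reproducible two-session cohort."""

    groups: list[GroupSpec]
    n_samples: int = 60000  # 2 min at 500 Hz, a typical resting-recording length
    fs: float = 500.0
    seed: int = 0
    m: int = 6
    coupling_edges: list[tuple[int, int, int, float]] = field(default_factory=list)
    band_centers: list[float] | None = None
    pole_radius: float = 0.9
    p_sim: int = 6
    mixing: np.ndarray | None = None
    mixing_leakage: float = 0.0  # builds neighbor_mixing(m) when > 0


@dataclass
class SubjectSessions:
    subject_id: str
    group: str
    session1: Recording
    session2: Recording


def generate_cohort(spec: CohortSpec) -> list[SubjectSessions]:
    """Materialize a cohort in memory; pure function of ``spec``."""
    mixing = spec.mixing
    if mixing is None and spec.mixing_leakage > 0:
        mixing = neighbor_mixing(spec.m, spec.mixing_leakage)
    template = make_template(
        spec.m,
        coupling_edges=spec.coupling_edges,
        band_centers=spec.band_centers,
        fs=spec.fs,
        pole_radius=spec.pole_radius,
        p_sim=spec.p_sim,
        mixing=mixing,
    )
    subjects: list[SubjectSessions] = []
    for gi, group in enumerate(spec.groups):
        g_ss = np.random.SeedSequence((spec.seed, gi))
        subject_seeds = g_ss.spawn(group.n_subjects)
        for si, sseed in enumerate(subject_seeds):
            rec1, rec2 = sample_subject_sessions(
                template,
                subject_sd=group.subject_sd,
                eta=group.session_jitter,
                n_samples=spec.n_samples,
                seed=sseed,
            )
            if group.artifact_plan:
                rec1, _ = inject_artifacts(rec1, group.artifact_plan)
                rec2, _ = inject_artifacts(rec2, group.artifact_plan)
            subjects.append(
                SubjectSessions(
                    subject_id=f"{group.label}_{si:03d}",
                    group=group.label,
                    session1=rec1,
                    session2=rec2,
                )
            )
    return subjects


def cohort_spec_from_dict(cfg: dict) -> CohortSpec:
    """Build a CohortSpec from a parsed YAML/JSON mapping."""
    groups = [
        GroupSpec(
            label=g["label"],
            n_subjects=int(g["n_subjects"]),
            subject_sd=float(g.get("subject_sd", 0.05)),
            session_jitter=float(g.get("session_jitter", 0.2)),
            artifact_plan=[
                ArtifactSpec(**a) for a in g.get("artifact_plan", [])
            ],
        )
        for g in cfg["groups"]
    ]
    return CohortSpec(
        groups=groups,
        n_samples=int(cfg.get("n_samples", 60000)),
        fs=float(cfg.get("fs", 500.0)),
        seed=int(cfg.get("seed", 0)),
        m=int(cfg.get("m", 6)),
        coupling_edges=[tuple(e) for e in cfg.get("coupling_edges", [])],
        band_centers=cfg.get("band_centers"),
        pole_radius=float(cfg.get("pole_radius", 0.9)),
        p_sim=int(cfg.get("p_sim", 6)),
        mixing_leakage=float(cfg.get("mixing_leakage", 0.0)),
    )
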