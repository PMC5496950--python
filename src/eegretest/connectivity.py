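"""Frequency-domain interaction measures derived from a fitted MVAR model.

Given x(t) = sum_k A_k x(t-k) + e(t) with innovation covariance V, the
frequency transform on a grid f (Hz, below Nyquist) is

    Abar(f) = I - sum_{k=1..p} A_k exp(-i 2 pi f k / fs)
    H(f)    = Abar(f)^{-1}                      (transfer function)
    S(f)    = H(f) V H(f)^H / fs                (two-sided spectral density)

From these the 14 measures of the package are computed.  Orientation
convention for directed measures: ``value[i, j]`` quantifies the
influence of channel j on channel i (j -> i).

========  ==========================================================
S         spectral density magnitude |S_ij(f)| (auto + cross)
DC        direct causality, sum_k A_k[i,j]^2 (frequency-independent)
h         transfer function magnitude |H_ij(f)|
Af        transfer-polynomial magnitude |Abar_ij(f)|
COH       real part of complex coherency S_ij / sqrt(S_ii S_jj)
iCOH      imaginary part of the coherency
pCOH      partial coherence, Re(-G_ij / sqrt(G_ii G_jj)), G = S^{-1}
PDC       |Abar_ij| / sqrt(sum_k |Abar_kj|^2)      (column-normalized)
PDCF      |Abar_ij| / sqrt(abar_j^H V^{-1} abar_j)
GPDC      (|Abar_ij|/sqrt(V_ii)) / sqrt(sum_k |Abar_kj|^2 / V_kk)
DTF       |H_ij| / sqrt(sum_k |H_ik|^2)            (row-normalized)
ffDTF     |H_ij(f)| / sqrt(sum_{f'} sum_k |H_ik(f')|^2)
dDTF      ffDTF_ij(f) * |pCOH_ij(f)|
GGC       bivariate Geweke-Granger causality (pairwise refits)
========  ==========================================================

Band averaging uses the classical ranges delta 2-4, theta 5-7, alpha
8-13, beta 14-30, gamma 31-80 and high gamma 81-125 Hz (inclusive,
arithmetic mean over the integer frequencies inside each range).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mvar import MVARModel, fit_mvar

#: Analysis frequency grid, 1 Hz steps from 2 to 125 Hz.
DEFAULT_FREQS = np.arange(2.0, 126.0)

#: (name, low, high) in Hz, bounds inclusive on the integer grid.
BANDS: list[tuple[str, float, float]] = [
    ("delta", 2, 4),
    ("theta", 5, 7),
    ("alpha", 8, 13),
    ("beta", 14, 30),
    ("gamma", 31, 80),
    ("high_gamma", 81, 125),
]

BAND_NAMES = [b[0] for b in BANDS]

#: The 14 measures, in the canonical reporting order.
MEASURES = [
    "S", "DC", "h", "Af", "COH", "iCOH", "pCOH",
    "PDC", "PDCF", "GPDC", "DTF", "dDTF", "ffDTF", "GGC",
]


@dataclass
class SpectralDecomposition:
    """Abar(f), H(f) and S(f) on the frequency grid (tensors f x m x m)."""

    freqs: np.ndarray
    Abar: np.ndarray
    H: np.ndarray
    S: np.ndarray
    fs: float
    V: np.ndarray

    @property
    def m(self) -> int:
        return self.Abar.shape[1]


def spectral_decompose(
    model: MVARModel, freqs: np.ndarray | None = None
) -> SpectralDecomposition:
    """Transform a fitted model to the frequency domain.

    Raises a LinAlgError naming the frequency if Abar(f) is singular
    (a unit root on the grid).
    """
    if freqs is None:
        freqs = DEFAULT_FREQS
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= model.fs / 2):
        raise ValueError("frequency grid must stay below the Nyquist frequency")
    p, m = model.p, model.m
    k = np.arange(1, p + 1)
    # phases: (f, k)
    phase = np.exp(-2j * np.pi * np.outer(freqs, k) / model.fs)
    Abar = np.eye(m) - np.einsum("fk,kij->fij", phase, model.A)
    try:
        H = np.linalg.inv(Abar)
    except np.linalg.LinAlgError:
        # identify the offending frequency for the error message
        for fi, f in enumerate(freqs):
            if abs(np.linalg.det(Abar[fi])) < 1e-300:
                raise np.linalg.LinAlgError(
                    f"Abar(f) is singular at f = {f:g} Hz (unit-root model)"
                ) from None
        raise
    S = H @ model.V @ np.conjugate(H).transpose(0, 2, 1) / model.fs
    return SpectralDecomposition(
        freqs=freqs, Abar=Abar, H=H, S=S, fs=model.fs, V=model.V.copy()
    )


# ---------------------------------------------------------------------------
# measure families
# ---------------------------------------------------------------------------

def coherence_family(dec: SpectralDecomposition) -> dict[str, np.ndarray]:
    """Spectrum magnitude, real coherence (COH) and imaginary coherence (iCOH)."""
    diag = np.real(np.diagonal(dec.S, axis1=1, axis2=2))  # (f, m)
    if np.any(diag <= 0):
        raise ValueError("zero or negative diagonal power in S(f)")
    denom = np.sqrt(diag[:, :, None] * diag[:, None, :])
    C = dec.S / denom
    return {"S": np.abs(dec.S), "COH": np.real(C), "iCOH": np.imag(C)}


def partial_family(dec: SpectralDecomposition) -> dict[str, np.ndarray]:
    """pCOH, PDC, PDCF, GPDC plus the raw |Abar| (Af) and |H| (h) tensors."""
    try:
        G = np.linalg.inv(dec.S)
    except np.linalg.LinAlgError:
        for fi, f in enumerate(dec.freqs):
            if abs(np.linalg.det(dec.S[fi])) < 1e-300:
                raise np.linalg.LinAlgError(
                    f"S(f) is singular at f = {f:g} Hz"
                ) from None
        raise
    gdiag = np.real(np.diagonal(G, axis1=1, axis2=2))
    pcoh = np.real(-G / np.sqrt(gdiag[:, :, None] * gdiag[:, None, :]))
    idx = np.arange(dec.m)
    pcoh[:, idx, idx] = 1.0

    absA = np.abs(dec.Abar)
    colnorm = np.sqrt((absA**2).sum(axis=1, keepdims=True))  # sum over rows i
    pdc = absA / colnorm

    Vinv = np.linalg.inv(dec.V)
    # abar_j^H Vinv abar_j for each column j at each f
    quad = np.real(
        np.einsum("fij,ik,fkj->fj", np.conjugate(dec.Abar), Vinv, dec.Abar)
    )
    pdcf = absA / np.sqrt(quad[:, None, :])

    vdiag = np.diag(dec.V)
    gcol = np.sqrt((absA**2 / vdiag[None, :, None]).sum(axis=1, keepdims=True))
    gpdc = (absA / np.sqrt(vdiag)[None, :, None]) / gcol

    return {
        "pCOH": pcoh, "PDC": pdc, "PDCF": pdcf, "GPDC": gpdc,
        "Af": absA, "h": np.abs(dec.H),
    }


def dtf_family(
    dec: SpectralDecomposition,
    pcoh: np.ndarray | None = None,
    pcoh_magnitude: bool = True,
) -> dict[str, np.ndarray]:
    """DTF, ffDTF and (when pCOH is supplied or computable) dDTF.

    ``pcoh_magnitude`` multiplies ffDTF by |pCOH| (keeps dDTF in [0, 1]);
    set False to keep the signed partial coherence factor.
    """
    absH = np.abs(dec.H)
    rownorm = np.sqrt((absH**2).sum(axis=2, keepdims=True))
    if np.any(rownorm == 0):
        raise ValueError("zero row of H(f)")
    dtf = absH / rownorm
    ffnorm = np.sqrt((absH**2).sum(axis=(0, 2)))  # per row i over all f
    ffdtf = absH / ffnorm[None, :, None]
    out = {"DTF": dtf, "ffDTF": ffdtf}
    if pcoh is None:
        pcoh = partial_family(dec)["pCOH"]
    out["dDTF"] = ffdtf * (np.abs(pcoh) if pcoh_magnitude else pcoh)
    return out


def direct_causality(model: MVARModel) -> np.ndarray:
    """DC_ij = sum_k A_k[i,j]^2 — frequency-independent lagged coupling."""
    return (model.A**2).sum(axis=0)


def granger_family(
    data: np.ndarray,
    order: int,
    fs: float,
    freqs: np.ndarray | None = None,
    method: str = "nuttall_strand_unbiased",
    eps: float = 1e-12,
    segment_length: int | None = None,
) -> np.ndarray:
    """Bivariate Geweke-Granger causality for every ordered channel pair.

    For each pair (i, j) a bivariate MVAR of the same order is fitted to
    channels (i, j) of ``data``; with its transfer function H and
    innovation covariance V,

        GGC[i, j](f) = ln( S_ii(f) / (S_ii(f) - (V_jj - V_ij^2/V_ii) |H_ij(f)|^2) )

    quantifies the flow j -> i.  Denominators that numerical noise pushes
    to or below zero are clipped at ``eps`` times the numerator, with a
    warning.  The diagonal is zero.
    """
    if freqs is None:
        freqs = DEFAULT_FREQS
    freqs = np.asarray(freqs, dtype=float)
    m = data.shape[0]
    out = np.zeros((len(freqs), m, m))
    clipped = 0
    for i in range(m):
        for j in range(i + 1, m):
            model = fit_mvar(
                data[[i, j]], order, fs=fs, method=method,
                segment_length=segment_length,
            )
            dec = spectral_decompose(model, freqs)
            Sloc = dec.S
            H = dec.H
            V = model.V
            for (a, b) in ((0, 1), (1, 0)):
                # flow of local channel b onto local channel a
                saa = np.real(Sloc[:, a, a])
                corr = (V[b, b] - V[a, b] ** 2 / V[a, a]) * np.abs(H[:, a, b]) ** 2 / fs
                denom = saa - corr
                bad = denom <= eps * saa
                if np.any(bad):
                    clipped += int(bad.sum())
                    denom = np.where(bad, eps * saa, denom)
                val = np.log(saa / denom)
                gi, gj = (i, j) if a == 0 else (j, i)
                out[:, gi, gj] = val
    if clipped:
        warnings.warn(
            f"GGC: clipped {clipped} non-positive denominator(s) at eps", stacklevel=2
        )
    return out


# ---------------------------------------------------------------------------
# orchestration and band averaging
# ---------------------------------------------------------------------------

def compute_all_measures(
    data: np.ndarray,
    order: int,
    fs: float,
    freqs: np.ndarray | None = None,
    method: str = "nuttall_strand_unbiased",
    measures: list[str] | None = None,
    segment_length: int | None = None,
) -> dict[str, np.ndarray]:
    """Fit the full model and compute the requested measures.

    Returns a dict of tensors, shape (f, m, m) for spectral measures and
    (m, m) for DC.  ``measures=None`` computes all 14.
    """
    if measures is None:
        measures = list(MEASURES)
    unknown = set(measures) - set(MEASURES)
    if unknown:
        raise ValueError(f"unknown measure(s) {sorted(unknown)}; valid: {MEASURES}")
    model = fit_mvar(
        data, order, fs=fs, method=method, segment_length=segment_length
    )
    dec = spectral_decompose(model, freqs)
    out: dict[str, np.ndarray] = {}
    coh_keys = {"S", "COH", "iCOH"}
    if coh_keys & set(measures):
        fam = coherence_family(dec)
        out.update({k: v for k, v in fam.items() if k in measures})
    partial_keys = {"pCOH", "PDC", "PDCF", "GPDC", "Af", "h"}
    need_pcoh = bool({"pCOH", "dDTF"} & set(measures))
    pcoh = None
    if partial_keys & set(measures) or need_pcoh:
        fam = partial_family(dec)
        pcoh = fam["pCOH"]
        out.update({k: v for k, v in fam.items() if k in measures})
    dtf_keys = {"DTF", "ffDTF", "dDTF"}
    if dtf_keys & set(measures):
        fam = dtf_family(dec, pcoh=pcoh)
        out.update({k: v for k, v in fam.items() if k in measures})
    if "DC" in measures:
        out["DC"] = direct_causality(model)
    if "GGC" in measures:
        out["GGC"] = granger_family(
            data, order, fs, freqs=dec.freqs, method=method,
            segment_length=segment_length,
        )
    return out


def band_average(
    values: np.ndarray,
    freqs: np.ndarray | None = None,
    bands: list[tuple[str, float, float]] | None = None,
) -> np.ndarray:
    """Arithmetic mean over the grid frequencies inside each band.

    ``values`` of shape (f, m, m) becomes (n_bands, m, m); a
    frequency-independent (m, m) matrix (direct causality) has no
    frequency axis and passes through unchanged.
    """
    if bands is None:
        bands = BANDS
    if values.ndim == 2:
        return values.copy()
    if freqs is None:
        freqs = DEFAULT_FREQS
    freqs = np.asarray(freqs, dtype=float)
    out = np.empty((len(bands),) + values.shape[1:])
    for bi, (name, lo, hi) in enumerate(bands):
        sel = (freqs >= lo) & (freqs <= hi)
        if not sel.any():
            raise ValueError(f"band {name} ({lo}-{hi} Hz) is outside the grid")
        out[bi] = values[sel].mean(axis=0)
    return out


def band_average_all(
    tensors: dict[str, np.ndarray],
    freqs: np.ndarray | None = None,
    bands: list[tuple[str, float, float]] | None = None,
) -> dict[str, np.ndarray]:
    """Band-average every measure tensor in a dict (see :func:`band_average`)."""
    return {k: band_average(v, freqs, bands) for k, v in tensors.items()}
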