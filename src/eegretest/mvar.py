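"""Multivariate autoregressive (MVAR) model fitting.

The MVAR model of an m-channel signal x(t) is

    x(t) = sum_{k=1..p} A_k x(t-k) + e(t),      e(t) ~ (0, V)

with coefficient matrices A_k (m x m) and innovation covariance V.  All
frequency-domain interaction measures downstream are functions of (A, V).

Two estimators are provided:

``nuttall_strand_unbiased``
    A multichannel lattice (Burg-type) recursion estimating the partial
    correlations between forward and backward prediction errors, with
    unbiased 1/(N-k) covariance normalization at every lag.  This is the
    classical "partial correlation" estimator of the multichannel AR
    literature and the package default.
``least_squares``
    Ordinary multivariate regression of x(t) on its p lags; kept as an
    independent cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.linalg import solve


@dataclass
class MVARModel:
    """Fitted MVAR model: stack ``A`` of shape (p, m, m) plus covariance ``V``."""

    A: np.ndarray
    V: np.ndarray
    fs: float
    n_effective: int = 0
    method: str = ""

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.A.ndim != 3 or self.A.shape[1] != self.A.shape[2]:
            raise ValueError("A must have shape (p, m, m)")
        if self.V.shape != self.A.shape[1:]:
            raise ValueError("V shape must match channel count of A")

    @property
    def p(self) -> int:
        return self.A.shape[0]

    @property
    def m(self) -> int:
        return self.A.shape[1]

    def spectral_radius(self) -> float:
        """Companion-matrix spectral radius; < 1 means the model is stable."""
        return companion_spectral_radius(self.A)

    @property
    def is_stable(self) -> bool:
        return self.spectral_radius() < 1.0


def companion_matrix(A: np.ndarray) -> np.ndarray:
    """Companion form of a coefficient stack (p, m, m) -> (pm, pm)."""
    A = np.asarray(A, dtype=float)
    p, m, _ = A.shape
    comp = np.zeros((p * m, p * m))
    comp[:m] = A.transpose(1, 0, 2).reshape(m, p * m)
    if p > 1:
        comp[m:, :-m] = np.eye((p - 1) * m)
    return comp


def companion_spectral_radius(A: np.ndarray) -> float:
    if A.size == 0 or not np.any(A):
        return 0.0
    return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(A)))))


def _check_data(data: np.ndarray, order: int) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be channels x samples")
    m, n = data.shape
    if order <= 0:
        raise ValueError(f"model order must be positive, got {order}")
    if n <= order:
        raise ValueError(f"need more than order={order} samples, got {n}")
    spans = np.ptp(data, axis=1)
    dead = np.flatnonzero(spans == 0)
    if dead.size:
        raise np.linalg.LinAlgError(
            f"channel(s) {dead.tolist()} are constant; covariance is singular"
        )
    if n < 10 * order:
        warnings.warn(
            f"only {n} samples for order {order}: parameters are weakly "
            "identified (fewer than 10 samples per lag)",
            stacklevel=3,
        )
    return data


def _fit_lattice(
    data: np.ndarray, order: int, boundaries: list[int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Multichannel partial-correlation lattice with unbiased normalization.

    Forward/backward prediction errors are propagated through a Levinson
    recursion; at each stage the reflection matrices are the cross-
    covariance of the two error processes normalized by the running error
    covariances, each covariance divided by its actual sample count N-k
    (the "unbiased" choice).

    With ``boundaries`` (segment start offsets), lag products that would
    straddle a segment boundary are excluded from every covariance, so
    concatenation discontinuities do not leak into the estimates.
    """
    m, n = data.shape
    X = np.ascontiguousarray(data.T)  # N x m
    if boundaries is None:
        chunks = [X]
    else:
        edges = list(boundaries) + [n]
        chunks = [X[a:b].copy() for a, b in zip(edges[:-1], edges[1:]) if b > a]
    F = [c.copy() for c in chunks]
    B = [c.copy() for c in chunks]
    C = sum(c.T @ c for c in chunks) / n
    pef = C.copy()
    peb = C.copy()
    ARF = np.zeros((order + 1, m, m))
    ARB = np.zeros((order + 1, m, m))
    for K in range(1, order + 1):
        count = sum(max(c.shape[0] - K, 0) for c in chunks)
        if count <= 0:
            raise ValueError(
                f"order {order} leaves no lag-{K} products within the segments"
            )
        D = np.zeros((m, m))
        for f, b in zip(F, B):
            nk = f.shape[0] - K
            if nk > 0:
                D += f[K:].T @ b[:nk]
        D /= count
        # KF = D @ inv(peb), KB = D.T @ inv(pef) without explicit inverses
        KF = solve(peb.T, D.T).T
        KB = solve(pef.T, D).T
        pef = np.zeros((m, m))
        peb = np.zeros((m, m))
        for si, (f, b) in enumerate(zip(F, B)):
            nk = f.shape[0] - K
            if nk <= 0:
                continue
            Fv = f[K:]
            Bv = b[:nk]
            Fnew = Fv - Bv @ KF.T
            Bnew = Bv - Fv @ KB.T
            F[si][K:] = Fnew
            B[si][:nk] = Bnew
            pef += Fnew.T @ Fnew
            peb += Bnew.T @ Bnew
        pef /= count
        peb /= count
        for L in range(1, K):
            tmp = ARF[L] - KF @ ARB[K - L]
            ARB[K - L] = ARB[K - L] - KB @ ARF[L]
            ARF[L] = tmp
        ARF[K] = KF
        ARB[K] = KB
    return ARF[1:], pef


def _fit_least_squares(
    data: np.ndarray, order: int, boundaries: list[int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    m, n = data.shape
    X = data.T  # N x m
    Y = X[order:]
    # regressor block: [x(t-1), ..., x(t-p)]
    Z = np.hstack([X[order - k : n - k] for k in range(1, order + 1)])
    if boundaries is not None:
        # drop equations whose lag window straddles a segment boundary
        t = np.arange(order, n)
        keep = np.ones(t.size, dtype=bool)
        for b in boundaries:
            keep &= (t < b) | (t - order >= b)
        Y, Z = Y[keep], Z[keep]
        if Y.shape[0] <= order * m:
            raise ValueError("too few within-segment equations for this order")
    coef, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    resid = Y - Z @ coef
    dof = max(Y.shape[0] - order * m, 1)
    V = resid.T @ resid / dof
    A = coef.T.reshape(m, order, m).transpose(1, 0, 2)
    return A, V


def fit_mvar(
    data: np.ndarray,
    order: int,
    fs: float = 1.0,
    method: str = "nuttall_strand_unbiased",
    segment_length: int | None = None,
) -> MVARModel:
    """Fit an MVAR model of the given order to a channels x samples matrix.

    Parameters
    ----------
    data
        Real matrix, channels x samples (the concatenated clean segments).
    order
        Model order p (number of lag matrices).
    fs
        Sampling rate in Hz, carried into the model for the frequency
        transform.
    method
        ``nuttall_strand_unbiased`` (default) or ``least_squares``.
    segment_length
        If given, the data are treated as a concatenation of segments of
        this many samples and lag products across segment boundaries are
        excluded (by default boundaries are ignored, i.e. the
        concatenated signal is fitted as if continuous).
    """
    data = _check_data(data, order)
    boundaries = None
    if segment_length is not None:
        if segment_length <= order:
            raise ValueError("segment_length must exceed the model order")
        boundaries = list(range(segment_length, data.shape[1], segment_length))
    if method == "nuttall_strand_unbiased":
        A, V = _fit_lattice(data, order, boundaries)
    elif method == "least_squares":
        A, V = _fit_least_squares(data, order, boundaries)
    else:
        raise ValueError(f"unknown method {method!r}")
    V = 0.5 * (V + V.T)  # symmetrize against round-off
    return MVARModel(
        A=A, V=V, fs=fs, n_effective=data.shape[1], method=method
    )


def save_model(model: MVARModel, path: str | Path) -> None:
    """Serialize a model (header fields + A and V blocks) as NumPy .npz."""
    np.savez(
        Path(path),
        A=model.A,
        V=model.V,
        fs=np.array(model.fs),
        n_effective=np.array(model.n_effective),
        method=np.array(model.method),
    )


def load_model(path: str | Path) -> MVARModel:
    with np.load(Path(path)) as z:
        return MVARModel(
            A=z["A"],
            V=z["V"],
            fs=float(z["fs"]),
            n_effective=int(z["n_effective"]),
            method=str(z["method"]),
        )
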