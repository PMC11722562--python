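"""State-space model core: discretization and scan primitives.

A linear time-invariant state-space model (SSM) maps a scalar input stream
``rho(t)`` to an output stream ``phi(t)`` through a hidden state
``psi(t) in R^{S_state}``::

    psi'(t) = A psi(t) + B rho(t)
    phi(t)  = C psi(t)

For sequence modelling the continuous system is discretized with the
zero-order-hold (ZOH) rule at time-scale ``delta``::

    A_bar = exp(delta A)
    B_bar = (delta A)^{-1} (exp(delta A) - I) (delta B)
    C_bar = C

after which the recurrence ``psi_t = A_bar psi_{t-1} + B_bar rho_t,
phi_t = C_bar psi_t`` can equivalently be computed as a causal convolution
with the structured kernel ``K = (C_bar B_bar, C_bar A_bar B_bar, ...,
C_bar A_bar^{L-1} B_bar)``.

The selective variant (Mamba-style) makes ``delta``, ``B`` and ``C``
functions of the input token, discretizing per time step; it degenerates to
the time-invariant scan when those parameters are constant.

Everything here is plain NumPy and deliberately independent of the neural
network layers in :mod:`multiphys.nn` that reuse the same mathematics; the
two implementations cross-check each other in the test-suite.

Note on symbols: the state width ``S_state`` (size of ``A``) and the token
count ``L_seq`` (length of the scanned sequence) are distinct quantities and
are kept apart throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

__all__ = [
    "SSMParams",
    "DiscreteSSMParams",
    "SSMKernel",
    "SelectiveParams",
    "discretize",
    "scan_recurrent",
    "build_kernel",
    "scan_convolutional",
    "selective_scan",
]

# below this norm of delta*A the explicit inverse in the ZOH formula for
# B_bar is ill-conditioned; switch to the truncated-series integral form
_SERIES_NORM_THRESHOLD = 1e-6


def _as_matrix(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim == 0:
        a = a.reshape(1, 1)
    if a.ndim == 1:
        a = a.reshape(-1, 1)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite entries")
    return a


@dataclass(frozen=True)
class SSMParams:
    """Continuous-time SSM parameters (A, B, C, delta).

    A : (S_state, S_state) state evolution matrix, units 1/time.
    B : (S_state, 1) input projection.
    C : (1, S_state) output projection.
    delta : positive time-scale of the zero-order hold.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    delta: float

    def __post_init__(self):
        A = _as_matrix(self.A, "A")
        B = _as_matrix(self.B, "B")
        C = _as_matrix(self.C, "C").reshape(1, -1)
        if A.shape[0] != A.shape[1]:
            raise ValueError(f"A must be square, got {A.shape}")
        n = A.shape[0]
        if B.shape != (n, 1):
            raise ValueError(f"B must have shape ({n}, 1), got {B.shape}")
        if C.shape != (1, n):
            raise ValueError(f"C must have shape (1, {n}), got {C.shape}")
        if not (np.isfinite(self.delta) and self.delta > 0):
            raise ValueError(f"delta must be a positive real, got {self.delta}")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "C", C)

    @property
    def state_size(self) -> int:
        return self.A.shape[0]


@dataclass(frozen=True)
class DiscreteSSMParams:
    """ZOH-discretized parameters (A_bar, B_bar, C_bar).

    ``method`` records which branch produced B_bar: ``"inverse"`` for the
    closed-form ``(delta A)^{-1}(exp(delta A) - I)(delta B)`` or ``"series"``
    for the truncated-series evaluation of the equivalent integral
    ``(∫_0^delta exp(sA) ds) B`` used when ``delta A`` is near-singular.
    """

    A_bar: np.ndarray
    B_bar: np.ndarray
    C_bar: np.ndarray
    method: str = field(default="inverse", compare=False)

    def __post_init__(self):
        A = _as_matrix(self.A_bar, "A_bar")
        B = _as_matrix(self.B_bar, "B_bar")
        C = _as_matrix(self.C_bar, "C_bar").reshape(1, -1)
        n = A.shape[0]
        if A.shape != (n, n) or B.shape != (n, 1) or C.shape != (1, n):
            raise ValueError(
                f"inconsistent shapes A_bar {A.shape}, B_bar {B.shape}, C_bar {C.shape}"
            )
        object.__setattr__(self, "A_bar", A)
        object.__setattr__(self, "B_bar", B)
        object.__setattr__(self, "C_bar", C)

    @property
    def state_size(self) -> int:
        return self.A_bar.shape[0]


@dataclass(frozen=True)
class SSMKernel:
    """Structured convolution kernel k[t] = C_bar A_bar^t B_bar."""

    k: np.ndarray

    def __post_init__(self):
        k = np.asarray(self.k, dtype=float).reshape(-1)
        if not np.all(np.isfinite(k)):
            raise ValueError("kernel contains non-finite entries")
        object.__setattr__(self, "k", k)

    def __len__(self) -> int:
        return self.k.size


@dataclass(frozen=True)
class SelectiveParams:
    """Per-timestep (input-dependent) SSM parameters with shared A.

    delta_t : (L,) or (L, C) positive time-scales per token (per channel).
    B_t : (L, S_state) input projections per token.
    C_t : (L, S_state) output projections per token.
    A : (S_state, S_state) shared evolution matrix.
    """

    delta_t: np.ndarray
    B_t: np.ndarray
    C_t: np.ndarray
    A: np.ndarray

    def __post_init__(self):
        A = _as_matrix(self.A, "A")
        if A.shape[0] != A.shape[1]:
            raise ValueError(f"A must be square, got {A.shape}")
        d = np.asarray(self.delta_t, dtype=float)
        Bt = np.asarray(self.B_t, dtype=float)
        Ct = np.asarray(self.C_t, dtype=float)
        if not np.all(np.isfinite(d)) or np.any(d <= 0):
            raise ValueError("delta_t must be finite and strictly positive")
        L = d.shape[0]
        n = A.shape[0]
        if Bt.shape != (L, n) or Ct.shape != (L, n):
            raise ValueError(
                f"B_t and C_t must have shape ({L}, {n}); got {Bt.shape}, {Ct.shape}"
            )
        object.__setattr__(self, "delta_t", d)
        object.__setattr__(self, "B_t", Bt)
        object.__setattr__(self, "C_t", Ct)
        object.__setattr__(self, "A", A)


def _zoh_bbar(dA: np.ndarray, dB: np.ndarray, A_bar: np.ndarray):
    """B_bar for ZOH; returns (B_bar, method)."""
    n = dA.shape[0]
    if np.linalg.norm(dA, ord=2) < _SERIES_NORM_THRESHOLD:
        # (delta A)^{-1}(exp(delta A)-I) = I + dA/2 + dA^2/6 + dA^3/24 + ...
        eye = np.eye(n)
        series = eye + dA / 2.0 + dA @ dA / 6.0 + dA @ dA @ dA / 24.0
        return series @ dB, "series"
    B_bar = np.linalg.solve(dA, (A_bar - np.eye(n))) @ dB
    return B_bar, "inverse"


def discretize(params: SSMParams) -> DiscreteSSMParams:
    """Zero-order-hold discretization of continuous SSM parameters.

    ``A_bar = exp(delta A)``; ``B_bar = (delta A)^{-1}(exp(delta A) - I)(delta B)``
    with a truncated-series fallback when ``delta A`` is nearly singular
    (reported in the ``method`` field); ``C_bar = C`` unchanged.
    """
    dA = params.delta * params.A
    A_bar = expm(dA)
    B_bar, method = _zoh_bbar(dA, params.delta * params.B, A_bar)
    return DiscreteSSMParams(A_bar=A_bar, B_bar=B_bar, C_bar=params.C, method=method)


def scan_recurrent(dparams: DiscreteSSMParams, rho) -> np.ndarray:
    """Run the discrete recurrence psi_t = A_bar psi_{t-1} + B_bar rho_t.

    The hidden state starts at zero; returns phi_t = C_bar psi_t for each of
    the L input samples. Raises on the first non-finite state, naming the
    step index.
    """
    rho = np.asarray(rho, dtype=float).reshape(-1)
    if rho.size < 1:
        raise ValueError("input sequence must have length >= 1")
    n = dparams.state_size
    psi = np.zeros(n)
    A, B, C = dparams.A_bar, dparams.B_bar.reshape(n), dparams.C_bar.reshape(n)
    out = np.empty(rho.size)
    for t in range(rho.size):
        psi = A @ psi + B * rho[t]
        if not np.all(np.isfinite(psi)):
            raise FloatingPointError(f"non-finite state at scan step {t}")
        out[t] = C @ psi
    return out


def build_kernel(dparams: DiscreteSSMParams, L: int) -> SSMKernel:
    """Structured kernel k = (C_bar B_bar, C_bar A_bar B_bar, ..., C_bar A_bar^{L-1} B_bar)."""
    if L < 1:
        raise ValueError("kernel length must be >= 1")
    n = dparams.state_size
    v = dparams.B_bar.reshape(n)
    C = dparams.C_bar.reshape(n)
    k = np.empty(L)
    for t in range(L):
        k[t] = C @ v
        if t + 1 < L:
            v = dparams.A_bar @ v
    return SSMKernel(k=k)


def scan_convolutional(dparams: DiscreteSSMParams, rho) -> np.ndarray:
    """Causal convolution phi_t = sum_{s<=t} k[s] rho_{t-s}; equals scan_recurrent."""
    rho = np.asarray(rho, dtype=float).reshape(-1)
    if rho.size < 1:
        raise ValueError("input sequence must have length >= 1")
    k = build_kernel(dparams, rho.size).k
    return np.convolve(rho, k)[: rho.size]


def selective_scan(x, sel: SelectiveParams) -> np.ndarray:
    """Input-dependent (selective) scan applied independently per channel.

    ``x`` is (L,) or (L, C). Each step discretizes the shared ``A`` with that
    token's ``delta_t`` (ZOH) and runs the time-varying recurrence
    ``psi_t = A_bar_t psi_{t-1} + B_bar_t x_t``, ``y_t = C_t psi_t``. With
    constant ``delta_t, B_t, C_t`` this reduces exactly to
    :func:`scan_recurrent` on each channel.
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    L, C = x.shape
    d = sel.delta_t
    if d.ndim == 1:
        d = np.repeat(d[:, None], C, axis=1)
    if d.shape != (L, C):
        raise ValueError(f"delta_t incompatible with input of shape {(L, C)}")
    n = sel.A.shape[0]

    # cache discretizations: delta values repeat across channels when shared
    cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    def disc(dt: float, Bt: np.ndarray):
        key = float(dt)
        if key not in cache:
            dA = dt * sel.A
            A_bar = expm(dA)
            # integral factor (∫_0^dt exp(sA) ds) applied to dt*B below
            if np.linalg.norm(dA, ord=2) < _SERIES_NORM_THRESHOLD:
                eye = np.eye(n)
                fac = eye + dA / 2.0 + dA @ dA / 6.0 + dA @ dA @ dA / 24.0
            else:
                fac = np.linalg.solve(dA, A_bar - np.eye(n))
            cache[key] = (A_bar, fac)
        A_bar, fac = cache[key]
        return A_bar, fac @ (dt * Bt)

    y = np.empty((L, C))
    psi = np.zeros((n, C))
    for t in range(L):
        for c in range(C):
            A_bar, B_bar = disc(d[t, c], sel.B_t[t])
            psi[:, c] = A_bar @ psi[:, c] + B_bar * x[t, c]
        y[t] = sel.C_t[t] @ psi
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite output in selective scan")
    return y[:, 0] if squeeze else y
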