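"""Structured state-space primitives: discretization, scan, gating.

The continuous-time system is ``h'(t) = A h(t) + B x(t)``, ``y(t) = C h(t)``.
For tabular rows the "time" axis is the feature axis: a row of d features is
read as a length-d sequence, so the scan mixes information across columns.
Discretization is zero-order hold: ``A_bar = exp(dt * A)`` and
``B_bar = A^{-1} (exp(dt*A) - I) B``, computed without an explicit inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.special import erf

_EIG_TOL = 1e-8


@dataclass
class SSMParams:
    """Continuous-time SSM matrices for a single input/output channel.

    ``A`` may be a full (d_h, d_h) matrix or a length-d_h vector of diagonal
    entries. Stability requires every eigenvalue of A to have non-positive
    real part; ``delta`` is the positive step size.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    delta: float

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float).ravel()
        self.C = np.asarray(self.C, dtype=float).ravel()
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.A.ndim == 1:
            eigs_real = self.A
        else:
            if self.A.shape[0] != self.A.shape[1]:
                raise ValueError("A must be square")
            eigs_real = np.linalg.eigvals(self.A).real
        if np.any(eigs_real > _EIG_TOL):
            raise ValueError("A must be stable (eigenvalue real parts <= 0)")
        d_h = self.A.shape[0]
        if self.B.shape != (d_h,) or self.C.shape != (d_h,):
            raise ValueError("B and C must have length d_h")

    @property
    def d_state(self) -> int:
        return self.A.shape[0]

    @property
    def is_diagonal(self) -> bool:
        return self.A.ndim == 1


def discretize_diagonal(
    a: np.ndarray, delta: np.ndarray, B: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form ZOH for diagonal A; broadcasts over channel axes.

    ``a_bar = exp(delta*a)``, ``b_bar = expm1(delta*a)/a * B`` with the
    ``a -> 0`` limit ``delta * B`` applied elementwise.
    """
    a = np.asarray(a, dtype=float)
    delta = np.asarray(delta, dtype=float)
    x = delta * a
    a_bar = np.exp(x)
    small = np.abs(a) < 1e-12
    safe_a = np.where(small, 1.0, a)
    f = np.where(small, delta, np.expm1(x) / safe_a)
    return a_bar, f * B


def discretize(ssm: SSMParams) -> tuple[np.ndarray, np.ndarray]:
    """Zero-order-hold discretization of an :class:`SSMParams`.

    Diagonal A uses the elementwise closed form. Full A uses the augmented
    matrix exponential ``expm(dt*[[A, B],[0, 0]])``, whose top blocks are
    exactly (A_bar, B_bar); this stays finite for singular A, where the
    textbook ``A^{-1}(exp(dt*A)-I)B`` formula breaks down.
    """
    if ssm.is_diagonal:
        a_bar, b_bar = discretize_diagonal(ssm.A, ssm.delta, ssm.B)
        return np.diag(a_bar), b_bar
    d_h = ssm.d_state
    aug = np.zeros((d_h + 1, d_h + 1))
    aug[:d_h, :d_h] = ssm.A
    aug[:d_h, d_h] = ssm.B
    M = expm(ssm.delta * aug)
    return M[:d_h, :d_h], M[:d_h, d_h]


def ssm_scan(ssm: SSMParams, sequence: np.ndarray) -> np.ndarray:
    """Run the discretized recurrence over a scalar input sequence.

    ``h_k = A_bar h_{k-1} + B_bar x_k`` with ``h_0 = 0`` and outputs
    ``y_k = C . h_k``; returns the length-L output vector.
    """
    sequence = np.asarray(sequence, dtype=float).ravel()
    L = len(sequence)
    if L == 0:
        return np.empty(0)
    A_bar, B_bar = discretize(ssm)
    h = np.zeros(ssm.d_state)
    out = np.empty(L)
    for k in range(L):
        h = A_bar @ h + B_bar * sequence[k]
        out[k] = ssm.C @ h
    return out


def channel_scan(
    U: np.ndarray,
    a_bar: np.ndarray,
    b_bar: np.ndarray,
    C: np.ndarray,
    return_states: bool = False,
):
    """Vectorized diagonal-SSM scan over a batch of multi-channel sequences.

    Parameters
    ----------
    U : (n, L, c) inputs, one scalar per position per channel.
    a_bar, b_bar : (c, d_h) discretized diagonal dynamics per channel.
    C : (d_h,) shared readout.

    Returns (n, L, c) outputs, plus the (n, L, c, d_h) state history when
    ``return_states`` (needed for backpropagation).
    """
    n, L, c = U.shape
    d_h = a_bar.shape[1]
    h = np.zeros((n, c, d_h))
    S = np.empty((n, L, c))
    H = np.empty((n, L, c, d_h)) if return_states else None
    for k in range(L):
        h = a_bar[None] * h + b_bar[None] * U[:, k, :, None]
        if return_states:
            H[:, k] = h
        S[:, k] = h @ C
    return (S, H) if return_states else S


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact (erf-based) Gaussian error linear unit."""
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    phi = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
    Phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
    return Phi + x * phi


def layer_norm(z: np.ndarray, gamma: np.ndarray, beta: np.ndarray, eps: float = 1e-6):
    """Normalize over the last (channel) axis, then scale/shift.

    Returns the output plus the normalized pre-affine tensor and inverse SD
    (reused by the analytic backward pass).
    """
    mu = z.mean(axis=-1, keepdims=True)
    zc = z - mu
    var = (zc * zc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    zn = zc * inv
    return gamma * zn + beta, zn, inv


@dataclass
class GatedBlockParams:
    """Parameters of the gated SSM block over an embedded feature sequence.

    Forward map: ``LayerNorm(SSM(E @ W_proj) + GELU(E @ W_gate))`` where E is
    the (L, c) embedded row; the SSM runs independently per channel with
    shared diagonal dynamics ``a`` (entries <= 0), per-channel step ``delta``.
    """

    W_proj: np.ndarray
    W_gate: np.ndarray
    a: np.ndarray
    delta: np.ndarray
    B: np.ndarray
    C: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        c = self.W_proj.shape[1]
        if self.W_proj.shape != self.W_gate.shape:
            raise ValueError(
                f"W_proj {self.W_proj.shape} and W_gate {self.W_gate.shape} differ"
            )
        for name in ("gamma", "beta"):
            v = getattr(self, name)
            if v.shape != (c,):
                raise ValueError(f"{name} must have shape ({c},)")
        if not np.all(np.isfinite(self.gamma)) or np.any(self.gamma == 0):
            raise ValueError("layer-norm scale must be finite and nonzero")
        if self.delta.shape != (c,):
            raise ValueError(f"delta must have shape ({c},)")
        if np.any(self.delta <= 0):
            raise ValueError("delta entries must be positive")
        if np.any(self.a > _EIG_TOL):
            raise ValueError("diagonal state matrix must be stable (a <= 0)")


def gated_block(E: np.ndarray, params: GatedBlockParams) -> np.ndarray:
    """Apply the gated SSM block to one embedded sequence of shape (L, c)."""
    E = np.asarray(E, dtype=float)
    if E.ndim != 2 or E.shape[1] != params.W_proj.shape[0]:
        raise ValueError(
            f"input shape {E.shape} incompatible with W_proj "
            f"{params.W_proj.shape}"
        )
    U = E @ params.W_proj
    G = gelu(E @ params.W_gate)
    a_bar, b_bar = discretize_diagonal(
        params.a[None, :], params.delta[:, None], params.B[None, :]
    )
    S = channel_scan(U[None], a_bar, b_bar, params.C)[0]
    out, _, _ = layer_norm(S + G, params.gamma, params.beta)
    return out
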