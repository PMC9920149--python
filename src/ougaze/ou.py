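"""Exact mathematics of the 2-D Ornstein-Uhlenbeck (O-U) process.

The gaze model treats every fixation and saccade as a mean-reverting
diffusion

    dx(t) = B (mu - x(t)) dt + Gamma dW(t),

with ``B`` a symmetric drift matrix with positive eigenvalues (units
1/sample), ``Gamma`` a symmetric positive-definite diffusion amplitude
(px/sqrt(sample)) and ``mu`` the attractor (fixation centre or saccade
landing point, px).  The instantaneous noise covariance is
``Gamma @ Gamma``.

The transition distribution over a step of ``dt`` samples is Gaussian,

    x(t + dt) | x(t) ~ N( mu + e^{-B dt} (x(t) - mu),  Psi(dt) ),
    Psi(dt) = D - e^{-B dt} D e^{-B^T dt},

where the stationary covariance ``D`` solves the continuous Lyapunov
equation ``B D + D B^T = Gamma^2`` (which reduces to the scalar familiar
form D = Gamma^2 / (2 B) componentwise when the matrices commute).

All routines work in the eigenbasis of the symmetric ``B``, which gives
closed forms for the matrix exponential and the Lyapunov solution and
keeps the per-step cost of the likelihood tiny.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ContractError, ValidationError

_SYM_ATOL = 1e-8
_PSD_TOL = 1e-12
_LOG2PI = np.log(2.0 * np.pi)


def _check_sym_posdef(M: np.ndarray, name: str, *, strict: bool = True) -> None:
    M = np.asarray(M, dtype=float)
    if M.shape != (2, 2):
        raise ValidationError(f"{name} must be 2x2, got shape {M.shape}")
    if not np.all(np.isfinite(M)):
        raise ValidationError(f"{name} contains non-finite entries")
    if not np.allclose(M, M.T, atol=_SYM_ATOL):
        raise ValidationError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(M)
    if strict and w.min() <= 0:
        raise ValidationError(f"{name} must have strictly positive eigenvalues, got {w}")


@dataclass(frozen=True)
class OUParams:
    """Parameters (B, Gamma, mu) of one O-U gaze event.

    ``B``: 2x2 symmetric drift matrix, positive eigenvalues, 1/sample.
    ``Gamma``: 2x2 symmetric positive-definite diffusion amplitude,
    px/sqrt(sample).  ``mu``: attractor in screen px.
    """

    B: np.ndarray
    Gamma: np.ndarray
    mu: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        object.__setattr__(self, "B", np.asarray(self.B, dtype=float))
        object.__setattr__(self, "Gamma", np.asarray(self.Gamma, dtype=float))
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float).reshape(2))
        _check_sym_posdef(self.B, "B")
        _check_sym_posdef(self.Gamma, "Gamma")
        if not np.all(np.isfinite(self.mu)):
            raise ValidationError("mu contains non-finite entries")


@dataclass(frozen=True)
class TransitionMoments:
    """Conditional mean and covariance of one O-U transition."""

    mean: np.ndarray
    cov_psi: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float).reshape(2))
        object.__setattr__(self, "cov_psi", np.asarray(self.cov_psi, dtype=float))
        _check_sym_posdef(self.cov_psi, "cov_psi", strict=False)
        if np.linalg.eigvalsh(self.cov_psi).min() < -1e-9:
            raise ValidationError("cov_psi must be positive semi-definite")


def _eigen_terms(B: np.ndarray, Gamma: np.ndarray):
    """Eigen-basis quantities shared by all transition formulas.

    Returns (w, Q, Dp, denom) with B = Q diag(w) Q^T, Dp the stationary
    covariance rotated into the eigenbasis and denom[a,b] = w[a] + w[b].
    """
    w, Q = np.linalg.eigh(B)
    G2p = Q.T @ (Gamma @ Gamma) @ Q
    denom = w[:, None] + w[None, :]
    Dp = G2p / denom
    return w, Q, Dp, denom


def _symmetrize_clip(M: np.ndarray, tol: float = _PSD_TOL) -> np.ndarray:
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    if w.min() < -tol * max(1.0, abs(w.max())):
        w = np.clip(w, 0.0, None)
        return (V * w) @ V.T
    # tiny negatives are still clipped so callers can factorise safely
    return (V * np.clip(w, 0.0, None)) @ V.T


def stationary_covariance(params: OUParams) -> np.ndarray:
    """Long-run covariance D solving B D + D B^T = Gamma^2."""
    w, Q, Dp, _ = _eigen_terms(params.B, params.Gamma)
    if w.min() <= 0:
        raise ValidationError("B must be positive-definite for a stationary law")
    D = Q @ Dp @ Q.T
    return 0.5 * (D + D.T)


def transition_moments(params: OUParams, x, dt: float) -> TransitionMoments:
    """Exact conditional mean and covariance of x(t+dt) given x(t)=x."""
    if dt < 0:
        raise ContractError(f"dt must be non-negative, got {dt}")
    x = np.asarray(x, dtype=float).reshape(2)
    w, Q, Dp, denom = _eigen_terms(params.B, params.Gamma)
    ew = np.exp(-w * dt)
    # rotate, propagate, rotate back
    yp = Q.T @ (x - params.mu)
    mean = params.mu + Q @ (ew * yp)
    Psip = Dp * (1.0 - np.exp(-denom * dt))
    Psi = _symmetrize_clip(Q @ Psip @ Q.T)
    return TransitionMoments(mean=mean, cov_psi=Psi)


def sample_transition(moments: TransitionMoments, rng: np.random.Generator) -> np.ndarray:
    """Draw one bivariate-normal sample from the given transition moments."""
    w, V = np.linalg.eigh(moments.cov_psi)
    root = V * np.sqrt(np.clip(w, 0.0, None))
    return moments.mean + root @ rng.standard_normal(2)


def _loglik_core(B: np.ndarray, Gamma: np.ndarray, y: np.ndarray, jitter: float) -> float:
    """Log-likelihood of the centred slice ``y = x_e - mu`` under unit steps.

    Fast 2x2 path: everything is computed in the eigenbasis of B, where
    e^{-B} is diagonal; the Gaussian density uses the analytic 2x2 inverse.
    """
    w, Q = np.linalg.eigh(B)
    if w.min() <= 0:
        return -np.inf
    yr = y @ Q
    ew = np.exp(-w)
    r = yr[1:] - yr[:-1] * ew
    G2p = Q.T @ (Gamma @ Gamma) @ Q
    denom = w[:, None] + w[None, :]
    Psip = (G2p / denom) * (1.0 - np.exp(-denom))
    a, b, c = Psip[0, 0], Psip[1, 1], Psip[0, 1]
    det = a * b - c * c
    if det <= _PSD_TOL * max(1.0, a * b) or min(a, b) <= 0.0:
        a += jitter
        b += jitter
        det = a * b - c * c
        if det <= 0.0 or min(a, b) <= 0.0:
            return -np.inf
    quad = (b * r[:, 0] ** 2 - 2.0 * c * r[:, 0] * r[:, 1] + a * r[:, 1] ** 2).sum() / det
    n_steps = r.shape[0]
    return -0.5 * quad - n_steps * (0.5 * np.log(det) + _LOG2PI)


def event_log_likelihood(x_e: np.ndarray, params: OUParams, jitter: float = 1e-9) -> float:
    """Markov log-likelihood of an event slice under unit time steps.

    Sums the transition log-densities of x_{i+1} given x_i over the slice.
    A diagonal ``jitter`` (px^2) is added to Psi when it is numerically
    singular (very short steps or vanishing diffusion).
    """
    x_e = np.asarray(x_e, dtype=float)
    if x_e.ndim != 2 or x_e.shape[1] != 2 or x_e.shape[0] < 2:
        raise ContractError("event slice must be an (n, 2) array with n >= 2")
    ll = _loglik_core(params.B, params.Gamma, x_e - params.mu, jitter)
    return float(ll)
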