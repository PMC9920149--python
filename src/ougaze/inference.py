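"""Bayesian estimation of per-event O-U drift and diffusion matrices.

Each gaze event contributes a Markov-Gaussian likelihood (product of the
exact unit-step transition densities of its slice, with the attractor
``mu`` fixed by segmentation).  ``B`` and ``Gamma`` are constrained to
be symmetric with positive eigenvalues by writing each as

    M = [[s1**2, r*s1*s2], [r*s1*s2, s2**2]],

i.e. a correlation ``r`` with an LKJ prior completed by half-normal
priors on the componentwise scales ``s``.  Inference runs in the
unconstrained space z = (log s1, log s2, atanh r) x 2.

Two posterior approximations are provided behind one contract:

* ``map_laplace`` — maximise the log posterior, then a Gaussian
  (curvature-based) approximation at the mode supplies the posterior
  draws.  Deterministic given a seed and fast; the default.
* ``vi`` — mean-field Gaussian variational approximation optimised by
  stochastic gradient ascent on the evidence lower bound with the
  reparameterisation trick (automatic-differentiation-free: gradients of
  the joint density are central finite differences, which is cheap in a
  6-dimensional parameter space).

Posterior draws are summarised per free matrix component (B_ii, B_ij,
B_jj, Gamma_ii, Gamma_ij, Gamma_jj) by the sample mean and the highest
density interval (HDI) — the narrowest interval holding the configured
probability mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .exceptions import ContractError
from .io import InferenceConfig
from .ou import _loglik_core
from .segmentation import GazeEvent

logger = logging.getLogger(__name__)

COMPONENTS = ("B_ii", "B_ij", "B_jj", "Gamma_ii", "Gamma_ij", "Gamma_jj")

_Z_BOUND = 12.0  # unconstrained coordinates are kept in [-12, 12]


@dataclass(frozen=True)
class PriorSpec:
    """LKJ concentration and half-normal scale priors for B and Gamma.

    Scales are the componentwise square roots of the diagonal entries;
    ``scale_sd_B`` is in sqrt(1/sample), ``scale_sd_Gamma`` in
    sqrt(px/sqrt(sample)) — weakly informative at the data's unit scale.
    """

    lkj_eta_B: float = 2.0
    lkj_eta_Gamma: float = 2.0
    scale_sd_B: float = 1.0
    scale_sd_Gamma: float = 5.0

    def __post_init__(self) -> None:
        if min(self.lkj_eta_B, self.lkj_eta_Gamma) <= 0:
            raise ContractError("LKJ concentration must be positive")
        if min(self.scale_sd_B, self.scale_sd_Gamma) <= 0:
            raise ContractError("scale prior sds must be positive")


@dataclass
class PosteriorSummary:
    """Mean and HDI of the six free matrix components."""

    mean: dict
    hdi_lower: dict
    hdi_upper: dict
    hdi_mass: float
    n_draws: int
    method: str
    converged: bool = True
    diagnostic: float | None = None

    def hdi_width(self, component: str) -> float:
        return self.hdi_upper[component] - self.hdi_lower[component]


# ---------------------------------------------------------------------------
# transforms

def _z_to_components(z: np.ndarray) -> np.ndarray:
    """Map unconstrained draws (…, 6) to matrix components (…, 6)."""
    z = np.asarray(z, dtype=float)
    s = np.exp(z[..., [0, 1, 3, 4]])
    r = np.tanh(z[..., [2, 5]])
    out = np.empty(z.shape)
    out[..., 0] = s[..., 0] ** 2                      # B_ii
    out[..., 1] = r[..., 0] * s[..., 0] * s[..., 1]   # B_ij
    out[..., 2] = s[..., 1] ** 2                      # B_jj
    out[..., 3] = s[..., 2] ** 2                      # Gamma_ii
    out[..., 4] = r[..., 1] * s[..., 2] * s[..., 3]   # Gamma_ij
    out[..., 5] = s[..., 3] ** 2                      # Gamma_jj
    return out


def _z_to_matrices(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = _z_to_components(z)
    B = np.array([[c[0], c[1]], [c[1], c[2]]])
    G = np.array([[c[3], c[4]], [c[4], c[5]]])
    return B, G


def _log_prior(z: np.ndarray, prior: PriorSpec) -> float:
    """Log prior density in unconstrained space (transform Jacobians included)."""
    logs = z[[0, 1, 3, 4]]
    s = np.exp(logs)
    atr = z[[2, 5]]
    # log(1 - tanh(a)^2) = 2*log(2) - 2*log(e^a + e^-a)
    log1m_r2 = 2.0 * np.log(2.0) - 2.0 * np.logaddexp(atr, -atr)
    sds = np.array([prior.scale_sd_B, prior.scale_sd_B,
                    prior.scale_sd_Gamma, prior.scale_sd_Gamma])
    lp = float(np.sum(-0.5 * (s / sds) ** 2 + logs))  # half-normal + log|ds/dz|
    etas = np.array([prior.lkj_eta_B, prior.lkj_eta_Gamma])
    lp += float(np.sum(etas * log1m_r2))  # LKJ (eta-1) + tanh Jacobian (1)
    return lp


def _moment_init(y: np.ndarray) -> np.ndarray:
    """Moment-based starting point from the centred slice y = x - mu.

    Fits per-dimension AR(1) coefficients a = e^{-b}, recovers the drift
    b = -log a and the diffusion via the stationary relation
    Gamma^2 = 2 b D with D = Var(resid) / (1 - a^2).
    """
    z0 = np.zeros(6)
    for d in range(2):
        num = float(y[1:, d] @ y[:-1, d])
        den = float(y[:-1, d] @ y[:-1, d]) + 1e-12
        a = np.clip(num / den, 0.01, 0.9999)
        b = -np.log(a)
        resid = y[1:, d] - a * y[:-1, d]
        psi = max(float(np.var(resid)), 1e-8)
        g2 = 2.0 * b * psi / (1.0 - a * a)
        z0[d] = 0.5 * np.log(b)
        z0[3 + d] = 0.25 * np.log(g2)
    return np.clip(z0, -_Z_BOUND + 1.0, _Z_BOUND - 1.0)


def _make_log_posterior(y: np.ndarray, prior: PriorSpec, jitter: float):
    def log_post(z: np.ndarray) -> float:
        z = np.clip(z, -_Z_BOUND, _Z_BOUND)
        B, G = _z_to_matrices(z)
        ll = _loglik_core(B, G, y, jitter)
        if not np.isfinite(ll):
            return -np.inf
        return ll + _log_prior(z, prior)

    return log_post


def _fd_gradient(f, z: np.ndarray, h: float = 1e-5) -> np.ndarray:
    g = np.empty(len(z))
    for a in range(len(z)):
        step = h * (1.0 + abs(z[a]))
        zp, zm = z.copy(), z.copy()
        zp[a] += step
        zm[a] -= step
        g[a] = (f(zp) - f(zm)) / (2.0 * step)
    return g


def _fd_hessian(f, z: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = len(z)
    H = np.empty((n, n))
    steps = h * (1.0 + np.abs(z))
    f0 = f(z)
    for a in range(n):
        ea = np.zeros(n)
        ea[a] = steps[a]
        H[a, a] = (f(z + ea) - 2.0 * f0 + f(z - ea)) / steps[a] ** 2
        for b in range(a + 1, n):
            eb = np.zeros(n)
            eb[b] = steps[b]
            H[a, b] = H[b, a] = (
                f(z + ea + eb) - f(z + ea - eb) - f(z - ea + eb) + f(z - ea - eb)
            ) / (4.0 * steps[a] * steps[b])
    return H


# ---------------------------------------------------------------------------
# posterior summaries

def hdi_interval(draws: np.ndarray, mass: float) -> tuple[float, float]:
    """Narrowest contiguous interval containing ``mass`` of the draws."""
    d = np.sort(np.asarray(draws, dtype=float))
    n = len(d)
    if n < 2:
        raise ContractError("HDI needs at least 2 draws")
    m = max(1, int(np.ceil(mass * n)))
    if m >= n:
        return float(d[0]), float(d[-1])
    widths = d[m:] - d[: n - m]
    i = int(np.argmin(widths))
    return float(d[i]), float(d[i + m])


def summarize_draws(
    draws: np.ndarray, hdi_mass: float = 0.94, method: str = "draws",
    converged: bool = True, diagnostic: float | None = None,
) -> PosteriorSummary:
    """Mean and HDI per component from an (n_draws, 6) component array."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[1] != len(COMPONENTS) or draws.shape[0] < 2:
        raise ContractError("draws must be an (n >= 2, 6) component array")
    if not 0.0 < hdi_mass < 1.0:
        raise ContractError("hdi_mass must lie in (0, 1)")
    mean, lo, hi = {}, {}, {}
    for a, comp in enumerate(COMPONENTS):
        col = draws[:, a]
        mean[comp] = float(col.mean())
        lo[comp], hi[comp] = hdi_interval(col, hdi_mass)
    return PosteriorSummary(
        mean=mean, hdi_lower=lo, hdi_upper=hi, hdi_mass=hdi_mass,
        n_draws=draws.shape[0], method=method, converged=converged,
        diagnostic=diagnostic,
    )


# ---------------------------------------------------------------------------
# inference drivers

def _map_laplace(log_post, z0: np.ndarray, n_draws: int, rng: np.random.Generator):
    neg = lambda z: -log_post(z)
    res = minimize(
        neg, z0, method="L-BFGS-B",
        bounds=[(-_Z_BOUND, _Z_BOUND)] * 6,
        options={"maxiter": 300},
    )
    z_map = res.x
    H = _fd_hessian(neg, z_map)  # observed information in z-space
    H = 0.5 * (H + H.T)
    w, V = np.linalg.eigh(H)
    curvature_ok = bool(w.min() > 0)
    # directions the data leave flat fall back to (roughly) the prior's
    # width in z-space instead of an unbounded Gaussian: floor the
    # curvature at 0.5 (draw sd <= sqrt(2) per direction)
    w = np.clip(w, 0.5, None)
    root_cov = V / np.sqrt(w)
    eps = rng.standard_normal((n_draws, 6))
    z_draws = z_map + eps @ root_cov.T
    converged = bool(res.success) and curvature_ok
    if not converged:
        logger.warning("map_laplace convergence flag raised: %s", res.message)
    return z_draws, converged, float(res.fun)


def _advi(log_post, z0: np.ndarray, iterations: int, n_draws: int,
          rng: np.random.Generator, lr: float = 0.05, patience: int = 1000):
    """Mean-field Gaussian VI by stochastic gradient ascent on the ELBO."""
    m = z0.copy()
    log_s = np.full(6, -1.0)
    am = np.zeros((2, 6))
    av = np.zeros((2, 6))
    b1, b2, eps_adam = 0.9, 0.999, 1e-8
    best, best_iter = -np.inf, 0
    smoothed = None
    for it in range(1, iterations + 1):
        s = np.exp(log_s)
        eps = rng.standard_normal(6)
        z = m + s * eps
        g = _fd_gradient(log_post, z)
        grads = [g, g * s * eps + 1.0]  # d/dm, d/dlog_s (entropy grad = 1)
        for p, (theta, gr) in enumerate(zip((m, log_s), grads)):
            am[p] = b1 * am[p] + (1 - b1) * gr
            av[p] = b2 * av[p] + (1 - b2) * gr**2
            mhat = am[p] / (1 - b1**it)
            vhat = av[p] / (1 - b2**it)
            theta += lr * mhat / (np.sqrt(vhat) + eps_adam)
        elbo = log_post(z) + float(log_s.sum())
        smoothed = elbo if smoothed is None else 0.99 * smoothed + 0.01 * elbo
        if smoothed > best + 0.01:
            best, best_iter = smoothed, it
        elif it - best_iter > patience:
            break
    # plateau of the smoothed objective counts as convergence
    converged = (it < iterations) or (it - best_iter) > patience // 2
    if not converged:
        logger.warning("VI objective still improving at the iteration budget")
    s = np.exp(log_s)
    z_draws = m + s * rng.standard_normal((n_draws, 6))
    return z_draws, bool(converged), float(-best if smoothed is not None else np.nan)


def infer_event_posterior(
    event: GazeEvent,
    prior: PriorSpec | None = None,
    method: str = "map_laplace",
    config: InferenceConfig | None = None,
) -> PosteriorSummary:
    """Approximate the posterior of (B, Gamma) for one gaze event.

    The event's attractor ``mu`` must be set (it is fixed, not inferred).
    Raises :class:`ContractError` if the event has fewer transitions than
    ``config.min_transitions``.
    """
    prior = prior or PriorSpec()
    config = config or InferenceConfig(method=method)
    if event.samples is None:
        raise ContractError("event carries no sample slice")
    if event.attractor_mu is None:
        raise ContractError("event attractor mu must be set before inference")
    if event.n_transitions < config.min_transitions:
        raise ContractError(
            f"event has {event.n_transitions} transitions; "
            f"needs >= {config.min_transitions}"
        )
    y = event.samples - event.attractor_mu
    log_post = _make_log_posterior(y, prior, config.jitter)
    z0 = _moment_init(y)
    rng = np.random.default_rng(config.seed)
    if method == "map_laplace":
        z_draws, converged, diag = _map_laplace(log_post, z0, config.n_draws, rng)
    elif method == "vi":
        z_draws, converged, diag = _advi(
            log_post, z0, config.vi_iterations, config.n_draws, rng
        )
    else:
        raise ContractError(f"unknown inference method {method!r}")
    comp_draws = _z_to_components(np.clip(z_draws, -_Z_BOUND, _Z_BOUND))
    return summarize_draws(
        comp_draws, hdi_mass=config.hdi_mass, method=method,
        converged=converged, diagnostic=diag,
    )
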