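"""Euler-Maruyama diffusion engine for the focal/others projection.

The per-step drift is the expected frequency change under the jump process
(events move frequencies by ±1/N) and the noise is the exact per-step
covariance of that change, so one Euler-Maruyama step at ``dt = 1`` matches
one discrete step to second order in distribution.  Host lifespans are
exponential with mean ``1/tau``; after each step negative components are
clipped to zero and, if the total exceeds one, microbial components are
rescaled (minimal boundary intervention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import ColonizerPool, HostState, LifeHistory, _check_xo, _transitions_xo

__all__ = [
    "DriftDiffusion",
    "SDEConfig",
    "drift_vector",
    "covariance_matrix",
    "drift_diffusion",
    "noise_factor",
    "euler_maruyama_step",
    "sample_host_lifespan",
    "simulate_host_sde",
    "simulate_xo_batch",
]


@dataclass(frozen=True)
class DriftDiffusion:
    """Per-step drift vector ``A``, covariance ``V`` and a factor ``Bfac``
    with ``Bfac.T @ Bfac == V`` (within 1e-10)."""

    A: np.ndarray
    V: np.ndarray
    Bfac: np.ndarray


@dataclass(frozen=True)
class SDEConfig:
    """Timestep (in units of jump-process timesteps) for the SDE engine."""

    dt: float = 1.0

    def __post_init__(self) -> None:
        if not self.dt > 0.0:
            raise ValueError("dt must be > 0")


def _xo(state) -> tuple[float, float]:
    if isinstance(state, HostState):
        return state.projection(0)
    return float(state[0]), float(state[1])


def _transition_terms(state, lh: LifeHistory, pool: ColonizerPool, taxon: int):
    if isinstance(state, HostState):
        x, o = state.projection(taxon)
    else:
        x, o = float(state[0]), float(state[1])
    _check_xo(x, o)
    return _transitions_xo(x, o, lh.m, lh.tau, lh.alpha0, float(pool.p[taxon]))


def drift_vector(state, lh: LifeHistory, pool: ColonizerPool, taxon: int = 0) -> np.ndarray:
    """Expected per-step change of ``(x_i, o_i)``."""
    t1a, t1b, t1c, t1d, t1e, t1f = _transition_terms(state, lh, pool, taxon)
    ax = (t1d + t1b - t1a - t1e) / lh.N
    ao = (t1a + t1c - t1b - t1f) / lh.N
    return np.array([ax, ao])


def covariance_matrix(state, lh: LifeHistory, pool: ColonizerPool, taxon: int = 0) -> np.ndarray:
    """Exact per-step covariance of the ``(x_i, o_i)`` jump,
    ``E[dd'] - A A'`` with jumps of magnitude 1/N."""
    t1a, t1b, t1c, t1d, t1e, t1f = _transition_terms(state, lh, pool, taxon)
    n2 = lh.N * lh.N
    exx = (t1a + t1b + t1d + t1e) / n2
    eoo = (t1a + t1b + t1c + t1f) / n2
    exo = -(t1a + t1b) / n2
    A = drift_vector(state, lh, pool, taxon)
    second = np.array([[exx, exo], [exo, eoo]])
    return second - np.outer(A, A)


def noise_factor(V: np.ndarray) -> np.ndarray:
    """Symmetric matrix square root of a PSD matrix.

    Satisfies ``B.T @ B == V`` (and ``B @ B.T == V``).  Eigenvalues in
    [-1e-12, 0) are floored at zero; asymmetry beyond 1e-8 or eigenvalues
    below -1e-8 raise.
    """
    V = np.asarray(V, dtype=float)
    if V.shape[0] != V.shape[1]:
        raise ValueError("V must be square")
    if np.max(np.abs(V - V.T)) > 1e-8:
        raise ValueError("V is not symmetric")
    w, Q = np.linalg.eigh((V + V.T) / 2.0)
    if np.any(w < -1e-8):
        raise ValueError(f"V has a significantly negative eigenvalue: {w.min()}")
    w = np.clip(w, 0.0, None)
    return (Q * np.sqrt(w)) @ Q.T


def drift_diffusion(state, lh: LifeHistory, pool: ColonizerPool, taxon: int = 0) -> DriftDiffusion:
    """Bundle drift, covariance and noise factor for one state."""
    A = drift_vector(state, lh, pool, taxon)
    V = covariance_matrix(state, lh, pool, taxon)
    return DriftDiffusion(A=A, V=V, Bfac=noise_factor(V))


def _apply_boundary(xo: np.ndarray) -> np.ndarray:
    xo = np.clip(xo, 0.0, None)
    s = xo.sum()
    if s > 1.0:
        xo = xo / s
    return xo


def euler_maruyama_step(
    state,
    dd: DriftDiffusion,
    cfg: SDEConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Euler-Maruyama update ``x + A dt + B dW``, then the boundary
    policy (clip negatives, renormalise if the total load exceeds one)."""
    xo = np.array(_xo(state), dtype=float)
    dw = rng.normal(0.0, np.sqrt(cfg.dt), size=xo.size)
    return _apply_boundary(xo + dd.A * cfg.dt + dd.Bfac @ dw)


def sample_host_lifespan(tau: float, rng: np.random.Generator) -> float:
    """Exponential lifespan with mean ``1/tau``; ``tau = 0`` -> infinity."""
    if tau < 0.0 or tau > 1.0:
        raise ValueError("tau must be in [0, 1]")
    if tau == 0.0:
        return np.inf
    return float(rng.exponential(1.0 / tau))


@dataclass
class SDETrajectory:
    times: np.ndarray
    xo: np.ndarray  # (n_records, 2) focal frequency and others frequency
    death_time: float | None


def simulate_host_sde(
    init,
    lh: LifeHistory,
    pool: ColonizerPool,
    cfg: SDEConfig,
    rng: np.random.Generator,
    t_end: float,
    taxon: int = 0,
    record_every: int = 1,
    lifespan: float | None = None,
) -> SDETrajectory:
    """Simulate one host's ``(x_i, o_i)`` trajectory on the ``dt`` grid.

    The host dies at an exponential lifespan (drawn here unless supplied);
    integration stops there or at ``t_end``, whichever is first.
    """
    if t_end < 0.0:
        raise ValueError("t_end must be >= 0")
    xo = np.array(_xo(init), dtype=float)
    _check_xo(xo[0], xo[1])
    if lifespan is None:
        lifespan = sample_host_lifespan(lh.tau, rng)
    death_time = lifespan if lifespan <= t_end else None
    horizon = min(t_end, lifespan)
    n_steps = int(np.floor(horizon / cfg.dt))
    times = [0.0]
    rec = [xo.copy()]
    for s in range(1, n_steps + 1):
        dd = drift_diffusion(xo, lh, pool, taxon)
        xo = euler_maruyama_step(xo, dd, cfg, rng)
        if s % record_every == 0 or s == n_steps:
            times.append(s * cfg.dt)
            rec.append(xo.copy())
    return SDETrajectory(
        times=np.array(times), xo=np.array(rec), death_time=death_time
    )


def _sqrt2x2(V: np.ndarray) -> np.ndarray:
    """Closed-form symmetric square roots of a batch of PSD 2x2 matrices.

    ``V`` has shape (n, 2, 2); returns the same shape.  Uses
    ``sqrt(V) = (V + sqrt(det V) I) / sqrt(tr V + 2 sqrt(det V))``.
    """
    a = np.clip(V[:, 0, 0], 0.0, None)
    b = np.clip(V[:, 1, 1], 0.0, None)
    c = V[:, 0, 1]
    det = np.clip(a * b - c * c, 0.0, None)
    s = np.sqrt(det)
    denom = np.sqrt(np.clip(a + b + 2.0 * s, 0.0, None))
    out = np.zeros_like(V)
    ok = denom > 0.0
    inv = np.where(ok, 1.0 / np.where(ok, denom, 1.0), 0.0)
    out[:, 0, 0] = (a + s) * inv
    out[:, 1, 1] = (b + s) * inv
    out[:, 0, 1] = out[:, 1, 0] = c * inv
    return out


def _em_step_batch(
    xo: np.ndarray,
    lh: LifeHistory,
    p_i: float,
    dt: float,
    rng: np.random.Generator,
) -> None:
    """One vectorised Euler-Maruyama step for a batch of (x, o) states,
    in place.  Same drift/covariance/boundary policy as the scalar path."""
    m, alpha0, N = lh.m, lh.alpha0, lh.N
    s = 1.0 - lh.tau
    R = xo.shape[0]
    x, o = xo[:, 0].copy(), xo[:, 1].copy()
    x0 = 1.0 - x - o
    D = alpha0 * x0 + x + o
    safe = D > 0.0
    Dinv = np.where(safe, 1.0 / np.where(safe, D, 1.0), 0.0)
    rx = (1.0 - m) * x * Dinv
    ro = (1.0 - m) * o * Dinv
    rz = (1.0 - m) * alpha0 * x0 * Dinv
    t1a = s * x * (m * (1.0 - p_i) + ro)
    t1b = s * o * (m * p_i + rx)
    t1c = s * x0 * (m * (1.0 - p_i) + ro)
    t1d = s * x0 * (m * p_i + rx)
    t1e = s * x * rz
    t1f = s * o * rz
    ax = (t1d + t1b - t1a - t1e) / N
    ao = (t1a + t1c - t1b - t1f) / N
    n2 = N * N
    V = np.zeros((R, 2, 2))
    V[:, 0, 0] = (t1a + t1b + t1d + t1e) / n2 - ax * ax
    V[:, 1, 1] = (t1a + t1b + t1c + t1f) / n2 - ao * ao
    V[:, 0, 1] = V[:, 1, 0] = -(t1a + t1b) / n2 - ax * ao
    B = _sqrt2x2(V)
    dw = rng.normal(0.0, np.sqrt(dt), size=(R, 2))
    xo[:, 0] = x + ax * dt + B[:, 0, 0] * dw[:, 0] + B[:, 0, 1] * dw[:, 1]
    xo[:, 1] = o + ao * dt + B[:, 1, 0] * dw[:, 0] + B[:, 1, 1] * dw[:, 1]
    np.clip(xo, 0.0, None, out=xo)
    tot = xo.sum(axis=1)
    over = tot > 1.0
    if np.any(over):
        xo[over] /= tot[over, None]


def simulate_xo_batch(
    init_xo: np.ndarray,
    lh: LifeHistory,
    pool: ColonizerPool,
    cfg: SDEConfig,
    rng: np.random.Generator,
    checkpoints: np.ndarray,
    taxon: int = 0,
) -> np.ndarray:
    """Vectorised immortal-host SDE integration of many replicates.

    ``init_xo`` is (R, 2); returns (n_checkpoints, R, 2) states at the
    requested times (multiples of ``dt``).  Used for engine
    cross-validation at scale; host death is not simulated here.
    """
    xo = np.array(init_xo, dtype=float)
    p_i = float(pool.p[taxon])
    checkpoints = np.asarray(checkpoints, dtype=float)
    steps_at = np.rint(checkpoints / cfg.dt).astype(np.int64)
    out = np.zeros((checkpoints.size, xo.shape[0], 2))
    next_cp = 0
    while next_cp < steps_at.size and steps_at[next_cp] == 0:
        out[next_cp] = xo
        next_cp += 1
    for step in range(1, int(steps_at.max()) + 1):
        _em_step_batch(xo, lh, p_i, cfg.dt, rng)
        while next_cp < steps_at.size and steps_at[next_cp] == step:
            out[next_cp] = xo
            next_cp += 1
    return out
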