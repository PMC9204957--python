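"""Analytics for lineage taxa: microbes present in hosts but absent from
the environmental pool (``p_i = 0``), which persist only through
inheritance.

Within a host, the expected lineage frequency increases while the total
microbial load stays below ``1 - m / (1 - alpha0)`` and declines once the
load exceeds it, so that threshold is also the analytic ceiling of the mean
lineage frequency.  At the population level the persistence question is
summarised by the host-death probability ``tau_z = -ln(1 - z) / t_z`` at
which a fraction ``z`` of hosts has lost the taxon by its typical
extinction time ``t_z``.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from ._kernels import advance_host
from .inheritance import InheritanceSpec
from .model_core import ColonizerPool, HostState, LifeHistory
from .population import _draw_parent, _split_counts

__all__ = [
    "LineageRun",
    "increase_condition",
    "max_lineage_frequency",
    "run_lineage_experiment",
    "persistence_threshold_tau",
    "estimate_increase_threshold",
]

LINEAGE_TAXON = 0


def _check_validity_domain(lh: LifeHistory) -> None:
    if lh.alpha0 >= 1.0:
        raise ValueError(
            "the mean-increase threshold 1 - m/(1 - alpha0) is derived for "
            f"alpha0 < 1; got alpha0 = {lh.alpha0}"
        )


def increase_condition(state, lh: LifeHistory) -> bool:
    """Whether the mean lineage frequency is currently increasing.

    True iff the total load ``x_i + o_i`` is below ``1 - m/(1 - alpha0)``.
    Valid for ``alpha0 < 1``.
    """
    _check_validity_domain(lh)
    if isinstance(state, HostState):
        load = state.load
    elif np.ndim(state) == 0:
        load = float(state)
    else:
        load = float(np.sum(state))
    if load < -1e-12 or load > 1.0 + 1e-12:
        raise ValueError("load outside [0, 1]")
    return load < max_lineage_frequency(lh)


def max_lineage_frequency(lh: LifeHistory) -> float:
    """Analytic mean ceiling of the lineage frequency,
    ``1 - m/(1 - alpha0)`` clipped to [0, 1]."""
    _check_validity_domain(lh)
    return float(np.clip(1.0 - lh.m / (1.0 - lh.alpha0), 0.0, 1.0))


@dataclass
class LineageRun:
    """Outcome of a lineage-persistence experiment.

    ``extinction_times`` holds, per host slot, the first timestep at which
    the slot's lineage count reached zero; censored slots (still carrying
    the taxon at ``t_max``) are ``inf``.  The slot's clock runs through
    birth events: the newborn inherits both the slot and its history.
    """

    extinction_times: np.ndarray
    survival_times: np.ndarray
    survival_curve: np.ndarray
    peak_freqs: np.ndarray
    t_max: int

    @property
    def censored(self) -> np.ndarray:
        return ~np.isfinite(self.extinction_times)


def run_lineage_experiment(
    lh: LifeHistory,
    pool: ColonizerPool,
    init_counts: np.ndarray,
    inheritance: InheritanceSpec,
    t_max: int,
    rng: np.random.Generator,
    n_curve_points: int = 50,
) -> LineageRun:
    """Track extinction of the lineage taxon (taxon 0) across H host slots.

    All hosts start with ``init_counts`` (a K-vector).  The pool must have
    ``p[0] == 0``; with ``tau = 0`` hosts are immortal and slots evolve
    independently, otherwise deaths/births are scheduled as in the
    population engine and extinction is tracked through the splits.
    """
    if pool.p[LINEAGE_TAXON] != 0.0:
        raise ValueError("the lineage taxon must have pool frequency 0")
    init_counts = np.asarray(init_counts, dtype=np.int64)
    if init_counts.ndim != 1 or init_counts.size != pool.n_taxa:
        raise ValueError("init_counts must be a K-vector matching the pool")
    if np.any(init_counts < 0) or init_counts.sum() > lh.N:
        raise ValueError("init_counts violate host invariants")
    H, K = lh.H, pool.n_taxa
    p = np.ascontiguousarray(pool.p, dtype=np.float64)
    N = float(lh.N)
    counts = np.tile(init_counts, (H, 1))
    ext = np.full(H, np.inf)
    peak = counts[:, LINEAGE_TAXON].astype(float).copy()
    if init_counts[LINEAGE_TAXON] == 0:
        ext[:] = 0.0
    last_sync = np.zeros(H, dtype=np.int64)

    def advance_to(h: int, t: int) -> None:
        steps = t - last_sync[h]
        if steps <= 0:
            last_sync[h] = max(last_sync[h], t)
            return
        if counts[h].sum() == 0 and lh.m == 0.0:
            last_sync[h] = t
            return
        fz, mx = advance_host(
            counts[h], np.int64(steps), lh.m, lh.alpha0, p, N, rng
        )
        if not np.isfinite(ext[h]):
            if counts[h, LINEAGE_TAXON] == 0 and fz >= 0:
                ext[h] = last_sync[h] + int(fz)
            peak[h] = max(peak[h], float(mx))
        last_sync[h] = t

    heap: list[tuple[int, int]] = []
    if lh.tau > 0.0:
        for h in range(H):
            heapq.heappush(heap, (int(rng.geometric(lh.tau)), h))
    while heap and heap[0][0] <= t_max:
        d, h = heapq.heappop(heap)
        parent = _draw_parent(H, h, rng)
        advance_to(parent, d)
        advance_to(h, d)  # the dying host's own extinction clock matters
        moved = _split_counts(counts[parent], inheritance, rng)
        counts[parent] -= moved
        counts[h] = moved
        last_sync[h] = d
        for slot in (h, parent):
            if not np.isfinite(ext[slot]):
                if counts[slot, LINEAGE_TAXON] == 0:
                    ext[slot] = d
                else:
                    peak[slot] = max(
                        peak[slot], float(counts[slot, LINEAGE_TAXON])
                    )
        heapq.heappush(heap, (d + int(rng.geometric(lh.tau)), h))
    for h in range(H):
        advance_to(h, t_max)
    grid = np.unique(np.linspace(0, t_max, n_curve_points).astype(np.int64))
    curve = np.array([(ext > t).mean() for t in grid])
    return LineageRun(
        extinction_times=ext,
        survival_times=grid.astype(float),
        survival_curve=curve,
        peak_freqs=peak / N,
        t_max=t_max,
    )


def _crossing_load(
    mean_x1: np.ndarray, mean_load: np.ndarray
) -> float:
    """Load at which the mean lineage trajectory stops increasing: linear
    interpolation of the first sign change of the lineage increment."""
    dx = np.diff(mean_x1)
    load_mid = 0.5 * (mean_load[1:] + mean_load[:-1])
    for i in range(1, dx.size):
        if dx[i - 1] > 0 and dx[i] <= 0:
            frac = dx[i - 1] / (dx[i - 1] - dx[i])
            return float(
                load_mid[i - 1] + frac * (load_mid[i] - load_mid[i - 1])
            )
    return np.nan


def estimate_increase_threshold(
    lh: LifeHistory,
    pool: ColonizerPool,
    init_counts: np.ndarray,
    t_end: int,
    rng: np.random.Generator,
    n_replicates: int = 400,
    n_checkpoints: int = 200,
    n_groups: int = 8,
) -> tuple[float, float]:
    """Simulated counterpart of :func:`max_lineage_frequency`.

    Runs ``n_replicates`` immortal hosts from ``init_counts`` and measures
    the total load at which the replicate-averaged lineage frequency stops
    increasing (the maximum of the mean lineage trajectory).  The point
    estimate uses all replicates; the standard error is the spread of the
    same estimator over ``n_groups`` disjoint replicate groups.
    """
    if pool.p[LINEAGE_TAXON] != 0.0:
        raise ValueError("the lineage taxon must have pool frequency 0")
    init_counts = np.asarray(init_counts, dtype=np.int64)
    p = np.ascontiguousarray(pool.p, dtype=np.float64)
    cps = np.unique(
        np.linspace(0, t_end, n_checkpoints + 1).astype(np.int64)
    )[1:]
    x1 = np.zeros((cps.size + 1, n_replicates))
    load = np.zeros((cps.size + 1, n_replicates))
    x1[0] = init_counts[LINEAGE_TAXON] / lh.N
    load[0] = init_counts.sum() / lh.N
    for r in range(n_replicates):
        c = init_counts.copy()
        prev = 0
        for i, t in enumerate(cps):
            advance_host(
                c, np.int64(t - prev), lh.m, lh.alpha0, p, float(lh.N), rng
            )
            prev = int(t)
            x1[i + 1, r] = c[LINEAGE_TAXON] / lh.N
            load[i + 1, r] = c.sum() / lh.N
    estimate = _crossing_load(x1.mean(axis=1), load.mean(axis=1))
    size = n_replicates // n_groups
    group_ests = np.array(
        [
            _crossing_load(
                x1[:, g * size:(g + 1) * size].mean(axis=1),
                load[:, g * size:(g + 1) * size].mean(axis=1),
            )
            for g in range(n_groups)
        ]
    )
    ok = np.isfinite(group_ests)
    se = float(np.nanstd(group_ests, ddof=1) / np.sqrt(ok.sum()))
    return estimate, se


def persistence_threshold_tau(extinction_times: np.ndarray, z: float) -> float:
    """Host-death probability at which a fraction ``z`` of hosts loses the
    lineage taxon: ``tau_z = -ln(1 - z) / t_z`` with ``t_z`` the empirical
    z-quantile of the extinction times (linear interpolation).

    Censored observations (``inf``) are allowed only above the quantile;
    if the z-quantile is not identified the estimate is undefined.
    """
    if not 0.0 < z < 1.0:
        raise ValueError("z must lie in (0, 1)")
    times = np.sort(np.asarray(extinction_times, dtype=float))
    if times.size == 0:
        raise ValueError("no extinction times")
    pos = z * (times.size - 1)
    lo, hi = int(np.floor(pos)), int(np.ceil(pos))
    if not np.isfinite(times[hi]):
        raise ValueError(
            "the z-quantile of the extinction times is censored; "
            "run longer or lower z"
        )
    t_z = times[lo] + (pos - lo) * (times[hi] - times[lo])
    if t_z <= 0.0:
        raise ValueError("non-positive extinction quantile")
    return float(-np.log1p(-z) / t_z)
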