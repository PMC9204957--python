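"""State space and exact discrete-time jump process for within-host dynamics.

A host holds up to ``N`` microbes.  Each timestep, with probability ``tau``
the host dies; otherwise one slot (microbe or empty space) is selected by
frequency, and the selected microbe dies and is replaced — by immigration
from the environmental pool with probability ``m``, or, with probability
``1 - m``, by duplication of a resident (weight ``x_k``) or by nothing
(weight ``alpha0 * x0``), normalised by ``alpha0 * x0 + sum_k x_k``.

``transition_probabilities`` exposes the focal-taxon projection of this
chain: the seven probabilities of moving the pair ``(x_i, o_i)`` (focal
frequency, everyone else) by ``±1/N``.  ``event_distribution_multitaxon``
is the full K-taxon elementary-event distribution; its marginal onto any
focal taxon reproduces the projection exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._kernels import advance_host

__all__ = [
    "LifeHistory",
    "ColonizerPool",
    "HostState",
    "TransitionSet",
    "EventDistribution",
    "transition_probabilities",
    "event_distribution_multitaxon",
    "step_discrete",
    "simulate_host_discrete",
    "DiscreteTrajectory",
]


@dataclass(frozen=True)
class LifeHistory:
    """The five scalar parameters governing all dynamics.

    Parameters
    ----------
    m : float
        Probability that a replacement event is an immigration from the
        environmental pool, in [0, 1].
    tau : float
        Per-timestep host death probability, in [0, 1].
    alpha0 : float
        Establishment parameter (weight on empty space in the replacement
        denominator), >= 0.  Small values mean empty slots fill fast.
    N : int
        Carrying capacity: number of microbe slots per host, >= 1.
    H : int
        Number of hosts in the population, >= 2.
    """

    m: float
    tau: float
    alpha0: float
    N: int
    H: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(f"m must be in [0, 1], got {self.m}")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"tau must be in [0, 1], got {self.tau}")
        if self.alpha0 < 0.0:
            raise ValueError(f"alpha0 must be >= 0, got {self.alpha0}")
        if int(self.N) != self.N or self.N < 1:
            raise ValueError(f"N must be a positive integer, got {self.N}")
        if int(self.H) != self.H or self.H < 2:
            raise ValueError(f"H must be an integer >= 2, got {self.H}")


@dataclass(frozen=True)
class ColonizerPool:
    """Environmental pool of colonizing microbes with fixed frequencies.

    ``p`` sums to one over taxa; there is no empty-space category in the
    pool.  Lineage taxa (present in hosts, absent from the environment) are
    represented by ``p_i = 0``.
    """

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.atleast_1d(np.asarray(self.p, dtype=float))
        object.__setattr__(self, "p", p)
        if p.ndim != 1 or p.size < 1:
            raise ValueError("pool frequencies must be a non-empty 1-d vector")
        if np.any(p < 0.0) or np.any(p > 1.0):
            raise ValueError("pool frequencies must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"pool frequencies must sum to 1, got {p.sum()}")

    @property
    def n_taxa(self) -> int:
        return self.p.size


@dataclass
class HostState:
    """One host's microbiome: integer counts (discrete engine) or simplex
    frequencies (SDE engine), plus accumulated age in timesteps."""

    N: int
    counts: np.ndarray | None = None
    freqs: np.ndarray | None = None
    age: float = 0.0

    def __post_init__(self) -> None:
        if (self.counts is None) == (self.freqs is None):
            raise ValueError("exactly one of counts/freqs must be given")
        if self.counts is not None:
            c = np.atleast_1d(np.asarray(self.counts, dtype=np.int64))
            object.__setattr__(self, "counts", c)
            if np.any(c < 0):
                raise ValueError("counts must be non-negative")
            if c.sum() > self.N:
                raise ValueError("total count exceeds carrying capacity N")
        else:
            f = np.atleast_1d(np.asarray(self.freqs, dtype=float))
            object.__setattr__(self, "freqs", f)
            if np.any(f < 0.0) or f.sum() > 1.0 + 1e-12:
                raise ValueError("frequencies must be in the simplex")

    @classmethod
    def empty(cls, n_taxa: int, N: int) -> "HostState":
        return cls(N=N, counts=np.zeros(n_taxa, dtype=np.int64))

    @property
    def n_taxa(self) -> int:
        return self.counts.size if self.counts is not None else self.freqs.size

    @property
    def x(self) -> np.ndarray:
        """Per-taxon frequencies."""
        if self.freqs is not None:
            return self.freqs
        return self.counts / self.N

    @property
    def load(self) -> float:
        """Total microbial load ``sum_i x_i``."""
        return float(self.x.sum())

    @property
    def x0(self) -> float:
        """Frequency of available space, ``1 - load``."""
        return 1.0 - self.load

    def projection(self, taxon: int) -> tuple[float, float]:
        """``(x_i, o_i)`` for the focal taxon vs. everyone else."""
        x = self.x
        xi = float(x[taxon])
        return xi, float(x.sum() - xi)

    def copy(self) -> "HostState":
        return replace(
            self,
            counts=None if self.counts is None else self.counts.copy(),
            freqs=None if self.freqs is None else self.freqs.copy(),
        )


@dataclass(frozen=True)
class TransitionSet:
    """Per-step probabilities of the seven focal-projection events plus
    host death.  Entries sum to one by construction (``t_stay`` is the
    complement)."""

    t_xm_op: float  # focal -1, others +1 (replacement of focal by other)
    t_xp_om: float  # focal +1, others -1 (replacement of other by focal)
    t_op: float     # others +1 (fill of empty space by other)
    t_xp: float     # focal +1 (fill of empty space by focal)
    t_xm: float     # focal -1 (unreplaced death of focal)
    t_om: float     # others -1 (unreplaced death of other)
    t_stay: float
    t_hostdeath: float

    _ORDER = (
        "t_hostdeath", "t_xm_op", "t_xp_om", "t_op",
        "t_xp", "t_xm", "t_om", "t_stay",
    )

    def as_array(self) -> np.ndarray:
        """Probabilities in the fixed sampling order: host death first,
        then the six microbial transitions, stay last."""
        return np.array([getattr(self, k) for k in self._ORDER])

    def total(self) -> float:
        return float(self.as_array().sum())


def _transitions_xo(
    x: float, o: float, m: float, tau: float, alpha0: float, p_i: float
) -> tuple[float, float, float, float, float, float]:
    """The six microbial transition probabilities for state ``(x, o)``.

    Replication terms with zero numerator are defined as 0 even when the
    denominator vanishes (0/0 -> 0 by continuity: there is no resident to
    duplicate in an empty host).
    """
    x0 = 1.0 - x - o
    D = alpha0 * x0 + x + o
    if D > 0.0:
        rx = (1.0 - m) * x / D
        ro = (1.0 - m) * o / D
        rz = (1.0 - m) * alpha0 * x0 / D
    else:
        rx = ro = rz = 0.0
    s = 1.0 - tau
    t1a = s * x * (m * (1.0 - p_i) + ro)
    t1b = s * o * (m * p_i + rx)
    t1c = s * x0 * (m * (1.0 - p_i) + ro)
    t1d = s * x0 * (m * p_i + rx)
    t1e = s * x * rz
    t1f = s * o * rz
    return t1a, t1b, t1c, t1d, t1e, t1f


def _check_xo(x: float, o: float) -> None:
    if x < -1e-12 or o < -1e-12 or x + o > 1.0 + 1e-12:
        raise ValueError(f"state (x={x}, o={o}) outside the simplex")


def transition_probabilities(
    state: HostState | tuple[float, float],
    lh: LifeHistory,
    pool: ColonizerPool,
    taxon: int = 0,
) -> TransitionSet:
    """Seven per-step probabilities of the focal/others projection.

    ``state`` may be a :class:`HostState` or a raw ``(x_i, o_i)`` pair.
    """
    if isinstance(state, HostState):
        x, o = state.projection(taxon)
    else:
        x, o = float(state[0]), float(state[1])
    _check_xo(x, o)
    p_i = float(pool.p[taxon])
    t1a, t1b, t1c, t1d, t1e, t1f = _transitions_xo(
        x, o, lh.m, lh.tau, lh.alpha0, p_i
    )
    stay = 1.0 - t1a - t1b - t1c - t1d - t1e - t1f - lh.tau
    return TransitionSet(
        t_xm_op=t1a, t_xp_om=t1b, t_op=t1c, t_xp=t1d,
        t_xm=t1e, t_om=t1f, t_stay=stay, t_hostdeath=lh.tau,
    )


@dataclass(frozen=True)
class EventDistribution:
    """Distribution over the elementary K-taxon events of one timestep.

    ``kinds`` labels each atom: ``("hostdeath",)``, ``("replace", j, k)``
    (a taxon-j microbe dies, a taxon-k microbe takes its slot),
    ``("fill", k)`` (empty space is occupied by taxon k),
    ``("unreplaced", j)`` (a taxon-j microbe dies, its slot stays empty),
    and ``("stay",)``.  ``deltas`` holds the per-taxon count changes.
    The order is fixed: host death, replacement pairs (j ascending, k
    ascending), fills, unreplaced deaths, stay.
    """

    kinds: tuple
    probs: np.ndarray
    deltas: np.ndarray  # (n_events, K) integer count changes

    def marginal(self, taxon: int, lh: LifeHistory) -> TransitionSet:
        """Project onto (focal taxon, all others); events that change
        neither ``x_i`` nor ``o_i`` contribute to ``t_stay``."""
        acc = {k: 0.0 for k in ("a", "b", "c", "d", "e", "f")}
        stay = 0.0
        for kind, pr, d in zip(self.kinds, self.probs, self.deltas):
            if kind[0] in ("hostdeath",):
                continue
            dx = d[taxon]
            do = d.sum() - dx
            if dx < 0 and do > 0:
                acc["a"] += pr
            elif dx > 0 and do < 0:
                acc["b"] += pr
            elif dx == 0 and do > 0:
                acc["c"] += pr
            elif dx > 0 and do == 0:
                acc["d"] += pr
            elif dx < 0 and do == 0:
                acc["e"] += pr
            elif dx == 0 and do < 0:
                acc["f"] += pr
            else:
                stay += pr
        return TransitionSet(
            t_xm_op=acc["a"], t_xp_om=acc["b"], t_op=acc["c"], t_xp=acc["d"],
            t_xm=acc["e"], t_om=acc["f"], t_stay=stay, t_hostdeath=lh.tau,
        )


def event_distribution_multitaxon(
    state: HostState, lh: LifeHistory, pool: ColonizerPool
) -> EventDistribution:
    """Full elementary-event distribution for a K-taxon host state."""
    x = state.x
    K = x.size
    if K != pool.n_taxa:
        raise ValueError("state and pool disagree on the number of taxa")
    if np.any(x < -1e-12) or x.sum() > 1.0 + 1e-12:
        raise ValueError("state outside the simplex")
    x0 = 1.0 - x.sum()
    D = lh.alpha0 * x0 + x.sum()
    if D > 0.0:
        rep = (1.0 - lh.m) * x / D
        rz = (1.0 - lh.m) * lh.alpha0 * x0 / D
    else:
        rep = np.zeros(K)
        rz = 0.0
    s = 1.0 - lh.tau
    kinds: list[tuple] = [("hostdeath",)]
    probs: list[float] = [lh.tau]
    deltas: list[np.ndarray] = [np.zeros(K, dtype=np.int64)]
    for j in range(K):
        for k in range(K):
            if k == j:
                continue
            d = np.zeros(K, dtype=np.int64)
            d[j], d[k] = -1, 1
            kinds.append(("replace", j, k))
            probs.append(s * x[j] * (lh.m * pool.p[k] + rep[k]))
            deltas.append(d)
    for k in range(K):
        d = np.zeros(K, dtype=np.int64)
        d[k] = 1
        kinds.append(("fill", k))
        probs.append(s * x0 * (lh.m * pool.p[k] + rep[k]))
        deltas.append(d)
    for j in range(K):
        d = np.zeros(K, dtype=np.int64)
        d[j] = -1
        kinds.append(("unreplaced", j))
        probs.append(s * x[j] * rz)
        deltas.append(d)
    kinds.append(("stay",))
    probs.append(1.0 - sum(probs))
    deltas.append(np.zeros(K, dtype=np.int64))
    return EventDistribution(
        kinds=tuple(kinds),
        probs=np.array(probs),
        deltas=np.array(deltas, dtype=np.int64),
    )


def step_discrete(
    state: HostState,
    lh: LifeHistory,
    pool: ColonizerPool,
    rng: np.random.Generator,
) -> tuple[HostState, bool]:
    """One timestep of the jump process (reference implementation).

    Samples one elementary event by inverse CDF over the fixed event order
    (host death first, replacements, fills, unreplaced deaths, stay last).
    On host death the state is returned unchanged with the death flag set;
    handling the replacement host is the population layer's job.
    """
    if state.counts is None:
        raise ValueError("step_discrete requires an integer-count state")
    dist = event_distribution_multitaxon(state, lh, pool)
    u = rng.random()
    idx = int(np.searchsorted(np.cumsum(dist.probs), u, side="right"))
    idx = min(idx, len(dist.kinds) - 1)
    if dist.kinds[idx][0] == "hostdeath":
        return state, True
    new = state.copy()
    new.counts += dist.deltas[idx]
    new.age += 1.0
    return new, False


@dataclass
class DiscreteTrajectory:
    """Recorded single-host trajectory of the discrete engine."""

    times: np.ndarray          # step counts at which states were recorded
    counts: np.ndarray         # (n_records, K) taxon counts
    N: int                     # carrying capacity, for frequency conversion
    death_step: int | None     # step at which the host died, if it did
    peak_count0: int = 0       # maximum taxon-0 count along the way
    first_zero0: int = -1      # first step at which taxon 0 hit zero

    @property
    def loads(self) -> np.ndarray:
        """Total microbial load at each recorded time."""
        return self.counts.sum(axis=1) / self.N


def simulate_host_discrete(
    init: HostState,
    lh: LifeHistory,
    pool: ColonizerPool,
    rng: np.random.Generator,
    max_steps: int,
    record_every: int = 1,
) -> DiscreteTrajectory:
    """Simulate one host for up to ``max_steps`` timesteps.

    Host death competes as an independent geometric clock with per-step
    probability ``tau``; conditional on survival the microbial events run
    with the survival-conditioned probabilities (an exact reformulation of
    the per-step chain).  Terminates at host death or ``max_steps``.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if record_every < 1:
        raise ValueError("record_every must be >= 1")
    if init.counts is None:
        raise ValueError("the discrete engine requires integer counts")
    if init.n_taxa != pool.n_taxa:
        raise ValueError("state and pool disagree on the number of taxa")
    death_step = None
    horizon = max_steps
    if lh.tau > 0.0:
        d = int(rng.geometric(lh.tau))
        if d <= max_steps:
            death_step = d
            horizon = d - 1  # microbial events run on steps 1..d-1
    counts = init.counts.copy()
    times = [0]
    rec = [counts.copy()]
    p = np.ascontiguousarray(pool.p, dtype=np.float64)
    peak = int(counts[0])
    first_zero = -1 if counts[0] > 0 else 0
    t = 0
    while t < horizon:
        chunk = min(record_every, horizon - t)
        fz, mx = advance_host(
            counts, np.int64(chunk), lh.m, lh.alpha0, p, float(lh.N), rng
        )
        if first_zero < 0 and fz >= 0:
            first_zero = t + int(fz)
        peak = max(peak, int(mx))
        t += chunk
        times.append(t)
        rec.append(counts.copy())
    return DiscreteTrajectory(
        times=np.array(times, dtype=np.int64),
        counts=np.array(rec, dtype=np.int64),
        N=lh.N,
        death_step=death_step,
        peak_count0=peak,
        first_zero0=first_zero,
    )
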