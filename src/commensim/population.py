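"""Population of H hosts: independent within-host dynamics, host turnover,
parental splitting of microbiomes at birth, snapshot recording.

Host deaths are scheduled per host (geometric clocks in the discrete
engine, exponential in the SDE engine) and processed in global time order;
between events hosts evolve independently, so the discrete engine advances
each host lazily with the compiled kernel.  At a death the replacement
newborn is seeded by splitting the microbiome of a parent chosen uniformly
among the other ``H - 1`` hosts; microbe numbers are conserved exactly in
the discrete engine.  Same-step deaths are processed in ascending host
index (seed-reproducible).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from ._kernels import advance_host
from .inheritance import InheritanceSpec
from .model_core import ColonizerPool, LifeHistory

__all__ = [
    "PopulationConfig",
    "PopulationSnapshot",
    "BirthEvent",
    "PopulationResult",
    "run_population",
    "replace_host",
]


@dataclass(frozen=True)
class PopulationConfig:
    """Run settings for a population simulation.

    ``record_times`` must be sorted and lie within ``[0, t_max]``.
    ``pairing`` marks matched with/without-inheritance runs that share a
    seed (bookkeeping only; the caller supplies the seeds).
    """

    t_max: int
    record_times: tuple = ()
    engine: str = "discrete"
    inheritance: InheritanceSpec = field(default_factory=InheritanceSpec)
    pairing: bool = False
    log_births: bool = False

    def __post_init__(self) -> None:
        if self.engine not in ("discrete", "sde"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.t_max < 0:
            raise ValueError("t_max must be >= 0")
        rt = tuple(float(t) for t in self.record_times)
        if list(rt) != sorted(rt):
            raise ValueError("record_times must be sorted")
        if rt and (rt[0] < 0 or rt[-1] > self.t_max):
            raise ValueError("record_times must lie within [0, t_max]")
        object.__setattr__(self, "record_times", rt)


@dataclass
class PopulationSnapshot:
    """All H host states at one recording time."""

    time: float
    N: int
    counts: np.ndarray | None = None  # (H, K) integer counts, discrete engine
    freqs: np.ndarray | None = None   # (H, 2) (x_i, o_i), SDE engine
    metadata: dict = field(default_factory=dict)

    @property
    def H(self) -> int:
        arr = self.counts if self.counts is not None else self.freqs
        return arr.shape[0]

    @property
    def host_freqs(self) -> np.ndarray:
        """(H, K) per-taxon frequencies."""
        if self.freqs is not None:
            return self.freqs
        return self.counts / self.N

    @property
    def loads(self) -> np.ndarray:
        """(H,) total microbial load per host."""
        return self.host_freqs.sum(axis=1)


@dataclass
class BirthEvent:
    """Audit record of one death/birth replacement."""

    time: float
    slot: int
    parent: int
    parent_before: np.ndarray
    parent_after: np.ndarray
    newborn: np.ndarray


class PopulationResult(list):
    """List of :class:`PopulationSnapshot` with an optional birth log."""

    def __init__(self, *args, births=None):
        super().__init__(*args)
        self.births: list[BirthEvent] = births if births is not None else []


def _draw_parent(H: int, dead: int, rng: np.random.Generator) -> int:
    q = int(rng.integers(H - 1))
    return q + 1 if q >= dead else q


def _split_counts(
    parent_counts: np.ndarray,
    spec: InheritanceSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Transferred counts for a newborn; parent keeps the complement."""
    if spec.mode == "none":
        return np.zeros_like(parent_counts)
    f = rng.beta(spec.a + 1.0, spec.b + 1.0)
    return np.rint(f * parent_counts).astype(np.int64)


def replace_host(
    snapshot: PopulationSnapshot,
    dead_index: int,
    inheritance: InheritanceSpec,
    rng: np.random.Generator,
) -> PopulationSnapshot:
    """Replace one host by a newborn seeded from a random other host.

    Mutates (and returns) the snapshot; the parent's state is debited in
    place so that microbes are conserved.
    """
    H = snapshot.H
    if not 0 <= dead_index < H:
        raise ValueError("dead_index out of range")
    parent = _draw_parent(H, dead_index, rng)
    if snapshot.counts is not None:
        moved = _split_counts(snapshot.counts[parent], inheritance, rng)
        snapshot.counts[parent] -= moved
        snapshot.counts[dead_index] = moved
    else:
        if inheritance.mode == "none":
            moved = np.zeros(snapshot.freqs.shape[1])
        else:
            a = np.array([inheritance.a[0], inheritance.a[-1]])
            b = np.array([inheritance.b[0], inheritance.b[-1]])
            moved = rng.beta(a + 1.0, b + 1.0) * snapshot.freqs[parent]
        snapshot.freqs[parent] -= moved
        snapshot.freqs[dead_index] = moved
    return snapshot


def run_population(
    lh: LifeHistory,
    pool: ColonizerPool,
    cfg: PopulationConfig,
    rng: np.random.Generator,
    init_counts: np.ndarray | None = None,
) -> PopulationResult:
    """Run a population simulation and return snapshots at the recording
    times (``cfg.record_times``, or just ``t_max`` if none are given).

    Hosts start empty unless ``init_counts`` (H, K) is given (discrete
    engine).  Requires ``H >= 2`` whenever inheritance is enabled, since a
    newborn needs a parent pool.
    """
    if lh.H < 2 and cfg.inheritance.mode != "none":
        raise ValueError("inheritance requires at least two hosts")
    if cfg.inheritance.mode == "beta" and cfg.inheritance.n_taxa != (
        2 if cfg.engine == "sde" else pool.n_taxa
    ):
        if cfg.engine == "discrete":
            raise ValueError("inheritance spec length must match the pool")
    if cfg.engine == "discrete":
        return _run_discrete(lh, pool, cfg, rng, init_counts)
    return _run_sde(lh, pool, cfg, rng)


def _run_discrete(
    lh: LifeHistory,
    pool: ColonizerPool,
    cfg: PopulationConfig,
    rng: np.random.Generator,
    init_counts: np.ndarray | None,
) -> PopulationResult:
    H, K = lh.H, pool.n_taxa
    if init_counts is None:
        counts = np.zeros((H, K), dtype=np.int64)
    else:
        counts = np.array(init_counts, dtype=np.int64)
        if counts.shape != (H, K):
            raise ValueError(f"init_counts must have shape {(H, K)}")
        if np.any(counts < 0) or np.any(counts.sum(axis=1) > lh.N):
            raise ValueError("init_counts violate host invariants")
    p = np.ascontiguousarray(pool.p, dtype=np.float64)
    N = float(lh.N)
    last_sync = np.zeros(H, dtype=np.int64)
    heap: list[tuple[int, int]] = []
    if lh.tau > 0.0:
        for h in range(H):
            heapq.heappush(heap, (int(rng.geometric(lh.tau)), h))

    def advance_to(h: int, t: int) -> None:
        steps = t - last_sync[h]
        if steps > 0:
            advance_host(counts[h], np.int64(steps), lh.m, lh.alpha0, p, N, rng)
            last_sync[h] = t

    result = PopulationResult()
    record_times = cfg.record_times or (float(cfg.t_max),)
    for rt in record_times:
        rt_step = int(rt)
        while heap and heap[0][0] <= rt_step:
            d, h = heapq.heappop(heap)
            parent = _draw_parent(H, h, rng)
            advance_to(parent, d)
            before = counts[parent].copy() if cfg.log_births else None
            moved = _split_counts(counts[parent], cfg.inheritance, rng)
            counts[parent] -= moved
            counts[h] = moved
            last_sync[h] = d
            if cfg.log_births:
                result.births.append(
                    BirthEvent(
                        time=float(d), slot=h, parent=parent,
                        parent_before=before,
                        parent_after=counts[parent].copy(),
                        newborn=moved.copy(),
                    )
                )
            heapq.heappush(heap, (d + int(rng.geometric(lh.tau)), h))
        for h in range(H):
            advance_to(h, rt_step)
        result.append(
            PopulationSnapshot(
                time=float(rt_step), N=lh.N, counts=counts.copy(),
                metadata={"engine": "discrete"},
            )
        )
    return result


def _run_sde(
    lh: LifeHistory,
    pool: ColonizerPool,
    cfg: PopulationConfig,
    rng: np.random.Generator,
) -> PopulationResult:
    """Synchronous SDE population run on the (x_0, o_0) projection."""
    from .diffusion import _em_step_batch

    H = lh.H
    p_i = float(pool.p[0])
    xo = np.zeros((H, 2))
    death_times = (
        rng.exponential(1.0 / lh.tau, size=H) if lh.tau > 0 else np.full(H, np.inf)
    )
    result = PopulationResult()
    record_times = cfg.record_times or (float(cfg.t_max),)
    rt_steps = [int(t) for t in record_times]
    next_rec = 0
    snap = PopulationSnapshot(
        time=0.0, N=lh.N, freqs=xo, metadata={"engine": "sde"}
    )
    while next_rec < len(rt_steps) and rt_steps[next_rec] == 0:
        result.append(
            PopulationSnapshot(time=0.0, N=lh.N, freqs=xo.copy(),
                               metadata={"engine": "sde"})
        )
        next_rec += 1
    for t in range(1, int(cfg.t_max) + 1):
        _em_step_batch(xo, lh, p_i, 1.0, rng)
        dying = np.flatnonzero(death_times <= t)
        for h in sorted(int(i) for i in dying):
            replace_host(snap, h, cfg.inheritance, rng)
            death_times[h] = t + rng.exponential(1.0 / lh.tau)
        while next_rec < len(rt_steps) and rt_steps[next_rec] == t:
            result.append(
                PopulationSnapshot(time=float(t), N=lh.N, freqs=xo.copy(),
                                   metadata={"engine": "sde"})
            )
            next_rec += 1
    return result
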