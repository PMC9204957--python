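"""Parent-to-offspring microbiome transfer kernel.

At host birth the newborn receives, per taxon, a fraction of the parent's
microbes drawn from a beta-shaped density on [0, 1] with shape parameters
``(a_i, b_i)``: the density of the transferred fraction ``f`` is
``f**a * (1 - f)**b / B(a + 1, b + 1)``, i.e. ``Beta(a + 1, b + 1)``.
Microbe numbers are conserved: the parent keeps the exact complement.

``a < b`` skews towards non-inheritance ("low" mode, e.g. mammalian birth),
``a > b`` towards full inheritance (fragmentation), ``a == b`` concentrates
the transfer around one half ("seed-like").  With integer counts, the drawn
fraction is rounded to the nearest transferred count (ties to even) — the
single approximation of the discrete engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model_core import HostState

__all__ = [
    "InheritanceSpec",
    "transfer_density",
    "expected_inherited_fraction",
    "sample_fractions",
    "sample_inheritance",
    "make_mode_spec",
]


@dataclass(frozen=True)
class InheritanceSpec:
    """Per-taxon transfer-kernel parameters.

    ``mode`` is ``"beta"`` (transfer fractions drawn from the beta kernel)
    or ``"none"`` (newborns start microbe-free; ``a``/``b`` are ignored).
    """

    mode: str = "none"
    a: np.ndarray | None = None
    b: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("none", "beta"):
            raise ValueError(f"unknown inheritance mode {self.mode!r}")
        if self.mode == "beta":
            if self.a is None or self.b is None:
                raise ValueError("beta mode requires shape vectors a and b")
            a = np.atleast_1d(np.asarray(self.a, dtype=float))
            b = np.atleast_1d(np.asarray(self.b, dtype=float))
            if a.shape != b.shape:
                raise ValueError("a and b must have the same length")
            if np.any(a < 0.0) or np.any(b < 0.0):
                raise ValueError("shape parameters must be >= 0")
            object.__setattr__(self, "a", a)
            object.__setattr__(self, "b", b)

    @property
    def n_taxa(self) -> int | None:
        return None if self.a is None else self.a.size


def transfer_density(f, a: float, b: float):
    """Density of the transferred fraction ``f = dx_i / x_i^(p)``.

    Equals the ``Beta(a + 1, b + 1)`` density; integrates to one on [0, 1].
    """
    if a < 0.0 or b < 0.0:
        raise ValueError("shape parameters must be >= 0")
    f = np.asarray(f, dtype=float)
    if np.any(f < 0.0) or np.any(f > 1.0):
        raise ValueError("fraction outside [0, 1]")
    out = stats.beta.pdf(f, a + 1.0, b + 1.0)
    return float(out) if out.ndim == 0 else out


def expected_inherited_fraction(a: float, b: float) -> float:
    """Mean transferred fraction, ``(a + 1) / (a + b + 2)``."""
    if a < 0.0 or b < 0.0:
        raise ValueError("shape parameters must be >= 0")
    return (a + 1.0) / (a + b + 2.0)


def sample_fractions(
    a, b, rng: np.random.Generator, size=None
) -> np.ndarray | float:
    """Draw transfer fractions from the kernel, ``Beta(a + 1, b + 1)``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a < 0.0) or np.any(b < 0.0):
        raise ValueError("shape parameters must be >= 0")
    return rng.beta(a + 1.0, b + 1.0, size=size)


def sample_inheritance(
    parent: HostState,
    spec: InheritanceSpec,
    rng: np.random.Generator,
) -> tuple[HostState, HostState]:
    """Split the parent's microbiome between offspring and parent.

    Per taxon, a fraction is drawn from the transfer kernel and applied to
    the parental amount; the parent keeps the exact complement, so
    ``offspring + parent_after == parent`` holds per taxon on every draw.
    With ``mode == "none"`` the offspring is empty and the parent is
    returned unchanged.
    """
    K = parent.n_taxa
    if spec.mode == "none":
        if parent.counts is not None:
            return HostState.empty(K, parent.N), parent.copy()
        return (
            HostState(N=parent.N, freqs=np.zeros(K)),
            parent.copy(),
        )
    if spec.n_taxa not in (K,):
        raise ValueError(
            f"inheritance spec has {spec.n_taxa} taxa, parent has {K}"
        )
    f = rng.beta(spec.a + 1.0, spec.b + 1.0)
    if parent.counts is not None:
        moved = np.rint(f * parent.counts).astype(np.int64)
        off = HostState(N=parent.N, counts=moved)
        after = HostState(N=parent.N, counts=parent.counts - moved)
    else:
        moved = f * parent.freqs
        off = HostState(N=parent.N, freqs=moved)
        after = HostState(N=parent.N, freqs=parent.freqs - moved)
    return off, after


def make_mode_spec(kind: str, strength: float, taxa: int) -> InheritanceSpec:
    """Build a named inheritance regime.

    ``low``       -> a = 0, b = strength (mode at fraction 0)
    ``full``      -> a = strength, b = 0 (mode at fraction 1)
    ``seed_like`` -> a = b = strength (symmetric around one half; larger
    strength concentrates the distribution)
    """
    if strength < 0.0:
        raise ValueError("strength must be >= 0")
    if kind == "low":
        a, b = 0.0, float(strength)
    elif kind == "full":
        a, b = float(strength), 0.0
    elif kind == "seed_like":
        a = b = float(strength)
    else:
        raise ValueError(f"unknown inheritance kind {kind!r}")
    return InheritanceSpec(
        mode="beta", a=np.full(taxa, a), b=np.full(taxa, b)
    )
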