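"""Discrete S-state population dynamics of the oxygen-evolving complex.

The water-splitting cycle of photosystem II steps through four oxidation
states S0..S3 of the oxygen-evolving complex (OEC), advancing one step per
successful single-turnover flash.  Following Kok's classical
parameterization, each flash advances a center by one step with probability
1−α−β, fails to advance it ("miss", probability α), or advances it by two
steps ("double hit", probability β).  Period-4 oscillations of flash-train
observables (per-flash F₀, Fm^ST, O₂ yield) all derive from this cycle:
F₀ tracks the pre-flash S0+S1 population and Fm^ST is depressed in
proportion to the pre-flash S2+S3 population, which controls donor-side
quenching via the P680⁺/Yz(ox) equilibrium.

Weak far-red background light, which drives PSI and keeps the PQ pool
oxidized, manifests phenomenologically as a forward shift of the pre-train
S-state distribution by one step; this is modeled by a convex one-step
advancement with probability ``advance_fraction`` applied per dark interval
(and, for the long pre-train illumination, once to the initial
distribution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SStateDistribution",
    "KokParams",
    "transition_matrix",
    "advance_flash",
    "apply_background_advance",
    "flash_train_populations",
]

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class SStateDistribution:
    """Probability distribution over the OEC states S0..S3."""

    s0: float
    s1: float
    s2: float
    s3: float

    def __post_init__(self) -> None:
        v = self.as_array()
        if np.any(v < -_SUM_TOL) or np.any(v > 1 + _SUM_TOL):
            raise ValueError(f"S-state fractions must lie in [0, 1]: {v}")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"S-state fractions must sum to 1, got {v.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.s0, self.s1, self.s2, self.s3], dtype=float)

    @classmethod
    def from_array(cls, v: np.ndarray) -> "SStateDistribution":
        v = np.asarray(v, dtype=float)
        if v.shape != (4,):
            raise ValueError("expected a length-4 vector")
        return cls(*(float(x) for x in v))

    @property
    def s23(self) -> float:
        """Pre-flash S2+S3 fraction — the donor-side quenching correlate."""
        return self.s2 + self.s3

    @classmethod
    def pure(cls, i: int) -> "SStateDistribution":
        v = np.zeros(4)
        v[i] = 1.0
        return cls.from_array(v)

    @classmethod
    def uniform(cls) -> "SStateDistribution":
        return cls(0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class KokParams:
    """Per-flash miss (α), double hit (β) and per-dark-interval background
    one-step advancement probability (far-red effect)."""

    miss: float = 0.1
    double_hit: float = 0.05
    advance_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("miss", "double_hit", "advance_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {p}")
        if self.miss + self.double_hit > 1.0 + _SUM_TOL:
            raise ValueError("miss + double_hit must not exceed 1")


def transition_matrix(params: KokParams) -> np.ndarray:
    """4×4 column-stochastic single-flash transition matrix.

    Column i distributes state S_i: stay with probability α, advance one step
    (mod 4) with 1−α−β, advance two steps (mod 4) with β.
    """
    a, b = params.miss, params.double_hit
    m = np.zeros((4, 4))
    for i in range(4):
        m[i, i] += a
        m[(i + 1) % 4, i] += 1.0 - a - b
        m[(i + 2) % 4, i] += b
    return m


def advance_flash(dist: SStateDistribution, params: KokParams) -> SStateDistribution:
    """Apply one flash: matrix–vector product with the Kok transition matrix."""
    v = transition_matrix(params) @ dist.as_array()
    return SStateDistribution.from_array(v / v.sum())


def apply_background_advance(
    dist: SStateDistribution, params: KokParams
) -> SStateDistribution:
    """One-step background advancement with probability ``advance_fraction``:
    dist' = (1−f)·dist + f·shift₁(dist)."""
    f = params.advance_fraction
    v = dist.as_array()
    return SStateDistribution.from_array((1.0 - f) * v + f * np.roll(v, 1))


def flash_train_populations(
    initial: SStateDistribution, params: KokParams, n_flashes: int
) -> list[SStateDistribution]:
    """Pre-flash S-state distributions for a train of ``n_flashes`` flashes.

    Element k (0-based) is the distribution immediately before flash k+1.
    Background advancement, when configured, is applied once per dark
    interval *between* flashes; a shift accumulated during pre-train
    illumination is modeled by calling :func:`apply_background_advance` on
    the initial distribution before the train.
    """
    if n_flashes < 1:
        raise ValueError("n_flashes must be >= 1")
    out = [initial]
    d = initial
    for _ in range(n_flashes - 1):
        d = advance_flash(d, params)
        if params.advance_fraction > 0.0:
            d = apply_background_advance(d, params)
        out.append(d)
    return out
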