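"""Polyphasic (O-I₁-I₂-P) fluorescence-rise analysis and trace generation.

A saturating multiple-turnover pulse drives the fluorescence yield of a
dark-adapted sample through the characteristic levels O (origin, F₀), I₁
(end of the photochemical phase — Q_A fully reduced), I₂ (thermal phase
plateau, maximal PSII fluorescence) and P (peak, including variable PSI
fluorescence F_v(I)).  This module provides

* a phenomenological generator of such traces — a sum of three saturating
  sigmoid phases (Hill shape in time, i.e. sigmoidal on a log-time axis)
  with configurable amplitudes and half-times, used as a stand-in for
  measured multi-turnover recordings (the mechanistic PQ-pool/PSI model is
  deliberately out of scope);
* level extraction at configurable marker times (I₁ read at a fixed marker
  by default, mirroring the practice of applying a saturating probe flash
  at 1 ms);
* the O-I₁ normalization used for dual-channel F>700 / F<710 comparisons,
  whose difference curve isolates the PSI contribution F_v(I) (a lower
  bound, since the short-wavelength channel also contains some F(I));
* the intensity-reciprocity conversion between multi-turnover and flash
  rise half-times.

Level presets encode the printed dark-adapted and far-red-preilluminated
level sets (O=1, I₁=3.0, I₂=3.35, P=3.6, relaxed Fm^ST=3.2 F₀ units, and
I₁=2.6, I₂=3.65, Fm^ST=2.7 under weak FR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trace import TimeTrace

__all__ = [
    "PolyphasicLevels",
    "PolyphasicSpec",
    "PRESETS",
    "generate_polyphasic",
    "extract_levels",
    "expected_st_halftime",
    "o_i1_normalize",
]


@dataclass
class PolyphasicLevels:
    """Extracted levels (F₀ units) and their time stamps (µs)."""

    O: float
    I1: float
    I2: float
    P: float
    t_I1: float
    t_I2: float
    t_P: float
    t_half_OI1: float

    @property
    def ordered(self) -> bool:
        """Whether O ≤ I1 ≤ I2 ≤ P (violations are reported, never fixed)."""
        return self.O <= self.I1 <= self.I2 <= self.P


@dataclass(frozen=True)
class PolyphasicSpec:
    """Generator settings: levels, phase half-times, grid, noise.

    Phases are Hill sigmoids ``t²/(t² + t_half²)`` so each phase passes
    through half of its amplitude at its half-time.  Half-times must be
    ordered ascending (photochemical ≪ thermal sub-phases).
    """

    O: float = 1.0
    I1: float = 3.0
    I2: float = 3.35
    P: float = 3.6
    t_half_OI1: float = 120.0  # µs
    t_half_I1I2: float = 4000.0  # µs
    t_half_I2P: float = 100000.0  # µs
    fm_st: float = 3.2  #: relaxed flash-protocol Fm (F₀ units), for comparisons
    t_start: float = 1.0  # µs
    t_end: float = 600000.0  # µs (600 ms pulse)
    n_samples: int = 2000
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.t_half_OI1 < self.t_half_I1I2 < self.t_half_I2P:
            raise ValueError("phase half-times must be ascending")
        if self.n_samples < 10:
            raise ValueError("need at least 10 samples")


#: Printed level sets of the dark-adapted and weak-FR conditions.
PRESETS: dict[str, PolyphasicSpec] = {
    "fig7-dark": PolyphasicSpec(O=1.0, I1=3.0, I2=3.35, P=3.6, fm_st=3.2),
    "fig8-fr": PolyphasicSpec(O=1.0, I1=2.6, I2=3.65, P=3.65, fm_st=2.7),
}


def _hill(t: np.ndarray, t_half: float) -> np.ndarray:
    return t * t / (t * t + t_half * t_half)


def generate_polyphasic(spec: PolyphasicSpec) -> TimeTrace:
    """Synthesize a polyphasic rise trace on a log-spaced grid.

    Deterministic for ``noise_sd=0``; otherwise reproducible from ``seed``.
    """
    t = np.geomspace(spec.t_start, spec.t_end, spec.n_samples)
    v = (
        spec.O
        + (spec.I1 - spec.O) * _hill(t, spec.t_half_OI1)
        + (spec.I2 - spec.I1) * _hill(t, spec.t_half_I1I2)
        + (spec.P - spec.I2) * _hill(t, spec.t_half_I2P)
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        v = v + rng.normal(0.0, spec.noise_sd, size=v.size)
    meta = {
        "kind": "polyphasic",
        "units": "F0_units",
        "seed": spec.seed,
        "noise_sd": spec.noise_sd,
    }
    return TimeTrace(t, v, metadata=meta)


def extract_levels(
    trace: TimeTrace,
    t_I1: float = 1000.0,
    i2_search: tuple[float, float] = (2000.0, 30000.0),
) -> PolyphasicLevels:
    """Read O, I₁, I₂, P levels and the O-I₁ half-time from a rise trace.

    O is the first valid sample; I₁ is read at the marker time ``t_I1``
    (default 1 ms, where a saturating probe flash would be applied); I₂ is
    the minimum-slope point (on log time) within ``i2_search``; P is the
    global maximum.  ``t_half_OI1`` is the earliest time where the trace
    crosses (O+I₁)/2, linearly interpolated.
    """
    t = trace.times[trace.valid]
    v = trace.values[trace.valid]
    if t.size < 10 or t[-1] < i2_search[1]:
        raise ValueError("trace too short to span the O-I1-I2-P rise")
    O = float(v[0])
    I1 = float(np.interp(t_I1, t, v))
    sel = (t >= i2_search[0]) & (t <= i2_search[1])
    if np.count_nonzero(sel) < 3:
        raise ValueError("I2 search window contains too few samples")
    ts, vs = t[sel], v[sel]
    slope = np.gradient(vs, np.log(ts))
    k = int(np.argmin(np.abs(slope)))
    I2, t_I2 = float(vs[k]), float(ts[k])
    ip = int(np.argmax(v))
    P, t_P = float(v[ip]), float(t[ip])
    half = 0.5 * (O + I1)
    above = np.flatnonzero(v >= half)
    if above.size == 0:
        raise ValueError("trace never reaches (O+I1)/2")
    j = above[0]
    if j == 0:
        t_half = float(t[0])
    else:
        t_half = float(np.interp(half, [v[j - 1], v[j]], [t[j - 1], t[j]]))
    return PolyphasicLevels(
        O=O, I1=I1, I2=I2, P=P, t_I1=t_I1, t_I2=t_I2, t_P=t_P, t_half_OI1=t_half
    )


def expected_st_halftime(t_half_mt: float, intensity_ratio: float) -> float:
    """Flash-rise half-time expected from a multi-turnover half-time.

    Assumes intensity–time reciprocity of PSII turnover: at
    ``intensity_ratio`` times higher intensity the same closure is reached
    in ``1/intensity_ratio`` of the time.
    """
    if intensity_ratio <= 0:
        raise ValueError("intensity_ratio must be positive")
    return t_half_mt / intensity_ratio


def o_i1_normalize(
    trace_a: TimeTrace, trace_b: TimeTrace, t_I1: float = 1000.0
) -> tuple[TimeTrace, TimeTrace, TimeTrace]:
    """Affinely map both traces so O→0 and I₁→1, and form their difference.

    After equalizing the O-I₁ amplitudes (pure PSII variable fluorescence),
    all F_v(II) components of the two channels coincide and the difference
    a − b isolates the F_v(I) contribution.  The difference is evaluated on
    the grid of ``trace_a`` (``trace_b`` linearly interpolated).  Idempotent
    on already-normalized traces.
    """
    out = []
    for tr in (trace_a, trace_b):
        lv_t = tr.times[tr.valid]
        lv_v = tr.values[tr.valid]
        O = float(lv_v[0])
        I1 = float(np.interp(t_I1, lv_t, lv_v))
        if abs(I1 - O) < 1e-300:
            raise ValueError("zero O-I1 amplitude")
        norm = tr.copy()
        norm.values = (tr.values - O) / (I1 - O)
        norm.metadata.update(normalized="O-I1", o_level=O, i1_level=I1)
        out.append(norm)
    a, b = out
    diff_vals = a.values - b.interp(a.times)
    diff = TimeTrace(
        a.times.copy(),
        diff_vals,
        a.valid.copy(),
        {"kind": "fv1_difference", "units": "O-I1_units"},
    )
    return a, b, diff
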