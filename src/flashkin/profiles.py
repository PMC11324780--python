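"""Synthetic flash intensity profiles (single, twin) and fluence arithmetic.

The LED single-turnover flash is close to rectangular: the rising edge
reaches half-maximal intensity at 0.3 µs and full intensity at 0.9 µs, the
plateau is flat to better than 10⁻³, and the pulse is jitter-free.  The
profile generator reproduces these anchors exactly with a two-segment
piecewise-linear rise (a single exponential cannot reach full intensity at
finite time); the fall edge mirrors the rise.  Generated profiles stand in
for blank-sample stray-light reference recordings used by the
profile-correction routines.

Intensities are handled in relative units (fraction of the maximal lamp
intensity) with an optional absolute scale in µmol quanta m⁻² s⁻¹; the
maximal lamp intensity is 1.3 mol 440 nm quanta m⁻² s⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.constants import Avogadro

from .trace import TimeTrace

__all__ = [
    "MAX_INTENSITY_UMOL",
    "FlashSpec",
    "TwinSpec",
    "profile_value",
    "make_st_profile",
    "make_twin_profile",
    "fluence",
]

#: Maximal lamp intensity, µmol quanta m⁻² s⁻¹ (1.3 mol quanta m⁻² s⁻¹).
MAX_INTENSITY_UMOL = 1.3e6

#: Default digitizer sampling interval, µs (40 MHz).
DEFAULT_SAMPLING_US = 0.025


@dataclass(frozen=True)
class FlashSpec:
    """Single flash: nominal width, intensity and rise-edge anchors.

    ``intensity`` is relative (fraction of maximal lamp intensity).  The
    absolute plateau intensity is ``intensity * max_intensity_umol``.
    ``rectangle=True`` selects the idealized zero-risetime rectangle used
    for fluence arithmetic.
    """

    width: float = 40.0  # µs
    intensity: float = 1.0  # relative, fraction of maximum
    t_half_rise: float = 0.3  # µs
    t_full_rise: float = 0.9  # µs
    start_time: float = 0.0  # µs
    max_intensity_umol: float = MAX_INTENSITY_UMOL
    rectangle: bool = False

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ValueError("intensity must be positive")
        if not self.rectangle:
            if not 0.0 < self.t_half_rise < self.t_full_rise:
                raise ValueError("need 0 < t_half_rise < t_full_rise")
            if self.t_full_rise >= self.width:
                raise ValueError("rise must complete before nominal width")
        if self.width <= 0:
            raise ValueError("width must be positive")

    @property
    def plateau_umol(self) -> float:
        return self.intensity * self.max_intensity_umol

    @property
    def end_time(self) -> float:
        """Time at which the profile returns to zero."""
        if self.rectangle:
            return self.start_time + self.width
        return self.start_time + self.width + self.t_full_rise


@dataclass(frozen=True)
class TwinSpec:
    """Pump/probe flash pair separated by a dark gap (ST#2 may be attenuated)."""

    st1: FlashSpec
    st2: FlashSpec
    dark_gap: float = 20.0  # µs

    def __post_init__(self) -> None:
        if self.dark_gap < 0:
            raise ValueError("dark_gap must be >= 0")
        st2 = self.resolved_st2()
        if st2.start_time < self.st1.end_time + self.dark_gap - 1e-12:
            raise ValueError("ST#2 must start after ST#1 ends plus the dark gap")

    def resolved_st2(self) -> FlashSpec:
        """ST#2 with its start time anchored after ST#1 + gap if unset (0)."""
        if self.st2.start_time == 0.0:
            return replace(self.st2, start_time=self.st1.end_time + self.dark_gap)
        return self.st2

    @property
    def st2_start(self) -> float:
        return self.resolved_st2().start_time


def profile_value(spec: FlashSpec, t: np.ndarray) -> np.ndarray:
    """Continuous profile in *relative* intensity units, evaluated at ``t`` (µs).

    Piecewise linear: 0→0.5·I over [0, t_half_rise], 0.5·I→I over
    [t_half_rise, t_full_rise], plateau to ``width``, mirrored fall.
    """
    t = np.asarray(t, dtype=float)
    s = t - spec.start_time
    I = spec.intensity
    if spec.rectangle:
        return np.where((s >= 0) & (s < spec.width), I, 0.0)
    th, tf, w = spec.t_half_rise, spec.t_full_rise, spec.width

    def rise(x: np.ndarray) -> np.ndarray:
        r = np.where(
            x < th,
            0.5 * I * x / th,
            0.5 * I + 0.5 * I * (x - th) / (tf - th),
        )
        return np.clip(r, 0.0, I)

    out = np.zeros_like(s)
    up = (s >= 0) & (s < tf)
    out[up] = rise(s[up])
    flat = (s >= tf) & (s <= w)
    out[flat] = I
    down = (s > w) & (s < w + tf)
    out[down] = rise(w + tf - s[down])
    return out


def _grid(t0: float, t1: float, dt: float) -> np.ndarray:
    n = int(np.ceil((t1 - t0) / dt - 1e-9)) + 1
    return t0 + dt * np.arange(n + 1)


def make_st_profile(
    spec: FlashSpec,
    sampling_interval: float = DEFAULT_SAMPLING_US,
    absolute: bool = False,
) -> TimeTrace:
    """Sample a single-flash profile on a uniform grid starting at t=0.

    With ``absolute=True`` values are in µmol quanta m⁻² s⁻¹, otherwise in
    relative intensity units.  The grid covers the flash plus one rise time
    of trailing zero.
    """
    if not spec.rectangle and sampling_interval > spec.t_half_rise / 3 + 1e-12:
        raise ValueError("sampling_interval must be <= t_half_rise / 3")
    t = _grid(0.0, spec.end_time + spec.t_full_rise if not spec.rectangle else spec.end_time,
              sampling_interval)
    v = profile_value(spec, t)
    if absolute:
        v = v * spec.max_intensity_umol
    meta = {
        "kind": "profile",
        "units": "umol_quanta_m-2_s-1" if absolute else "relative",
        "sampling_interval_us": sampling_interval,
    }
    return TimeTrace(t, v, metadata=meta)


def make_twin_profile(
    spec: TwinSpec,
    sampling_interval: float = DEFAULT_SAMPLING_US,
    absolute: bool = False,
) -> TimeTrace:
    """Sample a twin-flash profile (two flashes, zero intensity in the gap)."""
    st1, st2 = spec.st1, spec.resolved_st2()
    for f in (st1, st2):
        if not f.rectangle and sampling_interval > f.t_half_rise / 3 + 1e-12:
            raise ValueError("sampling_interval must be <= t_half_rise / 3")
    if st2.start_time < st1.end_time - 1e-12:
        raise ValueError("flashes overlap")
    t_end = st2.end_time + (0.0 if st2.rectangle else st2.t_full_rise)
    t = _grid(0.0, t_end, sampling_interval)
    v = profile_value(st1, t) + profile_value(st2, t)
    if absolute:
        # attenuation is carried by the relative intensity; absolute scale shared
        v = v * st1.max_intensity_umol
    meta = {
        "kind": "twin_profile",
        "units": "umol_quanta_m-2_s-1" if absolute else "relative",
        "sampling_interval_us": sampling_interval,
        "st2_start_us": st2.start_time,
        "gap_us": spec.dark_gap,
    }
    return TimeTrace(t, v, metadata=meta)


def fluence(spec: FlashSpec, per_cm2: bool = True) -> float:
    """Photon fluence of one flash in quanta cm⁻² (or quanta m⁻²).

    Time integral of the absolute intensity profile converted from
    µmol quanta m⁻² to quanta; for the idealized rectangle this is
    plateau_intensity × width.
    """
    if spec.rectangle:
        integral_umol_us = spec.plateau_umol * spec.width
    else:
        # exact integral of the piecewise-linear profile:
        # rise and fall each contribute (t_half/2 + (t_full−t_half)·3/4) ... do it
        # analytically per segment to avoid quadrature error.
        th, tf, w, I = spec.t_half_rise, spec.t_full_rise, spec.width, spec.plateau_umol
        edge = 0.5 * 0.5 * I * th + 0.5 * (0.5 * I + I) * (tf - th)
        integral_umol_us = 2.0 * edge + I * (w - tf)
    mol_per_m2 = integral_umol_us * 1e-6 * 1e-6  # µmol→mol, µs→s
    quanta_per_m2 = mol_per_m2 * Avogadro
    return quanta_per_m2 / 1e4 if per_cm2 else quanta_per_m2
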