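"""Time-trace container shared by all modules.

A :class:`TimeTrace` holds a sampled signal on a strictly increasing time grid
(microseconds).  It is used both for flash intensity profiles (values in
µmol quanta m⁻² s⁻¹ or relative units) and for fluorescence yield traces
(values in F₀-normalized relative yield units).  A per-sample validity mask
supports masking of samples that cannot be interpreted (e.g. below the
profile-correction threshold, or inside the dark gap of a twin flash).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeTrace"]


@dataclass
class TimeTrace:
    """Uniform- or nonuniform-grid time series.

    Parameters
    ----------
    times
        Sample times in µs, strictly increasing.
    values
        Sample values (units recorded in ``metadata``).
    valid
        Boolean mask, one flag per sample.  Invalid samples carry no
        information; their values are kept for round-tripping but must not be
        used in analysis.
    metadata
        Free-form key/value annotations (sampling interval, channel label,
        normalization factors, generator seed, ...).
    """

    times: np.ndarray
    values: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.times.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if self.times.shape != self.values.shape or self.times.shape != self.valid.shape:
            raise ValueError("times, values and valid mask must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("values must be finite wherever the valid mask is set")

    def __len__(self) -> int:
        return self.times.size

    def copy(self) -> "TimeTrace":
        return TimeTrace(
            self.times.copy(), self.values.copy(), self.valid.copy(), dict(self.metadata)
        )

    def window_mean(self, t_lo: float, t_hi: float) -> float:
        """Mean of valid samples with ``t_lo <= t <= t_hi``.

        Raises if the window contains no valid sample.
        """
        sel = (self.times >= t_lo) & (self.times <= t_hi)
        if not np.any(sel):
            raise ValueError(f"window [{t_lo}, {t_hi}] µs contains no samples")
        if not np.all(self.valid[sel]):
            raise ValueError(f"window [{t_lo}, {t_hi}] µs contains invalid samples")
        return float(np.mean(self.values[sel]))

    def interp(self, t: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of the valid part of the trace."""
        tv = self.times[self.valid]
        vv = self.values[self.valid]
        if tv.size == 0:
            raise ValueError("trace has no valid samples")
        return np.interp(t, tv, vv)

    def same_grid(self, other: "TimeTrace", rtol: float = 0.0, atol: float = 1e-12) -> bool:
        return self.times.shape == other.times.shape and np.allclose(
            self.times, other.times, rtol=rtol, atol=atol
        )
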