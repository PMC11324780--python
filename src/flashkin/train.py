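"""Interval analysis of flash-train recordings and Kok-model fitting.

Each flash of a train yields one kinetics trace; averaging over an early
window (t₁, during the rise, default 0.9–1.2 µs) gives the per-flash F₀ and
over a late window (t₂, near flash-off, default 18–20 µs) the per-flash
F^ST.  Plotting both against the flash number reveals the period-4
oscillation driven by the S-state cycle: F₀ rises and F^ST falls with the
pre-flash S2+S3 population.

``fit_kok`` inverts this relationship: it fits

    F₀(n)  = b0 + b1·(s2+s3)ₙ
    F^ST(n) = c0 − c1·(s2+s3)ₙ

with the pre-flash (s2+s3)ₙ sequence generated by the Kok transition model,
estimating the miss (α) and double-hit (β) probabilities, the initial
S-state distribution (softmax-reparameterized simplex) and the four yield
coefficients.  The linear coefficients are profiled out analytically (with
the physical sign constraints b1, c1 ≥ 0), leaving a 5-parameter bounded
nonlinear problem solved by multi-start least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .kok import KokParams, SStateDistribution
from .trace import TimeTrace

__all__ = [
    "IntervalSpec",
    "TrainAnalysisResult",
    "KokFitResult",
    "interval_analysis",
    "oscillation_amplitude",
    "fit_kok",
    "s23_sequence",
]


@dataclass(frozen=True)
class IntervalSpec:
    """Assessment windows (µs): t₁ for F₀, t₂ for F^ST."""

    t1_window: tuple[float, float] = (0.9, 1.2)
    t2_window: tuple[float, float] = (18.0, 20.0)

    def __post_init__(self) -> None:
        if not (self.t1_window[0] < self.t1_window[1] <= self.t2_window[0] < self.t2_window[1]):
            raise ValueError("need t1 before t2 and both windows non-degenerate")


def _local_extrema(series: np.ndarray, sign: int) -> list[int]:
    """1-based positions of strict local maxima (sign=+1) or minima (−1)."""
    s = sign * np.asarray(series, dtype=float)
    out = []
    n = s.size
    for i in range(n):
        left = s[i - 1] if i > 0 else -np.inf
        right = s[i + 1] if i < n - 1 else -np.inf
        if s[i] > left and s[i] > right:
            out.append(i + 1)
    return out


@dataclass
class TrainAnalysisResult:
    """Per-flash yield metrics of a flash train (all series flash-ordered)."""

    f0: np.ndarray
    f_st: np.ndarray
    difference: np.ndarray
    f_st_maxima: list[int] = field(default_factory=list)
    f_st_minima: list[int] = field(default_factory=list)
    f0_maxima: list[int] = field(default_factory=list)
    f0_minima: list[int] = field(default_factory=list)
    amplitude_1_3: float | None = None
    fit: "KokFitResult | None" = None

    @property
    def n_flashes(self) -> int:
        return len(self.f0)


def interval_analysis(
    traces: list[TimeTrace], spec: IntervalSpec = IntervalSpec()
) -> TrainAnalysisResult:
    """Per-flash window means and period-4 oscillation metrics."""
    f0 = np.empty(len(traces))
    f_st = np.empty(len(traces))
    for k, tr in enumerate(traces):
        try:
            f0[k] = tr.window_mean(*spec.t1_window)
            f_st[k] = tr.window_mean(*spec.t2_window)
        except ValueError as exc:
            raise ValueError(f"flash {k + 1}: {exc}") from exc
    res = TrainAnalysisResult(
        f0=f0,
        f_st=f_st,
        difference=f_st - f0,
        f_st_maxima=_local_extrema(f_st, +1),
        f_st_minima=_local_extrema(f_st, -1),
        f0_maxima=_local_extrema(f0, +1),
        f0_minima=_local_extrema(f0, -1),
    )
    if len(traces) >= 4:
        res.amplitude_1_3 = float(f_st[0] - f_st[2])
    return res


def oscillation_amplitude(result: TrainAnalysisResult, a: int, b: int) -> float:
    """F^ST difference between flashes ``a`` and ``b`` (1-based)."""
    n = result.n_flashes
    if not (1 <= a <= n and 1 <= b <= n):
        raise IndexError(f"flash indices must lie in 1..{n}")
    return float(result.f_st[a - 1] - result.f_st[b - 1])


# ---------------------------------------------------------------------------
# Kok fitting


def s23_sequence(alpha: float, beta: float, initial: np.ndarray, n: int) -> np.ndarray:
    """Pre-flash S2+S3 sequence of a flash train (fast array version)."""
    m = np.zeros((4, 4))
    for i in range(4):
        m[i, i] += alpha
        m[(i + 1) % 4, i] += 1.0 - alpha - beta
        m[(i + 2) % 4, i] += beta
    d = np.asarray(initial, dtype=float)
    out = np.empty(n)
    for k in range(n):
        out[k] = d[2] + d[3]
        d = m @ d
    return out


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = np.concatenate([[0.0], logits])
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _profiled_linear(x: np.ndarray, y: np.ndarray, slope_sign: int) -> tuple[float, float, np.ndarray]:
    """Least-squares intercept/slope of y ≈ a + s·b·x with b ≥ 0, s=±1.

    Returns (a, b, residuals); if the unconstrained slope has the wrong
    sign, it is clamped to zero (intercept = mean).
    """
    xs = slope_sign * x
    vx = xs - xs.mean()
    denom = float(vx @ vx)
    if denom < 1e-300:
        a = float(y.mean())
        return a, 0.0, y - a
    b = float(vx @ (y - y.mean())) / denom
    if b < 0.0:
        a = float(y.mean())
        return a, 0.0, y - a
    a = float(y.mean() - b * xs.mean())
    return a, b, y - (a + b * xs)


_ALT_MODE = np.array([1.0, -1.0, 1.0, -1.0])
_UNIFORM = np.full(4, 0.25)


def _canonical_initial(d: np.ndarray) -> np.ndarray:
    """Extremal representative of the fit-degenerate family containing ``d``.

    Two directions leave the predicted (s2+s3) sequence invariant for every
    (α, β): admixture of the uniform distribution (the Kok fixed point;
    rescales the oscillation, absorbed by the free linear coefficients) and
    the alternating mode [1,−1,1,−1] (an eigenvector of the circulant
    transition matrix orthogonal to the s2+s3 observable).  Among the 2-D
    polygon of equivalent distributions inside the simplex, return the one
    farthest from uniform (a vertex; the oscillation-phase sign is kept).
    """
    x = d - _UNIFORM
    t0 = float(x @ _ALT_MODE) / 4.0
    r = x - t0 * _ALT_MODE  # visible oscillation direction
    if float(r @ r) < 1e-24:
        return d
    # family: d(s, t) = uniform + s·r + t·alt, s >= 0, d >= 0
    lines = [(r[i], _ALT_MODE[i], 0.25) for i in range(4)]  # a·s + b·t + c >= 0
    lines.append((1.0, 0.0, 0.0))  # s >= 0
    best_pt = (1.0, t0)
    best_val = float(r @ r) + 4.0 * t0 * t0
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            a1, b1_, c1_ = lines[i]
            a2, b2_, c2_ = lines[j]
            det = a1 * b2_ - a2 * b1_
            if abs(det) < 1e-14:
                continue
            s = (-c1_ * b2_ + c2_ * b1_) / det
            t = (-a1 * c2_ + a2 * c1_) / det
            if s < -1e-12:
                continue
            if any(a * s + b * t + c < -1e-9 for a, b, c in lines):
                continue
            val = s * s * float(r @ r) + 4.0 * t * t
            if val > best_val + 1e-12:
                best_val = val
                best_pt = (s, t)
    s, t = best_pt
    out = _UNIFORM + s * r + t * _ALT_MODE
    out = np.clip(out, 0.0, None)
    return out / out.sum()


@dataclass
class KokFitResult:
    """Fitted Kok parameters, initial S-state distribution and yield maps."""

    params: KokParams
    initial: SStateDistribution
    b0: float
    b1: float
    c0: float
    c1: float
    residual_norm: float
    non_identifiable: bool = False
    covariance: np.ndarray | None = None  #: Gauss–Newton (JᵀJ)⁻¹ proxy for (α, β, logits)


def fit_kok(
    f0_series: np.ndarray,
    f_st_series: np.ndarray,
    mode: str = "joint",
    n_restarts: int = 10,
    seed: int = 0,
    bounds_alpha: tuple[float, float] = (0.0, 0.5),
    bounds_beta: tuple[float, float] = (0.0, 0.5),
) -> KokFitResult:
    """Fit the Kok model to per-flash F₀ and F^ST series.

    Parameters
    ----------
    mode
        ``"joint"`` (default) fits both series simultaneously; ``"f0"`` or
        ``"fst"`` fit only the respective series.
    n_restarts
        Number of seeded random restarts of the bounded least-squares solve.

    A series pair with (numerically) zero variance carries no oscillation
    information; the result is flagged ``non_identifiable``.

    Because the yield maps carry free intercepts, the initial distribution
    is only determined up to admixture of the uniform distribution (the
    fixed point of the Kok transition, whose s2+s3 is constant): mixing
    with uniform rescales the oscillation, which the linear coefficients
    absorb exactly.  The fit therefore reports the extremal representative
    of this degenerate family — the distribution pushed away from uniform
    until one component reaches zero — with the linear coefficients
    rescaled accordingly (predictions are unchanged).  α and β are not
    affected by the degeneracy.
    """
    f0 = np.asarray(f0_series, dtype=float)
    fst = np.asarray(f_st_series, dtype=float)
    if f0.shape != fst.shape or f0.ndim != 1:
        raise ValueError("f0 and f_st series must be equal-length 1-d arrays")
    n = f0.size
    if n < 4:
        raise ValueError("need at least 4 flashes to fit the Kok model")
    if mode not in ("joint", "f0", "fst"):
        raise ValueError(f"unknown mode {mode!r}")

    if np.std(f0) < 1e-12 * max(1.0, abs(f0).max()) and np.std(fst) < 1e-12 * max(
        1.0, abs(fst).max()
    ):
        return KokFitResult(
            params=KokParams(0.0, 0.0),
            initial=SStateDistribution.uniform(),
            b0=float(f0.mean()),
            b1=0.0,
            c0=float(fst.mean()),
            c1=0.0,
            residual_norm=float(
                np.sqrt(np.sum((f0 - f0.mean()) ** 2) + np.sum((fst - fst.mean()) ** 2))
            ),
            non_identifiable=True,
        )

    def residual(z: np.ndarray) -> np.ndarray:
        alpha, beta = z[0], z[1]
        init = _softmax(z[2:5])
        x = s23_sequence(alpha, beta, init, n)
        parts = []
        if mode in ("joint", "f0"):
            _, _, r0 = _profiled_linear(x, f0, +1)
            parts.append(r0)
        if mode in ("joint", "fst"):
            _, _, r1 = _profiled_linear(x, fst, -1)
            parts.append(r1)
        return np.concatenate(parts)

    rng = np.random.default_rng(seed)
    lo = np.array([bounds_alpha[0], bounds_beta[0], -10.0, -10.0, -10.0])
    hi = np.array([bounds_alpha[1], bounds_beta[1], 10.0, 10.0, 10.0])
    starts = [np.array([0.1, 0.05, 0.0, 0.0, 0.0])]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(
            np.concatenate(
                [
                    rng.uniform([0.0, 0.0], [0.3, 0.15]),
                    rng.normal(0.0, 2.0, size=3),
                ]
            )
        )
    best = None
    for z0 in starts:
        sol = least_squares(residual, z0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None
    z = best.x
    alpha, beta = float(z[0]), float(z[1])
    init = _canonical_initial(_softmax(z[2:5]))
    x = s23_sequence(alpha, beta, init, n)
    b0, b1, _ = _profiled_linear(x, f0, +1)
    c0, c1neg, _ = _profiled_linear(x, fst, -1)
    r = residual(z)
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.pinv(jtj) * (float(r @ r) / max(1, r.size - z.size))
    except np.linalg.LinAlgError:  # pragma: no cover
        cov = None
    return KokFitResult(
        params=KokParams(miss=alpha, double_hit=beta),
        initial=SStateDistribution.from_array(init),
        b0=b0,
        b1=b1,
        c0=c0,
        c1=c1neg,
        residual_norm=float(np.linalg.norm(r)),
        non_identifiable=False,
        covariance=cov,
    )
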