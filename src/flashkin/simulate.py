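"""Continuous-time simulation of PSII fluorescence yield during and after flashes.

Model
-----
The fluorescence yield of a PSII ensemble is controlled by three factors:

* **Photochemical quenching by open centers.**  The fraction of closed
  centers (Q_A reduced) is ``B``.  Excitonic connectivity between PSII units
  is described by the Joliot hyperbola ``v(B) = (1−p)·B / (1 − p·B)`` with
  connectivity parameter ``p``: an exciton reaching a closed center can
  escape to a neighboring open one, so variable fluorescence rises
  hyperbolically with closure and the closure rate of the remaining open
  centers is enhanced by ``1/(1−p·B)``.

* **Carotenoid-triplet quenching (TQ).**  Strong flashes populate carotenoid
  triplets that quench singlet excitons; occupancy ``T`` builds with light
  intensity and decays within a few µs after flash-off.

* **Donor-side quenching (DQ).**  Charge separation leaves P680⁺ in
  equilibrium with Yz(ox); P680⁺ quenches fluorescence until the
  oxygen-evolving complex reduces Yz(ox), which takes the S-state transition
  half-times 30 µs (S0→S1), 70 µs (S1→S2), 190 µs (S2→S3) and 1300 µs
  (S3→S0).  A cohort hit in pre-flash state S_i acquires an equilibrium
  quencher amplitude ``d_i`` (increasing with i, since higher S-states shift
  the Yz(ox)/P680⁺ equilibrium towards the quencher) that relaxes
  mono-exponentially with the half-time of its S_i→S_{i+1} transition.

TQ and DQ combine multiplicatively as independent Stern–Volmer factors:

    F = [f0_eff + (fm − f0)·v(B)] / [(1 + k_T·T)(1 + k_D·⟨D⟩)]

with ``f0_eff = f0·(1 + δ_F0·(s2+s3)_preflash)`` (the local field of stored
donor-side charges slightly raises F₀) and ⟨D⟩ the population-weighted
donor-quencher occupancy.  The composite of TQ and DQ during strong flashes
is the "high-intensity quenching" (HIQ) seen as a dip in the rise kinetics.

State equations (time in µs, intensity I(t) in µmol quanta m⁻² s⁻¹):

    dB/dt  = σ·I·(1−B)/(1−p·B) − B/τ_QA − B·⟨D⟩/τ_rec
    dT/dt  = σ_T·I·(1−T) − T/τ_T
    dE/dt  = I                             (accrued fluence)
    dU_i/dt = s_i·σ·I·e^{−σE} − ln2/τ_i·U_i  (per-cohort hit bookkeeping)

with per-flash hit probability 1−e^{−σE} and ⟨D⟩ = Σ_i d_i·U_i.  Q_A⁻
reoxidation (τ_QA) is blocked by DCMU; recombination of Q_A⁻ with P680⁺
(τ_rec) proceeds only while the donor quencher persists.  Within one flash
at most one donor-side advancement per center is booked; double hits are
handled at the discrete Kok level between flashes.

Integration is explicit fixed-step RK4 on the profile grid with automatic
sub-stepping whenever the fastest local rate times the step exceeds 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .kok import KokParams, SStateDistribution, advance_flash, apply_background_advance
from .profiles import FlashSpec, TwinSpec, make_st_profile, make_twin_profile, profile_value
from .trace import TimeTrace

__all__ = [
    "TQParams",
    "DQParams",
    "SimConfig",
    "KineticState",
    "TwinResult",
    "TrainResult",
    "SaturationResult",
    "yield_from_state",
    "simulate_stk",
    "simulate_twin",
    "simulate_train",
    "simulate_pump_probe_saturation",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class TQParams:
    """Carotenoid-triplet quenching: formation coefficient (per µmol m⁻² s⁻¹
    per µs), decay time (µs, e-folding) and Stern–Volmer coefficient."""

    sigma_T: float = 3.85e-7
    tau_T: float = 5.0
    k_sv_T: float = 1.0


@dataclass(frozen=True)
class DQParams:
    """Donor-side quenching: equilibrium quencher amplitude per pre-flash
    S-state, Stern–Volmer coefficient, and the S-state transition half-times
    (µs) that govern relaxation."""

    d: tuple[float, float, float, float] = (0.05, 0.15, 0.35, 0.6)
    k_sv_D: float = 1.0
    tau_S: tuple[float, float, float, float] = (30.0, 70.0, 190.0, 1300.0)

    def __post_init__(self) -> None:
        if any(x < 0 for x in self.d) or any(np.diff(self.d) < 0):
            raise ValueError("quencher amplitudes d must be non-negative and non-decreasing")
        if any(t <= 0 for t in self.tau_S):
            raise ValueError("relaxation half-times must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Full kinetic parameter set of the PSII flash-response model."""

    sigma_psii: float = 2.56e-6  # hit rate per (µmol m⁻² s⁻¹), µs⁻¹
    connectivity_p: float = 0.3
    f0_base: float = 1.0
    fm_base: float = 3.6
    tq: TQParams = field(default_factory=TQParams)
    dq: DQParams = field(default_factory=DQParams)
    tau_QA: float = 300.0  # µs, Q_A⁻ → Q_B forward reoxidation
    tau_rec: float | None = 150.0  # µs, recombination; None disables
    dcmu: bool = False  # blocks forward reoxidation
    delta_f0: float = 0.1  # F₀ sensitivity to pre-flash S2+S3

    def __post_init__(self) -> None:
        if not 0.0 <= self.connectivity_p < 1.0:
            raise ValueError("connectivity_p must lie in [0, 1)")
        if self.sigma_psii <= 0 or self.tau_QA <= 0 or self.tq.tau_T <= 0:
            raise ValueError("rates and times must be positive")
        if self.f0_base <= 0 or self.fm_base <= self.f0_base:
            raise ValueError("need 0 < f0_base < fm_base")
        if self.tau_rec is not None and self.tau_rec <= 0:
            raise ValueError("tau_rec must be positive or None")

    def hiq_off(self) -> "SimConfig":
        """Variant with TQ and DQ (and recombination) switched off."""
        return replace(
            self,
            tq=replace(self.tq, sigma_T=0.0),
            dq=replace(self.dq, d=(0.0, 0.0, 0.0, 0.0)),
            tau_rec=None,
            delta_f0=0.0,
        )


@dataclass
class KineticState:
    """Instantaneous ensemble state.

    ``D`` holds per-cohort amplitude-weighted donor-quencher occupancies
    (cohort i = centers that were in S_i before the flash); ⟨D⟩ = sum(D).
    """

    B: float
    T: float
    D: np.ndarray
    s_dist: SStateDistribution
    preflash_s23: float | None = None

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.preflash_s23 is None:
            self.preflash_s23 = self.s_dist.s23

    @property
    def mean_D(self) -> float:
        return float(np.sum(self.D))


def connectivity_v(B: float | np.ndarray, p: float) -> float | np.ndarray:
    """Joliot hyperbola: relative variable-fluorescence weight of closure B."""
    return (1.0 - p) * B / (1.0 - p * B)


def yield_from_state(state: KineticState, config: SimConfig) -> float:
    """Relative fluorescence yield of an ensemble state (F₀ units)."""
    f0_eff = config.f0_base * (1.0 + config.delta_f0 * state.preflash_s23)
    fv = config.fm_base - config.f0_base
    num = f0_eff + fv * connectivity_v(state.B, config.connectivity_p)
    den = (1.0 + config.tq.k_sv_T * state.T) * (1.0 + config.dq.k_sv_D * state.mean_D)
    return float(num / den)


# ---------------------------------------------------------------------------
# integrator


def _rhs(y: np.ndarray, I: float, s: np.ndarray, cfg: SimConfig, k_relax: np.ndarray) -> np.ndarray:
    B, T, E = y[0], y[1], y[2]
    U = y[3:7]
    sig_I = cfg.sigma_psii * I
    dB = sig_I * (1.0 - B) / (1.0 - cfg.connectivity_p * B)
    if not cfg.dcmu:
        dB -= B / cfg.tau_QA
    if cfg.tau_rec is not None:
        dB -= B * float(np.dot(cfg.dq.d, U)) / cfg.tau_rec
    dT = cfg.tq.sigma_T * I * (1.0 - T) - T / cfg.tq.tau_T
    dE = I
    dU = s * sig_I * math.exp(-cfg.sigma_psii * E) - k_relax * U
    out = np.empty(7)
    out[0], out[1], out[2] = dB, dT, dE
    out[3:7] = dU
    return out


def _integrate(
    times: np.ndarray,
    intensity: np.ndarray,
    s: np.ndarray,
    cfg: SimConfig,
    y0: np.ndarray | None = None,
) -> np.ndarray:
    """RK4 over the given grid; returns state array (len(times), 7).

    ``intensity`` is the flash intensity sampled on ``times``; within a step
    I(t) is interpolated linearly.  Sub-steps are inserted whenever the
    fastest local rate × step exceeds 0.05.
    """
    k_relax = LN2 / np.asarray(cfg.dq.tau_S, dtype=float)
    y = np.zeros(7) if y0 is None else np.array(y0, dtype=float)
    out = np.empty((times.size, 7))
    out[0] = y
    k_max_relax = float(np.max(k_relax))
    for i in range(times.size - 1):
        dt = times[i + 1] - times[i]
        I0, I1 = intensity[i], intensity[i + 1]
        rate = max(
            cfg.sigma_psii * max(I0, I1),
            cfg.tq.sigma_T * max(I0, I1) + 1.0 / cfg.tq.tau_T,
            k_max_relax,
        )
        m = max(1, int(math.ceil(rate * dt / 0.05)))
        h = dt / m
        for j in range(m):
            Ia = I0 + (I1 - I0) * (j / m)
            Im = I0 + (I1 - I0) * ((j + 0.5) / m)
            Ib = I0 + (I1 - I0) * ((j + 1) / m)
            k1 = _rhs(y, Ia, s, cfg, k_relax)
            k2 = _rhs(y + 0.5 * h * k1, Im, s, cfg, k_relax)
            k3 = _rhs(y + 0.5 * h * k2, Im, s, cfg, k_relax)
            k4 = _rhs(y + h * k3, Ib, s, cfg, k_relax)
            y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(y)):
            raise FloatingPointError(
                f"integration diverged at t={times[i + 1]:.4g} µs "
                f"(state {y!r}); reduce the step size"
            )
        out[i + 1] = y
    return out


def _yields(states: np.ndarray, s23_pre: float, cfg: SimConfig) -> np.ndarray:
    f0_eff = cfg.f0_base * (1.0 + cfg.delta_f0 * s23_pre)
    fv = cfg.fm_base - cfg.f0_base
    B = states[:, 0]
    T = states[:, 1]
    D = states[:, 3:7] @ np.asarray(cfg.dq.d, dtype=float)
    num = f0_eff + fv * connectivity_v(B, cfg.connectivity_p)
    den = (1.0 + cfg.tq.k_sv_T * T) * (1.0 + cfg.dq.k_sv_D * D)
    return num / den


def _sim_grid(profile: TimeTrace, t_end: float, tail_dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Profile grid, extended to t_end with coarser uniform sampling."""
    t = profile.times
    I = profile.values
    if t_end > t[-1] + 1e-12:
        n = max(2, int(math.ceil((t_end - t[-1]) / tail_dt)))
        ext = np.linspace(t[-1], t_end, n + 1)[1:]
        t = np.concatenate([t, ext])
        I = np.concatenate([I, np.zeros(ext.size)])
    return t, I


def simulate_stk(
    profile: TimeTrace,
    initial: SStateDistribution,
    config: SimConfig,
    t_end: float | None = None,
    tail_dt: float = 0.25,
    y0: np.ndarray | None = None,
) -> TimeTrace:
    """Fluorescence yield during (and optionally after) one flash.

    ``profile`` must carry absolute intensity (µmol quanta m⁻² s⁻¹) on its
    grid; the returned trace holds relative yield in F₀ units on the same
    grid, extended to ``t_end`` with step ``tail_dt`` after flash-off.
    """
    if t_end is None:
        t_end = profile.times[-1]
    t, I = _sim_grid(profile, t_end, tail_dt)
    states = _integrate(t, I, initial.as_array(), config, y0=y0)
    F = _yields(states, initial.s23, config)
    meta = {
        "kind": "fluorescence",
        "units": "F0_units",
        "preflash_s23": initial.s23,
    }
    return TimeTrace(t, F, metadata=meta)


@dataclass
class TwinResult:
    """Outcome of a twin-flash (pump/probe) simulation."""

    trace: TimeTrace
    f0: float  #: yield at t=0 (dark, open centers)
    f_end_st1: float  #: yield at end of ST#1 (HIQ-depressed)
    f_i_st2: float  #: initial yield of ST#2 — the "relaxed Fm^ST"

    @property
    def hiq_fraction(self) -> float:
        """Fraction of F_v suppressed by rapidly reversible HIQ at ST#1-off."""
        return (self.f_i_st2 - self.f_end_st1) / (self.f_i_st2 - self.f0)


def simulate_twin(
    twin: TwinSpec,
    initial: SStateDistribution,
    config: SimConfig,
    sampling_interval: float = 0.025,
    t_end: float | None = None,
) -> TwinResult:
    """Simulate a twin-flash recording and extract the relaxed Fm^ST.

    ``f_i_st2`` is the yield at ST#2 onset: with the dark gap exceeding the
    TQ decay time, it reflects the closed-center yield still modulated by
    slowly relaxing donor-side quenching.
    """
    profile = make_twin_profile(twin, sampling_interval, absolute=True)
    trace = simulate_stk(profile, initial, config, t_end=t_end)
    st1 = twin.st1
    t_on_end = st1.start_time + st1.width  # end of ST#1 plateau
    t_st2 = twin.st2_start
    F = trace.values
    f0 = float(F[0])
    f_end_st1 = float(np.interp(t_on_end, trace.times, F))
    f_i_st2 = float(np.interp(t_st2, trace.times, F))
    return TwinResult(trace=trace, f0=f0, f_end_st1=f_end_st1, f_i_st2=f_i_st2)


@dataclass
class TrainResult:
    """Per-flash traces and pre-flash S-state distributions of a flash train."""

    traces: list[TimeTrace]
    pre_states: list[SStateDistribution]


def simulate_train(
    n_flashes: int,
    repetition_time_ms: float,
    flash_spec: FlashSpec,
    initial: SStateDistribution,
    config: SimConfig,
    kok: KokParams,
    sampling_interval: float = 0.025,
) -> TrainResult:
    """Simulate a train of identical flashes separated by long dark intervals.

    Between flashes the repetition time (100–200 ms) is long against all TQ,
    DQ and Q_A reopening times, so the photochemical and quencher state is
    fully reset; only the S-state distribution carries over, advancing
    through the Kok transition (plus optional background advancement per
    dark interval).
    """
    if repetition_time_ms * 1000.0 <= flash_spec.width:
        raise ValueError("repetition time must exceed the flash width")
    if n_flashes < 1:
        raise ValueError("n_flashes must be >= 1")
    profile = make_st_profile(flash_spec, sampling_interval, absolute=True)
    traces: list[TimeTrace] = []
    pre_states: list[SStateDistribution] = []
    d = initial
    for k in range(n_flashes):
        pre_states.append(d)
        tr = simulate_stk(profile, d, config)
        tr.metadata["flash_number"] = k + 1
        traces.append(tr)
        d = advance_flash(d, kok)
        if kok.advance_fraction > 0.0:
            d = apply_background_advance(d, kok)
    return TrainResult(traces=traces, pre_states=pre_states)


@dataclass
class SaturationResult:
    """Pump–probe saturation curve: probe-time F_v versus pump intensity."""

    intensities: np.ndarray  #: relative pump intensities
    fluences: np.ndarray  #: pump fluences, (µmol m⁻² s⁻¹)·µs
    fv: np.ndarray  #: ST-induced yield increase at the probe time
    fv_max: float

    @property
    def fv_rel(self) -> np.ndarray:
        return self.fv / self.fv_max


def simulate_pump_probe_saturation(
    intensities: list[float] | np.ndarray,
    config: SimConfig,
    mode: str = "fixed-width",
    width: float = 3.0,
    probe_delay: float = 1000.0,
    sampling_interval: float = 0.025,
    flash_spec: FlashSpec | None = None,
    initial: SStateDistribution | None = None,
) -> SaturationResult:
    """Saturation curve of flash-induced variable fluorescence.

    For each pump intensity a flash is simulated (fixed width, or width
    scaled inversely with intensity in ``fixed-fluence`` mode) and F_v is
    read ``probe_delay`` µs after flash-off, when TQ and DQ have relaxed.
    Reopening during the delay is suppressed by running with DCMU (the
    recommended protocol); the curve is monotone non-decreasing in
    intensity.
    """
    intensities = np.asarray(intensities, dtype=float)
    if intensities.size == 0:
        raise ValueError("intensity list must not be empty")
    if mode not in ("fixed-width", "fixed-fluence"):
        raise ValueError(f"unknown mode {mode!r}")
    if initial is None:
        initial = SStateDistribution.pure(1)
    base = flash_spec if flash_spec is not None else FlashSpec(
        width=width, intensity=1.0, rectangle=True
    )
    i_ref = float(np.max(intensities))
    fvs = np.empty(intensities.size)
    flus = np.empty(intensities.size)
    for j, rel in enumerate(intensities):
        w = base.width if mode == "fixed-width" else base.width * i_ref / rel
        spec = replace(base, intensity=rel, width=w)
        profile = make_st_profile(spec, sampling_interval, absolute=True)
        t_probe = spec.end_time + probe_delay
        trace = simulate_stk(profile, initial, config, t_end=t_probe)
        f0 = trace.values[0]
        fvs[j] = float(trace.values[-1]) - f0
        flus[j] = float(np.trapezoid(profile.values, profile.times))
    # reference maximum: fully closed, relaxed
    st = KineticState(B=1.0, T=0.0, D=np.zeros(4), s_dist=initial)
    fv_max = yield_from_state(st, config) - yield_from_state(
        KineticState(B=0.0, T=0.0, D=np.zeros(4), s_dist=initial), config
    )
    return SaturationResult(intensities=intensities, fluences=flus, fv=fvs, fv_max=fv_max)
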