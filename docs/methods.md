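# Methods

## Scope

`flashkin` couples a discrete model of the oxygen-evolving complex (OEC)
S-state cycle to a continuous-time model of PSII fluorescence yield during
and after single-turnover flashes (ST), and implements the data-reduction
procedures used with such measurements: instrument-profile correction,
twin-flash (pump/probe) analysis, flash-train interval analysis with
Kok-model fitting, and polyphasic (O-I₁-I₂-P) level extraction on the PAM
side.  All test inputs are produced by the package's own generators; no
measured data ship with the package.

## Discrete S-state dynamics

States S₀..S₃ of the OEC; one flash advances a center by one step with
probability 1−α−β, by two steps with β (double hit), or not at all with α
(miss).  The transition matrix is circulant and column-stochastic; the
uniform distribution is its fixed point, and for 0<α<1 every trajectory
damps towards it, which is what limits the number of resolvable period-4
oscillations.  Double hits advance exactly two steps (no higher orders),
and S-state deactivation (S₂,S₃→S₁ over seconds) is omitted: the 100–200 ms
repetition times modeled here are short against deactivation.

Weak far-red (FR) background light preferentially drives PSI, oxidizes the
plastoquinone pool and phenomenologically advances the pre-train S-state
distribution by one step.  This is modeled as a convex one-step shift with
probability `advance_fraction` per dark interval.  Two regimes matter:

* the long pre-train illumination accumulates into an essentially complete
  shift — modeled by applying the shift once to the initial distribution
  (`apply_background_advance`), which moves the second F_m^ST maximum from
  flash 5 to flash 4;
* within a train, the per-interval probability at the intensities modeled
  (~1 PSII turnover per 40 s against 100–200 ms intervals) is of order
  10⁻³–10⁻² and barely perturbs the pattern.  `flash_train_populations`
  applies it per interval when configured.

A default dark-adapted state of 100% S₁ is a configuration choice, not a
claim about predawn samples; any initial distribution can be supplied.

## Flash profiles

The LED flash is modeled as a two-segment piecewise-linear rise (0→50% of
plateau over 0–0.3 µs, 50→100% over 0.3–0.9 µs), a flat plateau to the
nominal width, and a mirrored fall.  The two-segment form is chosen
because it reproduces both rise anchors exactly; a single exponential
cannot reach full intensity at finite time.  Electronics jitter and
intensity fluctuation (<10⁻³ in the modeled instrument class) are treated
as zero.  The default sampling interval is 0.025 µs (a 40 MHz digitizer).
Maximal lamp intensity is 1.3 mol 440 nm quanta m⁻² s⁻¹; fluence is the
exact analytic time integral of the profile (or intensity × width for the
idealized rectangle used in equal-fluence protocols).

## Continuous-time yield model

State variables: closed fraction `B` (Q_A⁻), triplet-quencher occupancy
`T`, accrued fluence `E`, and per-cohort donor-quencher occupancies `U_i`
(cohort i = centers in pre-flash state S_i).  With intensity `I(t)`:

    dB/dt  = σ·I·(1−B)/(1−p·B) − B/τ_QA − B·⟨D⟩/τ_rec
    dT/dt  = σ_T·I·(1−T) − T/τ_T
    dU_i/dt = s_i·σ·I·e^{−σE} − (ln2/τ_i)·U_i,   ⟨D⟩ = Σ_i d_i·U_i

    F = [f₀·(1+δ·(s₂+s₃)_pre) + (f_m−f₀)·v(B)] / [(1+k_T·T)(1+k_D·⟨D⟩)]

Modeling choices:

* **Quencher combination.** TQ and DQ multiply as independent Stern–Volmer
  factors; the literature treats HIQ as a composite of the two without a
  combination law, and independence is the simplest assumption.
* **Connectivity.** The Joliot hyperbola `v(B)=(1−p)B/(1−pB)`; sigmoidal
  saturation curves follow from the enhanced closure rate `1/(1−pB)`.
* **Hit statistics.** Per-flash hit probability `1−e^{−σE}`; within one
  flash at most one donor-side advancement per center is booked (double
  hits are handled at the discrete Kok level).  At twin-flash time scales a
  single charge separation per PSII is a good approximation.
* **DQ kinetics.** A cohort hit in S_i acquires amplitude `d_i` and decays
  mono-exponentially with the half-time of its S_i→S_{i+1} transition
  (30/70/190/1300 µs).  `d_i` increase with i because higher S-states shift
  the Yz(ox)/P680⁺ equilibrium towards the quencher.
* **Recombination.** Q_A⁻ recombines with the donor side only while the
  donor quencher persists, at rate `⟨D⟩/τ_rec`; `tau_rec=None` disables it.
  The `dcmu` flag disables forward reoxidation only.  "Q_A reoxidation
  disabled" protocols (pump–probe saturation curves, twin relaxation
  scans) set both.

### Parameter defaults (units, rationale)

| parameter | default | unit | rationale |
|---|---|---|---|
| σ (`sigma_psii`) | 2.56×10⁻⁶ | µs⁻¹ per µmol m⁻²s⁻¹ | 95% closure by a 3 µs flash at 30% of maximal intensity |
| `connectivity_p` | 0.3 | — | typical inter-unit connectivity in vivo |
| `f0_base`, `fm_base` | 1.0, 3.6 | F₀ units | dark F₀ and relaxed multi-turnover F_m |
| `sigma_T` | 3.85×10⁻⁷ | µs⁻¹ per µmol m⁻²s⁻¹ | gives strong TQ (T≈0.5) at maximal flash intensity |
| `tau_T` | 5 | µs | TQ largely relaxed within 20 µs after flash-off |
| `k_sv_T`, `k_sv_D` | 1.0 | — | free Stern–Volmer scales |
| `d` | (0.05, 0.15, 0.35, 0.6) | — | monotone with S-state; oscillation amplitudes of a few tenths of F₀ |
| `tau_S` | (30, 70, 190, 1300) | µs | S-state transition half-times |
| `tau_QA` | 300 | µs | Q_A⁻→Q_B forward reoxidation |
| `tau_rec` | 150 | µs | recombination when the donor side is still oxidized |
| `delta_f0` | 0.1 | — | F₀ increase with stored donor-side charges (magnitude unreported; order chosen to reproduce visible F₀ oscillations) |

σ_T, the Stern–Volmer coefficients, `d_i`, `tau_QA` and `delta_f0` are
free parameters of the model (not quantified in the underlying
literature); the defaults above are documented choices, fixed once.

### Integration

Explicit fixed-step RK4 on the profile grid (intensity interpolated
linearly within steps), with automatic sub-stepping whenever the fastest
local rate times the step exceeds 0.05.  After flash-off the grid is
extended with a 0.25 µs default step.  Halving the step changes reported
yields by <10⁻⁴ relative (tested); non-finite states raise a diagnostic
error.  The simulator is fully deterministic; randomness enters only
through explicitly seeded generators in fixtures and noise models.

## Profile correction

A raw in-flash recording is the product of yield and the flash profile.
Correction divides by a reference trace (blank-sample stray light or a
synthetic profile) normalized to its plateau, wherever the reference
exceeds `threshold` (default 15%) of the plateau; other samples are masked
rather than extrapolated, so with the default anchors the earliest valid
yield sample is at 0.09 µs.  Plateau normalization (rather than unit-max)
makes the correction yield-preserving on the plateau.  The plateau is the
mean over a user-set window when given; the default estimator is the
median of the ≥95%-of-maximum region, which is exact on a flat plateau and
robust to edge samples and overshoot.  Twin recordings are corrected per
flash segment with per-segment plateaus (handling an attenuated probe
flash); gap samples are masked.  Reference resampling, when needed, is
linear and must round-trip the identity test.

## Flash-train analysis and Kok fitting

Per-flash F₀ and F^ST are window means (defaults t₁ = 0.9–1.2 µs,
t₂ = 18–20 µs, following the caption values of the train protocol; the
body-text variant 0.9–1.5 µs is available through `IntervalSpec`).  The
fit model is F₀(n)=b0+b1·x_n, F^ST(n)=c0−c1·x_n with x_n the pre-flash
S₂+S₃ sequence of the Kok model.  The linear coefficients are profiled out
analytically under the physical sign constraints b1,c1 ≥ 0, leaving a
bounded 5-parameter problem (α, β and softmax logits of the initial
distribution) solved by multi-start least squares (10 seeded restarts).
Joint fitting of both series is the default; single-series modes are
provided.  Series without oscillation variance are flagged
non-identifiable.

**Identifiability convention.**  With free intercepts, the initial
distribution is determined only up to (i) admixture of the uniform
distribution, which rescales the oscillation and is absorbed exactly by
the linear coefficients, and (ii) the alternating mode [1,−1,1,−1], an
eigenvector of the circulant transition matrix that is orthogonal to the
S₂+S₃ observable at every flash.  The fit reports the extremal
representative of this two-parameter family — the distribution farthest
from uniform within the simplex (keeping the oscillation-phase sign) —
which coincides with the truth for boundary distributions such as 100% S₁
or the FR-shifted 100% S₂.  Interior truths are mapped to their extremal
representative; α and β are unaffected by the degeneracy.

## Polyphasic analysis

The generator is a sum of three Hill-shaped phases `t²/(t²+t½²)`
(sigmoidal on a log-time axis) with amplitudes (O→I₁, I₁→I₂, I₂→P) and
ascending half-times (defaults 120 µs, 4 ms, 100 ms on a log grid to
600 ms), plus optional seeded Gaussian noise.  No mechanistic PQ-pool/PSI
model is attempted; the functional form is a phenomenological stand-in
whose only job is to place the levels and half-times where configured
(each phase passes through half its amplitude at its half-time by
construction).

Extraction reads O at the first valid sample, I₁ at a fixed 1 ms marker
(mirroring the practice of applying a saturating probe flash there), I₂ at
the minimum-slope point between 2 and 30 ms, P as the global maximum, and
the O-I₁ half-time as the earliest interpolated crossing of (O+I₁)/2.
Level ordering violations are reported, never silently fixed.  The
generate→extract closure is within 1% per level for the noiseless default
presets.

O-I₁ normalization maps each channel affinely so O→0, I₁→1; after
equalizing the O-I₁ amplitudes the PSII variable-fluorescence components
coincide and the channel difference isolates F_v(I).  Because the
short-wavelength channel also contains some PSI fluorescence, the
recovered amplitude is a lower bound; no correction factor is applied.

The intensity-reciprocity helper converts a multi-turnover rise half-time
to the expected flash-rise half-time by simple division (t½/ratio),
making the reciprocity assumption explicit.

## Synthetic data versus real recordings

The generators emulate: rectangular flashes with the 0.3/0.9 µs rise
anchors, F₀-normalized yields between ~1 and ~3.6 F₀ units, period-4 flash
train patterns, twin-flash recordings with attenuated probe flashes, and
polyphasic rises with configurable level sets.  They do **not** emulate:
detector/amplifier impulse response, glass-luminescence artefacts,
Q_B-site heterogeneity ("inactive PSII"), state transitions,
chlororespiration, or PSI acceptor-side kinetics.  Passing tests therefore
demonstrate correctness of the algorithms on model-faithful inputs, not
robustness to every instrumental artefact of real recordings.

## Problem sizes

The shipped analyses use desk-scale sizes chosen for the package's test
cycle: 8–14-flash trains, 11-point twin dark-gap scans (10–500 µs),
8–12-point saturation curves, 50-replicate noise studies, and 0.025–0.05 µs
integration grids.  All scale linearly if larger runs are needed.

## Known limitations

* The linear (s₂+s₃) yield proxy used by the Kok fit is an approximation
  to the full kinetic model; fitting simulated kinetics (rather than
  proxy-generated series) biases α downward by a few hundredths.
* Whether the default model reproduces a common crossing point of
  superimposed train traces in the early microseconds is an emergent
  property, reported by simulation, not asserted.
* The twin-relaxation half-time recovered by a mono-exponential fit is
  biased by a few percent (Stern–Volmer curvature upward, residual TQ at
  the shortest gaps downward); recovery is within ±10% under the standard
  saturating-flash protocol.
* Only the (s₂+s₃) correlate enters the yield maps; per-state weights are
  deliberately not fitted.
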