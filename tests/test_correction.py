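"""Profile correction by reference division, masking and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flashkin import (
    CorrectionConfig,
    FlashSpec,
    TimeTrace,
    TwinSpec,
    make_st_profile,
    make_twin_profile,
    normalize_f0,
    profile_correct,
    twin_profile_correct,
)


def synthetic_yield(times, tau=3.0):
    return 1.0 + 2.0 * (1.0 - np.exp(-times / tau))


class TestProfileCorrect:
    def test_ideal_rectangle_reference_is_identity(self):
        t = np.arange(0, 10, 0.05)
        raw = TimeTrace(t, synthetic_yield(t))
        ref = TimeTrace(t, np.ones_like(t))
        out = profile_correct(raw, ref)
        assert np.allclose(out.values, raw.values)
        assert np.all(out.valid)

    def test_multiply_then_divide_recovers_yield(self):
        """Correction is the exact inverse of profile multiplication."""
        ref = make_st_profile(FlashSpec(width=10.0, intensity=1.0), 0.01)
        y = synthetic_yield(ref.times)
        raw = TimeTrace(ref.times, y * ref.values)
        out = profile_correct(raw, ref, CorrectionConfig(threshold=0.15))
        rel = np.abs(out.values[out.valid] / y[out.valid] - 1.0)
        assert rel.max() < 1e-10

    def test_first_valid_sample_at_threshold_crossing(self):
        """Rise crosses 15% of plateau at 0.3·(0.15/0.5) = 0.09 µs."""
        ref = make_st_profile(FlashSpec(width=10.0, intensity=1.0), 0.01)
        raw = TimeTrace(ref.times, ref.values.copy())
        out = profile_correct(raw, ref, CorrectionConfig(threshold=0.15))
        assert out.times[out.valid][0] == pytest.approx(0.09, abs=1e-12)

    def test_valid_region_grows_as_threshold_decreases(self):
        ref = make_st_profile(FlashSpec(width=10.0, intensity=1.0), 0.01)
        raw = TimeTrace(ref.times, ref.values.copy())
        counts = [
            np.count_nonzero(profile_correct(raw, ref, CorrectionConfig(threshold=th)).valid)
            for th in (0.5, 0.3, 0.15, 0.05)
        ]
        assert counts == sorted(counts)

    def test_grid_mismatch_rejected(self):
        t = np.arange(0, 10, 0.05)
        raw = TimeTrace(t, np.ones_like(t))
        ref = TimeTrace(t + 0.01, np.ones_like(t))
        with pytest.raises(ValueError):
            profile_correct(raw, ref)

    def test_zero_plateau_rejected(self):
        t = np.arange(0, 10, 0.05)
        raw = TimeTrace(t, np.ones_like(t))
        ref = TimeTrace(t, np.zeros_like(t))
        with pytest.raises(ValueError):
            profile_correct(raw, ref)


class TestTwinCorrect:
    @pytest.fixture
    def twin(self):
        return TwinSpec(
            st1=FlashSpec(width=10.0, intensity=1.0),
            st2=FlashSpec(width=10.0, intensity=0.2),
            dark_gap=20.0,
        )

    def test_recovery_with_attenuated_second_flash(self, twin):
        ref = make_twin_profile(twin, 0.01)
        y = synthetic_yield(ref.times, tau=5.0)
        raw = ref.copy()
        plateaus = np.where(ref.times < twin.st2_start, 1.0, 0.2)
        raw.values = y * ref.values / plateaus
        out = twin_profile_correct(raw, ref, CorrectionConfig(threshold=0.15))
        rel = np.abs(out.values[out.valid] / y[out.valid] - 1.0)
        assert rel.max() < 1e-10

    def test_equal_yields_map_to_equal_corrected_plateaus(self, twin):
        """Constant yield through both flashes corrects to the same level."""
        ref = make_twin_profile(twin, 0.01)
        raw = ref.copy()
        raw.values = 2.5 * ref.values / np.where(ref.times < twin.st2_start, 1.0, 0.2)
        out = twin_profile_correct(raw, ref)
        seg1 = out.valid & (ref.times > 2) & (ref.times < 9)
        seg2 = out.valid & (ref.times > twin.st2_start + 2) & (ref.times < twin.st2_start + 9)
        assert np.allclose(out.values[seg1], 2.5)
        assert np.allclose(out.values[seg2], 2.5)

    def test_gap_samples_masked(self, twin):
        ref = make_twin_profile(twin, 0.01)
        raw = ref.copy()
        out = twin_profile_correct(raw, ref)
        gap = (ref.times > twin.st1.end_time + 0.01) & (ref.times < twin.st2_start - 0.01)
        assert not out.valid[gap].any()

    def test_single_flash_reference_rejected(self):
        ref = make_st_profile(FlashSpec(width=10.0), 0.01)
        raw = ref.copy()
        with pytest.raises(ValueError):
            twin_profile_correct(raw, ref)


class TestNormalizeF0:
    def test_constant_trace_becomes_ones(self):
        t = np.arange(0, 10, 0.1)
        tr = TimeTrace(t, np.full_like(t, 3.7))
        out = normalize_f0(tr, (0.0, 2.0))
        assert np.allclose(out.values, 1.0)
        assert out.metadata["f0_norm_factor"] == pytest.approx(3.7)

    def test_idempotent(self):
        t = np.arange(0, 10, 0.1)
        tr = TimeTrace(t, 2.0 + t)
        once = normalize_f0(tr, (0.0, 1.0))
        twice = normalize_f0(once, (0.0, 1.0))
        assert np.allclose(once.values / once.values[0], twice.values / twice.values[0])
        # normalizing an already-normalized trace changes it only marginally
        assert np.allclose(twice.values, once.values / np.mean(once.values[t <= 1.0]))

    def test_empty_window_rejected(self):
        t = np.arange(0, 10, 0.1)
        tr = TimeTrace(t, np.ones_like(t))
        with pytest.raises(ValueError):
            normalize_f0(tr, (20.0, 30.0))


@given(scale=st.floats(0.1, 50.0))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_correction_commutes_with_rescaling(scale):
    ref = make_st_profile(FlashSpec(width=10.0, intensity=1.0), 0.05)
    y = synthetic_yield(ref.times)
    raw = TimeTrace(ref.times, y * ref.values)
    raw_scaled = TimeTrace(ref.times, scale * y * ref.values)
    a = profile_correct(raw, ref)
    b = profile_correct(raw_scaled, ref)
    assert np.allclose(b.values[b.valid], scale * a.values[a.valid], rtol=1e-12)
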