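"""Percent-length profiles, cubic interpolation, and Trabecular Extent."""

import numpy as np
import pandas as pd
import pytest

from osteoslice import (MorphProfile, SpecimenFrame, ValidationError,
                        build_profile, difference_profile, percent_grid,
                        trabecular_extent)

L = 36.81
VOX = 0.00689


def make_frame(n_slices=2400):
    return SpecimenFrame(distal_end_slice=n_slices - 1, bone_length_mm=L,
                         voxel_size_mm=VOX, n_slices=n_slices,
                         slice_axis_direction="distal_increasing")


def metrics_table(frame, fn, lo=60.0, hi=100.0):
    pct = frame.percent_array()
    keep = (pct >= lo) & (pct <= hi)
    idx = np.flatnonzero(keep)
    return pd.DataFrame({
        "slice": idx,
        "percent_length": pct[idx],
        "ba_ta": fn(pct[idx]),
    })


class TestBuildProfile:
    def test_constant_distribution_reproduced_exactly(self):
        frame = make_frame()
        table = metrics_table(frame, lambda p: np.full_like(p, 5.0))
        prof = build_profile(table, frame, "ba_ta", percent_grid(60, 100))
        assert np.allclose(prof.values, 5.0)

    def test_cubic_reproduces_linear_to_1e9(self):
        frame = make_frame()
        table = metrics_table(frame, lambda p: 0.3 * p - 7.0)
        grid = percent_grid(60, 100)
        prof = build_profile(table, frame, "ba_ta", grid)
        assert np.allclose(prof.values, 0.3 * grid - 7.0, atol=1e-9)

    def test_sinusoid_interpolated_below_1e3_of_amplitude(self):
        frame = make_frame()
        amp = 2.5
        fn = lambda p: amp * np.sin(p / 3.0)
        table = metrics_table(frame, fn)
        grid = percent_grid(60, 100)
        prof = build_profile(table, frame, "ba_ta", grid)
        assert np.abs(prof.values - fn(grid)).max() < 1e-3 * amp

    def test_grid_value_at_native_position_matches_native_sample(self):
        frame = make_frame()
        rng = np.random.default_rng(4)
        table = metrics_table(frame, lambda p: rng.random(p.shape))
        native = table.percent_length.to_numpy()[100:104]
        prof = build_profile(table, frame, "ba_ta",
                             np.sort(native))
        expected = table.ba_ta.to_numpy()[100:104]
        assert np.allclose(np.sort(prof.values), np.sort(expected), atol=1e-9)

    def test_out_of_range_grid_is_an_error_not_extrapolation(self):
        frame = make_frame()
        table = metrics_table(frame, lambda p: p, lo=60, hi=90)
        with pytest.raises(ValidationError, match="extrapolation"):
            build_profile(table, frame, "ba_ta", percent_grid(60, 100))

    def test_profile_invariants_enforced(self):
        with pytest.raises(ValidationError):
            MorphProfile("x", [60, 59, 61], [1, 2, 3])
        with pytest.raises(ValidationError):
            MorphProfile("x", [60, 61, 63], [1, 2, 3])  # non-uniform
        with pytest.raises(ValidationError):
            MorphProfile("x", [60, 61], [1, np.nan])


def linear_ba_ta(pct, top=0.40, at=91.0, zero_at=71.0):
    """0.40 at 91% falling linearly to 0 at 71%, clipped outside."""
    v = top * (pct - zero_at) / (at - zero_at)
    return np.clip(v, 0.0, top)


class TestTrabecularExtent:
    def test_linear_profile_hand_solution(self):
        # crossing of 0.30 at 86%: Tb.E30 = 5% of L; of 0 at 71%: 20% of L
        frame = make_frame()
        pct = frame.percent_array()
        keep = (pct >= 60) & (pct <= 91)
        pct = pct[keep]
        tbe = trabecular_extent(pct, linear_ba_ta(pct), frame, 91.0)
        step_mm = VOX  # one native slice step
        assert tbe.tbe_mm[0.30] == pytest.approx(1.8405, abs=step_mm)
        assert tbe.tbe_mm[0.0] == pytest.approx(7.362, abs=step_mm)
        assert not tbe.censored[0.30]

    def test_constant_profile_censored_at_full_range(self):
        frame = make_frame()
        pct = frame.percent_array()
        keep = (pct >= 60) & (pct <= 91)
        pct = pct[keep]
        tbe = trabecular_extent(pct, np.full_like(pct, 0.5), frame, 91.0)
        assert tbe.censored[0.30]
        assert tbe.tbe_mm[0.30] == pytest.approx((91 - pct.min()) / 100 * L, rel=1e-6)

    def test_threshold_above_reference_value_gives_zero_with_flag(self):
        frame = make_frame()
        pct = np.linspace(91, 60, 200)
        val = np.full_like(pct, 0.2)
        val[50:] = 0.0
        tbe = trabecular_extent(pct, val, frame, 91.0)
        assert tbe.tbe_mm[0.30] == 0.0
        assert tbe.censored[0.30]
        assert tbe.tbe_mm[0.10] > 0

    def test_extent_non_decreasing_across_default_thresholds(self):
        frame = make_frame()
        rng = np.random.default_rng(5)
        for _ in range(100):
            # random monotone-decreasing profile over [60, 91]
            pct = np.linspace(91, 60, 300)
            drops = rng.random(300)
            val = 0.45 * np.cumsum(drops[::-1])[::-1] / drops.sum()
            tbe = trabecular_extent(pct, val, frame, 91.0)
            e = [tbe.tbe_mm[t] for t in (0.30, 0.20, 0.10, 0.0)]
            assert all(b >= a - 1e-12 for a, b in zip(e, e[1:]))

    def test_first_occurrence_matches_brute_force_scan_on_wiggly_profiles(self):
        """Non-monotone profiles: crossing = first bracketing pair from the
        reference, verified against an index-scan oracle."""
        frame = make_frame()
        rng = np.random.default_rng(6)
        for _ in range(30):
            pct = np.linspace(91, 60, 250)
            val = np.clip(0.35 + np.cumsum(rng.normal(0, 0.02, 250)), 0, 1)
            thr = 0.25
            tbe = trabecular_extent(pct, val, frame, 91.0, thresholds=(thr,))
            # oracle: first i with val[i] <= thr, linear interp from i-1
            idx = np.flatnonzero(val <= thr)
            if idx.size == 0:
                assert tbe.censored[thr]
            elif idx[0] == 0:
                assert tbe.tbe_mm[thr] == 0.0
            else:
                i = idx[0]
                f = (val[i - 1] - thr) / (val[i - 1] - val[i])
                crossing = pct[i - 1] + f * (pct[i] - pct[i - 1])
                assert tbe.tbe_mm[thr] == pytest.approx(
                    (91.0 - crossing) / 100 * L, abs=1e-9)

    def test_mm_and_percent_terms_convert_by_L_over_100(self):
        frame = make_frame()
        pct = np.linspace(91, 60, 400)
        tbe = trabecular_extent(pct, linear_ba_ta(pct), frame, 91.0)
        crossing_pct = 91.0 - tbe.tbe_mm[0.30] / (L / 100.0)
        assert crossing_pct == pytest.approx(86.0, abs=0.1)

    def test_abs_extent_at_least_extent_at_zero_threshold(self):
        frame = make_frame()
        pct = np.linspace(91, 60, 400)
        val = linear_ba_ta(pct)
        val[-40:] = 0.02  # isolated distal remnant beyond the first zero
        tbe = trabecular_extent(pct, val, frame, 91.0)
        assert tbe.tbe_abs_mm >= tbe.tbe_mm[0.0] - 1e-12


class TestDifferenceProfile:
    def grid_profiles(self, values_list, name="ba_ta"):
        grid = percent_grid(60, 100)
        return [MorphProfile(name, grid, v) for v in values_list]

    def test_identical_groups_zero_difference(self):
        grid = percent_grid(60, 100)
        a = self.grid_profiles([np.linspace(0, 1, grid.size)] * 3)
        df = difference_profile(a, a)
        assert np.allclose(df["diff"], 0.0)

    def test_constant_shift_recovered(self):
        grid = percent_grid(60, 100)
        base = np.linspace(0.2, 0.8, grid.size)
        a = self.grid_profiles([base, base + 0.02])
        b = self.grid_profiles([base - 0.1, base - 0.08])
        df = difference_profile(a, b)
        assert np.allclose(df["diff"], 0.1)
        assert (df["sign"] == "positive").all()

    def test_grid_mismatch_rejected(self):
        a = [MorphProfile("x", percent_grid(60, 100), np.zeros(41))]
        b = [MorphProfile("x", percent_grid(40, 80), np.zeros(41))]
        with pytest.raises(ValidationError):
            difference_profile(a, b)

    def test_banded_deficit_localized_in_band(self):
        from osteoslice import PhantomSpec, simulate_groups

        sim = simulate_groups(
            PhantomSpec(), effects={"ct_ar_2d": [(60.0, 70.0, 0.80)]},
            n_per_group=8, noise_cv=0.02, seed=7,
            parameters=("ct_ar_2d",))
        a, b = sim.profiles["ct_ar_2d"]
        df = difference_profile(a, b)
        inside = df[(df.percent >= 61) & (df.percent <= 69)]
        outside = df[(df.percent >= 75)]
        rel_inside = (inside["diff"] / inside.mean_a).mean()
        rel_outside = (outside["diff"].abs() / outside.mean_a).mean()
        assert rel_inside > 0.15
        assert rel_outside < 0.05
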