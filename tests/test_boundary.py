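"""Border extraction, λ/d tortuosity, and the two-group comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from emborder.boundary import (
    BorderPolyline,
    compare_groups,
    curve_length,
    extract_border,
    linear_distance,
    tortuosity,
)
from emborder.errors import NoBorderError, ParameterError
from emborder.phantom import (
    PhantomSpec,
    generate_border,
    rasterize_phantom,
)

from .oracles import permutation_ts, polyline_length, pooled_t


class TestCurveLength:
    def test_circle_circumference(self):
        th = np.linspace(0, 2 * np.pi, 361)[:-1]
        poly = BorderPolyline(
            vertices=np.column_stack((10 * np.cos(th), 10 * np.sin(th))),
            closed=True)
        assert curve_length(poly) == pytest.approx(2 * np.pi * 10, rel=1e-3)

    def test_three_four_five(self):
        assert curve_length(np.array([[0.0, 0.0], [3.0, 4.0]])) == 5.0

    def test_sawtooth_matches_geometry(self):
        # 5 teeth, base 2, height 2 on a 10 um span: lambda = 10*sqrt(5)
        pts = [(0.0, 0.0)]
        for k in range(5):
            pts += [(2 * k + 1, 2.0), (2 * k + 2, 0.0)]
        v = np.array(pts)
        assert curve_length(v) == pytest.approx(10 * math.sqrt(5), rel=1e-12)
        assert curve_length(v) == pytest.approx(polyline_length(v), rel=1e-12)
        rec = tortuosity(v)
        assert rec.ratio == pytest.approx(math.sqrt(5), abs=1e-6)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(-4, 7, (40, 2))
        lam = curve_length(v)
        for theta in (0.3, 1.2, 2.9):
            rot = np.array([[np.cos(theta), -np.sin(theta)],
                            [np.sin(theta), np.cos(theta)]])
            moved = v @ rot.T + [13.0, -2.5]
            assert curve_length(moved) == pytest.approx(lam, rel=1e-6)
            assert linear_distance(moved) == pytest.approx(
                linear_distance(v), rel=1e-6)

    def test_midpoint_insertion_preserves_lambda_and_d(self):
        rng = np.random.default_rng(7)
        v = rng.uniform(0, 10, (15, 2))
        mids = (v[:-1] + v[1:]) / 2
        refined = np.empty((29, 2))
        refined[0::2] = v
        refined[1::2] = mids
        assert curve_length(refined) == pytest.approx(curve_length(v), rel=1e-12)
        assert linear_distance(refined) == pytest.approx(linear_distance(v))


class TestLinearDistance:
    def test_only_endpoints_matter(self):
        v = np.array([[0.0, 0.0], [3.0, 9.0], [-2.0, 4.0], [10.0, 0.0]])
        assert linear_distance(v) == 10.0

    def test_straight_segment_has_ratio_one(self):
        v = np.array([[0.0, 0.0], [5.0, 5.0]])
        assert linear_distance(v) == curve_length(v)
        assert tortuosity(v).ratio == 1.0

    def test_closed_curve_rejected(self):
        poly = BorderPolyline(
            vertices=np.array([[0.0, 0], [1, 0], [1, 1]]), closed=True)
        with pytest.raises(ParameterError):
            linear_distance(poly)

    def test_degenerate_endpoints_rejected(self):
        v = np.array([[1.0, 1.0], [3.0, 2.0], [1.0, 1.0]])
        with pytest.raises(ParameterError):
            tortuosity(v)

    @settings(deadline=None, max_examples=60)
    @given(arrays(float, (12, 2), elements=st.floats(-50, 50)))
    def test_ratio_at_least_one(self, v):
        # triangle inequality: arc length >= chord between endpoints
        dif = np.diff(v, axis=0)
        if (np.hypot(dif[:, 0], dif[:, 1]) < 1e-9).any():
            return  # consecutive duplicates are rejected input
        if linear_distance(v) < 1e-9:
            return
        assert tortuosity(v).ratio >= 1.0 - 1e-12


class TestExtractBorder:
    def test_halfplane_mask_gives_straight_border(self):
        mask = np.zeros((60, 40), dtype=bool)
        mask[:, :20] = True  # vertical border
        b = extract_border(mask=mask, pixel_size_um=0.5,
                           sides=("top", "bottom"))
        rec = tortuosity(b)
        assert rec.ratio == pytest.approx(1.0, abs=1e-3)
        assert rec.d_um == pytest.approx(60 * 0.5, rel=0.02)

    def test_phantom_mask_recovers_analytic_lambda(self):
        spec = PhantomSpec(group="post_branch", pixel_size_um=0.2, seed=6,
                           noise_sd=0.0)
        truth = generate_border(spec)
        _, mask = rasterize_phantom(truth, spec)
        b = extract_border(mask=mask, pixel_size_um=0.2)
        assert curve_length(b) == pytest.approx(truth.lambda_um, rel=0.05)
        assert linear_distance(b) == pytest.approx(
            spec.domain_size_um[0], rel=0.02)

    def test_single_phase_mask_rejected(self):
        with pytest.raises(NoBorderError):
            extract_border(mask=np.ones((10, 10), dtype=bool), pixel_size_um=1.0)

    def test_roi_restricts_the_measurement(self):
        spec = PhantomSpec(seed=8, noise_sd=0.0, pixel_size_um=0.2)
        truth = generate_border(spec)
        _, mask = rasterize_phantom(truth, spec)
        nrows, ncols = mask.shape
        b_full = extract_border(mask=mask, pixel_size_um=0.2)
        b_half = extract_border(mask=mask, pixel_size_um=0.2,
                                roi=(0, 0, nrows, ncols // 2))
        assert linear_distance(b_half) == pytest.approx(
            linear_distance(b_full) / 2, rel=0.05)
        x = b_half.vertices[:, 0]
        assert x.max() <= ncols // 2 * 0.2 + 1e-9

    def test_contour_missing_from_roi_raises(self):
        phi = np.fromfunction(lambda i, j: i - 10.0, (30, 30))
        with pytest.raises(NoBorderError):
            extract_border(phi=phi, pixel_size_um=1.0, roi=(20, 0, 30, 30))


class TestCompareGroups:
    def test_hand_computed_t_and_permutation_oracle(self):
        res = compare_groups([1, 2, 3], [4, 5, 6])
        assert res["t_stat"] == pytest.approx(-3.674, abs=1e-3)
        assert res["df"] == 4
        assert res["p_value"] == pytest.approx(0.021, abs=1e-3)
        assert res["t_stat"] == pytest.approx(pooled_t([1, 2, 3], [4, 5, 6]),
                                              rel=1e-12)
        # exhaustive permutation: observed |t| is the most extreme of all 20
        # label splits, so the permutation p equals its floor of 2/20
        ts = permutation_ts([1, 2, 3], [4, 5, 6])
        assert len(ts) == 20
        assert (np.abs(ts) >= abs(res["t_stat"]) - 1e-9).sum() == 2

    def test_identical_groups(self):
        res = compare_groups([1, 2, 3], [1, 2, 3])
        assert res["t_stat"] == pytest.approx(0.0)
        assert res["p_value"] == pytest.approx(1.0)
        assert res["percent_decrease"] == pytest.approx(0.0)

    def test_published_group_means_percent_decrease(self):
        # groups held at the printed means 11 (pre) and 6 (post): the exact
        # decrease is 45.45%, commonly rounded to "about 50%"
        res = compare_groups([11.0, 11.0], [6.0, 6.0])
        assert res["percent_decrease"] == pytest.approx(100 * 5 / 11, abs=1e-9)
        assert res["percent_decrease"] == pytest.approx(45.5, abs=0.05)

    def test_small_groups_rejected(self):
        with pytest.raises(ParameterError):
            compare_groups([1.0], [2.0, 3.0])

    def test_welch_variant(self):
        res = compare_groups([1, 2, 3, 9], [4, 5, 6], welch=True)
        assert res["welch"] is True
        assert res["df"] != 5
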