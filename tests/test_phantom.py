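"""Synthetic phantom generator: exact geometry, rasterization, datasets."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from emborder.errors import InfeasibleDensityError, ParameterError
from emborder.phantom import (
    PhantomSpec,
    epithelium_polygon,
    generate_border,
    make_dataset,
    rasterize_phantom,
    spec_for_ratio,
)

from .oracles import polyline_length, shoelace_area


def flat_spec(**kw):
    base = dict(group="custom", domain_size_um=(10.0, 8.0),
                border_depth_um=4.0, filopodia_density_per_um=0.0,
                noise_sd=0.0)
    base.update(kw)
    return PhantomSpec(**base)


class TestGenerateBorder:
    def test_straight_border_has_unit_ratio(self):
        t = generate_border(flat_spec())
        assert t.lambda_um == pytest.approx(10.0)
        assert t.d_um == pytest.approx(10.0)
        assert t.ratio == pytest.approx(1.0)

    def test_five_even_triangles_exact_length(self):
        # 5 teeth of base 1 um and height 4 um on a 10 um border:
        # lambda = 5*2*sqrt(0.5^2+4^2) + 5*1 um of flat base
        spec = flat_spec(domain_size_um=(10.0, 12.0),
                         filopodia_density_per_um=0.5,
                         filopodia_length_fixed_um=4.0,
                         filopodia_base_width_um=1.0,
                         filopodia_jitter=0.0)
        t = generate_border(spec)
        expect = 10 * math.sqrt(0.25 + 16.0) + 5.0
        assert t.lambda_um == pytest.approx(expect, rel=1e-12)
        assert t.ratio == pytest.approx(expect / 10.0, rel=1e-12)
        assert t.lambda_um == pytest.approx(45.31, abs=0.01)

    def test_contiguous_sawtooth_ratio_is_sqrt5(self):
        # base 2, height 2, no flat gaps -> per-tooth side sqrt(1+4)
        spec = flat_spec(domain_size_um=(10.0, 10.0),
                         filopodia_density_per_um=0.5,
                         filopodia_length_fixed_um=2.0,
                         filopodia_base_width_um=2.0,
                         filopodia_jitter=0.0)
        t = generate_border(spec)
        assert t.ratio == pytest.approx(math.sqrt(5.0), rel=1e-9)
        assert t.lambda_um == pytest.approx(10.0 * math.sqrt(5.0), rel=1e-9)

    def test_infeasible_density_reports_maximum(self):
        spec = flat_spec(filopodia_density_per_um=2.0,
                         filopodia_base_width_um=1.0,
                         filopodia_length_um=(1.0, 3.0))
        with pytest.raises(InfeasibleDensityError, match="maximum feasible"):
            generate_border(spec)

    @pytest.mark.parametrize("spec", [
        PhantomSpec(seed=3),
        PhantomSpec(group="post_branch", seed=4),
        PhantomSpec(seed=5, filopodia_shape="rounded_finger"),
        flat_spec(baseline_amplitude_um=1.0, baseline_period_um=2.5),
        spec_for_ratio(7.0),
    ], ids=["pre", "post", "rounded", "sinusoid", "sawtooth"])
    def test_length_matches_bruteforce_oracle(self, spec):
        t = generate_border(spec)
        assert t.lambda_um == pytest.approx(
            polyline_length(t.border_polyline), rel=1e-9)
        assert t.d_um == pytest.approx(
            math.dist(t.border_polyline[0], t.border_polyline[-1]), rel=1e-12)
        assert t.ratio >= 1.0

    def test_lambda_increases_with_density_and_length(self):
        base = PhantomSpec(seed=9, noise_sd=0.0)
        lams = [generate_border(replace(base, filopodia_density_per_um=d)).lambda_um
                for d in (0.1, 0.2, 0.3, 0.4, 0.5)]
        assert all(b > a for a, b in zip(lams, lams[1:]))
        lams = [generate_border(
            replace(base, filopodia_length_um=(2.0 + s, 10.0 + s))).lambda_um
            for s in (0.0, 1.0, 2.0, 4.0)]
        assert all(b > a for a, b in zip(lams, lams[1:]))

    def test_same_seed_is_bit_identical(self):
        spec = PhantomSpec(seed=21)
        a, b = generate_border(spec), generate_border(spec)
        assert np.array_equal(a.border_polyline, b.border_polyline)
        assert a.lambda_um == b.lambda_um


class TestRasterize:
    def test_noiseless_image_has_two_values_and_correct_area(self):
        spec = flat_spec(domain_size_um=(10.0, 8.0), pixel_size_um=0.05)
        t = generate_border(spec)
        img, mask = rasterize_phantom(t, spec)
        assert set(np.unique(img)) == {spec.intensity_mesenchyme,
                                       spec.intensity_epithelium}
        poly = epithelium_polygon(t, spec)
        area_frac_analytic = shoelace_area(poly.exterior.coords[:-1]) / 80.0
        assert mask.mean() == pytest.approx(area_frac_analytic, rel=0.01)

    def test_seeded_noise_is_bit_identical(self):
        spec = PhantomSpec(seed=2, noise_sd=0.1, pixel_size_um=0.4)
        t = generate_border(spec)
        img1, _ = rasterize_phantom(t, spec)
        img2, _ = rasterize_phantom(t, spec)
        assert np.array_equal(img1, img2)

    def test_linear_bias_makes_column_means_monotonic(self):
        spec = flat_spec(bias_field="linear", bias_amplitude=0.3,
                         pixel_size_um=0.1)
        t = generate_border(spec)
        img, _ = rasterize_phantom(t, spec)
        col_means = img.mean(axis=0)
        assert np.all(np.diff(col_means) > 0)

    def test_warns_when_protrusions_are_subpixel(self):
        spec = PhantomSpec(seed=1, pixel_size_um=1.0)
        t = generate_border(spec)
        with pytest.warns(UserWarning, match="fewer than 3 pixels"):
            rasterize_phantom(t, spec)

    def test_halving_pixel_size_refines_mask_border_length(self):
        # mask-derived border length approaches the analytic lambda
        from emborder.boundary import curve_length, extract_border

        spec0 = spec_for_ratio(4.5)
        errs = []
        for px in (0.4, 0.2, 0.1):
            spec = replace(spec0, pixel_size_um=px)
            t = generate_border(spec)
            _, mask = rasterize_phantom(t, spec)
            lam = curve_length(extract_border(mask=mask, pixel_size_um=px))
            errs.append(abs(lam - t.lambda_um) / t.lambda_um)
        assert errs[0] > errs[1] > errs[2]


class TestMakeDataset:
    def test_default_layout_and_group_separation(self, tmp_path):
        table, info = make_dataset(10, 10, tmp_path, seed=1)
        assert len(table) == 20
        assert sorted(table.group.unique()) == ["post", "pre"]
        assert len(list((tmp_path / "images").glob("*.tif"))) == 20
        assert len(list((tmp_path / "masks").glob("*.png"))) == 20
        pre = table.loc[table.group == "pre", "ratio"]
        post = table.loc[table.group == "post", "ratio"]
        assert pre.min() > post.max()

    def test_zero_count_rejected(self, tmp_path):
        with pytest.raises(ParameterError):
            make_dataset(0, 10, tmp_path)

    def test_same_master_seed_reproduces_table(self, tmp_path):
        t1, _ = make_dataset(3, 3, tmp_path / "a", seed=7)
        t2, _ = make_dataset(3, 3, tmp_path / "b", seed=7)
        pd.testing.assert_frame_equal(t1, t2)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ParameterError):
            PhantomSpec(intensity_epithelium=0.5,
                        intensity_mesenchyme=0.5).validate()
        with pytest.raises(ParameterError):
            PhantomSpec(filopodia_length_um=(5.0, 2.0)).validate()
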