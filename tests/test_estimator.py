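import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slicevol import CARROT, CUCUMBER
from slicevol.estimator import (
    OUT_OF_RANGE,
    ProductProfile,
    VolumeEstimate,
    classify,
    estimate_from_silhouette,
    estimate_mass,
    estimate_volume,
    sweep_slices,
)
from slicevol.silhouette import WidthProfile
from slicevol.synthetic import make_shape

from conftest import render_silhouette


def profile_from_widths(widths, length):
    widths = np.asarray(widths, dtype=float)
    n = len(widths) - 1
    return WidthProfile(
        n_slices=n,
        stations=np.linspace(0.0, length, n + 1),
        widths=widths,
        length=length,
    )


def unit_ratio_product(**kwargs):
    defaults = dict(name="test", aspect_ratio=1.0, density=1.0)
    defaults.update(kwargs)
    return ProductProfile(**defaults)


class TestEstimateVolume:
    def test_constant_profile_hand_arithmetic(self):
        # w = 2.5 cm everywhere, L = 10, n = 8, r = 1, h = 1.25:
        # caps: pi*2.5*2.5*1.25/6 each; 6 mid cylinders: pi*1.25^2*1.25
        profile = profile_from_widths([2.5] * 9, 10.0)
        est = estimate_volume(profile, unit_ratio_product())
        cap = math.pi * 2.5 * 2.5 * 1.25 / 6.0
        mid = math.pi * 1.25**2 * 1.25
        assert est.cap_top == pytest.approx(cap)
        assert est.cap_bottom == pytest.approx(cap)
        assert est.frustums == pytest.approx([mid] * 6)
        assert est.total == pytest.approx(2 * cap + 6 * mid)
        assert est.total == pytest.approx(44.997, abs=0.01)

    def test_all_zero_widths(self):
        profile = profile_from_widths([0.0] * 9, 10.0)
        est = estimate_volume(profile, unit_ratio_product())
        assert est.total == 0.0

    def test_synthetic_spindle_within_3pct(self, spindle_silhouette):
        sil, truth = spindle_silhouette
        vol, _, _, _ = estimate_from_silhouette(sil, CARROT, n_slices=8)
        assert abs(vol.total - truth.volume_ml) / truth.volume_ml <= 0.03

    def test_additivity(self, spindle_silhouette):
        sil, _ = spindle_silhouette
        vol, _, _, _ = estimate_from_silhouette(sil, CARROT)
        assert vol.total == pytest.approx(
            vol.cap_top + vol.cap_bottom + sum(vol.frustums), rel=1e-12
        )

    def test_monotonicity(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(1.0, 3.0, 9)
        bigger = base + rng.uniform(0.0, 0.5, 9)
        p = unit_ratio_product()
        v1 = estimate_volume(profile_from_widths(base, 12.0), p).total
        v2 = estimate_volume(profile_from_widths(bigger, 12.0), p).total
        assert v2 >= v1

    def test_uniform_scaling_cubes_volume(self):
        widths = np.array([0.5, 1.5, 2.0, 2.2, 2.0, 1.8, 1.2, 0.8, 0.2])
        p = unit_ratio_product()
        v1 = estimate_volume(profile_from_widths(widths, 10.0), p).total
        v2 = estimate_volume(profile_from_widths(2.0 * widths, 20.0), p).total
        assert v2 == pytest.approx(8.0 * v1, rel=1e-12)

    def test_volume_proportional_to_inverse_aspect_ratio(self):
        widths = np.array([0.5, 1.5, 2.0, 2.2, 2.0, 1.8, 1.2, 0.8, 0.2])
        v1 = estimate_volume(
            profile_from_widths(widths, 10.0), unit_ratio_product(aspect_ratio=1.0)
        ).total
        v_half = estimate_volume(
            profile_from_widths(widths, 10.0), unit_ratio_product(aspect_ratio=0.5)
        ).total
        assert v_half == pytest.approx(2.0 * v1, rel=1e-12)

    def test_oracle_equivalence_at_high_slice_count(self):
        # truncated convex fixture: widths of a parabola-like arch, n = 500;
        # estimate must match numerical integration of pi*a(t)^2/r
        r = 0.9531
        n = 500
        length = 12.0
        t = np.linspace(0.0, length, n + 1)
        widths = 3.0 + 1.2 * np.sin(np.pi * t / length)  # truncated (no sharp tips)
        profile = profile_from_widths(widths, length)
        est = estimate_volume(profile, unit_ratio_product(aspect_ratio=r)).total
        from scipy.integrate import quad

        oracle, _ = quad(
            lambda x: math.pi * ((3.0 + 1.2 * math.sin(math.pi * x / length)) / 2.0) ** 2 / r,
            0.0,
            length,
            limit=200,
        )
        assert est == pytest.approx(oracle, rel=0.005)

    def test_negative_width_rejected(self):
        with pytest.raises(ValueError):
            profile_from_widths([1.0, -1.0, 1.0, 1.0, 1.0], 4.0)

    @settings(max_examples=25, deadline=None)
    @given(
        widths=st.lists(st.floats(0.0, 5.0), min_size=5, max_size=12),
        r=st.floats(0.3, 1.5),
    )
    def test_parts_nonnegative_and_additive(self, widths, r):
        profile = profile_from_widths(widths, 10.0)
        est = estimate_volume(profile, unit_ratio_product(aspect_ratio=r))
        assert est.cap_top >= 0 and est.cap_bottom >= 0
        assert all(f >= 0 for f in est.frustums)
        assert est.total == pytest.approx(
            est.cap_top + est.cap_bottom + sum(est.frustums), rel=1e-12, abs=1e-12
        )


class TestMassAndClassify:
    def test_carrot_density_arithmetic(self):
        est = VolumeEstimate(
            total=100.0, cap_top=10.0, cap_bottom=10.0, frustums=(80.0,), n_slices=3
        )
        mass = estimate_mass(est, CARROT)
        assert mass.mass == pytest.approx(109.87)
        assert mass.class_label == "S"

    def test_zero_volume_out_of_range(self):
        est = VolumeEstimate(
            total=0.0, cap_top=0.0, cap_bottom=0.0, frustums=(0.0,), n_slices=3
        )
        mass = estimate_mass(est, CARROT)
        assert mass.mass == 0.0
        assert mass.class_label == OUT_OF_RANGE

    def test_cucumber_150ml(self):
        est = VolumeEstimate(
            total=150.0, cap_top=20.0, cap_bottom=20.0, frustums=(110.0,), n_slices=3
        )
        mass = estimate_mass(est, CUCUMBER)
        assert mass.mass == pytest.approx(152.85)
        assert mass.class_label == "L"

    @pytest.mark.parametrize(
        "mass,label",
        [
            (125.0, "M"),  # shared endpoint goes to the upper class
            (60.0, OUT_OF_RANGE),
            (80.0, "S"),
            (200.0, "L"),
            (250.0, "2L"),
            (320.0, OUT_OF_RANGE),
        ],
    )
    def test_carrot_boundaries(self, mass, label):
        assert classify(mass, CARROT) == label

    @pytest.mark.parametrize(
        "mass,label",
        [
            (99.9, "S"),
            (100.0, "M"),
            (150.0, "L"),
            (200.0, "L"),  # 200 stays in L, XL is open (200, inf)
            (200.1, "XL"),
            (5.0, "S"),  # S is open-ended below
            (1000.0, "XL"),
        ],
    )
    def test_cucumber_boundaries(self, mass, label):
        assert classify(mass, CUCUMBER) == label


class TestSweepSlices:
    @pytest.fixture(scope="class")
    @staticmethod
    def spindle_samples():
        samples = []
        for i, (length, width) in enumerate([(14.0, 4.0), (16.0, 3.5), (18.0, 4.5)]):
            shape = make_shape(
                "spindle", length=length, max_width=width, aspect_ratio=CARROT.aspect_ratio
            )
            sil, truth = render_silhouette(
                shape, px_per_cm=55.0, rotation_deg=25.0 * i, seed=i
            )
            samples.append((sil, truth.volume_ml))
        return samples

    def test_convergence_8_vs_3(self, spindle_samples):
        table = sweep_slices(spindle_samples, CARROT, [3, 8])
        err = dict(zip(table["n_slices"], table["mean_abs_pct_error"]))
        assert err[8] <= err[3]

    def test_cylinder_cap_deficit_law(self):
        # for a cylinder the only error is the two end caps, each modelling a
        # flat-ended slice as a semi-ellipsoid: relative deficit = 2/(3n)
        shape = make_shape("cylinder", length=14.0, max_width=3.5, aspect_ratio=1.0)
        sil, truth = render_silhouette(shape, px_per_cm=55.0)
        product = unit_ratio_product()
        table = sweep_slices([(sil, truth.volume_ml)], product, range(4, 13))
        for n, err in zip(table["n_slices"], table["mean_abs_pct_error"]):
            assert err == pytest.approx(100.0 * 2.0 / (3.0 * n), abs=0.5)

    def test_empty_range(self, spindle_samples):
        with pytest.raises(ValueError):
            sweep_slices(spindle_samples, CARROT, [])

    def test_empty_samples(self):
        with pytest.raises(ValueError):
            sweep_slices([], CARROT, [3, 8])

    def test_table_schema(self, spindle_samples):
        table = sweep_slices(spindle_samples, CARROT, range(3, 6))
        assert list(table.columns) == ["n_slices", "mean_abs_pct_error", "sd_pct_error"]
        assert len(table) == 3


class TestProductProfile:
    def test_invalid_values(self):
        with pytest.raises(ValueError):
            ProductProfile(name="x", aspect_ratio=0.0, density=1.0)
        with pytest.raises(ValueError):
            ProductProfile(name="x", aspect_ratio=1.0, density=-1.0)
        with pytest.raises(ValueError):
            ProductProfile(name="x", aspect_ratio=1.0, density=1.0, n_slices=2)

    def test_builtin_constants(self):
        assert CARROT.aspect_ratio == pytest.approx(0.9531)
        assert CARROT.density == pytest.approx(1.0987)
        assert CUCUMBER.aspect_ratio == pytest.approx(0.9677)
        assert CUCUMBER.density == pytest.approx(1.019)
        assert CARROT.n_slices == 8
        assert CUCUMBER.n_slices == 8


class TestVolumeEstimateInvariant:
    def test_sum_mismatch_rejected(self):
        with pytest.raises(ValueError):
            VolumeEstimate(
                total=10.0, cap_top=1.0, cap_bottom=1.0, frustums=(1.0,), n_slices=3
            )
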