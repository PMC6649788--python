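import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import knotfiber as kf
from knotfiber.errors import (DegenerateAxisError, InvalidParametersError,
                              UndefinedAutocorrelationError)


class TestModelParams:
    def test_ratio_construction_and_normalization(self):
        p = kf.ModelParams.from_ratio(25, 0.47)
        assert p.center_spacing == pytest.approx(1.0)
        assert p.dl_ratio == pytest.approx(0.47)

    @pytest.mark.parametrize("kwargs", [
        dict(n_beads=3), dict(bead_diameter=-0.1), dict(linker_length=0.0),
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(InvalidParametersError):
            kf.ModelParams(**kwargs)


class TestBuildInitial:
    def test_regular_polygon_geometry(self):
        conf = kf.build_initial(kf.ModelParams.from_ratio(25, 0.47))
        R = 0.5 / math.sin(math.pi / 25)
        assert R == pytest.approx(3.9894, abs=5e-4)
        # vertices equidistant from centroid: Rg equals the circumradius
        assert kf.radius_of_gyration(conf) == pytest.approx(R, rel=1e-12)
        lens = conf.segment_lengths()
        assert np.allclose(lens, 1.0, rtol=1e-12)
        # chord geometry leaves room for the beads at D/L = 0.47
        assert not kf.has_overlap(conf, 0.47 / 1.47)
        conf.validate(kf.ModelParams.from_ratio(25, 0.47))

    def test_initial_polygon_is_unknotted(self):
        conf = kf.build_initial(kf.ModelParams.from_ratio(25, 0.47))
        assert kf.classify(conf, seed=3).label == "0_1"

    @pytest.mark.parametrize("ratio", [0.0, 0.25, 0.47, 0.75, 1.0, 3.0])
    def test_initial_polygon_valid_across_ratios(self, ratio):
        # the next-nearest chord 2 (D+L) cos(pi/N) always exceeds D when
        # L > 0, so every valid parameter set admits the polygon start
        params = kf.ModelParams.from_ratio(25, ratio)
        conf = kf.build_initial(params)
        conf.validate(params)


class TestCrankshaft:
    @pytest.fixture()
    def conf(self):
        return kf.build_initial(kf.ModelParams.from_ratio(25, 0.47))

    def test_zero_angle_is_identity(self, conf):
        out = kf.crankshaft(conf, 3, 9, 0.0)
        assert np.allclose(out.coords, conf.coords, atol=1e-12)

    def test_full_turn_is_identity(self, conf):
        out = kf.crankshaft(conf, 3, 9, 2.0 * math.pi)
        assert np.allclose(out.coords, conf.coords, atol=1e-9)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(i=st.integers(0, 24), k=st.integers(2, 23),
           angle=st.floats(-3.1, 3.1))
    def test_inverse_rotation_and_bond_lengths(self, i, k, angle):
        conf = kf.build_initial(kf.ModelParams.from_ratio(25, 0.47))
        j = (i + k) % 25
        moved = kf.crankshaft(conf, i, j, angle)
        assert np.allclose(moved.segment_lengths(), 1.0, atol=1e-9)
        back = kf.crankshaft(moved, i, j, -angle)
        assert np.allclose(back.coords, conf.coords, atol=1e-9)

    def test_complementary_arc_unchanged(self, conf):
        out = kf.crankshaft(conf, 3, 9, 1.1)
        untouched = [m % 25 for m in range(9, 3 + 26)]
        assert np.array_equal(out.coords[untouched], conf.coords[untouched])
        touched = list(range(4, 9))
        assert not np.allclose(out.coords[touched], conf.coords[touched])

    def test_bad_arc_rejected(self, conf):
        with pytest.raises(InvalidParametersError):
            kf.crankshaft(conf, 3, 3, 1.0)
        with pytest.raises(InvalidParametersError):
            kf.crankshaft(conf, 3, 4, 1.0)   # empty arc

    def test_degenerate_axis(self):
        coords = kf.build_initial(kf.ModelParams.from_ratio(25, 0.47)).coords.copy()
        coords[9] = coords[3]
        conf = kf.RingConformation(coords)
        with pytest.raises(DegenerateAxisError):
            kf.crankshaft(conf, 3, 9, 1.0)


class TestHasOverlap:
    def test_regular_polygon_has_no_overlap(self):
        conf = kf.build_initial(kf.ModelParams.from_ratio(25, 0.47))
        assert kf.has_overlap(conf, 0.3197) is False

    def test_strict_inequality_at_contact(self):
        # rhombus ring whose non-adjacent center distances are exactly 2
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 0.0],
                           [2.0, 0.0, 0.0], [1.0, -1.0, 0.0]])
        assert kf.has_overlap(coords, 2.0) is False          # contact allowed
        assert kf.has_overlap(coords, 2.0 * (1 + 1e-6)) is True

    def test_zero_diameter_never_overlaps(self, ens_small):
        assert all(not kf.has_overlap(ens_small.coords[i], 0.0)
                   for i in range(0, ens_small.n, 50))


class TestRadiusOfGyration:
    def test_rigid_motion_invariance(self, rng):
        conf = kf.build_initial(kf.ModelParams.from_ratio(25, 0.47))
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        moved = conf.coords @ q + np.array([5.0, -2.0, 11.0])
        assert kf.radius_of_gyration(moved) == pytest.approx(
            kf.radius_of_gyration(conf), rel=1e-12)

    def test_antipodal_clusters(self):
        a = 2.5
        coords = np.zeros((10, 3))
        coords[:5, 0] = a
        coords[5:, 0] = -a
        assert kf.radius_of_gyration(coords) == pytest.approx(a, rel=1e-12)


class TestAutocorrelationTime:
    def test_white_noise_is_about_one(self, rng):
        tau = kf.autocorrelation_time(rng.standard_normal(100_000))
        assert tau == pytest.approx(1.0, abs=0.1)

    def test_ar1_matches_closed_form(self, rng):
        phi = 0.9
        n = 400_000
        eps = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = eps[0]
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        tau = kf.autocorrelation_time(x)
        assert tau == pytest.approx((1 + phi) / (1 - phi), rel=0.2)

    def test_short_series_rejected(self):
        with pytest.raises(InvalidParametersError):
            kf.autocorrelation_time(np.arange(10.0))

    def test_constant_series_rejected(self):
        with pytest.raises(UndefinedAutocorrelationError):
            kf.autocorrelation_time(np.ones(1000))


class TestSampleEnsemble:
    def test_bitwise_reproducibility(self, params_047):
        a = kf.sample_ensemble(params_047, 200, seed=5)
        b = kf.sample_ensemble(params_047, 200, seed=5)
        assert np.array_equal(a.coords, b.coords)
        assert a.burn_in_sweeps == b.burn_in_sweeps
        assert a.decorrelation_sweeps == b.decorrelation_sweeps
        assert a.acceptance_rate == b.acceptance_rate

    def test_different_seeds_differ(self, params_047):
        a = kf.sample_ensemble(params_047, 50, seed=5)
        b = kf.sample_ensemble(params_047, 50, seed=6)
        assert not np.array_equal(a.coords, b.coords)

    def test_segment_length_conservation(self, ens_047_20k):
        # the late frames have seen well over 1e6 accepted moves
        spacing = ens_047_20k.params.center_spacing
        lens = np.linalg.norm(
            np.roll(ens_047_20k.coords, -1, axis=1) - ens_047_20k.coords,
            axis=2)
        assert np.max(np.abs(lens - spacing)) < 1e-6

    def test_excluded_volume_on_stored_conformations(self, ens_047_20k):
        D = ens_047_20k.params.bead_diameter
        step = max(1, ens_047_20k.n // 500)
        for i in range(0, ens_047_20k.n, step):
            assert not kf.has_overlap(ens_047_20k.coords[i], D)

    def test_metadata_recorded(self, ens_047_20k):
        assert ens_047_20k.decorrelation_sweeps >= math.ceil(
            ens_047_20k.tau_int_sweeps)
        assert 0.0 < ens_047_20k.acceptance_rate < 1.0
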