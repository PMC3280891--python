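import numpy as np
import pytest

from cochlea.filters import FilterParameters, extremal_h
from cochlea.groups import (build_group_model, conjugation_map,
                            dilation_group, flow, general_extremal,
                            group_filter, group_wavelet_transform,
                            model_example_1, model_example_2,
                            plancherel_check, reconstruct,
                            sigma_localization, uncertainty_functionals)
from cochlea.structure import residuals
from cochlea.tonotopy import ScaleGrid, TonotopicMap
from cochlea.transform import SampledSignal, analytic_transform


@pytest.fixture(scope="module")
def ex1():
    return model_example_1(R=2 * np.pi * 20000.0, K=2 * np.pi * 1000.0)


@pytest.fixture(scope="module")
def ex2():
    return model_example_2(S=2 * np.pi * 200.0)


class TestFlow:
    def test_identity_at_one(self, ex1):
        w = 2 * np.pi * 500.0
        assert flow(ex1, 1.0, w) == w

    def test_dilation_closed_form(self):
        gd = dilation_group()
        assert flow(gd, 2.0, 3.0) == pytest.approx(1.5, abs=1e-9)

    def test_matches_example1_closed_form(self, ex1):
        w = 2 * np.pi * 500.0
        assert flow(ex1, 2.5, w) == pytest.approx(
            ex1.flow_closed(2.5, w), rel=1e-9)

    def test_group_law(self, ex1):
        w = 2 * np.pi * 700.0
        w6 = flow(ex1, 6.0, w)
        w23 = flow(ex1, 2.0, flow(ex1, 3.0, w))
        assert abs(w6 - w23) / w < 1e-8

    def test_fixed_point_exact(self, ex1):
        assert flow(ex1, 7.0, 0.0) == 0.0

    def test_outside_interval_raises(self, ex1):
        with pytest.raises(ValueError, match="interval"):
            flow(ex1, 2.0, ex1.band * 1.5)

    def test_stays_in_interval(self, ex1):
        w = ex1.band * 0.95
        for a in (0.1, 10.0):
            out = flow(ex1, a, w)
            assert 0.0 < out < ex1.band


class TestConjugationMap:
    def test_quadrature_matches_example1_closed_form(self, ex1):
        smap_q, sinv_q = conjugation_map(ex1)
        probe = np.geomspace(2 * np.pi * 20, 2 * np.pi * 15000, 40)
        rel = np.abs(smap_q(probe) - ex1.smap(probe)) / ex1.smap(probe)
        assert np.max(rel) < 1e-4
        # exact per-point path for small requests
        assert smap_q(ex1.anchor) == pytest.approx(1.0, abs=1e-10)

    def test_maps_band_onto_positive_axis(self, ex1):
        probe = np.geomspace(ex1.band * 1e-6, ex1.band * (1 - 1e-9), 1000)
        s = ex1.smap(probe)
        assert np.all(np.diff(s) > 0)
        assert s[0] < 1e-12 * s[-1]
        assert s[-1] > 1e6

    def test_conjugation_property(self, ex1):
        # s(lambda_a w) = s(w)/a
        probe = np.geomspace(2 * np.pi * 50, 2 * np.pi * 15000, 200)
        for a in (0.3, 2.7):
            lhs = ex1.smap(ex1.flow_closed(a, probe))
            rhs = ex1.smap(probe) / a
            assert np.max(np.abs(lhs - rhs) / rhs) < 1e-8

    def test_dilation_special_case(self):
        gd = dilation_group()
        probe = np.geomspace(0.1, 10, 17)
        assert np.array_equal(gd.smap(probe), probe)

    def test_smap_derivative_identity(self, ex1):
        # s' = -s/v, cross-checked against finite differences
        w = 2 * np.pi * 800.0
        fd = (ex1.smap(w * (1 + 1e-7)) - ex1.smap(w * (1 - 1e-7))) \
            / (2e-7 * w)
        assert ex1.smap_derivative(w) == pytest.approx(fd, rel=1e-5)

    def test_vanishing_field_raises(self):
        with pytest.raises(ArithmeticError, match="singular|vanishes"):
            conjugation_map(lambda w: np.asarray(w) * 0.0,
                            interval=(0.0, 10.0), anchor=1.0)


class TestGeneralExtremal:
    def test_dilation_reduction_bit_match(self, p1):
        gd = dilation_group()
        w = np.geomspace(0.1, 5.0, 25)
        assert np.array_equal(general_extremal(gd, w, p1), extremal_h(w, p1))

    def test_localization_transform_law(self, ex1, p1):
        # sigma(lambda_a h) = lambda_a sigma(h)
        w = np.geomspace(2 * np.pi * 10, ex1.band * 0.999, 60000)
        a = 1.0 / (2 * np.pi * 900.0)  # arbitrary group parameter
        ga = group_filter(ex1, a, w, p1)
        sigma = sigma_localization(w, ga, p1.c, ex1)
        expected = ex1.localization_frequency(a)
        assert sigma == pytest.approx(expected, rel=1e-5)

    def test_gap_zero_for_extremal_positive_for_perturbed(self, ex1, p1):
        w = np.geomspace(2 * np.pi * 5, ex1.band * 0.9999, 20000)
        h = general_extremal(ex1, w, p1)
        uf = uncertainty_functionals(w, h, p1.c, gm=ex1)
        hp = h * np.exp(-0.5 * (ex1.smap(w) - 1.0) ** 2)
        ufp = uncertainty_functionals(w, hp, p1.c, gm=ex1)
        assert abs(uf.gap) < 5e-3
        assert ufp.gap > 5 * abs(uf.gap)


def multi_tone(rate=8192.0, n=8192, freqs=(48.0, 64.0, 80.0)):
    t = np.arange(n) / rate
    x = sum(np.cos(2 * np.pi * f * t + 0.2 * i) for i, f in enumerate(freqs))
    return SampledSignal(x, rate), t


class TestGroupWaveletTransform:
    def test_dilation_reduction(self, p1):
        sig, t = multi_tone()
        gd = dilation_group()
        numid = 2 * np.pi * 64
        grid = ScaleGrid(scales=np.geomspace(0.5 / numid, 2.0 / numid, 16),
                         k_const=0.0)
        std = analytic_transform(sig, grid, p1, pad=False)
        grp = group_wavelet_transform(sig, gd, p1, grid, pad=False)
        rms = np.sqrt(np.mean(np.abs(std.Z - grp.Z) ** 2))
        assert rms / np.sqrt(np.mean(np.abs(std.Z) ** 2)) < 1e-10

    def test_plancherel_identity(self, p1):
        sig, _ = multi_tone()
        gd = dilation_group()
        numid = 2 * np.pi * 64
        grid = ScaleGrid(scales=np.geomspace(0.05 / numid, 20.0 / numid, 160),
                         k_const=0.0)
        coch = group_wavelet_transform(sig, gd, p1, grid, pad=False)
        rep = plancherel_check(coch, sig, gd, p1)
        assert rep["relative_difference"] < 1e-4

    def test_banded_model_ignores_out_of_band(self, p1):
        gm = model_example_1(R=2 * np.pi * 1000.0, K=2 * np.pi * 100.0)
        rate, n = 8192.0, 4096
        t = np.arange(n) / rate
        grid = ScaleGrid(
            scales=np.geomspace(1.0 / gm.smap(2 * np.pi * 90.0),
                                1.0 / gm.smap(2 * np.pi * 40.0), 24),
            k_const=0.0)
        inband = SampledSignal(np.cos(2 * np.pi * 64 * t), rate)
        ref = group_wavelet_transform(inband, gm, p1, grid, pad=False)
        beyond = SampledSignal(np.cos(2 * np.pi * 3900.0 * t), rate)
        with pytest.warns(RuntimeWarning, match="band"):
            out = group_wavelet_transform(beyond, gm, p1, grid, pad=False)
        assert np.sum(np.abs(out.Z) ** 2) < 1e-6 * np.sum(np.abs(ref.Z) ** 2)

    def test_general_structure_equations_c1(self, ex1, ex2, p1):
        # framework-level analogue: residuals small at c = 1
        sig, _ = multi_tone()
        lo, hi = 2 * np.pi * 40.0, 2 * np.pi * 90.0
        for gm, tol in ((ex1, 0.02), (ex2, 0.002)):
            grid = ScaleGrid(scales=np.geomspace(1.0 / gm.smap(hi),
                                                 1.0 / gm.smap(lo), 48),
                             k_const=0.0)
            coch = group_wavelet_transform(sig, gm, p1, grid, pad=False)
            res = residuals(coch, p1, gm=gm, method="direct")
            assert res.complex_rms_weighted_relative < tol


class TestReconstruction:
    def grid_for(self, gm, f_lo, f_hi, n=320, widen=24.0):
        lo, hi = 2 * np.pi * f_lo, 2 * np.pi * f_hi
        return ScaleGrid(scales=np.geomspace(1.0 / gm.smap(hi) / widen,
                                             widen / gm.smap(lo), n),
                         k_const=0.0)

    def test_band_limited_recovery(self, ex1, p1):
        sig, _ = multi_tone()
        grid = self.grid_for(ex1, 40.0, 90.0)
        coch = group_wavelet_transform(sig, ex1, p1, grid, pad=False)
        rec = reconstruct(coch, ex1, p1)
        err = np.sqrt(np.mean((rec.samples - sig.samples) ** 2)
                      / np.mean(sig.samples ** 2))
        assert err < 1e-3

    def test_broadband_projects_to_band(self, p1):
        # content above R vanishes; in-band content is recovered
        gm = model_example_1(R=2 * np.pi * 1000.0, K=2 * np.pi * 100.0)
        rate, n = 8192.0, 8192
        t = np.arange(n) / rate
        x_in = np.cos(2 * np.pi * 64 * t)
        x_out = 0.7 * np.cos(2 * np.pi * 3900.0 * t)
        sig = SampledSignal(x_in + x_out, rate)
        grid = self.grid_for(gm, 40.0, 90.0)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            coch = group_wavelet_transform(sig, gm, p1, grid, pad=False)
        rec = reconstruct(coch, gm, p1)
        err = np.sqrt(np.mean((rec.samples - x_in) ** 2) / np.mean(x_in**2))
        assert err < 1e-3

    def test_zero_signal(self, p1):
        gd = dilation_group()
        sig = SampledSignal(np.zeros(1024), 1024.0)
        grid = ScaleGrid(scales=np.geomspace(1e-4, 1e-2, 32), k_const=0.0)
        coch = group_wavelet_transform(sig, gd, p1, grid, pad=False)
        rec = reconstruct(coch, gd, p1)
        assert np.allclose(rec.samples, 0.0)


class TestExampleModels:
    def test_example1_zeros_and_band(self, ex1):
        assert ex1.zeros == (0.0, ex1.band)
        assert ex1.v(ex1.band) == pytest.approx(0.0, abs=1e-9)
        w = np.geomspace(1.0, ex1.band * 0.999, 50)
        assert np.all(ex1.v(w) < 0)

    def test_example1_limit_to_dilation(self):
        # R -> inf approaches the dilation flow on compact sets
        wref = np.geomspace(0.5, 50.0, 20)
        devs = []
        for R in (1e3, 1e6, 1e12):
            g = model_example_1(R=R, K=1.0)
            dev = np.max(np.abs(g.flow_closed(2.0, wref) - wref / 2.0)
                         / (wref / 2.0))
            devs.append(dev)
        assert devs[0] > devs[1] > devs[2]
        assert devs[2] < devs[0] / 3.0

    def test_example2_shift_form(self, ex2):
        S = 2 * np.pi * 200.0
        w = np.geomspace(2.0, 2 * np.pi * 10000, 40)
        assert np.allclose(ex2.smap(w), w + S)
        assert np.allclose(ex2.v(w), -(w + S))

    def test_example2_zero_shift_is_dilation(self):
        assert model_example_2(S=0.0).kind == "dilation"

    def test_example2_blend_monotone_c1(self, ex2):
        w = np.linspace(1e-8, 3.0, 4000)
        s = ex2.smap(w)
        assert np.all(np.diff(s) > 0)
        eps = ex2.meta["eps_blend"]
        left = (ex2.smap(eps) - ex2.smap(eps - 1e-8)) / 1e-8
        right = (ex2.smap(eps + 1e-8) - ex2.smap(eps)) / 1e-8
        assert left == pytest.approx(right, rel=1e-5)

    def test_example2_conjugation(self, ex2):
        # w chosen so lambda_a w stays above the blend region
        w = np.geomspace(2 * np.pi * 600, 2 * np.pi * 5000, 30)
        for a in (0.4, 3.1):
            assert np.allclose(ex2.smap(ex2.flow_closed(a, w)),
                               ex2.smap(w) / a, rtol=1e-12)

    def test_example2_scaling_variable_matches_tonotopy(self, ex2):
        from cochlea.tonotopy import scaling_variable

        S_hz = 200.0
        tmap = TonotopicMap(kind="shifted", K=20000.0, l=6.6, S=S_hz,
                            units="hz").in_units("rad/s")
        x = 12.0
        w = 2 * np.pi * 700.0
        a = ex2.scale_for_place(x, tmap)
        assert ex2.scaling_variable(a, w) == pytest.approx(
            scaling_variable(x, w, tmap), rel=1e-12)

    def test_example2_panoramic_family_fig9(self):
        # K=20000, S=200, l=6.6, c=4: family computable with one peak per place
        g2 = model_example_2(S=2 * np.pi * 200.0)
        p4 = FilterParameters(c=4.0, kappa=2.0)
        tmap = TonotopicMap(kind="shifted", K=20000.0, l=6.6, S=200.0,
                            units="hz").in_units("rad/s")
        w = np.geomspace(2 * np.pi * 20.0, 2 * np.pi * 19000.0, 8000)
        for f in (250.0, 1000.0, 4000.0, 16000.0):
            from cochlea.tonotopy import frequency_to_position

            x = frequency_to_position(2 * np.pi * f, tmap)
            a = g2.scale_for_place(x, tmap)
            vals = np.abs(group_filter(g2, a, w, p4))
            assert np.all(np.isfinite(vals))
            imax = np.argmax(vals)
            assert 0 < imax < len(w) - 1

    def test_example1_quality_factor_sharpens_with_cf(self, ex1, p1):
        qs = []
        for f in (200.0, 800.0, 3200.0, 6400.0):
            sigma = 2 * np.pi * f
            a = 1.0 / ex1.smap(sigma)
            w = np.linspace(1.0, ex1.band * 0.999, 200000)
            vals = np.abs(group_filter(ex1, a, w, p1))
            pk = vals.max()
            above = w[vals >= pk * 10 ** -0.5]
            qs.append(w[np.argmax(vals)] / (above.max() - above.min()))
        assert np.all(np.diff(qs) > 0)

    def test_custom_symbolic_vector_field(self):
        from cochlea.signals import parse_vector_field

        v = parse_vector_field("-omega")
        gm = build_group_model(v, (0.0, np.inf), anchor=1.0, zeros=(0.0,))
        assert flow(gm, 2.0, 4.0) == pytest.approx(2.0, abs=1e-8)

    def test_example1_validation(self):
        with pytest.raises(ValueError):
            model_example_1(R=1.0, K=2.0)
        with pytest.raises(ValueError):
            model_example_2(S=-1.0)
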