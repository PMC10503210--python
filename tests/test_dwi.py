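"""ADC fitting, computed DWI, station composition and normalisation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wbatlas as w
from wbatlas.volume import DWISeries, Volume


def _series_from_signal(s0, adc, bvals, shape=(3, 3, 3)):
    vols = {
        b: Volume(values=np.full(shape, s0 * math.exp(-b * adc))) for b in bvals
    }
    return DWISeries(vols)


class TestFitADC:
    def test_noiseless_kidney_signal_recovers_tissue_mean(self):
        # three-point signal at the healthy-cohort kidney mean (1.5T)
        series = _series_from_signal(1000.0, 1.91e-3, [50, 400, 900])
        fit = w.fit_adc(series)
        np.testing.assert_allclose(fit.adc.values, 1.91e-3, rtol=1e-12)
        np.testing.assert_allclose(fit.s0.values, 1000.0, rtol=1e-12)
        assert np.asarray(fit.valid_mask.values).all()

    def test_flat_signal_gives_zero_adc(self):
        series = _series_from_signal(123.0, 0.0, [0, 400, 900])
        fit = w.fit_adc(series)
        np.testing.assert_allclose(fit.adc.values, 0.0, atol=1e-15)
        np.testing.assert_allclose(fit.s0.values, 123.0)

    def test_two_point_fit_equals_closed_form(self):
        # oracle: ADC = ln(S1/S2) / (b2 - b1) for two b-values
        rng = np.random.default_rng(0)
        s1 = rng.uniform(50, 500, (10, 10, 1))
        s2 = rng.uniform(10, 400, (10, 10, 1))
        series = DWISeries({50.0: Volume(values=s1), 900.0: Volume(values=s2)})
        fit = w.fit_adc(series)
        oracle = np.log(s1 / s2) / (900.0 - 50.0)
        expected = np.maximum(oracle, 0.0)
        np.testing.assert_allclose(fit.adc.values, expected, rtol=1e-10)
        # voxels with negative closed-form slope are clamped and flagged
        assert (np.asarray(fit.clamped_mask.values, bool) == (oracle < 0)).all()

    def test_nonpositive_signals_invalidate_voxel(self):
        s1 = np.ones((2, 2, 1)) * 100
        s2 = np.ones((2, 2, 1)) * 50
        s2[0, 0, 0] = 0.0
        series = DWISeries({50.0: Volume(values=s1), 900.0: Volume(values=s2)})
        fit = w.fit_adc(series)
        valid = np.asarray(fit.valid_mask.values, bool)
        assert not valid[0, 0, 0] and valid[1, 1, 0]
        assert fit.adc.values[0, 0, 0] == 0.0

    def test_requires_two_bvalues_present(self):
        series = _series_from_signal(100, 1e-3, [50, 900])
        with pytest.raises(ValueError):
            w.fit_adc(series, [50])
        with pytest.raises(ValueError):
            w.fit_adc(series, [50, 400])

    @settings(deadline=None, max_examples=20)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_equivariance(self, scale):
        # multiplying all signals by c leaves ADC unchanged, scales S0 by c
        series = _series_from_signal(200.0, 0.9e-3, [50, 400, 900], shape=(2, 2, 2))
        scaled = DWISeries({b: v.with_values(v.values * scale) for b, v in series.volumes.items()})
        f0, f1 = w.fit_adc(series), w.fit_adc(scaled)
        np.testing.assert_allclose(f1.adc.values, f0.adc.values, rtol=1e-9)
        np.testing.assert_allclose(f1.s0.values, f0.s0.values * scale, rtol=1e-9)


class TestFractions:
    def test_hand_arithmetic(self):
        water = Volume(values=np.full((2, 2, 1), 3.0))
        fat = Volume(values=np.full((2, 2, 1), 1.0))
        wf, ff = w.compute_fractions(water, fat)
        np.testing.assert_allclose(wf.values, 0.75)
        np.testing.assert_allclose(ff.values, 0.25)

    def test_pure_water_and_empty_voxels(self):
        water = Volume(values=np.array([[[5.0, 0.0]]]))
        fat = Volume(values=np.zeros((1, 1, 2)))
        wf, ff = w.compute_fractions(water, fat)
        assert wf.values[0, 0, 0] == 1.0 and ff.values[0, 0, 0] == 0.0
        assert wf.values[0, 0, 1] == 0.0 and ff.values[0, 0, 1] == 0.0

    def test_negative_input_rejected(self):
        vol = Volume(values=np.full((1, 1, 1), -1.0))
        with pytest.raises(ValueError):
            w.compute_fractions(vol, Volume(values=np.ones((1, 1, 1))))


class TestComputedDWI:
    def test_identity_extrapolation(self):
        series = _series_from_signal(100, 1e-3, [50, 400, 900])
        fit = w.fit_adc(series)
        out = w.compute_cdwi(series, fit, b_target=50, b_source=50)
        np.testing.assert_allclose(out.values, series[50].values, rtol=1e-12)

    def test_scalar_forward_model(self):
        # S(50)=100, ADC=1e-3, b_target=1500 -> 100*exp(-1.45) = 23.457
        series = _series_from_signal(100 * math.exp(0.05), 1.0e-3, [50, 400, 900])
        fit = w.fit_adc(series)
        out = w.compute_cdwi(series, fit, b_target=1500, b_source=50)
        np.testing.assert_allclose(out.values, 100 * math.exp(-1.45), rtol=1e-9)

    def test_zero_adc_passes_source_through(self):
        series = _series_from_signal(77.0, 0.0, [50, 900])
        fit = w.fit_adc(series)
        out = w.compute_cdwi(series, fit, b_target=2000, b_source=50)
        np.testing.assert_allclose(out.values, 77.0, rtol=1e-9)


class TestVcDWI:
    def _voxels(self, s0, adc):
        shape = (len(s0), 1, 1)
        s0 = np.asarray(s0, float).reshape(shape)
        adc = np.asarray(adc, float).reshape(shape)
        vols = {b: Volume(values=s0 * np.exp(-b * adc)) for b in [50.0, 400.0, 900.0]}
        series = DWISeries(vols)
        return series, w.fit_adc(series)

    def test_lesion_voxel_at_least_as_bright_as_measured_b900(self):
        # low-ADC, high-S0 voxels across the sub-cutoff ADC range
        adcs = [0.1e-3, 0.3e-3, 0.7e-3, 1.2e-3, 1.9e-3]
        series, fit = self._voxels([800.0] * len(adcs), adcs)
        out = np.asarray(w.compute_vcdwi(series, fit).values).ravel()
        measured = np.asarray(series[900.0].values).ravel()
        assert (out >= measured - 1e-9).all()

    def test_free_fluid_suppressed_below_measured_b900(self):
        adcs = [2.0e-3, 2.5e-3, 3.0e-3]
        series, fit = self._voxels([800.0] * len(adcs), adcs)
        out = np.asarray(w.compute_vcdwi(series, fit).values).ravel()
        measured = np.asarray(series[900.0].values).ravel()
        assert (out < measured).all()

    def test_monotone_transform_under_uniform_adc(self):
        s0 = [100.0, 300.0, 200.0, 900.0]
        series, fit = self._voxels(s0, [1.0e-3] * 4)
        out = np.asarray(w.compute_vcdwi(series, fit).values).ravel()
        src = np.asarray(series[50.0].values).ravel()
        assert (np.argsort(out) == np.argsort(src)).all()


class TestComposeStations:
    def _stations(self, counts, seed=0):
        rng = np.random.default_rng(seed)
        return [Volume(values=rng.normal(size=(4, 5, c))) for c in counts]

    def test_two_forty_slice_stations_overlap_three_give_77(self):
        out = w.compose_stations(self._stations([40, 40]), overlap=3)
        assert out.shape[2] == 77

    def test_zero_overlap_is_concatenation(self):
        stations = self._stations([6, 7])
        out = w.compose_stations(stations, overlap=0)
        np.testing.assert_array_equal(
            out.values, np.concatenate([s.values for s in stations], axis=2)
        )

    def test_slice_provenance_three_stations(self):
        # 3 x 38 slices, overlap 2 -> 110 slices, each bit-equal to an input slice
        stations = self._stations([38, 38, 38], seed=1)
        out = w.compose_stations(stations, overlap=2)
        assert out.shape[2] == 110
        source_slices = {
            arr.tobytes()
            for s in stations
            for arr in np.moveaxis(np.asarray(s.values), 2, 0)
        }
        for k in range(out.shape[2]):
            assert np.asarray(out.values)[:, :, k].tobytes() in source_slices

    def test_overlap_too_large_rejected(self):
        with pytest.raises(ValueError):
            w.compose_stations(self._stations([5, 5]), overlap=5)


class TestHistogramMatchOverlap:
    def test_already_matched_is_near_identity(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(10, 100, (8, 8, 6))
        head = Volume(values=vals)
        neck = Volume(values=np.concatenate([vals[:, :, -3:], vals[:, :, :3]], axis=2))
        out = w.histogram_match_overlap(head, neck, overlap=3)
        np.testing.assert_allclose(out.values, head.values, rtol=0.05, atol=1.0)

    def test_pure_gain_removed_and_ranks_preserved(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(10, 100, (10, 10, 4))
        neck = Volume(values=base)
        head = Volume(values=2.0 * np.concatenate([base[:, :, 2:], base[:, :, :2]], axis=2))
        out = w.histogram_match_overlap(head, neck, overlap=4)
        ratio = np.asarray(out.values) / (np.asarray(head.values) / 2.0)
        np.testing.assert_allclose(ratio, 1.0, rtol=0.05)
        from scipy.stats import spearmanr

        rho = spearmanr(np.asarray(out.values).ravel(), np.asarray(head.values).ravel()).statistic
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_neck_histogram_maps_to_constant(self):
        head = Volume(values=np.random.default_rng(2).uniform(0, 1, (4, 4, 2)))
        neck = Volume(values=np.full((4, 4, 2), 7.0))
        out = w.histogram_match_overlap(head, neck, overlap=2)
        np.testing.assert_allclose(out.values, 7.0)


class TestNormalizeIntensity:
    def test_output_in_unit_range_and_scale_invariant(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 100, (8, 8, 8))
        vol = Volume(values=vals)
        mask = Volume(values=np.ones_like(vals))
        out1 = w.normalize_intensity(vol, mask)
        out2 = w.normalize_intensity(vol.with_values(vals * 37.5), mask)
        assert np.asarray(out1.values).min() >= 0 and np.asarray(out1.values).max() <= 1
        np.testing.assert_allclose(out1.values, out2.values, rtol=1e-9)

    def test_extreme_outlier_clipped_not_scaling(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.5, 1.5, (50, 50, 40))
        vals[0, 0, 0] = 1e6
        vol = Volume(values=vals)
        mask = Volume(values=np.ones_like(vals))
        out = np.asarray(w.normalize_intensity(vol, mask).values)
        assert out[0, 0, 0] == 1.0
        # the bulk keeps a usable dynamic range: cap set by p99.99, not max
        assert np.median(out) > 0.3

    def test_empty_or_zero_body_rejected(self):
        vol = Volume(values=np.zeros((3, 3, 3)))
        with pytest.raises(ValueError):
            w.normalize_intensity(vol, Volume(values=np.zeros((3, 3, 3))))
        with pytest.raises(ValueError):
            w.normalize_intensity(vol, Volume(values=np.ones((3, 3, 3))))
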