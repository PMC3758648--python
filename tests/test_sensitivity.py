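import numpy as np
import pytest

from hypercal.datamodel import Roi, SpectralCube, SpectralLibrary, make_wavelength_axis
from hypercal.sensitivity import (
    SpikeInSpec,
    add_spikein,
    classify_positives,
    nearest_rank_quantile,
    rescale_to_common_depth,
    run_sensitivity,
)
from hypercal.simulate import SceneObject, SceneSpec, acquire, preset, render_scene


class TestNearestRankQuantile:
    def test_spike_roi_rank(self):
        """900 values 1..900 at q = 0.985: rank ceil(886.5) = 887."""
        values = np.arange(1, 901)
        assert nearest_rank_quantile(values, 0.985) == 887.0

    def test_order_independent(self, rng):
        values = rng.permutation(np.arange(1, 901))
        assert nearest_rank_quantile(values, 0.985) == 887.0

    def test_monotone_in_q(self, rng):
        values = rng.normal(size=500)
        qs = [0.5, 0.9, 0.985, 0.9985]
        thresholds = [nearest_rank_quantile(values, q) for q in qs]
        assert thresholds == sorted(thresholds)

    def test_invalid_q_rejected(self):
        with pytest.raises(ValueError):
            nearest_rank_quantile([1, 2, 3], 1.0)


class TestRescale:
    def test_full_scale_endpoint(self, axis5):
        cube = SpectralCube(np.full((1, 1, 5), 4095.0), axis5, bit_depth=12)
        out = rescale_to_common_depth(cube, 16)
        assert np.allclose(out.data, 65535.0)
        assert out.bit_depth == 16

    def test_zero_maps_to_zero(self, axis5):
        cube = SpectralCube(np.zeros((1, 1, 5)), axis5, bit_depth=12)
        assert not rescale_to_common_depth(cube, 16).data.any()

    def test_direct_arithmetic(self, axis5):
        cube = SpectralCube(np.full((1, 1, 5), 1000.0), axis5, bit_depth=12)
        out = rescale_to_common_depth(cube, 16)
        # 1000 * 65535/4095, computed independently
        assert out.data[0, 0, 0] == pytest.approx(16003.663003663, rel=1e-9)


class TestAddSpikein:
    def test_zero_level_identity(self, confocal_library, rng):
        data = rng.uniform(0, 100, (8, 8, 32))
        cube = SpectralCube(data, confocal_library.axis)
        roi = Roi.square((8, 8), 4)
        out = add_spikein(cube, confocal_library.spectrum("GFP"), roi, 0.0)
        assert np.array_equal(out.data, data)

    def test_roi_spectra_peak_anchored(self, confocal_library):
        cube = SpectralCube(np.zeros((8, 8, 32)), confocal_library.axis)
        roi = Roi.square((8, 8), 4)
        s = confocal_library.spectrum("GFP")
        out = add_spikein(cube, s, roi, 100.0)
        expected = s * (100.0 / s.max())
        assert np.allclose(out.data[roi.mask], expected)
        assert out.data[roi.mask].max() == pytest.approx(100.0)

    def test_outside_roi_untouched(self, confocal_library, rng):
        data = rng.uniform(0, 100, (8, 8, 32))
        cube = SpectralCube(data, confocal_library.axis)
        roi = Roi.square((8, 8), 4)
        out = add_spikein(cube, confocal_library.spectrum("GFP"), roi, 500.0)
        assert np.array_equal(out.data[~roi.mask], data[~roi.mask])

    def test_zero_spectrum_rejected(self, confocal_library):
        cube = SpectralCube(np.zeros((4, 4, 32)), confocal_library.axis)
        with pytest.raises(ValueError, match="all-zero"):
            add_spikein(cube, np.zeros(32), Roi.square((4, 4), 2), 10.0)


class TestClassifyPositives:
    def test_fraction_reported_as_percentage(self):
        """157 positives among 262,144 pixels is 0.06%."""
        img = np.zeros(262_144)
        img[:157] = 10.0
        _, count, pct = classify_positives(img.reshape(512, 512), 5.0)
        assert count == 157
        assert round(pct, 2) == 0.06

    def test_threshold_above_max(self, rng):
        img = rng.uniform(0, 1, (10, 10))
        _, count, _ = classify_positives(img, 2.0)
        assert count == 0

    def test_zero_threshold_on_nonnegative(self, rng):
        img = rng.uniform(0, 1, (10, 10))
        _, count, pct = classify_positives(img, 0.0)
        assert count == 100 and pct == 100.0

    def test_strict_mode_excludes_ties(self):
        img = np.array([[1.0, 2.0], [2.0, 3.0]])
        _, inclusive, _ = classify_positives(img, 2.0)
        _, strict, _ = classify_positives(img, 2.0, inclusive=False)
        assert inclusive == 3 and strict == 1


@pytest.fixture
def af_library(confocal_library):
    """Two-endmember library: the spike target plus the background."""
    return SpectralLibrary(
        ["GFP", "AF"],
        np.vstack([confocal_library.spectrum("GFP"), confocal_library.spectrum("AF")]),
        confocal_library.axis,
        confocal_library.normalization,
    )


def _noise_free_af_control(af_library, level=150.0, shape=(48, 48)):
    scene = SceneSpec(shape, [SceneObject("AF", "background", level)], seed=0)
    _, cube = render_scene(scene, af_library)
    return cube


class TestRunSensitivity:
    def test_noise_free_ideal_response(self, af_library):
        """A noise-free pure-background control responds with slope exactly 1
        (peak-normalized library) and no false positives at any level."""
        control = _noise_free_af_control(af_library)
        spec = SpikeInSpec("GFP", roi=Roi.square((48, 48), 30),
                           levels=tuple(range(0, 1001, 100)), scale_to_bits=None)
        report = run_sensitivity(control, af_library, spec)
        assert report.slope == pytest.approx(1.0, abs=1e-6)
        assert report.intercept == pytest.approx(0.0, abs=1e-6)
        assert np.all(report.false_positive_fraction == 0.0)
        # every spiked level detects the full ROI
        assert np.all(report.positive_counts[1:] == 900)

    def test_levels_must_include_zero(self):
        with pytest.raises(ValueError, match="include 0"):
            SpikeInSpec("GFP", levels=(100, 200))

    def test_threshold_is_null_quantile(self, af_library):
        sys_preset = preset("confocal")
        control_nf = _noise_free_af_control(af_library)
        control = acquire(control_nf, sys_preset.detector, 1, seed=4).cubes[0]
        spec = SpikeInSpec("GFP", roi=Roi.square((48, 48), 30),
                           levels=(0, 500), scale_to_bits=None)
        report = run_sensitivity(control, af_library, spec)
        null = report.roi_abundances[0]
        assert report.threshold == nearest_rank_quantile(null, spec.quantile)
        assert report.n_roi_pixels == 900

    def test_level0_positive_count_bounded(self, af_library):
        """At level 0 the in-ROI positive count cannot exceed the quantile
        complement of the ROI size."""
        sys_preset = preset("confocal")
        control = acquire(_noise_free_af_control(af_library),
                          sys_preset.detector, 1, seed=7).cubes[0]
        roi = Roi.square((48, 48), 30)
        spec = SpikeInSpec("GFP", roi=roi, levels=(0, 500), scale_to_bits=None)
        report = run_sensitivity(control, af_library, spec)
        res0 = report.roi_abundances[0]
        in_roi_positives = int((res0 > report.threshold).sum())
        assert in_roi_positives <= int(np.ceil((1 - spec.quantile) * roi.n_pixels))

    def test_positive_counts_monotone_in_quantile(self, af_library):
        """Raising the detection quantile never increases positive counts."""
        sys_preset = preset("confocal")
        control = acquire(_noise_free_af_control(af_library),
                          sys_preset.detector, 1, seed=9).cubes[0]
        counts = []
        for q in (0.90, 0.985, 0.9985):
            spec = SpikeInSpec("GFP", roi=Roi.square((48, 48), 30),
                               levels=(0, 200, 400), quantile=q, scale_to_bits=None)
            counts.append(run_sensitivity(control, af_library, spec).positive_counts)
        for lo, hi in zip(counts[1:], counts[:-1]):
            assert np.all(lo <= hi)

    def test_noisier_system_more_false_positives(self, af_library):
        """At a fixed shared threshold, the preset with larger null-abundance
        variance yields the higher false-positive fraction."""
        reports = {}
        for name in ("widefield", "confocal"):
            sys_preset = preset(name)
            lib = sys_preset.library()
            two = SpectralLibrary(
                ["GFP", "AF"],
                np.vstack([lib.spectrum("GFP"), lib.spectrum("AF")]),
                lib.axis, lib.normalization,
            )
            scene = SceneSpec((48, 48), [SceneObject("AF", "background", 150.0)], seed=1)
            _, nf = render_scene(scene, two)
            control = acquire(nf, sys_preset.detector, 1, seed=13).cubes[0]
            spec = SpikeInSpec("GFP", roi=Roi.square((48, 48), 30), levels=(0, 500))
            reports[name] = run_sensitivity(control, two, spec)
        var = {k: float(np.var(r.roi_abundances[0])) for k, r in reports.items()}
        noisier = max(var, key=var.get)
        quieter = min(var, key=var.get)
        shared_threshold = max(r.threshold for r in reports.values())
        # classify both systems' level-0 null abundances at the shared threshold
        fp = {}
        for k, r in reports.items():
            null = r.roi_abundances[0]
            fp[k] = float((null > shared_threshold).mean())
        assert fp[noisier] >= fp[quieter]

    def test_target_must_be_in_library(self, af_library):
        control = _noise_free_af_control(af_library)
        spec = SpikeInSpec("mCherry", roi=Roi.square((48, 48), 30), levels=(0, 100))
        with pytest.raises(ValueError, match="mCherry"):
            run_sensitivity(control, af_library, spec)

    def test_report_summary_prints(self, af_library):
        control = _noise_free_af_control(af_library)
        spec = SpikeInSpec("GFP", roi=Roi.square((48, 48), 30),
                           levels=(0, 500, 1000), scale_to_bits=None)
        text = run_sensitivity(control, af_library, spec).summary()
        assert "GFP" in text and "threshold" in text

    def test_report_plot_smoke(self, af_library):
        import matplotlib

        matplotlib.use("Agg")
        control = _noise_free_af_control(af_library)
        spec = SpikeInSpec("GFP", roi=Roi.square((48, 48), 30),
                           levels=(0, 500, 1000), scale_to_bits=None)
        ax = run_sensitivity(control, af_library, spec).plot()
        assert ax.get_xlabel().startswith("GFP")
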