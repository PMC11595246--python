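"""Spectral chain: normalization, stitching, masking, FFT, peaks, images."""

import numpy as np
import pytest

import timewrap as tw
from timewrap.physics import frequency_from_wavenumber
from timewrap.spectral import StitchedTrace, _next_pow2
from conftest import single_line_raw


def damped_cosine_trace(center_cm=90.0, span_fs=4500.0, n=270, t0=0.0):
    """Uniform cosine trace used as a direct FFT input."""
    tau = t0 + np.arange(n) * (span_fs / n)
    f = frequency_from_wavenumber(center_cm) * 1e-3  # cycles per fs
    return StitchedTrace(delays=tau, values=np.cos(2 * np.pi * f * tau))


def pixel_windows(raw, y=0, x=0):
    """Split one pixel's registered traces into per-window pieces."""
    cfg = raw.config
    cubes = tw.reshape_to_cubes(raw)
    nw, ntau = cfg.n_windows, cfg.n_delay_samples
    raman = cubes.raman_cube[y, x].reshape(nw, ntau)
    trans = cubes.transmission_cube[y, x].reshape(nw, ntau)
    axes = [tw.build_delay_axis(cfg, w) for w in range(nw)]
    return raman, trans, axes


class TestNormalizeByTransmission:
    def test_constant_transmission_scales(self):
        raman = np.sin(np.linspace(0, 6, 100))
        out, valid = tw.normalize_by_transmission(raman, np.full(100, 0.5))
        assert valid.all()
        np.testing.assert_allclose(out, 2 * raman)

    def test_recovers_ground_truth_transient(self, bgo_raw, bgo_cubes):
        gt = bgo_raw.ground_truth.transient[0, 0]
        out, valid = tw.normalize_by_transmission(
            bgo_cubes.raman_cube[0, 0], bgo_cubes.transmission_cube[0, 0]
        )
        scale = np.max(np.abs(gt))
        np.testing.assert_allclose(out[valid], gt[valid], atol=1e-10 * scale)

    def test_envelope_zeros_marked_invalid_never_infinite(self, bgo_cubes):
        out, valid = tw.normalize_by_transmission(
            bgo_cubes.raman_cube[0, 0], bgo_cubes.transmission_cube[0, 0]
        )
        assert not valid[0] and not valid[-1]
        assert np.all(np.isfinite(out))

    def test_all_below_floor_errors_with_pixel(self):
        with pytest.raises(ValueError, match=r"\(2, 3\)"):
            tw.normalize_by_transmission(
                np.ones(10), np.zeros(10), pixel=(2, 3)
            )


class TestStitchWindows:
    def test_single_window_identity(self, bgo_raw):
        raman, trans, axes = pixel_windows(bgo_raw)
        norm, valid = tw.normalize_by_transmission(raman[0], trans[0])
        st = tw.stitch_windows([norm], axes, [trans[0]], [valid])
        idx = np.flatnonzero(valid)
        np.testing.assert_array_equal(st.values, norm[idx[0] : idx[-1] + 1])
        np.testing.assert_array_equal(st.delays, axes[0].values[idx[0] : idx[-1] + 1])
        assert st.junctions.size == 0

    def test_two_window_stitch_matches_analytic_transient(self):
        """Stitched trace of a pure damped line vs the closed-form
        transient evaluated on the stitched axis: <=1% RMS."""
        cfg = tw.AcquisitionConfig(n_macro_x=1, n_lines_y=1, n_windows=2)
        raw = single_line_raw(cfg, center=90.0, t2=100.0, with_spike=False)
        raman, trans, axes = pixel_windows(raw)
        norm, masks = [], []
        for w in range(2):
            t, m = tw.normalize_by_transmission(raman[w], trans[w])
            norm.append(t)
            masks.append(m)
        st = tw.stitch_windows(norm, axes, list(trans), masks)
        line = tw.VibrationalLine(90.0, 1.0, 100.0)
        oracle = tw.transient_trace(
            [line], tw.DelayAxis(st.delays), overlap_amplitude=0.0
        )
        rms = np.sqrt(np.mean((st.values - oracle) ** 2))
        assert rms <= 0.01 * np.max(np.abs(oracle))
        assert st.junctions.size == 1

    def test_value_and_slope_continuous_at_junction(self):
        cfg = tw.AcquisitionConfig(n_macro_x=1, n_lines_y=1, n_windows=3)
        raw = single_line_raw(cfg, center=90.0, t2=100.0, with_spike=False)
        raman, trans, axes = pixel_windows(raw)
        norm, masks = [], []
        for w in range(3):
            t, m = tw.normalize_by_transmission(raman[w], trans[w])
            norm.append(t)
            masks.append(m)
        st = tw.stitch_windows(norm, axes, list(trans), masks)
        jumps = np.abs(np.diff(st.values))
        interior = np.ones(jumps.size, dtype=bool)
        near_junction = np.zeros(jumps.size, dtype=bool)
        for j in st.junctions:
            near_junction[max(j - 5, 0) : j + 5] = True
        assert jumps[near_junction].max() <= jumps[~near_junction].max()

    def test_subrange_processing_agrees_on_shared_support(self):
        """Stitching windows [0..2] and [1..2] gives the same trace on the
        delays both cover, away from the junction only the full range has."""
        cfg = tw.AcquisitionConfig(n_macro_x=1, n_lines_y=1, n_windows=3)
        raw = single_line_raw(cfg, center=90.0, t2=100.0, with_spike=False)
        raman, trans, axes = pixel_windows(raw)
        norm, masks = [], []
        for w in range(3):
            t, m = tw.normalize_by_transmission(raman[w], trans[w])
            norm.append(t)
            masks.append(m)
        full = tw.stitch_windows(norm, axes, list(trans), masks)
        sub = tw.stitch_windows(norm[1:], axes[1:], list(trans[1:]), masks[1:])
        first_junction = full.delays[full.junctions[0]]
        lo = first_junction + 10 * full.step  # clear of the 0-1 guard refit
        common = (sub.delays >= lo) & (sub.delays <= full.delays[-1])
        interp_full = np.interp(sub.delays[common], full.delays, full.values)
        np.testing.assert_allclose(interp_full, sub.values[common], atol=1e-9)

    def test_non_overlapping_windows_rejected(self):
        cfg = tw.AcquisitionConfig(
            n_macro_x=1, n_lines_y=1, n_windows=2, mechanical_step=6.0
        )
        raw = single_line_raw(cfg, with_spike=False)
        raman, trans, axes = pixel_windows(raw)
        norm = [tw.normalize_by_transmission(raman[w], trans[w])[0] for w in range(2)]
        with pytest.raises(ValueError, match="overlap"):
            tw.stitch_windows(norm, axes, list(trans))


class TestMaskOverlap:
    def test_alpha_zero_is_rectangular_gate(self):
        tr = damped_cosine_trace()
        masked = tw.mask_overlap(tr, cut_delay=300.0, tukey_alpha=0.0)
        kept = tr.delays >= 300.0
        assert np.all(masked.values[~kept] == 0)
        expected = tr.values[kept] - tr.values[kept].mean()
        np.testing.assert_allclose(masked.values[kept], expected, atol=1e-12)

    def test_all_zero_trace_stays_zero(self):
        tr = StitchedTrace(delays=np.arange(100.0), values=np.zeros(100))
        masked = tw.mask_overlap(tr, cut_delay=10.0)
        assert np.all(masked.values == 0)

    def test_cut_beyond_end_rejected(self):
        tr = damped_cosine_trace()
        with pytest.raises(ValueError):
            tw.mask_overlap(tr, cut_delay=1e6)

    def test_spike_masked_spectrum_peak_unmoved(self, single_pixel_config):
        """The 10x overlap spike, once gated, shifts the recovered peak by
        at most one padded-FFT bin relative to a spike-free run."""
        specs = []
        for with_spike in (False, True):
            raw = single_line_raw(single_pixel_config, with_spike=with_spike)
            hc = tw.process_acquisition(raw)
            specs.append(tw.roi_spectrum(hc, np.ones((1, 1), dtype=bool)))
        peaks = [tw.peak_stats(s, band=(10.0, 150.0)).position for s in specs]
        assert abs(peaks[0] - peaks[1]) <= specs[0].bin_width


class TestComputeSpectrum:
    def test_cosine_peak_within_one_bin(self):
        tr = damped_cosine_trace(center_cm=90.0)
        spec = tw.compute_spectrum(tr, pad_factor=8)
        peak = spec.wavenumbers[np.argmax(spec.magnitude)]
        assert abs(peak - 90.0) <= spec.bin_width

    def test_parseval_energy_conservation(self):
        tr = damped_cosine_trace()
        spec = tw.compute_spectrum(tr, pad_factor=4, mode="magnitude")
        n = spec.metadata["n_fft"]
        # fold the one-sided magnitudes back into the full-DFT energy sum
        energy = spec.magnitude[0] ** 2 + 2 * np.sum(spec.magnitude[1:-1] ** 2)
        energy += spec.magnitude[-1] ** 2 if n % 2 == 0 else 2 * spec.magnitude[-1] ** 2
        assert energy / n == pytest.approx(np.sum(tr.values**2), rel=1e-10)

    def test_axis_definition(self):
        tr = damped_cosine_trace(n=256)
        spec = tw.compute_spectrum(tr, pad_factor=2)
        assert spec.wavenumbers[0] == 0.0
        total_duration_s = spec.metadata["n_fft"] * tr.step * 1e-15
        from scipy.constants import c

        assert spec.bin_width == pytest.approx(1 / total_duration_s / (100 * c))

    def test_non_uniform_axis_rejected(self):
        delays = np.concatenate([np.arange(100.0), [100.5]])
        tr = StitchedTrace(delays=delays, values=np.zeros(101))
        with pytest.raises(ValueError, match="uniform"):
            tw.compute_spectrum(tr)

    def test_next_pow2(self):
        assert _next_pow2(270) == 512
        assert _next_pow2(512) == 512


class TestPeakStats:
    def test_triangular_peak_fwhm(self):
        wn = np.linspace(0.0, 200.0, 2001)
        mag = np.clip(1.0 - np.abs(wn - 90.0) / 10.0, 0.0, None)  # base 2w, w=10
        stats = tw.peak_stats(tw.Spectrum(wn, mag), band=(50.0, 130.0))
        assert stats.position == pytest.approx(90.0, abs=0.1)
        assert stats.fwhm == pytest.approx(10.0, abs=0.1)
        assert not stats.on_edge

    def test_fwhm_halves_when_trace_doubles(self):
        """Window-limited linewidth scales as 1/T for an undamped line."""
        fwhms = []
        for n, span in ((270, 4500.0), (540, 9000.0)):
            tr = damped_cosine_trace(center_cm=90.0, span_fs=span, n=n)
            spec = tw.compute_spectrum(tr, pad_factor=8, mode="magnitude")
            fwhms.append(tw.peak_stats(spec, band=(50.0, 130.0)).fwhm)
        assert fwhms[0] / fwhms[1] == pytest.approx(2.0, rel=0.05)

    def test_band_edge_peak_flagged(self):
        wn = np.linspace(0.0, 100.0, 101)
        mag = wn.copy()  # monotone: argmax sits on the band edge
        stats = tw.peak_stats(tw.Spectrum(wn, mag), band=(10.0, 50.0))
        assert stats.on_edge


class TestProcessCube:
    def test_matches_manual_chain_single_pixel(self, single_pixel_config):
        raw = single_line_raw(single_pixel_config)
        cubes = tw.reshape_to_cubes(raw)
        params = tw.ProcessingParams()
        hc = tw.process_cube(cubes, params=params)

        raman, trans, axes = pixel_windows(raw)
        norm, m = tw.normalize_by_transmission(raman[0], trans[0], params.floor_fraction)
        st = tw.stitch_windows([norm], axes, [trans[0]], [m], guard=params.guard)
        masked = tw.mask_overlap(st, params.cut_delay, params.tukey_alpha)
        spec = tw.compute_spectrum(
            masked, params.pad_factor, params.mode, n_fft=hc.data.shape[-1] * 2 - 2
        )
        np.testing.assert_allclose(hc.data[0, 0], spec.magnitude)

    def test_shared_axis_and_finiteness(self, two_species_small):
        _, _, hc = two_species_small
        assert np.all(np.isfinite(hc.data))
        assert hc.wavenumbers.ndim == 1
        assert hc.data.shape[-1] == hc.wavenumbers.size

    def test_noisy_cube_has_no_nonfinite_values(self, small_config):
        phantom = tw.bgo_phantom(small_config)
        raw = tw.simulate_acquisition(
            phantom,
            small_config,
            tw.NoiseModel(raman_sigma=0.01, transmission_sigma=0.01, seed=2),
        )
        hc = tw.process_acquisition(raw)
        assert np.all(np.isfinite(hc.data))

    def test_linearity_of_spectral_chain(self, single_pixel_config):
        """Doubling every line amplitude doubles every magnitude bin."""
        specs = []
        for amp in (1.0, 2.0):
            phantom = tw.Phantom(
                np.zeros((1, 1), dtype=int),
                {0: [tw.VibrationalLine(90.0, amp, 10.0)]},
            )
            raw = tw.simulate_acquisition(phantom, single_pixel_config)
            hc = tw.process_acquisition(
                raw, tw.ProcessingParams(mode="magnitude")
            )
            specs.append(hc.data[0, 0])
        ref = specs[0]
        sel = ref > 1e-9 * ref.max()
        np.testing.assert_allclose(specs[1][sel] / ref[sel], 2.0, rtol=1e-9)

    def test_recovery_sweep_random_lines(self):
        """End-to-end recovery: any line below the bandwidth limits comes
        back within one padded-FFT bin of its configured center."""
        cfg = tw.AcquisitionConfig(n_macro_x=1, n_lines_y=1)
        rng = np.random.default_rng(1234)
        centers = rng.uniform(20.0, 200.0, size=10)
        limit = min(
            tw.nyquist_max_shift(cfg.delay_step_fs),
            tw.max_shift_for_filter(cfg.detection_filter, cfg.delay_scaling),
        )
        assert np.all(centers < limit)
        for center in centers:
            raw = single_line_raw(cfg, center=center, t2=20.0)
            hc = tw.process_acquisition(raw)
            spec = tw.roi_spectrum(hc, np.ones((1, 1), dtype=bool))
            peak = tw.peak_stats(spec, band=(10.0, 250.0)).position
            assert abs(peak - center) <= spec.bin_width


class TestImagesAndRois:
    def test_slice_normalization_modes(self, two_species_small):
        _, _, hc = two_species_small
        img = tw.frequency_slice(hc, 56.0, normalize="image-max")
        assert img.max() == pytest.approx(1.0)
        raw_img = tw.frequency_slice(hc, 56.0, smooth=False, normalize="none")
        i = int(np.argmin(np.abs(hc.wavenumbers - 56.0)))
        np.testing.assert_array_equal(raw_img, hc.data[:, :, i])

    def test_chemical_contrast(self, two_species_small):
        _, phantom, hc = two_species_small
        rois = tw.two_species_rois(phantom)
        img = tw.frequency_slice(hc, 56.0, smooth=True, normalize="cube-max")
        a = img[rois["acetaminophen"]].mean()
        b = img[rois["anthracene"]].mean()
        assert a >= 5 * b

    def test_out_of_range_shift_rejected(self, two_species_small):
        _, _, hc = two_species_small
        with pytest.raises(ValueError):
            tw.frequency_slice(hc, hc.wavenumbers[-1] + 1.0)

    def test_single_pixel_roi_is_that_pixel(self, two_species_small):
        _, _, hc = two_species_small
        mask = np.zeros(hc.pixel_valid.shape, dtype=bool)
        mask[3, 4] = True
        spec = tw.roi_spectrum(hc, mask)
        np.testing.assert_array_equal(spec.magnitude, hc.data[3, 4])

    def test_whole_fov_contains_both_species_peaks(self, two_species_small):
        _, phantom, hc = two_species_small
        spec = tw.roi_spectrum(hc, np.ones(hc.pixel_valid.shape, dtype=bool))
        wn, mag = spec.wavenumbers, spec.magnitude
        for center in (56.0, 37.0):
            sel = np.abs(wn - center) <= 3.0
            near = mag[sel].max()
            background = np.median(mag[(wn >= 10) & (wn <= 150)])
            assert near > 10 * background

    def test_empty_roi_rejected(self, two_species_small):
        _, _, hc = two_species_small
        with pytest.raises(ValueError):
            tw.roi_spectrum(hc, np.zeros(hc.pixel_valid.shape, dtype=bool))

    def test_roi_equals_brute_force_pixel_mean(self, two_species_small):
        _, _, hc = two_species_small
        mask = np.zeros(hc.pixel_valid.shape, dtype=bool)
        mask[2:6, 3:9] = True
        spec = tw.roi_spectrum(hc, mask)
        brute = np.mean([hc.data[y, x] for y, x in zip(*np.where(mask))], axis=0)
        np.testing.assert_allclose(spec.magnitude, brute, rtol=1e-12)
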