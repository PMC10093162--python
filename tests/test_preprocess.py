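"""Preprocessing chain: baseline, TIC normalization, peak picking, alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import msidissect as md
from msidissect.preprocess import build_peak_table


def profile_spectrum(intensities):
    n = len(intensities)
    return md.Spectrum(np.linspace(600.0, 3200.0, n), np.asarray(intensities, dtype=float))


class TestBaseline:
    def test_constant_spectrum_is_pure_baseline(self):
        sp = profile_spectrum(np.full(300, 7.5))
        out = md.subtract_baseline(sp, half_width=20)
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-12)

    def test_all_zero_stays_zero(self):
        sp = profile_spectrum(np.zeros(300))
        out = md.subtract_baseline(sp, half_width=20)
        np.testing.assert_array_equal(out.intensity, 0.0)

    def test_gaussian_peak_on_ramp_recovered(self):
        # planted truth is the oracle: ramp 0->50 over 1000 bins, one
        # Gaussian peak (sigma 3 bins, height 100) at bin 500
        n, half_width = 1000, 50
        bins = np.arange(n)
        ramp = 50.0 * bins / (n - 1)
        peak = 100.0 * np.exp(-0.5 * ((bins - 500) / 3.0) ** 2)
        sp = profile_spectrum(ramp + peak)
        out = md.subtract_baseline(sp, half_width=half_width)
        apex = out.intensity[500]
        assert abs(apex - 100.0) <= 5.0  # within 5% of planted height
        # ramp removed away from the peak (interior, outside 5 sigma)
        interior = np.ones(n, dtype=bool)
        interior[: 2 * half_width + 1] = interior[-(2 * half_width + 1):] = False
        interior[500 - 15 : 500 + 16] = False
        assert np.max(out.intensity[interior]) < 2.0

    def test_idempotent_on_representable_baseline(self):
        n = 600
        flat = np.zeros(n)
        flat[300] = 80.0  # isolated narrow peak, zero baseline
        sp = profile_spectrum(flat + 4.0)
        once = md.subtract_baseline(sp, half_width=40)
        twice = md.subtract_baseline(once, half_width=40)
        np.testing.assert_allclose(twice.intensity, once.intensity, atol=1e-6)

    def test_half_width_bounds(self):
        sp = profile_spectrum(np.ones(10))
        with pytest.raises(ValueError):
            md.subtract_baseline(sp, half_width=10)
        with pytest.raises(ValueError):
            md.subtract_baseline(sp, half_width=0)


class TestTicNormalize:
    @pytest.mark.parametrize(
        "vec,target,expected",
        [([1, 3], 1.0, [0.25, 0.75]), ([5, 5, 10], 100.0, [25, 25, 50])],
    )
    def test_definition(self, vec, target, expected):
        np.testing.assert_allclose(md.tic_normalize(np.array(vec, float), target), expected)

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(st.floats(min_value=0, max_value=1e6), min_size=1, max_size=50).filter(
            lambda v: sum(v) > 0
        ),
        st.floats(min_value=1e-3, max_value=1e6),
    )
    def test_sum_equals_target(self, vec, target):
        out = md.tic_normalize(np.array(vec), target)
        assert out.sum() == pytest.approx(target, rel=1e-12)

    def test_all_zero_flagged_and_unchanged(self):
        out = md.tic_normalize(np.zeros(4), 10.0)
        np.testing.assert_array_equal(out, 0.0)

    def test_spectrum_in_spectrum_out(self):
        sp = md.Spectrum([700.0, 800.0], [2.0, 6.0])
        out = md.tic_normalize(sp, 1.0)
        assert isinstance(out, md.Spectrum)
        np.testing.assert_allclose(out.intensity, [0.25, 0.75])


class TestPickPeaks:
    def test_single_triangle_peak(self):
        inten = np.zeros(101)
        inten[48:53] = [25, 50, 100, 50, 25]
        sp = profile_spectrum(inten)
        peaks = md.pick_peaks(sp, snr=1.0)
        assert len(peaks) == 1
        assert peaks[0][1] == 100.0

    def test_pure_noise_at_extreme_snr(self):
        rng = np.random.default_rng(0)
        sp = profile_spectrum(np.abs(rng.normal(0, 1, 500)))
        assert md.pick_peaks(sp, snr=1e6) == []

    def test_snr_must_be_positive(self):
        with pytest.raises(ValueError):
            md.pick_peaks(profile_spectrum(np.ones(10)), snr=0)

    def test_planted_peaks_recovered(self):
        # 20 peaks at SNR ~ 20 over baseline-free noise, snr threshold 5
        rng = np.random.default_rng(42)
        n = 4000
        axis = np.linspace(600, 3200, n)
        noise_sigma = 5.0
        inten = np.abs(rng.normal(0, noise_sigma, n))
        planted_bins = np.linspace(150, n - 150, 20).astype(int)
        for b in planted_bins:
            inten[b - 2 : b + 3] += 20 * noise_sigma * np.array([0.2, 0.6, 1.0, 0.6, 0.2])
        peaks = md.pick_peaks(md.Spectrum(axis, inten), snr=5.0)
        peak_bins = [int(np.argmin(np.abs(axis - mz))) for mz, _ in peaks]
        recovered = sum(
            any(abs(pb - b) <= 1 for pb in peak_bins) for b in planted_bins
        )
        assert recovered >= 19


class TestAlignPeaks:
    def test_identical_peak_two_pixels(self):
        table = md.align_peaks(
            [[(1000.0, 5.0)], [(1000.0, 7.0)]], [(0, 0), (1, 0)], tolerance_da=0.3
        )
        assert table.n_bins == 1
        assert (table.matrix > 0).all()

    @pytest.mark.parametrize("tol,expected_bins", [(0.3, 1), (0.05, 2)])
    def test_gap_rule(self, tol, expected_bins):
        table = md.align_peaks(
            [[(1000.0, 1.0), (1000.10, 1.0)]], [(0, 0)], tolerance_da=tol
        )
        assert table.n_bins == expected_bins

    def test_tolerance_must_be_positive(self):
        with pytest.raises(ValueError):
            md.align_peaks([[(1000.0, 1.0)]], [(0, 0)], tolerance_da=0)

    def test_planted_species_recovered(self):
        # 100 pixels, 50 species jittered N(0, 0.05) Da, tolerance 0.3
        rng = np.random.default_rng(11)
        species = np.sort(rng.uniform(620, 3180, 50))
        while np.any(np.diff(species) < 1.0):  # enforce the spacing the phantom uses
            species = np.sort(rng.uniform(620, 3180, 50))
        pixels = [(i % 10, i // 10) for i in range(100)]
        lists = [
            [(mz + rng.normal(0, 0.05), 10.0) for mz in species] for _ in pixels
        ]
        lists = [sorted(l) for l in lists]
        table = md.align_peaks(lists, pixels, tolerance_da=0.3)
        assert table.n_bins == 50
        np.testing.assert_allclose(table.bin_centers, species, atol=0.1)

    def test_permutation_invariance_and_monotonicity(self):
        rng = np.random.default_rng(5)
        pixels = [(i, 0) for i in range(20)]
        lists = [
            sorted((float(m), float(v)) for m, v in zip(rng.uniform(600, 700, 8), rng.uniform(1, 9, 8)))
            for _ in pixels
        ]
        base = md.align_peaks(lists, pixels, tolerance_da=0.2)
        perm = rng.permutation(20)
        shuffled = md.align_peaks([lists[i] for i in perm], [pixels[i] for i in perm], tolerance_da=0.2)
        np.testing.assert_allclose(np.sort(base.bin_centers), np.sort(shuffled.bin_centers))
        assert base.matrix.sum() == pytest.approx(shuffled.matrix.sum())
        prev_bins = None
        for tol in (0.05, 0.1, 0.5, 2.0, 10.0):
            nb = md.align_peaks(lists, pixels, tolerance_da=tol).n_bins
            if prev_bins is not None:
                assert nb <= prev_bins
            prev_bins = nb


class TestBuildPeakTable:
    def test_tic_conservation_invariant(self, phantom_bundle):
        table = phantom_bundle["table"]
        sums = table.matrix.sum(axis=1)
        nonblank = ~table.empty_rows()
        target = table.provenance["tic_target"]
        np.testing.assert_allclose(sums[nonblank], target, rtol=1e-9)
        assert np.all(sums[~nonblank] == 0)

    def test_csv_round_trip(self, tmp_path, phantom_bundle):
        table = phantom_bundle["table"]
        table.to_csv(tmp_path / "pt.csv")
        back = md.PeakTable.from_csv(tmp_path / "pt.csv")
        np.testing.assert_allclose(back.bin_centers, table.bin_centers, rtol=1e-9)
        np.testing.assert_allclose(back.matrix, table.matrix, rtol=1e-6, atol=1e-9)
        assert back.pixel_index == table.pixel_index

    def test_profile_mode_chain(self):
        # tiny profile dataset: 4 pixels, 2 planted peaks on a ramp baseline
        n = 1200
        axis = np.linspace(600.0, 3200.0, n)
        rng = np.random.default_rng(3)
        pixels, spectra = [], []
        for i in range(4):
            ramp = np.linspace(0, 30, n)
            inten = ramp.copy()
            for center, height in [(300, 400.0), (800, 300.0)]:
                inten[center - 2 : center + 3] += height * np.array([0.2, 0.6, 1.0, 0.6, 0.2])
            inten += np.abs(rng.normal(0, 2.0, n))
            pixels.append((i, 0))
            spectra.append(md.Spectrum(axis, inten))
        ds = md.MSIDataset(pixels=pixels, spectra=spectra, mode="profile")
        table = build_peak_table(ds, baseline_half_width=50, snr=5.0, tolerance_da=3.0)
        # both planted species present in every pixel
        for target_bin in (axis[300], axis[800]):
            j = int(np.argmin(np.abs(table.bin_centers - target_bin)))
            assert abs(table.bin_centers[j] - target_bin) < 3.0
            assert (table.matrix[:, j] > 0).all()
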