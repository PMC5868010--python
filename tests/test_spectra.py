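"""FTIR/2D spectra: stick placement, scaling laws, slices, disorder."""

import numpy as np
import pytest

import dihedralir as d
from dihedralir import coupling, exciton, spectra
from dihedralir.spectra import LineshapeParams, default_grid

from test_exciton import antiparallel_dimer, parallel_dimer


def single_site(freq=1650.0):
    model = d.build_model([d.ALPHA_HELIX], site_frequency=freq)
    model.dipoles[0].direction = np.array([0.0, 0.0, 1.0])
    return model, np.zeros((1, 1))


class TestFtir:
    def test_parallel_dimer_single_band_at_upshifted_frequency(self):
        model, couplings = parallel_dimer(1595.0, 8.3)
        sys_ = exciton.solve(model, couplings)
        spec = d.ftir(sys_, LineshapeParams(fwhm=8.0))
        assert spec.grid[np.argmax(spec.intensity)] == pytest.approx(
            1595.0 + 8.3, abs=0.5)

    def test_helix_dimer_upper_peak_more_intense(self):
        model = d.build_model([d.ALPHA_HELIX] * 2, site_frequency=1595.0)
        beta = coupling.coupling_matrix(model)
        sys_ = exciton.solve(model, beta)
        w = sys_.mu01_sq()
        assert sys_.e1[1] > sys_.e1[0] and w[1] > w[0]

    def test_strand_dimer_lower_peak_more_intense(self):
        model = d.build_model([d.PARALLEL_BETA_STRAND] * 2,
                              site_frequency=1595.0)
        beta = coupling.coupling_matrix(model)
        sys_ = exciton.solve(model, beta)
        w = sys_.mu01_sq()
        assert w[0] > w[1]  # anti-parallel carbonyls: lower state bright

    def test_integrated_intensity_conserved_under_coupling(self):
        grid = default_grid(1200.0, 2000.0, 0.25)
        lines = LineshapeParams(profile="gaussian", fwhm=8.0)
        model, _ = parallel_dimer(1595.0, 0.0)
        uncoupled = d.ftir(exciton.solve(model, np.zeros((2, 2))), lines, grid)
        coupled = d.ftir(
            exciton.solve(model, np.array([[0.0, 8.3], [8.3, 0.0]])),
            lines, grid)
        a0 = np.trapezoid(uncoupled.intensity, grid)
        a1 = np.trapezoid(coupled.intensity, grid)
        assert a1 == pytest.approx(a0, rel=1e-6)

    def test_sticks_outside_grid_dropped_with_warning(self, caplog):
        model, couplings = single_site(1650.0)
        sys_ = exciton.solve(model, couplings)
        import logging
        with caplog.at_level(logging.WARNING, logger="dihedralir.spectra"):
            spec = d.ftir(sys_, grid=default_grid(1700.0, 1750.0, 0.5))
        assert "dropped" in caplog.text
        assert np.all(spec.intensity == 0.0)


class TestAbsorptive2D:
    def test_single_site_positive_and_negative_peaks(self):
        model, couplings = single_site(1650.0)
        sys_ = exciton.solve(model, couplings, exciton.ExcitonParams(16.0))
        spec = d.absorptive_2d(sys_, LineshapeParams(profile="gaussian",
                                                     fwhm=8.0))
        i, j = np.unravel_index(np.argmax(spec.z), spec.z.shape)
        assert (spec.pump[i], spec.probe[j]) == (1650.0, 1650.0)
        i, j = np.unravel_index(np.argmin(spec.z), spec.z.shape)
        assert (spec.pump[i], spec.probe[j]) == (1650.0, 1634.0)

    def test_parallel_dimer_dominant_peak_weight(self):
        model, couplings = parallel_dimer(1595.0, 8.3)
        sys_ = exciton.solve(model, couplings)
        # bright state |mu|^2 = 2 -> positive diagonal stick weight
        # (2 mu^2)^2 = 4 per pathway
        assert sys_.mu01_sq().max() == pytest.approx(2.0)
        w4 = sys_.mu01_sq() ** 2
        assert w4.max() == pytest.approx(4.0)
        spec = d.absorptive_2d(sys_, LineshapeParams(profile="gaussian",
                                                     fwhm=6.0))
        i, j = np.unravel_index(np.argmax(spec.z), spec.z.shape)
        assert spec.pump[i] == pytest.approx(1603.5, abs=0.5)

    def test_positive_diagonal_integral_matches_stick_sum(self):
        model, couplings = parallel_dimer(1600.0, 5.0)
        sys_ = exciton.solve(model, couplings)
        lines = LineshapeParams(profile="gaussian", fwhm=6.0)
        grid = default_grid(1500.0, 1700.0, 0.25)
        spec = d.absorptive_2d(sys_, lines, grid, grid)
        # suppress the negative manifold by summing the positive sticks only
        expected = 2.0 * (sys_.mu01_sq() ** 2).sum()
        # reconstruct positive part on the grid and integrate
        pos = np.zeros_like(spec.z)
        from dihedralir.spectra import _profile
        for k, wk in enumerate(sys_.e1):
            pos += 2.0 * sys_.mu01_sq()[k] ** 2 * np.outer(
                _profile(grid, wk, lines), _profile(grid, wk, lines))
        integral = np.trapezoid(np.trapezoid(pos, grid, axis=1), grid)
        assert integral == pytest.approx(expected, rel=1e-3)

    def test_power_law_scaling_under_dipole_rescaling(self):
        lines = LineshapeParams(profile="gaussian", fwhm=8.0)
        grid = default_grid(1500.0, 1700.0, 0.5)
        specs, ftirs = [], []
        for scale in (1.0, 1.7):
            model, couplings = parallel_dimer(1600.0, 6.0)
            for dip in model.dipoles:
                dip.magnitude = scale
            sys_ = exciton.solve(model, couplings)
            specs.append(d.absorptive_2d(sys_, lines, grid, grid))
            ftirs.append(d.ftir(sys_, lines, grid))
        r2 = np.trapezoid(ftirs[1].intensity, grid) / \
            np.trapezoid(ftirs[0].intensity, grid)
        assert r2 == pytest.approx(1.7 ** 2, rel=1e-6)
        rpos = specs[1].z.max() / specs[0].z.max()
        assert rpos == pytest.approx(1.7 ** 4, rel=1e-3)


class TestDiagonalSlice:
    def test_sequence_band_minimum_at_site_frequency(self):
        model, couplings = single_site(1650.0)
        sys_ = exciton.solve(model, couplings)
        spec = d.absorptive_2d(sys_, LineshapeParams(profile="gaussian",
                                                     fwhm=8.0))
        sl = d.diagonal_slice(spec, "sequence", 16.0)
        assert sl.grid[np.argmin(sl.intensity)] == pytest.approx(1650.0)
        # non-positive up to the far tail of the fundamental band, which the
        # track crosses 16 cm-1 above the site frequency
        assert np.all(sl.intensity <= 1e-2 * np.abs(sl.intensity).max())

    def test_fundamental_slice_nonnegative_for_lone_site(self):
        model, couplings = single_site(1650.0)
        sys_ = exciton.solve(model, couplings, exciton.ExcitonParams(16.0))
        spec = d.absorptive_2d(sys_, LineshapeParams(profile="gaussian",
                                                     fwhm=8.0))
        sl = d.diagonal_slice(spec, "fundamental")
        assert np.all(sl.intensity >= -1e-2 * np.abs(sl.intensity).max())

    def test_sequence_mirror_of_fundamental_for_lone_site(self):
        model, couplings = single_site(1650.0)
        sys_ = exciton.solve(model, couplings, exciton.ExcitonParams(30.0))
        spec = d.absorptive_2d(sys_, LineshapeParams(profile="gaussian",
                                                     fwhm=6.0),
                               default_grid(1500, 1750, 0.5),
                               default_grid(1500, 1750, 0.5))
        fund = d.diagonal_slice(spec, "fundamental")
        seq = d.diagonal_slice(spec, "sequence", 30.0)
        assert seq.intensity.min() == pytest.approx(-fund.intensity.max(),
                                                    rel=5e-3)

    def test_track_outside_probe_grid_errors(self):
        model, couplings = single_site(1650.0)
        sys_ = exciton.solve(model, couplings)
        spec = d.absorptive_2d(sys_, pump_grid=default_grid(1600, 1700, 1.0),
                               probe_grid=default_grid(1600, 1700, 1.0))
        with pytest.raises(ValueError, match="outside"):
            d.diagonal_slice(spec, "sequence", 200.0)

    def test_slice_save_load_round_trip_bit_identical(self, tmp_path):
        model, couplings = single_site(1650.0)
        sys_ = exciton.solve(model, couplings)
        spec = d.absorptive_2d(sys_)
        sl = d.diagonal_slice(spec, "sequence")
        p1, p2 = tmp_path / "s1.tsv", tmp_path / "s2.tsv"
        sl.save(p1)
        back = spectra.DiagonalSlice.load(p1)
        assert back.band == "sequence"
        back.save(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_spectrum2d_save_load_round_trip(self, tmp_path):
        model, couplings = single_site(1650.0)
        sys_ = exciton.solve(model, couplings)
        spec = d.absorptive_2d(sys_, pump_grid=default_grid(1600, 1700, 2.0),
                               probe_grid=default_grid(1600, 1700, 2.0))
        path = tmp_path / "2d.tsv"
        spec.save(path)
        back = spectra.Spectrum2D.load(path)
        np.testing.assert_array_equal(back.pump, spec.pump)
        np.testing.assert_allclose(back.z, spec.z, rtol=1e-7)


class TestDisorderAverage:
    def pipeline(self, lines):
        def run(model):
            beta = coupling.coupling_matrix(model)
            return d.absorptive_2d(exciton.solve(model, beta),
                                   LineshapeParams(profile=lines.profile,
                                                   fwhm=lines.fwhm))
        return run

    def test_zero_sigma_identical_to_single_shot(self):
        model = d.build_model([d.ALPHA_HELIX] * 2, site_frequency=1595.0)
        lines = LineshapeParams(fwhm=10.0, disorder_sigma=0.0,
                                n_realizations=3, seed=4)
        avg = d.disorder_average(model, lines, self.pipeline(lines))
        single = self.pipeline(lines)(model)
        np.testing.assert_allclose(avg.z, single.z, atol=1e-14)

    def test_same_seed_bit_identical(self):
        model = d.build_model([d.ALPHA_HELIX] * 2, site_frequency=1595.0)
        lines = LineshapeParams(fwhm=10.0, disorder_sigma=8.0,
                                n_realizations=5, seed=42)
        a = d.disorder_average(model, lines, self.pipeline(lines))
        b = d.disorder_average(model, lines, self.pipeline(lines))
        np.testing.assert_array_equal(a.z, b.z)

    def test_large_disorder_broadens_and_washes_out_splitting(self):
        model = d.build_model([d.ALPHA_HELIX] * 2, site_frequency=1595.0)
        lines0 = LineshapeParams(fwhm=10.0, disorder_sigma=0.0, seed=0)
        clean = d.disorder_average(model, lines0, self.pipeline(lines0))
        lines1 = LineshapeParams(fwhm=10.0, disorder_sigma=25.0,
                                 n_realizations=64, seed=0)
        noisy = d.disorder_average(model, lines1, self.pipeline(lines1))

        def diag_fwhm(spec):
            sl = d.diagonal_slice(spec, "fundamental")
            y = sl.intensity
            half = y.max() / 2
            above = sl.grid[y >= half]
            return above[-1] - above[0]

        assert diag_fwhm(noisy) > diag_fwhm(clean)
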