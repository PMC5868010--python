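"""Peak statistics and the dihedral-indexing decision rule."""

import numpy as np
import pytest

import dihedralir as d
from dihedralir.indexing import IndexThresholds, peak_stats
from dihedralir.spectra import DiagonalSlice


def lorentzian_slice(center=1595.0, fwhm=12.0, area=1.0, grid=None,
                     band="fundamental", sign=1.0):
    if grid is None:
        grid = np.arange(1500.0, 1700.0, 0.5)
    g = fwhm / 2
    y = area * (g / np.pi) / ((grid - center) ** 2 + g ** 2)
    return DiagonalSlice(grid=grid, intensity=sign * y, band=band)


class TestPeakStats:
    @staticmethod
    def truncated_lorentzian_area(center, fwhm, area, lo, hi):
        g = fwhm / 2
        return area * (np.arctan((hi - center) / g)
                       - np.arctan((lo - center) / g)) / np.pi

    def test_single_lorentzian_closed_form(self):
        s = lorentzian_slice(1595.0, 12.0, 1.0)
        ps = peak_stats(s, (1520.0, 1670.0))
        assert ps.position == pytest.approx(1595.0, abs=0.25)
        expected = self.truncated_lorentzian_area(1595.0, 12.0, 1.0,
                                                  1520.0, 1670.0)
        assert ps.area == pytest.approx(expected, rel=1e-3)
        assert ps.area == pytest.approx(1.0, rel=0.06)  # heavy tails
        assert ps.fwhm == pytest.approx(12.0, abs=1.0)
        assert not ps.at_edge

    def test_sequence_band_analyzed_on_negated_values(self):
        s = lorentzian_slice(1600.0, 10.0, 2.0, band="sequence", sign=-1.0)
        ps = peak_stats(s, (1550.0, 1650.0))
        assert ps.position == pytest.approx(1600.0, abs=0.25)
        expected = self.truncated_lorentzian_area(1600.0, 10.0, 2.0,
                                                  1550.0, 1650.0)
        assert ps.area == pytest.approx(expected, rel=1e-3)

    def test_two_overlapping_lorentzians_match_dense_grid_oracle(self):
        coarse = np.arange(1550.0, 1650.0, 0.5)
        fine = np.arange(1550.0, 1650.0, 0.001)

        def two(grid):
            out = np.zeros_like(grid)
            for c, a, f in [(1592.0, 1.0, 12.0), (1603.0, 0.6, 10.0)]:
                g = f / 2
                out += a * (g / np.pi) / ((grid - c) ** 2 + g ** 2)
            return out

        ps = peak_stats(DiagonalSlice(grid=coarse, intensity=two(coarse),
                                      band="fundamental"), (1560.0, 1640.0))
        yf = two(fine)
        sel = (fine >= 1560.0) & (fine <= 1640.0)
        pos_ref = fine[sel][np.argmax(yf[sel])]
        area_ref = np.trapezoid(yf[sel], fine[sel])
        half = yf[sel].max() / 2
        above = fine[sel][yf[sel] >= half]
        assert ps.position == pytest.approx(pos_ref, abs=0.25)
        assert ps.area == pytest.approx(area_ref, rel=0.01)
        assert ps.fwhm == pytest.approx(above[-1] - above[0], abs=0.6)

    def test_window_excluding_peak_flags_edge(self):
        s = lorentzian_slice(1595.0)
        ps = peak_stats(s, (1610.0, 1660.0))
        assert ps.at_edge
        assert ps.position == pytest.approx(1610.0)

    def test_too_few_points_rejected(self):
        s = lorentzian_slice(1595.0)
        with pytest.raises(ValueError, match="fewer than 3"):
            peak_stats(s, (1595.0, 1595.4))

    def test_all_zero_window_rejected(self):
        grid = np.arange(1500.0, 1700.0, 0.5)
        s = DiagonalSlice(grid=grid, intensity=np.zeros_like(grid),
                          band="fundamental")
        with pytest.raises(ValueError, match="no signal"):
            peak_stats(s, (1550.0, 1650.0))


class TestDihedralIndex:
    WIN = (1540.0, 1660.0)

    def test_identity_slices_not_helix_not_sheet(self):
        s = lorentzian_slice(1595.0)
        res = d.dihedral_index(s, s, self.WIN, n_labels_double=1)
        assert res.shift == pytest.approx(0.0, abs=1e-9)
        assert res.enhancement == pytest.approx(1.0, rel=1e-9)
        assert res.call not in ("helix", "sheet")

    def test_upshifted_enhanced_pair_is_helix(self):
        dbl = lorentzian_slice(1603.0, 12.0, area=4.0)
        sng = lorentzian_slice(1595.0, 12.0, area=1.0)
        res = d.dihedral_index(dbl, sng, self.WIN)
        assert res.call == "helix"
        assert res.shift == pytest.approx(8.0, abs=0.5)
        assert res.enhancement == pytest.approx(2.0, rel=0.02)

    def test_mirrored_shift_gives_sheet(self):
        dbl = lorentzian_slice(1587.0, 12.0, area=4.0)
        sng = lorentzian_slice(1595.0, 12.0, area=1.0)
        res = d.dihedral_index(dbl, sng, self.WIN)
        assert res.call == "sheet"
        assert res.shift == pytest.approx(-8.0, abs=0.5)

    def test_broad_unshifted_pair_is_disordered(self):
        dbl = lorentzian_slice(1595.5, 20.0, area=1.8)
        sng = lorentzian_slice(1595.0, 12.0, area=1.0)
        res = d.dihedral_index(dbl, sng, self.WIN)
        assert res.call == "disordered"

    def test_enhancement_invariant_to_global_rescaling(self):
        dbl = lorentzian_slice(1603.0, 12.0, area=4.0)
        sng = lorentzian_slice(1595.0, 12.0, area=1.0)
        r1 = d.dihedral_index(dbl, sng, self.WIN)
        dbl2 = DiagonalSlice(grid=dbl.grid, intensity=7.3 * dbl.intensity,
                             band=dbl.band)
        sng2 = DiagonalSlice(grid=sng.grid, intensity=7.3 * sng.intensity,
                             band=sng.band)
        r2 = d.dihedral_index(dbl2, sng2, self.WIN)
        assert r2.enhancement == pytest.approx(r1.enhancement, rel=1e-9)
        assert r2.call == r1.call

    def test_band_mismatch_rejected(self):
        dbl = lorentzian_slice(1603.0, band="fundamental")
        sng = lorentzian_slice(1595.0, band="sequence", sign=-1.0)
        with pytest.raises(ValueError, match="band"):
            d.dihedral_index(dbl, sng, self.WIN)

    def test_thresholds_recorded_in_record(self):
        dbl = lorentzian_slice(1603.0, 12.0, area=4.0)
        sng = lorentzian_slice(1595.0, 12.0, area=1.0)
        res = d.dihedral_index(dbl, sng, self.WIN,
                               thresholds=IndexThresholds(shift=2.0))
        rec = res.to_record()
        assert "helix" in rec and "2.0000" in rec


class TestHelixPopulation:
    WIN = (1560.0, 1640.0)

    def test_identity_contains_one(self, helix_pair):
        ref, single = helix_pair
        ps = peak_stats(single, self.WIN)
        lo, hi = d.helix_population(ref, ref, self.WIN,
                                    split_frequency=ps.position)
        assert lo <= 1.0 <= hi + 1e-9
        assert hi == pytest.approx(1.0, abs=1e-6)

    def test_zero_coupled_band_gives_zero_interval(self, helix_pair):
        ref, single = helix_pair
        ps = peak_stats(single, self.WIN)
        # all intensity strictly below the split: no coupled-band content
        below = np.where(single.grid < ps.position - 2.0,
                         single.intensity, 0.0)
        sub = DiagonalSlice(grid=single.grid, intensity=below,
                            band=single.band)
        lo, hi = d.helix_population(sub, ref, self.WIN,
                                    split_frequency=ps.position)
        assert (lo, hi) == (0.0, 0.0)

    @pytest.mark.parametrize("pstar", [0.25, 0.5, 0.75])
    def test_planted_mixture_bracketed(self, helix_pair, pstar):
        ref, single = helix_pair
        ps = peak_stats(single, self.WIN)
        uncoupled = 2.0 * single.intensity  # two uncoupled labels
        mix = DiagonalSlice(
            grid=ref.grid,
            intensity=pstar * ref.intensity + (1 - pstar) * uncoupled,
            band=ref.band)
        lo, hi = d.helix_population(mix, ref, self.WIN,
                                    split_frequency=ps.position)
        assert lo - 0.02 <= pstar <= hi + 0.02

    def test_monotone_in_coupled_band_content(self, helix_pair):
        ref, single = helix_pair
        ps = peak_stats(single, self.WIN)
        uncoupled = 2.0 * single.intensity
        values = []
        for pstar in (0.2, 0.4, 0.6, 0.8):
            mix = DiagonalSlice(
                grid=ref.grid,
                intensity=pstar * ref.intensity + (1 - pstar) * uncoupled,
                band=ref.band)
            values.append(d.helix_population(mix, ref, self.WIN,
                                             split_frequency=ps.position))
        los, his = zip(*values)
        assert list(los) == sorted(los)
        assert list(his) == sorted(his)

    def test_reference_without_coupled_band_rejected(self, helix_pair):
        ref, single = helix_pair
        ps = peak_stats(single, self.WIN)
        below = DiagonalSlice(
            grid=single.grid,
            intensity=np.where(single.grid < ps.position - 2.0,
                               single.intensity, 0.0),
            band=single.band)
        with pytest.raises(ValueError, match="reference"):
            d.helix_population(single, below, self.WIN,
                               split_frequency=ps.position)
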