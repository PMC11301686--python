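"""Three-evidence quantification: integration, splits, composition."""

import numpy as np
import pytest

from venompep.quant import (BandAssignment, Chromatogram, DegenerateBandError,
                            GelBand, PeakFraction, VenomComposition,
                            band_split, compose, integrate_fractions,
                            suggest_boundaries, top3_split)
from venompep.synth import GaussianPeak, SynthSpec, gen_chromatogram


def gaussians(peaks, seed=0, noise=0.0):
    c, areas = gen_chromatogram(SynthSpec(seed=seed, peaks=peaks, noise_sd=noise))
    return c, areas


class TestIntegrate:
    def test_two_identical_peaks_split_evenly(self):
        c, _ = gaussians([GaussianPeak(15, 0.5, 50), GaussianPeak(40, 0.5, 50)])
        fr = integrate_fractions(c, [(11, 19), (36, 44)], baseline="none")
        assert [f.area_fraction for f in fr] == pytest.approx([0.5, 0.5], abs=1e-6)

    def test_sixty_forty(self):
        c, _ = gaussians([GaussianPeak(15, 0.5, 60), GaussianPeak(40, 0.5, 40)])
        fr = integrate_fractions(c, [(11, 19), (36, 44)], baseline="none")
        assert [f.area_fraction for f in fr] == pytest.approx([0.6, 0.4], abs=1e-4)

    def test_single_fraction_normalizes_to_one(self):
        c, _ = gaussians([GaussianPeak(30, 1.0, 20)])
        fr = integrate_fractions(c, [(0, 70)], baseline="none")
        assert fr[0].area_fraction == pytest.approx(1.0, abs=1e-12)

    def test_overlapping_windows_rejected(self):
        c, _ = gaussians([GaussianPeak(30, 1.0, 20)])
        with pytest.raises(ValueError, match="overlap"):
            integrate_fractions(c, [(10, 35), (30, 50)])

    def test_out_of_range_rejected(self):
        c, _ = gaussians([GaussianPeak(30, 1.0, 20)])
        with pytest.raises(ValueError, match="outside"):
            integrate_fractions(c, [(-5, 10)])

    def test_linear_baseline_removes_drift(self):
        c, areas = gaussians([GaussianPeak(30, 0.8, 50)])
        drifted = Chromatogram(c.time, c.absorbance + 5.0 + 0.1 * c.time)
        fr = integrate_fractions(drifted, [(26, 34)], baseline="linear")
        assert fr[0].integral == pytest.approx(areas[0], rel=5e-3)

    def test_chromatogram_validation(self):
        with pytest.raises(ValueError):
            Chromatogram(np.array([0.0, 0.0, 1.0]), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            Chromatogram(np.array([0.0, 1.0]), np.array([1.0, 2.0, 3.0]))

    def test_suggest_boundaries_finds_valley(self):
        c, _ = gaussians([GaussianPeak(15, 0.5, 50), GaussianPeak(25, 0.5, 50)])
        cuts = suggest_boundaries(c, height_frac=0.05)
        assert any(18 < t < 22 for t in cuts)


class TestSplits:
    def test_band_split_products(self):
        f = PeakFraction("F1", 0, 1, 1.0, 0.5)
        out = band_split(f, [GelBand("F1", "a", 0.7), GelBand("F1", "b", 0.2),
                             GelBand("F1", "c", 0.1)])
        assert out == pytest.approx({"a": 0.35, "b": 0.10, "c": 0.05})

    def test_band_shares_must_sum_to_one(self):
        f = PeakFraction("F1", 0, 1, 1.0, 0.4)
        with pytest.raises(ValueError, match="sum"):
            band_split(f, [GelBand("F1", "a", 0.5), GelBand("F1", "b", 0.4)])

    def test_foreign_band_rejected(self):
        f = PeakFraction("F1", 0, 1, 1.0, 0.4)
        with pytest.raises(ValueError, match="belongs"):
            band_split(f, [GelBand("F2", "a", 1.0)])

    def test_top3_ratio(self):
        out = top3_split(0.30, BandAssignment("b", [("svSP", 2e9), ("PLA2", 1e9)]))
        assert out == pytest.approx({"svSP": 0.20, "PLA2": 0.10})

    def test_top3_single_family_passthrough(self):
        assert top3_split(0.15, BandAssignment("b", [("CTL", 3.3e8)])) == \
            pytest.approx({"CTL": 0.15})

    def test_top3_degenerate_band(self):
        with pytest.raises(DegenerateBandError):
            top3_split(0.1, BandAssignment("b", [("CTL", 0.0)]))


class TestCompose:
    def test_two_fraction_peptide_split(self):
        fr = [PeakFraction("F1", 0, 1, 0.6, 0.6), PeakFraction("F2", 1, 2, 0.4, 0.4)]
        vc = compose(fr, [GelBand("F1", "B1", 1.0)],
                     [BandAssignment("B1", [("svMP_PIII", 1.0)])],
                     peptide_fraction_ids=["F2"])
        assert vc.percent == pytest.approx({"svMP_PIII": 60.0, "peptides": 40.0})

    def test_worked_micro_example(self):
        # 0.6 all-CTL fraction; 0.4 fraction with bands 0.5/0.5, second band
        # split 2:1 svSP:PLA2 -> 60 / 20 / 13.33 / 6.67
        fr = [PeakFraction("F1", 0, 1, 0.6, 0.6), PeakFraction("F2", 1, 2, 0.4, 0.4)]
        bands = [GelBand("F1", "B1", 1.0), GelBand("F2", "B2a", 0.5),
                 GelBand("F2", "B2b", 0.5)]
        assigns = [BandAssignment("B1", [("svMP_PIII", 1.0)]),
                   BandAssignment("B2a", [("CTL", 5.0)]),
                   BandAssignment("B2b", [("svSP", 2e9), ("PLA2", 1e9)])]
        vc = compose(fr, bands, assigns)
        assert vc.rounded(2) == {"svMP_PIII": 60.0, "CTL": 20.0,
                                 "svSP": 13.33, "PLA2": 6.67}

    def test_unassigned_goes_unknown(self):
        vc = compose([PeakFraction("F1", 0, 1, 1.0, 1.0)], [], [])
        assert vc.percent == {"unknown": 100.0}

    def test_double_assignment_rejected(self):
        fr = [PeakFraction("F1", 0, 1, 1.0, 1.0)]
        with pytest.raises(ValueError, match="flagged peptide"):
            compose(fr, [GelBand("F1", "B1", 1.0)],
                    [BandAssignment("B1", [("CTL", 1.0)])],
                    peptide_fraction_ids=["F1"])

    def test_degenerate_band_routed_to_unknown(self):
        fr = [PeakFraction("F1", 0, 1, 1.0, 1.0)]
        vc = compose(fr, [GelBand("F1", "B1", 1.0)],
                     [BandAssignment("B1", [("CTL", 0.0)])])
        assert vc.percent == {"unknown": 100.0}

    def test_composition_validation(self):
        with pytest.raises(ValueError):
            VenomComposition({"CTL": 50.0})
        with pytest.raises(ValueError):
            VenomComposition({"martian": 100.0})

    def test_svmp_umbrella(self):
        vc = VenomComposition({"svMP_PI": 2.0, "svMP_PIII": 12.0, "DC": 8.0,
                               "unknown": 78.0})
        assert vc.svmp_total() == pytest.approx(22.0)


class TestInvariances:
    def _pipeline(self, c, bounds, bands, assigns, pep):
        fr = integrate_fractions(c, bounds, baseline="none")
        return compose(fr, bands, assigns, pep)

    def test_absorbance_scaling_invariance(self):
        c, _ = gaussians([GaussianPeak(15, 0.5, 60), GaussianPeak(40, 0.5, 40)])
        bounds = [(11, 19), (36, 44)]
        bands = [GelBand("F1", "B1", 1.0)]
        assigns = [BandAssignment("B1", [("svSP", 1.0)])]
        a = self._pipeline(c, bounds, bands, assigns, ["F2"])
        scaled = Chromatogram(c.time, 7.3 * c.absorbance)
        b = self._pipeline(scaled, bounds, bands, assigns, ["F2"])
        assert a.percent == pytest.approx(b.percent)

    def test_fraction_order_invariance(self):
        c, _ = gaussians([GaussianPeak(15, 0.5, 60), GaussianPeak(40, 0.5, 40)])
        bands = [GelBand("F1", "B1", 1.0)]
        assigns = [BandAssignment("B1", [("svSP", 1.0)])]
        a = self._pipeline(c, [(11, 19), (36, 44)], bands, assigns, ["F2"])
        # reversed boundary order: ids follow the sorted windows either way
        b = self._pipeline(c, [(36, 44), (11, 19)], bands, assigns, ["F2"])
        assert a.percent == pytest.approx(b.percent)

    def test_mass_conserved_at_every_stage(self):
        c, _ = gaussians([GaussianPeak(15, 0.5, 60), GaussianPeak(40, 0.5, 40)])
        fr = integrate_fractions(c, [(11, 19), (36, 44)], baseline="none")
        assert sum(f.area_fraction for f in fr) == pytest.approx(1.0, abs=1e-9)
        bands = [GelBand("F1", "a", 0.3), GelBand("F1", "b", 0.7)]
        split = band_split(fr[0], bands)
        assert sum(split.values()) == pytest.approx(fr[0].area_fraction, abs=1e-12)
        fam = top3_split(split["a"], BandAssignment("a", [("DI", 2.0), ("CTL", 3.0)]))
        assert sum(fam.values()) == pytest.approx(split["a"], abs=1e-12)
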