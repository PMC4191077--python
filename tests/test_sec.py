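import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemopk import (
    Chromatogram,
    PeakAreas,
    generate_chromatogram,
    integrate_peaks,
    percent_free,
    speciate_concentration,
)
from hemopk.sec import RETENTION_MIN, default_windows

PHENOTYPES = ("dog", "human_dimeric", "human_multimeric")


class TestIntegratePeaks:
    def test_triangular_peak_area(self):
        t = np.array([0.0, 19.0, 19.7, 20.7, 21.7, 22.0, 30.0])
        y = np.array([0.0, 0.0, 0.0, 2.0, 0.0, 0.0, 0.0])
        chrom = Chromatogram(t, y, {"free_hb": (19.7, 21.7),
                                    "bound_hb": (16.0, 18.0)})
        areas = integrate_peaks(chrom)
        assert areas.area_free == pytest.approx(2.0, rel=1e-12)
        assert areas.area_bound == 0.0

    def test_flat_signal_on_baseline_gives_zero(self):
        t = np.linspace(0.0, 30.0, 301)
        chrom = Chromatogram(t, np.full_like(t, 0.7), default_windows("dog"))
        areas = integrate_peaks(chrom)
        assert areas.area_free == 0.0 and areas.area_bound == 0.0

    def test_gaussian_peak_matches_analytic_area(self):
        t = np.arange(0.0, 30.0, 0.01)
        amp, mu, sigma = 1.0, 20.7, 0.2
        y = amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
        chrom = Chromatogram(t, y, default_windows("dog"))
        analytic = amp * sigma * np.sqrt(2 * np.pi)
        assert integrate_peaks(chrom).area_free == pytest.approx(
            analytic, rel=0.005)

    def test_missing_window_rejected(self):
        t = np.linspace(0.0, 30.0, 301)
        chrom = Chromatogram(t, np.zeros_like(t))
        with pytest.raises(ValueError):
            integrate_peaks(chrom)


class TestPercentFree:
    @pytest.mark.parametrize("free,bound,expected", [
        (25.0, 75.0, 25.0), (1.0, 0.0, 100.0), (1.0, 1.0, 50.0),
    ])
    def test_printed_formula(self, free, bound, expected):
        assert percent_free(PeakAreas(free, bound)) == pytest.approx(expected)

    def test_both_zero_is_missing(self):
        assert np.isnan(percent_free(PeakAreas(0.0, 0.0)))


class TestSpeciateConcentration:
    def test_partition_arithmetic(self):
        s = speciate_concentration(400.0, 25.0)
        assert (s.free_uM, s.bound_uM) == (100.0, 300.0)
        assert s.pct_free + s.pct_bound == 100.0

    @pytest.mark.parametrize("total,pct", [(0.0, 40.0), (260.0, 0.0),
                                           (260.0, 100.0)])
    def test_boundaries(self, total, pct):
        s = speciate_concentration(total, pct)
        assert s.free_uM + s.bound_uM == total
        assert s.free_uM == total * pct / 100.0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(min_value=0.0, max_value=1000.0),
           st.floats(min_value=0.0, max_value=100.0))
    def test_conservation_to_machine_precision(self, total, pct):
        # bound is stored as total - free, so the sum re-rounds at most once
        s = speciate_concentration(total, pct)
        assert s.free_uM + s.bound_uM == pytest.approx(total, rel=4e-16)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            speciate_concentration(100.0, 101.0)
        with pytest.raises(ValueError):
            speciate_concentration(-1.0, 50.0)


class TestGenerateChromatogram:
    def test_zero_concentrations_give_flat_noise_trace(self):
        chrom = generate_chromatogram(0.0, 0.0, "dog", noise_sd=0.001, seed=0)
        assert np.abs(chrom.a405_AU).max() < 0.01

    @pytest.mark.parametrize("phenotype", PHENOTYPES)
    def test_round_trip_recovers_percent_free(self, phenotype):
        chrom = generate_chromatogram(100.0, 300.0, phenotype)
        pct = percent_free(integrate_peaks(chrom))
        assert pct == pytest.approx(25.0, abs=0.5)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.floats(min_value=1.0, max_value=500.0),
           st.floats(min_value=1.0, max_value=500.0),
           st.sampled_from(PHENOTYPES))
    def test_round_trip_property(self, free, bound, phenotype):
        """Noiseless forward/inverse consistency within 0.5% absolute for
        any positive pair, all phenotypes."""
        chrom = generate_chromatogram(free, bound, phenotype)
        pct = percent_free(integrate_peaks(chrom))
        assert pct == pytest.approx(100.0 * free / (free + bound), abs=0.5)

    def test_dimeric_complex_elutes_half_minute_before_dog(self):
        dog = generate_chromatogram(0.0, 300.0, "dog")
        dim = generate_chromatogram(0.0, 300.0, "human_dimeric")
        apex_dog = dog.elution_min[np.argmax(dog.a405_AU)]
        apex_dim = dim.elution_min[np.argmax(dim.a405_AU)]
        assert apex_dog - apex_dim == pytest.approx(0.5, abs=0.02)
        assert apex_dog == pytest.approx(17.7, abs=0.02)

    def test_free_hb_elutes_at_20_7_min(self):
        chrom = generate_chromatogram(200.0, 0.0, "dog")
        assert chrom.elution_min[np.argmax(chrom.a405_AU)] == pytest.approx(
            20.7, abs=0.02)

    def test_multimeric_profile_is_broad_between_12_and_16(self):
        """The multimeric complex is a broad band between 12 and 16 min
        built from overlapping 14.7/15.1 min components."""
        chrom = generate_chromatogram(0.0, 300.0, "human_multimeric")
        inside = (chrom.elution_min > 12.0) & (chrom.elution_min < 16.0)
        inside_mass = np.trapezoid(chrom.a405_AU[inside],
                                   chrom.elution_min[inside])
        total_mass = np.trapezoid(chrom.a405_AU, chrom.elution_min)
        assert inside_mass / total_mass > 0.9
        apex = chrom.elution_min[np.argmax(chrom.a405_AU)]
        assert 14.6 <= apex <= 15.2
        # broader than a dimeric complex peak of the same load
        dim = generate_chromatogram(0.0, 300.0, "human_dimeric")
        assert chrom.a405_AU.max() < 0.5 * dim.a405_AU.max()

    def test_monotonicity_more_bound_lowers_percent_free(self):
        pcts = []
        for bound in (100.0, 200.0, 400.0):
            chrom = generate_chromatogram(100.0, bound, "dog")
            pcts.append(percent_free(integrate_peaks(chrom)))
        assert pcts[0] > pcts[1] > pcts[2]

    def test_unknown_phenotype_rejected(self):
        with pytest.raises(ValueError):
            generate_chromatogram(1.0, 1.0, "mouse")


class TestChromatogramValidation:
    def test_overlapping_windows_rejected(self):
        t = np.linspace(0.0, 30.0, 31)
        with pytest.raises(ValueError, match="overlap"):
            Chromatogram(t, np.zeros_like(t),
                         {"free_hb": (10.0, 20.0), "bound_hb": (15.0, 25.0)})

    def test_window_outside_range_rejected(self):
        t = np.linspace(0.0, 18.0, 19)
        with pytest.raises(ValueError, match="outside"):
            Chromatogram(t, np.zeros_like(t), {"free_hb": (19.7, 21.7)})

    def test_csv_round_trip(self, tmp_path):
        chrom = generate_chromatogram(50.0, 150.0, "dog")
        p = tmp_path / "c.csv"
        chrom.to_csv(p)
        back = Chromatogram.from_csv(p, windows=default_windows("dog"))
        np.testing.assert_allclose(back.a405_AU, chrom.a405_AU, rtol=1e-12)
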