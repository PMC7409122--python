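"""Mobilogram extraction, MassI, peak integration and the 2D m/z-DT map."""

import numpy as np
import pytest
from scipy.signal import find_peaks

from mobiquant.design import SampleRecord, SampleRole
from mobiquant.mobilogram import (
    ANALYTE_WINDOW,
    IS_WINDOW,
    ExtractionWindow,
    Mobilogram,
    combine_spectrum,
    detect_mobility_peak,
    dt_mz_map,
    extract_mobilogram,
    massi,
    moba,
)
from mobiquant.simulate import InstrumentModel, simulate_spot

from conftest import make_acquisition


def _spot(conc, instrument, signal, seed=0, interferent=True):
    rec = SampleRecord(sample_id="s", role=SampleRole.CAL, level=f"CAL{conc:g}",
                       nominal_conc=conc)
    return simulate_spot(rec, instrument, signal, seed=seed, include_interferent=interferent)


class TestExtractMobilogram:
    def test_single_centroid_lands_in_its_bin(self):
        acq = make_acquisition([(40, 185.10, 500.0)])
        mob = extract_mobilogram(acq, ANALYTE_WINDOW)
        assert mob.intensity[40] == 500.0
        assert mob.total == 500.0

    def test_disjoint_window_gives_all_zero(self):
        acq = make_acquisition([(40, 185.10, 500.0)])
        mob = extract_mobilogram(acq, IS_WINDOW)
        assert mob.total == 0.0

    def test_empty_acquisition_gives_all_zero_mobilogram(self):
        acq = make_acquisition(np.empty((0, 3)))
        mob = extract_mobilogram(acq, ANALYTE_WINDOW)
        assert len(mob.intensity) == 200 and mob.total == 0.0

    def test_matches_brute_force_sum_on_synthetic_spot(self, instrument_w, default_config):
        acq = _spot(100.0, instrument_w, default_config.signal, seed=4)
        mob = extract_mobilogram(acq, ANALYTE_WINDOW)
        # independent brute force over raw centroids
        expected = np.zeros(len(acq.dt_centers))
        for b, m, i in zip(acq.drift_bins, acq.mz, acq.intensity):
            if ANALYTE_WINDOW.mz_low <= m <= ANALYTE_WINDOW.mz_high:
                expected[b] += i
        np.testing.assert_allclose(mob.intensity, expected, rtol=1e-12)


class TestCombineSpectrumAndMassI:
    def test_single_centroid_profile(self):
        acq = make_acquisition([(3, 185.1025, 42.0)])
        centers, profile = combine_spectrum(acq)
        assert profile.sum() == 42.0
        assert massi(acq, ANALYTE_WINDOW) == 42.0

    def test_additivity_of_identical_centroids_across_scans(self):
        acq = make_acquisition([(3, 185.1025, 42.0), (90, 185.1025, 8.0)])
        _, profile = combine_spectrum(acq)
        assert profile.max() == 50.0

    def test_total_intensity_conserved(self, instrument_w, default_config):
        acq = _spot(50.0, instrument_w, default_config.signal, seed=2)
        _, profile = combine_spectrum(acq)
        assert profile.sum() == pytest.approx(acq.total_intensity, rel=1e-12)

    def test_blank_massi_is_zero(self):
        acq = make_acquisition(np.empty((0, 3)))
        assert massi(acq, ANALYTE_WINDOW) == 0.0


class TestDetectMobilityPeak:
    def test_triangular_peak_area_closed_form(self):
        # Height-100 triangle spanning 0.5 ms on a zero baseline: area = 25.
        dt = np.arange(200) * 0.02 + 0.01
        apex = 92  # dt ~1.85
        y = np.zeros(200)
        for k in range(-13, 14):  # half-base 0.25 ms, linear ramps reaching zero
            y[apex + k] = max(0.0, 100.0 * (1 - abs(k) * 0.02 / 0.25))
        mob = Mobilogram(dt_grid=dt, intensity=y)
        window = ExtractionWindow(mz_low=185.0, mz_high=185.2, expected_dt=dt[apex],
                                  dt_tolerance=0.2)
        peak = detect_mobility_peak(mob, window)
        assert peak.area == pytest.approx(0.5 * 0.5 * 100.0, rel=0.01)
        assert abs(peak.apex_dt - dt[apex]) <= 0.03

    def test_all_zero_mobilogram_returns_zero_area_at_expected_dt(self):
        mob = Mobilogram(dt_grid=np.arange(200) * 0.02 + 0.01, intensity=np.zeros(200))
        window = ExtractionWindow(mz_low=185.0, mz_high=185.2, expected_dt=1.85,
                                  dt_tolerance=0.2)
        peak = detect_mobility_peak(mob, window)
        assert peak.area == 0.0 and peak.apex_dt == 1.85

    def test_apex_assigned_to_expected_peak_not_larger_neighbor(self):
        """Two Gaussians 0.08 ms apart with a tight tolerance: the apex must be
        the one near the expected DT even when the neighbor is 5x larger."""
        dt = np.arange(200) * 0.02 + 0.01
        g = lambda c, s, a: a * np.exp(-0.5 * ((dt - c) / s) ** 2)
        y = g(1.85, 0.03, 100.0) + g(1.93, 0.03, 500.0)
        mob = Mobilogram(dt_grid=dt, intensity=y)
        window = ExtractionWindow(mz_low=185.0, mz_high=185.2, expected_dt=1.85,
                                  dt_tolerance=0.03)
        peak = detect_mobility_peak(mob, window)
        assert abs(peak.apex_dt - 1.85) <= 0.03

    def test_excessive_tolerance_rejected(self):
        mob = Mobilogram(dt_grid=np.arange(200) * 0.02 + 0.01, intensity=np.zeros(200))
        window = ExtractionWindow(mz_low=185.0, mz_high=185.2, expected_dt=1.85,
                                  dt_tolerance=10.0)
        with pytest.raises(ValueError, match="tolerance"):
            detect_mobility_peak(mob, window)


class TestMobA:
    def test_blank_is_zero(self, instrument_w, noiseless_signal):
        rec = SampleRecord(sample_id="bv", role=SampleRole.BV, level="BV")
        acq = simulate_spot(rec, instrument_w, noiseless_signal, seed=0,
                            include_interferent=False)
        assert moba(acq, ANALYTE_WINDOW) == 0.0

    def test_doubling_concentration_doubles_area(self, instrument_w, noiseless_signal):
        a1 = moba(_spot(100.0, instrument_w, noiseless_signal, interferent=False),
                  ANALYTE_WINDOW)
        a2 = moba(_spot(200.0, instrument_w, noiseless_signal, interferent=False),
                  ANALYTE_WINDOW)
        assert a2 / a1 == pytest.approx(2.0, rel=0.01)

    def test_area_equals_brute_force_trapezoid_over_bounds(self, instrument_w, default_config):
        acq = _spot(50.0, instrument_w, default_config.signal, seed=9)
        mob = extract_mobilogram(acq, ANALYTE_WINDOW)
        peak = detect_mobility_peak(mob, ANALYTE_WINDOW)
        sel = (mob.dt_grid >= peak.left_dt) & (mob.dt_grid <= peak.right_dt)
        dt, y = mob.dt_grid[sel], mob.intensity[sel]
        brute = sum(
            0.5 * (y[k] + y[k + 1]) * (dt[k + 1] - dt[k]) for k in range(len(dt) - 1)
        )
        assert peak.area == pytest.approx(brute, rel=1e-12)

    def test_monotone_in_concentration_noiseless(self, instrument_w, noiseless_signal):
        areas = [
            moba(_spot(c, instrument_w, noiseless_signal, interferent=False), ANALYTE_WINDOW)
            for c in (5.0, 20.0, 100.0, 1000.0)
        ]
        assert all(b > a for a, b in zip(areas, areas[1:]))


class TestDtMzMap:
    def test_single_centroid_single_cell(self):
        acq = make_acquisition([(40, 185.1025, 7.0)])
        m = dt_mz_map(acq, (185.0, 185.2), (0.5, 1.5))
        assert m.matrix.sum() == 7.0
        assert (m.matrix > 0).sum() == 1

    def test_marginals_match_spectrum_and_mobilogram(self, instrument_w, default_config):
        acq = _spot(200.0, instrument_w, default_config.signal, seed=5)
        mz_range, dt_range = (184.9, 185.9), (0.0, 4.0)
        m = dt_mz_map(acq, mz_range, dt_range)
        wide = ExtractionWindow(mz_low=mz_range[0], mz_high=mz_range[1], expected_dt=1.85)
        mob = extract_mobilogram(acq, wide)
        np.testing.assert_allclose(m.dt_marginal, mob.intensity, rtol=1e-9, atol=1e-9)
        assert m.matrix.sum() == pytest.approx(
            acq.intensity[(acq.mz >= mz_range[0]) & (acq.mz <= mz_range[1])].sum(), rel=1e-12
        )

    def test_w_mode_resolves_interferent_v_mode_merges(self, noiseless_signal):
        """The 2D map shows two m/z columns 0.03 apart in W mode and a single
        merged column in V mode (the mass-resolution argument)."""
        n_peaks = {}
        for mode in ("V", "W"):
            inst = InstrumentModel(resolution_mode=mode)
            acq = _spot(5.0, inst, noiseless_signal, interferent=True)
            centers, profile = combine_spectrum(acq, mz_range=(185.05, 185.2))
            peaks, _ = find_peaks(profile, prominence=0.05 * profile.max())
            n_peaks[mode] = len(peaks)
        assert n_peaks["W"] >= 2
        assert n_peaks["V"] == 1

    def test_inverted_ranges_rejected(self):
        acq = make_acquisition([(40, 185.1, 7.0)])
        with pytest.raises(ValueError, match="increasing"):
            dt_mz_map(acq, (185.2, 185.0), (0.5, 1.5))
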