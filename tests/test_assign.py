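"""Charge-series assignment: MacSED, peak picking, finder and prediction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nativems import (
    ChargeSeriesModel,
    Peak,
    SpeciesSpec,
    macsed_assign,
    mass_finder,
    mz_from_mass,
    pick_peaks,
    predict_adjacent,
    simulate_spectrum,
)
from nativems.assign import PROTON_MASS
from nativems.exceptions import AssignmentError, ParameterError, WindowError
from conftest import brute_force_base_charge, series_peaks


class TestMzFromMass:
    @pytest.mark.parametrize(
        "mass,z,expected",
        [(10000.0, 10, 1001.007276), (10000.0, 1, 10001.007276)],
    )
    def test_electrospray_relation(self, mass, z, expected):
        assert mz_from_mass(mass, z) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("mass,z", [(0, 1), (-5, 2), (100, 0), (100, -1)])
    def test_domain_errors(self, mass, z):
        with pytest.raises(ParameterError):
            mz_from_mass(mass, z)


class TestPickPeaks:
    def test_apex_inside_window(self, tenk_spectrum):
        s, _ = tenk_spectrum
        (peak,) = pick_peaks(s, [(990.0, 1010.0)])
        # apex should land on the grid point nearest the z=10 peak centre
        truth_mz = mz_from_mass(10000.0, 10)
        grid_step = s.mz[1] - s.mz[0]
        assert abs(peak.mz - truth_mz) <= grid_step / 2 + 1e-9

    def test_window_beyond_data_raises(self, tenk_spectrum):
        s, _ = tenk_spectrum
        with pytest.raises(WindowError):
            pick_peaks(s, [(2000.0, 2100.0)])

    def test_three_windows_hit_simulator_truth(self, tenk_spectrum):
        s, truth = tenk_spectrum
        rows = {z: mz for z, mz, _ in truth.peak_table["tenk"]}
        windows = [(rows[z] - 4.0, rows[z] + 4.0) for z in (9, 10, 11)]
        peaks = pick_peaks(s, windows)
        grid_step = s.mz[1] - s.mz[0]
        assert len(peaks) == 3
        for peak, z in zip(peaks, (9, 10, 11)):
            assert abs(peak.mz - rows[z]) <= grid_step / 2 + 1e-9

    def test_all_zero_window_excluded(self):
        from nativems import Spectrum

        s = Spectrum(np.array([1000.0, 1001.0, 1002.0, 1003.0]),
                     np.array([0.0, 0.0, 5.0, 1.0]))
        peaks = pick_peaks(s, [(1000.0, 1001.0), (1002.0, 1003.0)])
        assert len(peaks) == 1 and peaks[0].mz == 1002.0

    def test_tie_breaks_to_lowest_mz(self):
        from nativems import Spectrum

        s = Spectrum(np.array([1000.0, 1001.0, 1002.0]),
                     np.array([7.0, 7.0, 3.0]))
        (peak,) = pick_peaks(s, [(999.0, 1003.0)])
        assert peak.mz == 1000.0


class TestMacsed:
    def test_exact_inversion_zero_variance(self):
        peaks = [
            Peak(1112.118387, 10.0, (1110, 1114)),
            Peak(1001.007276, 10.0, (999, 1003)),
            Peak(910.098185, 10.0, (908, 912)),
        ]
        series = macsed_assign(peaks)
        assert series.charges == (9, 10, 11)
        assert series.mass == pytest.approx(10000.0, abs=1e-3)
        assert series.uncertainty < 1e-6

    def test_rounded_inputs_match_brute_force(self):
        mzs = [1112.12, 1001.01, 910.10]
        peaks = [Peak(m, 10.0, (m - 1, m + 1)) for m in mzs]
        series = macsed_assign(peaks)
        z0, masses = brute_force_base_charge(mzs)
        assert series.charges[0] == z0
        assert series.charges == (9, 10, 11)
        assert series.mass == pytest.approx(float(np.mean(masses)), abs=1e-9)
        assert series.uncertainty == pytest.approx(
            float(np.std(masses, ddof=1)), rel=1e-9)
        assert abs(series.mass - 10000.0) < 0.05
        assert series.uncertainty > 0

    def test_two_peaks_equal_exhaustive_argmin(self):
        mzs = [1001.007276, 910.098185]
        peaks = [Peak(m, 10.0, (m - 1, m + 1)) for m in mzs]
        series = macsed_assign(peaks)
        z0, _ = brute_force_base_charge(mzs)
        assert series.charges[0] == z0

    def test_oracle_equivalence_on_random_inputs(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            mass = rng.uniform(8e3, 9e5)
            z_lo = int(rng.integers(2, 60))
            k = int(rng.integers(2, 8))
            mzs = sorted(
                (mz_from_mass(mass, z) + rng.normal(0, 0.05)
                 for z in range(z_lo, z_lo + k)),
                reverse=True,
            )
            series = macsed_assign(
                [Peak(m, 1.0, (m - 1, m + 1)) for m in mzs])
            z0, _ = brute_force_base_charge(mzs)
            assert series.charges[0] == z0

    @given(
        mass=st.floats(5e3, 5e6),
        z_lo=st.integers(1, 460),
        k=st.integers(2, 40),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_roundtrip_recovers_exact_mass_and_charges(self, mass, z_lo, k):
        """Noiseless peaks on the electrospray relation invert exactly."""
        if z_lo + k - 1 > 500:
            k = 500 - z_lo + 1
            if k < 2:
                return
        charges = list(range(z_lo, z_lo + k))
        series = macsed_assign(series_peaks(mass, charges))
        assert series.charges == tuple(charges)
        assert abs(series.mass - mass) / mass < 1e-9
        assert series.uncertainty < 1e-6

    def test_alternative_adduct_mass(self):
        # sodium adducts instead of protons
        na = 22.989218
        peaks = series_peaks(50000.0, [20, 21, 22], adduct=na)
        series = macsed_assign(peaks, adduct_mass=na)
        assert series.charges == (20, 21, 22)
        assert series.mass == pytest.approx(50000.0, rel=1e-9)

    def test_error_cases(self):
        one = series_peaks(10000.0, [10])
        with pytest.raises(AssignmentError):
            macsed_assign(one)
        dup = [Peak(1000.0, 1.0, (999, 1001)), Peak(1000.0, 2.0, (999, 1001))]
        with pytest.raises(AssignmentError):
            macsed_assign(dup)
        many = series_peaks(100000.0, range(10, 20))
        with pytest.raises(AssignmentError):
            macsed_assign(many, z_max=9)

    def test_results_object_diagnostics(self):
        peaks = series_peaks(100000.0, [40, 41, 42, 43])
        res = ChargeSeriesModel(peaks).fit("big")
        assert res.mass == pytest.approx(100000.0, rel=1e-9)
        best = int(np.argmin(res.variance_profile))
        assert res.base_charges[best] == 40
        assert len(res.mass_vector) == 4
        text = res.summary()
        assert "40..43" in text and "MacSED" in text

    def test_noise_robustness_and_monotone_error(self):
        """m/z jitter of 0.1 Th still yields correct charges >= 95% of runs."""
        mass, charges = 1e5, list(range(40, 51))
        true_mz = [mz_from_mass(mass, z) for z in charges]
        correct = 0
        n_rep = 200
        medians = []
        for sigma in (0.01, 0.1, 0.5):
            rng = np.random.default_rng(2024)
            errors = []
            ok = 0
            for _ in range(n_rep):
                mzs = sorted((m + rng.normal(0, sigma) for m in true_mz),
                             reverse=True)
                series = macsed_assign(
                    [Peak(m, 1.0, (m - 1, m + 1)) for m in mzs])
                if series.charges == tuple(charges):
                    ok += 1
                errors.append(abs(series.mass - mass))
            medians.append(float(np.median(errors)))
            if sigma == 0.1:
                correct = ok
        assert correct >= 0.95 * n_rep
        assert medians[0] < medians[1] < medians[2]


class TestMassFinderAndPrediction:
    def test_mass_finder_values(self):
        out = mass_finder(100000.0, 10, 12)
        assert [z for z, _ in out] == [10, 11, 12]
        expect = [10001.007276, 9091.916367, 8334.340609]
        for (_, mz), e in zip(out, expect):
            assert mz == pytest.approx(e, abs=1e-6)

    def test_single_charge_and_errors(self):
        assert len(mass_finder(5000.0, 7, 7)) == 1
        with pytest.raises(ParameterError):
            mass_finder(5000.0, 5, 4)
        with pytest.raises(ParameterError):
            mass_finder(5000.0, 0, 4)

    def test_assign_roundtrip_through_mass_finder(self):
        M = 250000.0
        placed = mass_finder(M, 20, 25)
        peaks = [Peak(mz, 1.0, (mz - 1, mz + 1)) for _, mz in placed]
        series = macsed_assign(peaks)
        assert series.charges == tuple(range(20, 26))
        assert series.mass == pytest.approx(M, rel=1e-9)

    def test_predict_adjacent_values(self):
        series = macsed_assign(series_peaks(10000.0, [9, 10, 11]))
        out = predict_adjacent(series, n=1)
        assert [z for z, _ in out] == [8, 12]
        assert out[0][1] == pytest.approx(1251.007276, abs=1e-6)
        assert out[1][1] == pytest.approx(834.340609, abs=1e-6)

    def test_predict_adjacent_clips_below_charge_one(self):
        series = macsed_assign(series_peaks(10000.0, [1, 2]))
        out = predict_adjacent(series, n=1)
        assert [z for z, _ in out] == [3]

    def test_predict_adjacent_n3(self):
        series = macsed_assign(series_peaks(10000.0, [9, 10, 11]))
        out = predict_adjacent(series, n=3)
        assert [z for z, _ in out] == [6, 7, 8, 12, 13, 14]

    def test_predictions_lie_on_mass_finder(self):
        series = macsed_assign(series_peaks(77777.0, [30, 31, 32]))
        for z, mz in predict_adjacent(series, n=2):
            [(zf, mzf)] = mass_finder(series.mass, z, z)
            assert zf == z and mzf == mz
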