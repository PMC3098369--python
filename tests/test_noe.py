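"""NOE calibration and restraint generation: the r^-6 spin-pair model,
overlap normalisation, and distance binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chondronmr.errors import InputError, MissingPeakError
from chondronmr.noe import (
    MEDIUM_BOUNDS,
    STRONG_BOUNDS,
    CalibrationModel,
    NoePeak,
    back_predict_references,
    bin_restraint,
    build_restraint_set,
    fit_calibration,
    normalize_overlapped,
    predict_distance,
    read_peaks,
    read_restraints,
    write_peaks,
    write_restraints,
)


class TestCalibration:
    def test_single_exact_point(self):
        assert fit_calibration([(1.0, 1.0)]).k == pytest.approx(1.0)

    def test_noiseless_recovery_k64(self):
        refs = [(64.0 * r ** -6, r) for r in (2.0, 2.5, 3.0)]
        assert fit_calibration(refs).k == pytest.approx(64.0, rel=1e-12)

    def test_zero_intensity_rejected(self):
        with pytest.raises(InputError):
            fit_calibration([(0.0, 2.0)])

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            fit_calibration([])

    @settings(max_examples=60, derandomize=True)
    @given(logk=st.floats(min_value=-3.0, max_value=3.0))
    def test_noiseless_recovery_any_k(self, logk):
        k = 10.0 ** logk
        refs = [(k * r ** -6, r) for r in (1.8, 2.2, 2.6, 3.0, 3.4)]
        assert fit_calibration(refs).k == pytest.approx(k, rel=1e-9)


class TestPredictDistance:
    def test_identity_at_k(self):
        m = CalibrationModel(k=7.3)
        assert predict_distance(7.3, m) == pytest.approx(1.0)

    def test_k64_gives_two_angstrom(self):
        assert predict_distance(1.0, CalibrationModel(k=64.0)) == pytest.approx(2.0)

    @settings(max_examples=60, derandomize=True)
    @given(r=st.floats(min_value=0.5, max_value=10.0))
    def test_algebraic_roundtrip(self, r):
        m = CalibrationModel(k=123.4)
        assert predict_distance(m.k * r ** -6, m) == pytest.approx(r, rel=1e-12)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(InputError):
            predict_distance(0.0, CalibrationModel(k=1.0))


class TestNoiseRobustness:
    def test_r6_compresses_multiplicative_noise(self, rng):
        """20% intensity noise -> median relative distance error <= 4%."""
        k, r = 100.0, 2.5
        sigma = np.sqrt(np.log1p(0.2 ** 2))
        factors = rng.lognormal(-sigma ** 2 / 2, sigma, size=1000)
        model = CalibrationModel(k=k)
        rel_err = np.abs(
            [(predict_distance(k * r ** -6 * f, model) - r) / r for f in factors]
        )
        assert np.median(rel_err) <= 0.04

    def test_back_prediction_table_shape(self, calibration, noiseless_peaks):
        refs = [p for p in noiseless_peaks if p.role == "reference"]
        table = back_predict_references(calibration, refs)
        assert len(table) == 5
        assert np.allclose(table.abs_delta_A, 0.0, atol=1e-9)


class TestOverlap:
    def test_division_by_multiplicity(self):
        p = NoePeak("N1:H3", "U2:H1", intensity=9.0, overlap_multiplicity=3)
        assert normalize_overlapped(p) == pytest.approx(3.0)

    def test_multiplicity_one_unchanged(self):
        p = NoePeak("N1:H3", "U2:H1", intensity=9.0)
        assert normalize_overlapped(p) == pytest.approx(9.0)

    def test_zero_multiplicity_rejected(self):
        with pytest.raises(InputError):
            NoePeak("a:b", "c:d", intensity=1.0, overlap_multiplicity=0)


class TestBinning:
    @pytest.mark.parametrize(
        "r,expected_bin,bounds",
        [
            (2.0, "strong", STRONG_BOUNDS),
            (2.74, "strong", STRONG_BOUNDS),
            (2.76, "medium", MEDIUM_BOUNDS),
            (3.0, "medium", MEDIUM_BOUNDS),
            (3.8, "medium", MEDIUM_BOUNDS),
        ],
    )
    def test_bins(self, r, expected_bin, bounds):
        rst = bin_restraint(r, "a:b", "c:d")
        assert rst.bin == expected_bin
        assert (rst.lower, rst.upper) == bounds
        assert rst.force_constant == 10.0

    def test_unbinnable_warns_and_returns_none(self):
        with pytest.warns(UserWarning, match="beyond the medium bin"):
            assert bin_restraint(4.5, "a:b", "c:d") is None

    def test_idempotent_on_binnable_range(self):
        for r in np.linspace(0.1, 3.8, 200):
            assert bin_restraint(r, "a:b", "c:d") is not None


class TestRestraintSet:
    def test_eight_restraints_matching_experimental_bins(
        self, noiseless_peaks, calibration
    ):
        restraints = build_restraint_set(noiseless_peaks, calibration)
        assert len(restraints) == 8
        by_pair = {(r.atom_a.split(":")[1], r.atom_b.split(":")[1]): r.bin
                   for r in restraints}
        # the experimentally observed intensity classes
        assert by_pair[("HN", "H1")] == "medium"
        assert by_pair[("H3", "H1")] == "strong"
        assert by_pair[("H1", "H4")] == "strong"

    def test_missing_peak_named(self, noiseless_peaks, calibration):
        trimmed = [
            p for p in noiseless_peaks
            if not (p.atom_a == "N3:H1" and p.atom_b == "U2:H4")
        ]
        with pytest.raises(MissingPeakError, match="N3:U2 N3:H1/U2:H4"):
            build_restraint_set(trimmed, calibration)

    def test_all_strong_when_intensities_high(self, cn6_fixture):
        from chondronmr.synthetic import SyntheticNoesyConfig, simulate_noesy

        peaks = simulate_noesy(cn6_fixture, SyntheticNoesyConfig(k_true=10.0))
        # calibration constant below the generator's k scales every predicted
        # distance down by (k_cal/k_true)^(1/6), pushing all pairs strong
        cal = CalibrationModel(k=3.0)
        restraints = build_restraint_set(peaks, cal)
        assert len(restraints) == 8
        assert all(r.bin == "strong" for r in restraints)


class TestTables:
    def test_peak_and_restraint_roundtrip(self, tmp_path, noiseless_peaks,
                                          calibration):
        ppath = tmp_path / "peaks.tsv"
        write_peaks(noiseless_peaks, ppath)
        again = read_peaks(ppath)
        assert len(again) == len(noiseless_peaks)
        assert again[0].atom_a == noiseless_peaks[0].atom_a
        restraints = build_restraint_set(again, calibration)
        rpath = tmp_path / "restraints.tsv"
        write_restraints(restraints, rpath)
        back = read_restraints(rpath)
        assert [(r.atom_a, r.bin) for r in back] == [
            (r.atom_a, r.bin) for r in restraints
        ]
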