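"""Heavy-label mass accounting, fragment m/z, XIC and co-elution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neopept.prm import (
    STANDARD_LABELS,
    ChromatogramTrace,
    IsotopeLabel,
    NoLabelSiteError,
    check_light_contamination,
    coelution_score,
    enumerate_fragments,
    extract_xic,
    fragment_mz,
    heavy_mass_shift,
    precursor_mz,
)

# independent residue-mass oracle (monoisotopic values transcribed from
# standard isotope mass tables, not taken from the implementation)
ORACLE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
ORACLE_PROTON = 1.007276
ORACLE_WATER = 18.010565

AA = "".join(ORACLE_MASS)


def _oracle_mz(peptide, series, index, charge):
    span = peptide[:index] if series == "b" else peptide[len(peptide) - index:]
    neutral = sum(ORACLE_MASS[a] for a in span)
    if series == "y":
        neutral += ORACLE_WATER
    return (neutral + charge * ORACLE_PROTON) / charge


class TestHeavyMassShift:
    def test_single_arg_label(self):
        # 13C6 15N4 arginine, delta from isotope mass tables
        assert heavy_mass_shift("TGAARFDEF", STANDARD_LABELS["R"]) == (
            pytest.approx(10.00827, abs=1e-4)
        )

    def test_two_lysines_double_the_delta(self):
        assert heavy_mass_shift("AKAAKA", STANDARD_LABELS["K"]) == (
            pytest.approx(2 * 8.01420, abs=1e-4)
        )

    def test_absent_residue_is_an_error(self):
        with pytest.raises(NoLabelSiteError):
            heavy_mass_shift("AAAA", STANDARD_LABELS["R"])


class TestFragmentMz:
    def test_y1_of_phe(self):
        # F + H2O + proton, summed from the independent oracle table
        assert fragment_mz("TGAARFDEF", "y", 1, 1) == pytest.approx(
            166.0863, abs=1e-3
        )

    def test_b2_of_tg(self):
        assert fragment_mz("TGAARFDEF", "b", 2, 1) == pytest.approx(
            159.0764, abs=1e-3
        )

    def test_fragment_not_spanning_label_identical_in_both_channels(self):
        label = STANDARD_LABELS["R"]  # R at position 5 of TGAARFDEF
        light = fragment_mz("TGAARFDEF", "y", 4, 1)
        heavy = fragment_mz("TGAARFDEF", "y", 4, 1, label=label)
        assert heavy == light

    def test_fragment_spanning_label_shifted_by_delta_over_charge(self):
        label = STANDARD_LABELS["R"]
        for charge in (1, 2):
            light = fragment_mz("TGAARFDEF", "y", 5, charge)
            heavy = fragment_mz("TGAARFDEF", "y", 5, charge, label=label)
            assert heavy - light == pytest.approx(
                label.mass_delta / charge, abs=1e-9
            )

    def test_index_and_charge_range_errors(self):
        with pytest.raises(IndexError):
            fragment_mz("PEPTIDE", "b", 7, 1)
        with pytest.raises(ValueError):
            fragment_mz("PEPTIDE", "b", 2, 0)

    @given(
        peptide=st.text(alphabet=AA, min_size=2, max_size=20),
        charge=st.integers(min_value=1, max_value=3),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_residue_sum_oracle(self, peptide, charge):
        for series in ("b", "y"):
            for index in range(1, len(peptide)):
                assert fragment_mz(peptide, series, index, charge) == (
                    pytest.approx(
                        _oracle_mz(peptide, series, index, charge), abs=2e-4
                    )
                )

    @given(peptide=st.text(alphabet=AA, min_size=2, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_b_y_mass_additivity(self, peptide):
        # neutral(b_i) + neutral(y_{n-i}) = neutral(precursor)
        n = len(peptide)
        precursor_neutral = precursor_mz(peptide, 1) - ORACLE_PROTON
        for i in range(1, n):
            b_neutral = fragment_mz(peptide, "b", i, 1) - ORACLE_PROTON
            y_neutral = fragment_mz(peptide, "y", n - i, 1) - ORACLE_PROTON
            assert b_neutral + y_neutral == pytest.approx(
                precursor_neutral, abs=1e-9
            )


def _signals(rows):
    return pd.DataFrame(rows, columns=["mz", "time", "intensity"])


class TestExtractXic:
    def test_peak_at_target_recovered(self):
        sig = _signals([(500.0, 10.0, 100.0), (500.0, 10.5, 200.0)])
        trace = extract_xic(sig, 500.0)
        assert list(trace.times) == [10.0, 10.5]
        assert list(trace.intensities) == [100.0, 200.0]

    def test_signal_outside_tolerance_excluded(self):
        sig = _signals([(500.03, 10.0, 100.0)])
        trace = extract_xic(sig, 500.0, tol=0.02)
        assert trace.times.size == 0

    def test_signals_within_window_summed(self):
        sig = _signals([(499.99, 10.0, 100.0), (500.01, 10.0, 50.0)])
        trace = extract_xic(sig, 500.0, tol=0.02)
        assert list(trace.intensities) == [150.0]


def _gaussian_traces(apex, n=4, width=0.1, times=None):
    if times is None:
        times = np.arange(apex - 1, apex + 1, 0.02)
    out = {}
    for i in range(n):
        amp = 1e5 * (i + 1)
        out[f"y{i + 1}"] = ChromatogramTrace(
            times=times,
            intensities=amp * np.exp(-0.5 * ((times - apex) / width) ** 2),
            channel="x",
        )
    return out


class TestCoelution:
    def test_identical_traces_validated(self):
        light = _gaussian_traces(30.0)
        heavy = _gaussian_traces(30.0)
        report = coelution_score(light, heavy)
        assert all(
            r == pytest.approx(1.0) for r in report.fragment_correlations.values()
        )
        assert report.verdict == "validated"

    def test_all_zero_light_not_validated(self):
        heavy = _gaussian_traces(30.0)
        times = next(iter(heavy.values())).times
        light = {
            k: ChromatogramTrace(times=times, intensities=np.zeros_like(times))
            for k in heavy
        }
        report = coelution_score(light, heavy)
        assert report.n_qualifying == 0
        assert report.verdict == "not_validated"
        assert set(report.excluded_fragments) == set(heavy)

    def test_apex_shift_beyond_tolerance_rejected(self):
        # Gaussian light peaks shifted by 0.5 min: per-fragment shapes are
        # still mutually correlated but the apexes no longer align
        heavy = _gaussian_traces(30.0, times=np.arange(29.0, 31.5, 0.02))
        light = _gaussian_traces(30.5, times=np.arange(29.0, 31.5, 0.02))
        report = coelution_score(light, heavy, max_apex_dt=0.2)
        assert report.apex_dt == pytest.approx(0.5, abs=0.05)
        assert report.verdict == "not_validated"

    def test_verdict_monotone_in_thresholds(self):
        heavy = _gaussian_traces(30.0)
        light = _gaussian_traces(30.05)
        strict = coelution_score(light, heavy, r_min=0.99, min_fragments=4)
        loose = coelution_score(light, heavy, r_min=0.5, min_fragments=1)
        if strict.verdict == "validated":
            assert loose.verdict == "validated"
        assert loose.n_qualifying >= strict.n_qualifying


class TestLightContamination:
    def test_zero_light_signal_passes(self):
        heavy = _gaussian_traces(30.0)
        times = next(iter(heavy.values())).times
        light = {
            k: ChromatogramTrace(times=times, intensities=np.zeros_like(times))
            for k in heavy
        }
        assert check_light_contamination(light, heavy) is True

    def test_light_equal_to_heavy_fails(self):
        heavy = _gaussian_traces(30.0)
        assert check_light_contamination(heavy, heavy) is False

    def test_trace_below_threshold_passes(self):
        heavy = _gaussian_traces(30.0)
        light = {
            k: ChromatogramTrace(
                times=t.times, intensities=0.001 * t.intensities
            )
            for k, t in heavy.items()
        }
        assert check_light_contamination(light, heavy, threshold=0.01) is True


class TestEnumerateFragments:
    def test_full_ladder_at_two_charges(self):
        frags = enumerate_fragments("PEPTIDEK")
        # (n-1) indices x 2 series x 2 charges
        assert len(frags) == 7 * 2 * 2

    def test_label_containment_marked(self):
        label = STANDARD_LABELS["K"]  # C-terminal K of PEPTIDEK
        frags = enumerate_fragments("PEPTIDEK", label=label, charges=[1])
        for f in frags:
            if f.series == "y":
                assert f.contains_label  # every y ion spans the C-term K
            else:
                assert f.contains_label == (f.index == 8 - 1 + 1)
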