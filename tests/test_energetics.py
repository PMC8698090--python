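import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vstenergetics.energetics import (
    EnergeticsConfig,
    cost_of_transport,
    energy_expenditure,
    hr_zone_fractions,
    metabolic_power,
    summarize_session,
)
from vstenergetics.errors import AnalysisError, DomainError, ParameterError
from vstenergetics.gait_segmentation import Gait, RaceSegment, detect_races, label_session

from .conftest import make_session

# frozen independent evaluations of the published coefficients
EE_AT_100_BPM = 554.3913317413236            # 0.0566 * 100 ** 1.9955
COT_DIMENSIONAL_EXAMPLE = 0.8333333333333334  # (185-35)*(25/60)/(500*150)*1e3
COT_PAPER_NUMERIC_EXAMPLE = 46.477732793522264  # (189.98-35)/(6.5*513)*1e3
PMET_EXAMPLE = 149.40254652301667             # (111.27-35)/510.5*1e3


class TestEnergyExpenditure:
    def test_zero_hr(self):
        assert energy_expenditure(0.0) == 0.0

    def test_unit_hr_returns_coefficient(self):
        assert energy_expenditure(1.0) == pytest.approx(0.0566)

    def test_hr_100(self):
        assert energy_expenditure(100.0) == pytest.approx(EE_AT_100_BPM, rel=1e-12)
        assert energy_expenditure(100.0) == pytest.approx(554.4, abs=0.05)

    def test_negative_hr_rejected(self):
        with pytest.raises(DomainError):
            energy_expenditure(-1.0)

    def test_vector_input(self):
        out = energy_expenditure(np.array([0.0, 1.0, 100.0]))
        assert out == pytest.approx([0.0, 0.0566, EE_AT_100_BPM])

    @settings(max_examples=100, deadline=None)
    @given(
        hr=st.floats(0, 259, allow_nan=False),
        delta=st.floats(0.01, 50, allow_nan=False),
    )
    def test_strictly_increasing(self, hr, delta):
        assert energy_expenditure(hr + delta) > energy_expenditure(hr)

    @settings(max_examples=50, deadline=None)
    @given(hr=st.floats(0, 260, allow_nan=False), factor=st.floats(0.1, 10))
    def test_linear_in_coefficient(self, hr, factor):
        base = EnergeticsConfig()
        scaled = EnergeticsConfig(ee_coeff=0.0566 * factor)
        assert energy_expenditure(hr, scaled) == pytest.approx(
            factor * energy_expenditure(hr, base), rel=1e-12
        )


class TestCostOfTransport:
    def test_zero_at_baseline(self):
        assert cost_of_transport(35.0, 500.0, distance_m=100.0, duration_s=60.0) == 0.0

    def test_dimensional_example(self):
        got = cost_of_transport(185.0, 500.0, distance_m=150.0, duration_s=25.0)
        assert got == pytest.approx(COT_DIMENSIONAL_EXAMPLE, rel=1e-12)

    def test_paper_numeric_example(self):
        config = EnergeticsConfig(cot_mode="paper_numeric")
        got = cost_of_transport(189.98, 513.0, mean_speed_mps=6.5, config=config)
        assert got == pytest.approx(COT_PAPER_NUMERIC_EXAMPLE, rel=1e-12)
        # same order of magnitude as the published gallop COT (~46.65)
        assert got == pytest.approx(46.5, abs=0.2)

    def test_below_baseline_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            got = cost_of_transport(30.0, 500.0, distance_m=100.0, duration_s=60.0)
        assert got == 0.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mass_kg=0.0, distance_m=1.0, duration_s=1.0),
            dict(mass_kg=500.0, distance_m=0.0, duration_s=1.0),
            dict(mass_kg=500.0, distance_m=1.0, duration_s=0.0),
            dict(mass_kg=500.0),  # dimensional mode without distance/duration
        ],
    )
    def test_domain_errors_dimensional(self, kwargs):
        with pytest.raises(DomainError):
            cost_of_transport(150.0, **kwargs)

    def test_domain_errors_paper_numeric(self):
        config = EnergeticsConfig(cot_mode="paper_numeric")
        with pytest.raises(DomainError):
            cost_of_transport(150.0, 500.0, mean_speed_mps=0.0, config=config)
        with pytest.raises(DomainError):
            cost_of_transport(150.0, 500.0, config=config)

    def test_scale_factor_one_is_literal_formula(self):
        config = EnergeticsConfig(scale_factor=1.0)
        got = cost_of_transport(185.0, 500.0, distance_m=150.0, duration_s=25.0,
                                config=config)
        assert got == pytest.approx(COT_DIMENSIONAL_EXAMPLE / 1000.0, rel=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(hr=st.floats(35, 260), mass=st.floats(100, 800))
    def test_linear_above_baseline_and_inverse_in_mass(self, hr, mass):
        got = cost_of_transport(hr, mass, distance_m=100.0, duration_s=60.0)
        expected = (hr - 35.0) * 1.0 / (mass * 100.0) * 1000.0
        assert got == pytest.approx(expected, rel=1e-12)


class TestMetabolicPower:
    def test_zero_at_baseline(self):
        assert metabolic_power(35.0, 500.0) == 0.0

    def test_simple_example(self):
        assert metabolic_power(135.0, 500.0) == pytest.approx(200.0, rel=1e-12)

    def test_published_magnitude_example(self):
        got = metabolic_power(111.27, 510.5)
        assert got == pytest.approx(PMET_EXAMPLE, rel=1e-12)
        assert got == pytest.approx(149.4, abs=0.05)

    def test_below_baseline_clamped(self):
        with pytest.warns(UserWarning, match="clamp"):
            assert metabolic_power(20.0, 500.0) == 0.0

    def test_bad_mass(self):
        with pytest.raises(DomainError):
            metabolic_power(100.0, -5.0)

    def test_scale_factor_one(self):
        config = EnergeticsConfig(scale_factor=1.0)
        assert metabolic_power(135.0, 500.0, config) == pytest.approx(0.2, rel=1e-12)


class TestSummarizeSession:
    def _constant_session(self, hr=100.0, speed=3.0, n=30):
        return make_session([hr] * n, [speed] * n)

    def test_constant_stream_ee_exact(self):
        session = self._constant_session()
        labels = [Gait.TROT] * 30
        races = [RaceSegment(index=1, start_s=0, end_s=30, distance_m=90.0)]
        summary = summarize_session(session, labels, races)
        cell = summary.cells.iloc[0]
        assert cell["gait"] == "trot"
        assert cell["ee_J_per_kg_min"] == pytest.approx(energy_expenditure(100.0), rel=1e-12)
        assert cell["mean_hr_bpm"] == pytest.approx(100.0)

    def test_ee_from_mean_hr_equals_per_sample_on_constant_stream(self):
        session = self._constant_session()
        labels = [Gait.TROT] * 30
        races = [RaceSegment(1, 0, 30, 90.0)]
        per_sample = summarize_session(session, labels, races)
        of_mean = summarize_session(
            session, labels, races, EnergeticsConfig(ee_from_mean_hr=True)
        )
        assert per_sample.cells["ee_J_per_kg_min"].iloc[0] == pytest.approx(
            of_mean.cells["ee_J_per_kg_min"].iloc[0], rel=1e-12
        )

    def test_empty_race_set_rejected(self):
        session = self._constant_session()
        with pytest.raises(AnalysisError):
            summarize_session(session, [Gait.TROT] * 30, [])

    def test_misaligned_labels(self):
        session = self._constant_session()
        with pytest.raises(AnalysisError):
            summarize_session(session, [Gait.TROT] * 10, [RaceSegment(1, 0, 30, 90.0)])

    def test_totals_conserve_cell_samples(self, vst_session):
        labels = label_session(vst_session)
        races = detect_races(vst_session, labels)
        summary = summarize_session(vst_session, labels, races)
        n_transition = int(np.sum([label is Gait.TRANSITION for label in labels]))
        assert summary.cells["n_samples"].sum() + n_transition == vst_session.n_samples
        assert summary.totals["n_samples"] == vst_session.n_samples - n_transition
        # totals mean HR is the sample-count weighted combination of cells
        weighted = (
            summary.cells["mean_hr_bpm"] * summary.cells["n_samples"]
        ).sum() / summary.cells["n_samples"].sum()
        assert summary.totals["mean_hr_bpm"] == pytest.approx(weighted, rel=1e-12)
        assert summary.totals["distance_m"] == pytest.approx(
            summary.cells["distance_m"].sum(), rel=1e-9
        )

    def test_mass_used_is_total_carried(self, vst_session):
        labels = label_session(vst_session)
        races = detect_races(vst_session, labels)
        summary = summarize_session(vst_session, labels, races)
        assert summary.mass_kg == pytest.approx(428.0 + 75.0 + 10.0)


class TestHrZoneFractions:
    def test_all_below_single_bound(self):
        session = make_session([100] * 10, [1.0] * 10)
        assert hr_zone_fractions(session, [150.0]).tolist() == [1.0, 0.0]

    def test_even_split(self):
        session = make_session([140] * 50 + [160] * 50, [1.0] * 100)
        assert hr_zone_fractions(session, [150.0]).tolist() == [0.5, 0.5]

    def test_fractions_sum_to_one(self, vst_session):
        fractions = hr_zone_fractions(vst_session, [100.0, 150.0, 180.0])
        assert fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert fractions.size == 4

    def test_unsorted_bounds_rejected(self, vst_session):
        with pytest.raises(ParameterError):
            hr_zone_fractions(vst_session, [150.0, 100.0])

    def test_cohort_contrast_below_150(self, cohort):
        # with the preset set-points, PH trot sits below 150 bpm while HH
        # trot sits above it, so by construction PH accumulates the larger
        # sub-150 fraction (walk time, shared by both roles, dominates)
        ph = [hr_zone_fractions(s, [150.0])[0] for s in cohort.sessions
              if s.metadata.role.value == "PH"]
        hh = [hr_zone_fractions(s, [150.0])[0] for s in cohort.sessions
              if s.metadata.role.value == "HH"]
        assert np.mean(ph) > np.mean(hh)
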