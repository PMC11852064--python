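"""Probability-of-target-attainment engine: thresholds, windows, monotonicity."""

import numpy as np
import pytest

from dalbapk import (
    PTAConfig,
    Regimen,
    SimulationConfig,
    WeightBand,
    concentration,
    extend_regimen,
    pta_by_mic,
    pta_by_week,
    sample_population,
    target_attained,
    total_threshold_from_mic,
)
from dalbapk.pk import DoseEvent
from dalbapk.pta import evaluation_grid

BANDS = (WeightBand(40, 80), WeightBand(80, 120), WeightBand(120, 200))


@pytest.fixture(scope="module")
def small_population(reference_model):
    return sample_population(
        reference_model, BANDS, SimulationConfig(n_per_band=300, seed=17)
    )


class TestThreshold:
    def test_clinical_breakpoint_value(self):
        thr = total_threshold_from_mic(0.25, 4, 0.07)
        assert f"{thr:.2f}" == "14.29"
        assert thr == pytest.approx(4 * 0.25 / 0.07, rel=1e-15)

    def test_fully_free_drug(self):
        assert total_threshold_from_mic(0.25, 4, 1.0) == pytest.approx(1.0)

    def test_former_breakpoint(self):
        assert total_threshold_from_mic(0.125, 4, 0.07) == pytest.approx(
            7.142857, rel=1e-6
        )

    def test_zero_free_fraction_rejected(self):
        with pytest.raises(ValueError):
            total_threshold_from_mic(0.25, 4, 0.0)


class TestTargetAttained:
    def test_constant_profile_above(self):
        cfg = PTAConfig()
        times = np.arange(0.0, 200.0)
        profile = np.full(times.size, 2.0 * cfg.free_target / cfg.fu)
        assert target_attained(times, profile, cfg, 150.0)

    def test_touching_threshold_fails(self):
        """Strict inequality: exactly reaching 4xMIC does not attain."""
        cfg = PTAConfig()
        times = np.arange(0.0, 10.0)
        profile = np.full(times.size, 2.0 * cfg.free_target / cfg.fu)
        profile[5] = cfg.free_target / cfg.fu
        assert not target_attained(times, profile, cfg, 9.0)

    def test_window_beyond_grid_rejected(self):
        cfg = PTAConfig()
        with pytest.raises(ValueError, match="window"):
            target_attained(np.arange(10.0), np.ones(10), cfg, 50.0)

    def test_typical_subject_five_weeks(self, typical_params, two_dose_regimen):
        """A typical 70 kg adult on day 0 + day 7 dosing holds the target
        for 5 weeks: total trough at day 35 is ~30 mg/L > 14.29."""
        cfg = PTAConfig(horizon_weeks=5)
        grid = evaluation_grid(two_dose_regimen, 840.0, 1.0)
        prof = concentration(typical_params, two_dose_regimen, grid)
        assert prof[-1] > 14.29
        assert prof[-1] == pytest.approx(30.0, abs=2.0)
        assert target_attained(grid, prof, cfg, 840.0)


class TestPtaByWeek:
    def test_tiny_mic_attains_everywhere(self, reference_model, small_population,
                                         two_dose_regimen):
        cfg = PTAConfig(mic=1e-9, horizon_weeks=6)
        res = pta_by_week(reference_model, small_population, BANDS,
                          two_dose_regimen, cfg)
        for frac in res.fractions.values():
            np.testing.assert_array_equal(frac, 1.0)
        assert all(w == 6 for w in res.latest_optimal_week.values())

    def test_monotone_in_week_and_band(self, reference_model, small_population,
                                       two_dose_regimen):
        cfg = PTAConfig(horizon_weeks=8)
        res = pta_by_week(reference_model, small_population, BANDS,
                          two_dose_regimen, cfg)
        fr = [res.fractions[b.label] for b in BANDS]
        for f in fr:
            assert np.all(np.diff(f) <= 0)
        # heavier bands fail earlier at every week
        assert np.all(fr[0] >= fr[1]) and np.all(fr[1] >= fr[2])

    def test_single_subject_fraction_degenerate(self, reference_model,
                                                two_dose_regimen):
        pop = sample_population(
            reference_model, [WeightBand(40, 80)],
            SimulationConfig(n_per_band=1, seed=2),
        )
        cfg = PTAConfig(horizon_weeks=8)
        res = pta_by_week(reference_model, pop, [WeightBand(40, 80)],
                          two_dose_regimen, cfg)
        assert set(np.unique(res.fractions["40-80 kg"])) <= {0.0, 1.0}

    def test_empty_band_rejected(self, reference_model, small_population,
                                 two_dose_regimen):
        with pytest.raises(ValueError, match="no subjects"):
            pta_by_week(
                reference_model, small_population,
                [WeightBand(300, 400)], two_dose_regimen, PTAConfig(),
            )

    def test_reproducible_and_extra_dose_helps(self, reference_model,
                                               two_dose_regimen):
        cfg = PTAConfig(horizon_weeks=8)
        pop = sample_population(
            reference_model, BANDS, SimulationConfig(n_per_band=150, seed=5)
        )
        res1 = pta_by_week(reference_model, pop, BANDS, two_dose_regimen, cfg)
        res2 = pta_by_week(reference_model, pop, BANDS, two_dose_regimen, cfg)
        for b in BANDS:
            np.testing.assert_array_equal(
                res1.fractions[b.label], res2.fractions[b.label]
            )
        # adding a dose never decreases PTA at any week
        extended = extend_regimen(two_dose_regimen, 3)
        res3 = pta_by_week(reference_model, pop, BANDS, extended, cfg)
        for b in BANDS:
            assert np.all(
                res3.fractions[b.label] >= res1.fractions[b.label] - 1e-12
            )


class TestExtendRegimen:
    def test_third_dose_at_week_five(self, two_dose_regimen):
        reg = extend_regimen(two_dose_regimen, 5)
        times = [e.time for e in reg.events]
        assert times == [0.0, 168.0, 840.0]
        assert np.all(np.diff(times) > 0)
        assert reg.events[-1].amount == 1500.0
        assert reg.events[-1].duration == 0.5

    def test_scheduling_before_last_dose_rejected(self, two_dose_regimen):
        with pytest.raises(ValueError, match="after the last"):
            extend_regimen(two_dose_regimen, 1)

    def test_zero_amount_rejected(self, two_dose_regimen):
        with pytest.raises(ValueError, match="amount"):
            extend_regimen(two_dose_regimen, 5, amount=0.0)


class TestPtaByMic:
    def test_monotone_and_consistent(self, reference_model, small_population,
                                     two_dose_regimen):
        cfg = PTAConfig(horizon_weeks=4)
        mics = [0.001, 0.016, 0.032, 0.064, 0.125, 0.25, 0.5, 1.0]
        table = pta_by_mic(
            reference_model, small_population, BANDS, two_dose_regimen,
            mics, cfg, window_weeks=4,
        )
        for b in BANDS:
            sub = table[table["band"] == b.label].sort_values("mic")
            assert np.all(np.diff(sub["pta"].to_numpy()) <= 0)
        # MIC far below any achievable trough attains for everyone
        assert (table[table["mic"] == 0.001]["pta"] == 1.0).all()
        # entry-point consistency at the breakpoint MIC
        weekly = pta_by_week(reference_model, small_population, BANDS,
                             two_dose_regimen, cfg)
        for b in BANDS:
            at_bp = table[(table["band"] == b.label) & (table["mic"] == 0.25)]
            assert at_bp["pta"].iloc[0] == pytest.approx(
                weekly.fractions[b.label][3], abs=1e-12
            )

    def test_unsorted_grid_rejected(self, reference_model, small_population,
                                    two_dose_regimen):
        with pytest.raises(ValueError):
            pta_by_mic(
                reference_model, small_population, BANDS, two_dose_regimen,
                [0.5, 0.25], PTAConfig(),
            )
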