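"""Bioreactor metrics: worked unit-conversion examples frozen from hand
calculation, plus linearity/additivity/monotonicity property tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import trapezoid

from beadassay import (ConcentrationSeries, DOEscalationConfig, MediaRegime,
                       ParameterError, ProcessLog, check_nutrient_bounds,
                       do_setpoint_recipe, functional_value_bilirubin,
                       media_biomass_ratio, oxygen_consumption_per_cell,
                       production_efficiency, protein_auc_mg, secretion_rate,
                       viability_drop_summary)


def _log(**overrides) -> ProcessLog:
    n = overrides.pop("n", 4)
    base = dict(
        time_h=np.arange(n, dtype=float),
        glucose_mM=np.full(n, 20.0),
        lactate_mM=np.full(n, 5.0),
        do_sub_pct=np.full(n, 21.0),
        do_post_pct=np.full(n, 12.0),
        flow_mL_min=np.full(n, 380.0),
        cell_count=np.full(n, 7e10),
        biomass_volume_L=np.full(n, 2.5),
        media_volume_L=np.full(n, 116.0),
    )
    base.update(overrides)
    return ProcessLog(**base)


# ---------------------------------------------------------------------------
# nutrient bounds
# ---------------------------------------------------------------------------

class TestNutrientBounds:
    def test_safe_levels_pass(self):
        log = _log(glucose_mM=np.full(4, 16.0), lactate_mM=np.full(4, 9.0))
        assert check_nutrient_bounds(log) == []

    def test_low_glucose_flagged(self):
        g = np.array([20.0, 14.0, 20.0, 20.0])
        v = check_nutrient_bounds(_log(glucose_mM=g))
        assert len(v) == 1
        assert v[0]["variable"] == "glucose_mM" and v[0]["value"] == 14.0

    def test_bounds_are_strict(self):
        """Exactly 15 mM glucose / 10 mM lactate violate the 'above 15',
        'below 10' safety levels."""
        log = _log(glucose_mM=np.full(1, 15.0), lactate_mM=np.full(1, 10.0),
                   n=1)
        v = check_nutrient_bounds(log)
        assert {x["variable"] for x in v} == {"glucose_mM", "lactate_mM"}


# ---------------------------------------------------------------------------
# oxygen consumption
# ---------------------------------------------------------------------------

class TestOxygenConsumption:
    def test_no_drop_means_zero(self):
        assert oxygen_consumption_per_cell(21.0, 21.0, 380.0, 7e10) == 0.0

    def test_hand_unit_conversion(self):
        """ΔC = 10 µM at 380 mL/min over 8e10 cells:
        10 µmol/L x 0.38 L/min / 60 / 8e10 cells = 7.92e-4 fmol/cell/s."""
        got = oxygen_consumption_per_cell(
            do_in_pct=26.0, do_out_pct=21.0, flow_mL_min=380.0,
            cell_count=8e10, sat_uM=200.0)  # 5% of 200 µM = 10 µM
        expected = 10.0 * 0.38 / 60.0 / 8e10 * 1e9
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(7.9167e-4, rel=1e-4)

    @settings(derandomize=True, max_examples=60)
    @given(delta=st.floats(0.1, 50.0), flow=st.floats(1.0, 1000.0),
           cells=st.floats(1e6, 1e12))
    def test_linearity_and_inverse_scaling(self, delta, flow, cells):
        base = oxygen_consumption_per_cell(21.0 + delta, 21.0, flow, cells)
        assert oxygen_consumption_per_cell(
            21.0 + delta, 21.0, 2 * flow, cells) == pytest.approx(
                2 * base, rel=1e-9)
        assert oxygen_consumption_per_cell(
            21.0 + 2 * delta, 21.0, flow, cells) == pytest.approx(
                2 * base, rel=1e-9)
        assert oxygen_consumption_per_cell(
            21.0 + delta, 21.0, flow, 2 * cells) == pytest.approx(
                base / 2, rel=1e-9)

    def test_negative_drop_warned_not_raised(self):
        with pytest.warns(UserWarning, match="negative"):
            got = oxygen_consumption_per_cell(20.0, 25.0, 380.0, 7e10)
        assert got < 0

    def test_invalid_cell_count(self):
        with pytest.raises(ParameterError):
            oxygen_consumption_per_cell(21.0, 12.0, 380.0, 0.0)


# ---------------------------------------------------------------------------
# efficiency, drops, ratio
# ---------------------------------------------------------------------------

class TestProductionEfficiency:
    def test_regime_comparison_worked_example(self):
        """2.59e7 -> 3.27e7 cells/mL is a 26% improvement (rounded)."""
        rounded, exact = production_efficiency(2.59e7, 3.27e7)
        assert rounded == 26
        assert exact == pytest.approx(26.254, abs=0.01)

    @pytest.mark.parametrize("old,new,expected", [
        (1e7, 1e7, 0), (1e7, 2e7, 100), (2e7, 1e7, -50)])
    def test_simple_ratios(self, old, new, expected):
        assert production_efficiency(old, new)[0] == expected

    def test_nonpositive_old_density_rejected(self):
        with pytest.raises(ParameterError):
            production_efficiency(0.0, 1e7)


class TestViabilityDropSummary:
    def test_plasma_exposure_worked_example(self):
        """The three in vitro start/end pairs give mean drop 6.2 with
        SEM 2.0 (1 d.p.)."""
        out = viability_drop_summary(
            [(91.3, 87.2), (96.8, 86.6), (96.3, 92.0)])
        assert out["mean_drop"] == pytest.approx(6.2, abs=1e-9)
        assert round(out["sem"], 1) == 2.0
        assert out["n"] == 3

    def test_single_pair_has_undefined_sem(self):
        out = viability_drop_summary([(95.0, 95.0)])
        assert out["mean_drop"] == 0.0
        assert math.isnan(out["sem"])

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.tuples(st.floats(10, 90), st.floats(10, 90)),
                    min_size=2, max_size=8),
           st.floats(-9.9, 9.9))
    def test_translation_invariance(self, pairs, shift):
        shifted = [(s + shift, e + shift) for s, e in pairs]
        a = viability_drop_summary(pairs)
        b = viability_drop_summary(shifted)
        assert a["mean_drop"] == pytest.approx(b["mean_drop"], abs=1e-9)
        assert a["sem"] == pytest.approx(b["sem"], abs=1e-9, nan_ok=True)

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            viability_drop_summary([])


class TestMediaBiomassRatio:
    def test_production_scale_worked_example(self):
        """2.5 L beads in 116 L media is a 1:46 ratio (46.4 exact)."""
        label, n = media_biomass_ratio(2.5, 116.0)
        assert label == "1:46"
        assert n == pytest.approx(46.4)

    def test_unit_ratio_and_scaling(self):
        assert media_biomass_ratio(1.0, 1.0)[0] == "1:1"
        label, n = media_biomass_ratio(2.0, 92.8)
        assert label == "1:46" and n == pytest.approx(46.4)

    def test_zero_biomass_rejected(self):
        with pytest.raises(ParameterError):
            media_biomass_ratio(0.0, 116.0)


# ---------------------------------------------------------------------------
# functional value, secretion, AUC
# ---------------------------------------------------------------------------

def _series(time_h, conc, volume_L, unit):
    return ConcentrationSeries(np.asarray(time_h, float),
                               np.asarray(conc, float), volume_L, unit=unit)


class TestFunctionalValueBilirubin:
    def test_zero_slope_is_zero(self):
        s = _series([1, 4, 8], [30.0, 30.0, 30.0], 8.0, "umol/L")
        assert functional_value_bilirubin(s, 7e10) == pytest.approx(0.0)

    def test_hand_conversion(self):
        """10 µM rise over 8 h in 8 L with 7e10 cells:
        10 µmol/h x 584.66 µg/µmol x 24 h -> 140.3 mg/day, scaled by
        1e11/7e10 -> 200.4 mg/1e11 cells/day."""
        t = np.arange(1.0, 9.0 + 1e-9)
        conc = 30.0 + (t - 1.0) * (10.0 / 8.0)
        s = _series(t, conc, 8.0, "umol/L")
        got = functional_value_bilirubin(s, 7e10)
        assert got == pytest.approx(10.0 / 8.0 * 8.0 * 584.66e-3 * 24.0
                                    * (1e11 / 7e10), rel=1e-9)
        assert got == pytest.approx(200.4, abs=0.1)

    def test_dilution_window_excludes_early_samples(self):
        """The pre-hour-1 dilution artefact must not bias the slope."""
        t = np.array([-1.0, 0.0, 1.0, 2.0, 4.0, 6.0, 8.0])
        conc = np.array([50.0, 30.0, 30.0, 31.25, 33.75, 36.25, 38.75])
        s = _series(t, conc, 8.0, "umol/L")
        clean = _series(t[2:], conc[2:], 8.0, "umol/L")
        assert functional_value_bilirubin(s, 7e10) == pytest.approx(
            functional_value_bilirubin(clean, 7e10), rel=1e-12)

    def test_too_few_points_rejected(self):
        s = _series([1.0, 2.0], [1.0, 2.0], 8.0, "umol/L")
        with pytest.raises(ParameterError):
            functional_value_bilirubin(_series([2.0, 3.0], [1.0, 2.0], 8.0,
                                               "umol/L"), 7e10,
                                       window_start_h=2.5)
        assert functional_value_bilirubin(s, 7e10) > 0


class TestSecretionRate:
    def test_hand_conversion(self):
        """100 ng/mL over 10 h in 1 L with 1e9 cells -> 10,000 ng/h total
        -> 10 ng per 1e6 cells per hour."""
        t = np.arange(0.0, 11.0)
        s = _series(t, 10.0 * t, 1.0, "ng/mL")
        out = secretion_rate(s, 1e9)
        assert out["ng_per_h_total"] == pytest.approx(10000.0, rel=1e-9)
        assert out["ng_per_1e6_cells_per_h"] == pytest.approx(10.0, rel=1e-9)
        assert out["ng_per_1e6_cells_per_day"] == pytest.approx(240.0,
                                                               rel=1e-9)

    def test_halving_cells_doubles_per_cell_rate(self):
        t = np.arange(0.0, 11.0)
        s = _series(t, 10.0 * t, 1.0, "ng/mL")
        a = secretion_rate(s, 1e9)["ng_per_1e6_cells_per_h"]
        b = secretion_rate(s, 5e8)["ng_per_1e6_cells_per_h"]
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_zero_slope_is_zero(self):
        s = _series([1.0, 5.0, 9.0], [7.0, 7.0, 7.0], 1.0, "ng/mL")
        assert secretion_rate(s, 1e9)["ng_per_1e6_cells_per_h"] == \
            pytest.approx(0.0, abs=1e-12)


class TestProteinAUC:
    def test_constant_zero(self):
        s = _series([0.0, 4.0, 8.0], [0.0, 0.0, 0.0], 1.0, "ng/mL")
        assert protein_auc_mg(s) == 0.0

    def test_triangle_closed_form(self):
        """Two points rising from zero form a triangle: ½ x base x
        height of the mass curve."""
        s = _series([0.0, 8.0], [0.0, 1000.0], 2.0, "ng/mL")
        # mass at end = 1000 ng/mL x 2 L = 2 mg; area = 0.5 x 8 x 2
        assert protein_auc_mg(s) == pytest.approx(8.0, rel=1e-12)

    def test_matches_fine_grid_integrator(self, rng):
        """Trapezoidal AUC equals an independent dense-grid integration
        of the piecewise-linear mass curve to 1e-9 relative."""
        for _ in range(20):
            n = int(rng.integers(3, 12))
            t = np.sort(rng.uniform(0, 24, n))
            t += np.arange(n) * 1e-3  # enforce strict increase
            conc = rng.uniform(0, 500, n)
            vol = rng.uniform(0.5, 10.0)
            s = _series(t, conc, vol, "ng/mL")
            dense = np.union1d(t, np.linspace(t[0], t[-1], 20001))
            mass = np.interp(dense, t, conc) * vol * 1e-3
            expected = trapezoid(mass, dense)
            assert protein_auc_mg(s) == pytest.approx(expected, rel=1e-9)

    def test_additive_over_concatenated_windows(self, rng):
        t = np.sort(rng.uniform(0, 24, 9))
        t += np.arange(9) * 1e-3
        conc = rng.uniform(0, 500, 9)
        s = _series(t, conc, 3.0, "ng/mL")
        left = _series(t[:5], conc[:5], 3.0, "ng/mL")
        right = _series(t[4:], conc[4:], 3.0, "ng/mL")
        assert protein_auc_mg(left) + protein_auc_mg(right) == \
            pytest.approx(protein_auc_mg(s), rel=1e-12)


# ---------------------------------------------------------------------------
# DO setpoint recipe
# ---------------------------------------------------------------------------

class TestDOSetpointRecipe:
    CFG = DOEscalationConfig(low_trigger_pct=10.0)

    def test_above_trigger_stays(self):
        assert do_setpoint_recipe(15.0, 21.0, self.CFG) == 21.0

    def test_below_trigger_escalates(self):
        assert do_setpoint_recipe(8.0, 21.0, self.CFG) == 35.0

    def test_top_setpoint_is_absorbing(self):
        for reading in (2.0, 10.0, 50.0):
            assert do_setpoint_recipe(reading, 35.0, self.CFG) == 35.0

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0.0, 40.0), min_size=1, max_size=30))
    def test_trajectory_monotone_nondecreasing(self, readings):
        sp = 21.0
        trajectory = []
        for r in readings:
            sp = do_setpoint_recipe(r, sp, self.CFG)
            trajectory.append(sp)
        assert all(a <= b for a, b in zip(trajectory, trajectory[1:]))

    def test_unknown_setpoint_rejected(self):
        with pytest.raises(ParameterError):
            do_setpoint_recipe(10.0, 25.0, self.CFG)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

class TestContainers:
    def test_process_log_validation(self):
        with pytest.raises(ParameterError):
            _log(time_h=np.array([0.0, 1.0, 1.0, 2.0]))
        with pytest.raises(ParameterError):
            _log(glucose_mM=np.array([1.0, -2.0, 1.0, 1.0]))

    def test_process_log_csv_round_trip(self, tmp_path):
        import pandas as pd

        log = _log()
        df = pd.DataFrame({c: getattr(log, c) for c in ProcessLog.COLUMNS})
        path = tmp_path / "log.csv"
        df.to_csv(path, index=False)
        log2 = ProcessLog.from_csv(path)
        assert np.allclose(log2.glucose_mM, log.glucose_mM)
        assert len(log2) == len(log)

    def test_media_regime_validation(self):
        MediaRegime(((4, 50), (7, 60)))
        with pytest.raises(ParameterError):
            MediaRegime(((7, 50), (4, 60)))
        with pytest.raises(ParameterError):
            MediaRegime(((4, 0),))

    def test_series_scalar_volume_broadcast(self):
        s = _series([0.0, 1.0], [1.0, 2.0], 3.0, "ng/mL")
        assert np.allclose(s.volume_L, [3.0, 3.0])
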