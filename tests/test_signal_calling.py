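import warnings

import numpy as np
import pandas as pd
import pytest

import estoligo as eo
from estoligo.signal_calling import (
    CalibrationError,
    CalibrationResult,
    SATURATION_LEVEL,
    calibration_tsv,
)


def spike_frame(values_by_species, array_id="A1", pmt=400):
    rows = []
    for sid, values in values_by_species.items():
        for r, v in enumerate(values):
            rows.append((sid, array_id, pmt, r, float(v), True))
    return pd.DataFrame(
        rows, columns=["probe_id", "array_id", "pmt", "replicate", "si", "is_control"]
    )


def default_spikes(n=10):
    return eo.SpikeInSet()


class TestCalibrateThreshold:
    def test_zero_variance_threshold_equals_mean(self):
        spots = spike_frame({f"SPIKE_{k:02d}": [100.0, 100.0] for k in (1, 2, 3)})
        cal = eo.calibrate_threshold(spots, default_spikes())
        assert cal.threshold == pytest.approx(100.0)

    def test_arithmetic_against_direct_oracle(self):
        values = {"SPIKE_01": [90, 92, 88], "SPIKE_02": [100, 101, 99], "SPIKE_03": [110, 112, 108],
                  "SPIKE_04": [5000, 5100, 4900]}
        spots = spike_frame(values)
        pooled = np.array(values["SPIKE_01"] + values["SPIKE_02"] + values["SPIKE_03"], float)
        expected = pooled.mean() + 2 * pooled.std(ddof=1)
        cal = eo.calibrate_threshold(spots, default_spikes())
        assert cal.threshold == pytest.approx(expected)
        assert set(cal.lowest_spike_ids) == {"SPIKE_01", "SPIKE_02", "SPIKE_03"}

    def test_translation_equivariance(self):
        base = {f"SPIKE_{k:02d}": [50.0 + k, 60.0 + k, 70.0 + k] for k in range(1, 5)}
        shifted = {sid: [v + 37.5 for v in vals] for sid, vals in base.items()}
        c0 = eo.calibrate_threshold(spike_frame(base), default_spikes())
        c1 = eo.calibrate_threshold(spike_frame(shifted), default_spikes())
        assert c1.threshold == pytest.approx(c0.threshold + 37.5)

    def test_lowest_selected_by_median_signal_not_concentration(self):
        # highest nominal species given the lowest signal: selection follows signal
        values = {"SPIKE_01": [900, 910], "SPIKE_02": [800, 810], "SPIKE_03": [700, 710],
                  "SPIKE_10": [10, 12]}
        cal = eo.calibrate_threshold(spike_frame(values), default_spikes())
        assert "SPIKE_10" in cal.lowest_spike_ids

    def test_too_few_species_rejected(self):
        spots = spike_frame({"SPIKE_01": [1, 2], "SPIKE_02": [3, 4]})
        with pytest.raises(CalibrationError):
            eo.calibrate_threshold(spots, default_spikes())

    def test_single_replicate_rejected(self):
        spots = spike_frame({"SPIKE_01": [1], "SPIKE_02": [3, 4], "SPIKE_03": [5, 6]})
        with pytest.raises(CalibrationError):
            eo.calibrate_threshold(spots, default_spikes())

    def test_mixed_arrays_rejected(self):
        a = spike_frame({f"SPIKE_{k:02d}": [1, 2] for k in (1, 2, 3)}, array_id="A1")
        b = spike_frame({f"SPIKE_{k:02d}": [1, 2] for k in (1, 2, 3)}, array_id="A2")
        with pytest.raises(CalibrationError):
            eo.calibrate_threshold(pd.concat([a, b]), default_spikes())


class TestCallSpot:
    @pytest.fixture()
    def cal(self):
        return CalibrationResult("A1", 400, 250.0, ("SPIKE_01", "SPIKE_02", "SPIKE_03"))

    def test_saturation_boundary_inclusive(self, cal):
        assert eo.call_spot(65000.0, cal) == "saturated"
        assert eo.call_spot(64999.9, cal) == "present"

    def test_threshold_boundary_is_absent(self, cal):
        assert eo.call_spot(250.0, cal) == "absent"
        assert eo.call_spot(250.01, cal) == "present"
        assert eo.call_spot(-5.0, cal) == "absent"

    def test_calls_monotone_in_si(self, cal):
        order = {"absent": 0, "present": 1, "saturated": 2}
        calls = [order[eo.call_spot(si, cal)] for si in np.linspace(-100, 70000, 500)]
        assert calls == sorted(calls)


class TestNegativeControls:
    def _cals(self):
        return {("A1", 400): CalibrationResult(
            "A1", 400, 250.0, ("SPIKE_01", "SPIKE_02", "SPIKE_03"),
            min_spike_median=120.0)}

    def test_all_background_passes(self):
        spots = pd.DataFrame(
            [["NEG_001", "A1", 400, 0, 40.0, True], ["NEG_002", "A1", 400, 0, 55.0, True]],
            columns=["probe_id", "array_id", "pmt", "replicate", "si", "is_control"],
        )
        assert eo.check_negative_controls(spots, self._cals()).passed

    def test_hot_control_listed(self):
        spots = pd.DataFrame(
            [["NEG_001", "A1", 400, 0, 40.0, True], ["NEG_002", "A1", 400, 0, 500.0, True]],
            columns=["probe_id", "array_id", "pmt", "replicate", "si", "is_control"],
        )
        rep = eo.check_negative_controls(spots, self._cals())
        assert not rep.passed
        assert list(rep.offending["probe_id"]) == ["NEG_002"]

    def test_empty_set_vacuous_pass_with_warning(self):
        empty = pd.DataFrame(columns=["probe_id", "array_id", "pmt", "replicate", "si", "is_control"])
        with pytest.warns(UserWarning):
            assert eo.check_negative_controls(empty, self._cals()).passed


class TestTabulateCalls:
    def _spots(self, si_map, arrays=("A1", "A2", "A3", "A4"), pmts=(400, 500), reps=(0,)):
        rows = []
        for pid, si in si_map.items():
            for a in arrays:
                for p in pmts:
                    for r in reps:
                        rows.append((pid, a, p, r, si, False))
        return pd.DataFrame(
            rows, columns=["probe_id", "array_id", "pmt", "replicate", "si", "is_control"]
        )

    def _cals(self, arrays=("A1", "A2", "A3", "A4"), pmts=(400, 500)):
        return {
            (a, p): CalibrationResult(a, p, 250.0, ("SPIKE_01", "SPIKE_02", "SPIKE_03"))
            for a in arrays for p in pmts
        }

    def test_eight_measurement_denominator(self):
        m = eo.tabulate_calls(self._spots({"p0": 1000.0}), self._cals())
        assert tuple(m.loc["p0", ["n_measurements", "n_positive", "n_flagged"]]) == (8, 8, 0)

    def test_duplicate_fill_gives_sixteen(self):
        m = eo.tabulate_calls(self._spots({"p0": 1000.0}, reps=(0, 1)), self._cals())
        assert m.loc["p0", "n_measurements"] == 16

    def test_saturated_flagged_not_positive(self):
        m = eo.tabulate_calls(self._spots({"p0": 66000.0}), self._cals())
        assert tuple(m.loc["p0", ["n_positive", "n_flagged"]]) == (0, 8)

    def test_mean_si_over_nonflagged_only(self):
        spots = self._spots({"p0": 1000.0})
        spots.loc[(spots.array_id == "A1") & (spots.pmt == 400), "si"] = 70000.0
        m = eo.tabulate_calls(spots, self._cals())
        assert m.loc["p0", "mean_si"] == pytest.approx(1000.0)
        assert m.loc["p0", "n_flagged"] == 1

    def test_missing_probe_zero_row_with_warning(self):
        with pytest.warns(UserWarning):
            m = eo.tabulate_calls(
                self._spots({"p0": 500.0}), self._cals(), probe_universe=["p0", "ghost"]
            )
        assert tuple(m.loc["ghost", ["n_measurements", "n_positive", "n_flagged"]]) == (0, 0, 0)

    def test_spot_conservation(self, small_study):
        s = small_study
        matrix = s["matrix"]
        n_feature_spots = int((~s["spots"]["is_control"]).sum())
        assert matrix["n_measurements"].sum() == n_feature_spots

    def test_noiseless_dichotomy(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from conftest import run_study

            s = run_study(seed=3, n_targets=40, noise=False,
                          n_negative_controls=20, duplicate_fill=10)
        m = s["matrix"]
        usable = m["n_measurements"] - m["n_flagged"]
        assert ((m["n_positive"] == 0) | (m["n_positive"] == usable)).all()

    def test_calibration_tsv_shape(self):
        text = calibration_tsv(self._cals())
        assert text.splitlines()[0].startswith("array_id\tpmt\tthreshold")
        assert len(text.splitlines()) == 9
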