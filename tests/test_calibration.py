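import numpy as np
import pandas as pd
import pytest

from cdpbpk.calibration import (HUMAN_ANCHOR_CSS, HUMAN_ANCHOR_DOSE,
                                ObservationSet, calibrate_human_scale,
                                concordance, fit, relative_error_loglik)
from cdpbpk.dosimetry import reverse_dose
from cdpbpk.exposure import single_oral


def _obs(values, times=None, matrix="blood", below_lod=None, lod=0.0):
    n = len(values)
    return ObservationSet(pd.DataFrame({
        "subject": ["s"] * n,
        "time_days": times if times is not None else np.arange(1.0, n + 1.0),
        "matrix": [matrix] * n,
        "value": values,
        "unit": ["ug/L"] * n,
        "below_lod": below_lod if below_lod is not None else [False] * n,
        "lod": [lod] * n,
    }))


class TestRelativeErrorLoglik:
    def test_zero_residual_reduces_to_normalization(self):
        pred = np.array([1.0, 5.0, 20.0])
        ll = relative_error_loglik(_obs(pred), pred, sigma=0.2)
        expected = -np.sum(np.log(0.2 * pred * np.sqrt(2.0 * np.pi)))
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_two_point_hand_value(self):
        # obs = (1, 2), pred = (1, 1), sigma = 1:
        # ll = -2 ln(sqrt(2 pi)) - 0 - 0.5
        ll = relative_error_loglik(_obs([1.0, 2.0]), np.array([1.0, 1.0]), 1.0)
        assert ll == pytest.approx(-2.0 * np.log(np.sqrt(2 * np.pi)) - 0.5,
                                   rel=1e-12)

    def test_decreases_with_any_single_relative_residual(self):
        pred = np.array([1.0, 1.0])
        base = relative_error_loglik(_obs([1.0, 1.0]), pred, 0.3)
        worse = relative_error_loglik(_obs([1.0, 1.4]), pred, 0.3)
        worst = relative_error_loglik(_obs([1.0, 1.8]), pred, 0.3)
        assert base > worse > worst

    def test_censored_records_use_left_tail_mass(self):
        from scipy.stats import norm
        obs = _obs([0.0], below_lod=[True], lod=0.06)
        pred = np.array([0.1])
        ll = relative_error_loglik(obs, pred, 0.5)
        assert ll == pytest.approx(norm.logcdf((0.06 - 0.1) / (0.5 * 0.1)))

    def test_nonpositive_prediction_names_the_record(self):
        with pytest.raises(ValueError, match="record 1"):
            relative_error_loglik(_obs([1.0, 2.0]), np.array([1.0, 0.0]), 0.3)

    def test_maximum_at_zero_residual(self):
        """Numerical gradient of the likelihood vanishes at obs == pred."""
        pred = np.array([2.0, 4.0])
        def ll(eps):
            return relative_error_loglik(_obs([2.0 + eps, 4.0]), pred, 0.25)
        grad = (ll(1e-5) - ll(-1e-5)) / 2e-5
        assert abs(grad) < 1e-4
        assert ll(0.0) > ll(0.1) and ll(0.0) > ll(-0.1)


class TestFit:
    def test_zero_free_parameters_returns_start(self, rat_params, rat_phys):
        obs = _obs([100.0, 50.0], times=[1.0, 7.0])
        scn = single_oral(1000.0, species="rat")
        fitted, report = fit({}, [(obs, scn)], rat_params, rat_phys)
        assert fitted == rat_params
        assert np.isfinite(report.loglik)

    def test_duplicated_dataset_doubles_loglik(self, rat_params, rat_phys):
        obs = _obs([100.0, 50.0], times=[1.0, 7.0])
        scn = single_oral(1000.0, species="rat")
        _, single = fit({}, [(obs, scn)], rat_params, rat_phys, sigma=0.1)
        _, double = fit({}, [(obs, scn), (obs, scn)], rat_params, rat_phys,
                        sigma=0.1)
        assert double.loglik == pytest.approx(2.0 * single.loglik, rel=1e-9)

    def test_bound_violation_at_start_rejected(self, rat_params, rat_phys):
        obs = _obs([1.0])
        scn = single_oral(1000.0, species="rat")
        with pytest.raises(ValueError, match="bounds"):
            fit({"cl_bile": (1.0, 2.0)}, [(obs, scn)], rat_params, rat_phys)

    def test_parameter_recovery_on_synthetic_data(self, recovery_fit):
        """Identifiable parameters are recovered within 15% from noisy
        (10% relative SD) pseudo-observations."""
        truth, fitted, report = recovery_fit
        assert abs(fitted.cl_bile / truth.cl_bile - 1.0) <= 0.15
        assert abs(fitted.p_adipose / truth.p_adipose - 1.0) <= 0.15
        assert report.residual_summary["rms_relative_residual"].iloc[0] < 0.2


class TestHumanScaleCalibration:
    def test_anchor_is_pinned(self, calibrated_human, human_phys):
        r = reverse_dose(HUMAN_ANCHOR_CSS, calibrated_human, human_phys)
        assert r.dose_ug_per_kg_per_day == pytest.approx(HUMAN_ANCHOR_DOSE,
                                                         rel=2e-3)

    def test_idempotent(self, calibrated_human, human_phys):
        again = calibrate_human_scale(calibrated_human, human_phys)
        assert again.cl_bile == pytest.approx(calibrated_human.cl_bile, rel=2e-3)
        assert again.p_adipose == pytest.approx(calibrated_human.p_adipose,
                                                rel=2e-3)


class TestConcordance:
    def test_identical_vectors(self):
        assert concordance([1, 2, 3], [1, 2, 3])[0] == 1.0

    def test_reversed_ranks(self):
        assert concordance([1, 2, 3, 4], [4, 3, 2, 1])[0] == -1.0

    def test_against_brute_force_rank_formula(self):
        obs, sim = [1, 2, 3, 4], [1, 3, 2, 4]
        rho, _ = concordance(obs, sim)
        # independent oracle: 1 - 6 sum(d^2) / (n (n^2 - 1)) without ties
        ranks_o = np.argsort(np.argsort(obs))
        ranks_s = np.argsort(np.argsort(sim))
        d2 = np.sum((ranks_o - ranks_s) ** 2)
        expected = 1.0 - 6.0 * d2 / (4 * (16 - 1))
        assert rho == pytest.approx(expected) == pytest.approx(0.8)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            concordance([1, 2, 3], [1, 2])
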