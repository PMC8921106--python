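import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cdpbpk.core import (MassBalanceError, StateError, StateIndex, derivatives,
                         simulate, steady_state_concentrations)
from cdpbpk.dosimetry import terminal_half_life
from cdpbpk.exposure import (iv_bolus, repeated_daily_oral, single_oral,
                             zero_dose, HOURS_PER_DAY)


class TestDerivatives:
    def test_zero_state_zero_dosing_gives_zero_derivative(self, rat_params, rat_phys):
        dy = derivatives(np.zeros(StateIndex.N), 0.0, rat_params, rat_phys,
                         zero_dose("rat"))
        assert np.all(dy == 0.0)

    def test_negative_state_rejected(self, rat_params, rat_phys):
        state = np.zeros(StateIndex.N)
        state[StateIndex.BLOOD] = -1.0
        with pytest.raises(StateError, match="negative"):
            derivatives(state, 0.0, rat_params, rat_phys, zero_dose("rat"))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1e5), min_size=14, max_size=14))
    def test_conservation_with_all_clearances_off(self, rat_phys, amounts):
        """Without excretion pathways the total body amount is conserved."""
        from cdpbpk.parameters import rat_default
        params = rat_default().with_(k_urine=0.0, kst=0.0)
        state = np.zeros(StateIndex.N)
        state[list(StateIndex.BODY)] = amounts
        dy = derivatives(state, 0.0, params, rat_phys, zero_dose("rat"))
        d_body = dy[list(StateIndex.BODY)].sum()
        scale = max(np.abs(dy).max(), 1.0)
        assert abs(d_body) <= 1e-9 * scale

    def test_derivative_conserves_administered_mass(self, rat_params, rat_phys):
        """d(body + excreta)/dt equals the dietary administration rate."""
        scn = repeated_daily_oral(100.0, 0.0, 1e6, species="rat")
        state = np.full(StateIndex.N, 10.0)
        dy = derivatives(state, 1.0, rat_params, rat_phys, scn)
        outflow = (dy[list(StateIndex.BODY)].sum() + dy[StateIndex.FAECES]
                   + dy[StateIndex.URINE])
        assert outflow == pytest.approx(dy[StateIndex.ADMIN_CUM], rel=1e-9)


class TestSimulate:
    def test_zero_dose_stays_zero(self, rat_params, rat_phys):
        res = simulate(zero_dose("rat"), rat_params, rat_phys, 100.0)
        assert np.all(res.states == 0.0)

    def test_iv_bolus_mass_balance(self, rat_params, rat_phys):
        res = simulate(iv_bolus(1000.0, species="rat"), rat_params, rat_phys,
                       56 * 24.0)
        assert res.mass_balance_residual().max() <= 1e-6
        assert res.administered()[-1] == pytest.approx(1000.0 * 0.25)

    def test_oral_mass_balance_and_nonnegativity(self, rat_oral_40mgkg):
        res = rat_oral_40mgkg
        assert res.mass_balance_residual().max() <= 1e-6
        assert np.all(res.states >= 0.0)
        # cumulative quantities never decrease
        for idx in (StateIndex.FAECES, StateIndex.URINE,
                    StateIndex.ABSORBED_CUM, StateIndex.ADMIN_CUM):
            assert np.all(np.diff(res.states[:, idx]) >= -1e-9)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.floats(10.0, 1e5), st.floats(0.0, 47.0))
    def test_mass_balance_under_random_boluses(self, rat_params, rat_phys,
                                               dose, t0):
        res = simulate(single_oral(dose, t0, species="rat"), rat_params,
                       rat_phys, 96.0, np.linspace(0.0, 96.0, 30))
        assert res.mass_balance_residual().max() <= 1e-6

    def test_one_compartment_oracle(self, rat_phys, one_compartment_setup):
        """Degenerate parameterization matches the analytic mono-exponential."""
        params, v_total = one_compartment_setup
        res = simulate(iv_bolus(1000.0, species="rat"), params, rat_phys,
                       700.0, np.linspace(0.0, 700.0, 120))
        k = params.k_urine / v_total
        analytic = 1000.0 * 0.25 * np.exp(-k * res.time_h)
        assert np.abs(res.in_body() / analytic - 1.0).max() <= 1e-3
        mixed = res.time_h >= 20.0  # after distributional equilibration
        blood = res.blood_concentration()[mixed]
        assert np.abs(blood / (analytic[mixed] / v_total) - 1.0).max() <= 1e-3

    def test_free_fraction_rule(self, rat_phys):
        """Near-complete blood binding shuts off tissue uptake and elimination."""
        from cdpbpk.parameters import rat_default
        params = rat_default().with_(bind=1.0 - 1e-12)
        res = simulate(iv_bolus(1000.0, species="rat"), params, rat_phys,
                       30 * 24.0)
        dose = 1000.0 * 0.25
        tissue_idx = [StateIndex.BRAIN_B, StateIndex.BRAIN_T, StateIndex.SKIN_B,
                      StateIndex.SKIN_T, StateIndex.ADIPOSE_B,
                      StateIndex.ADIPOSE_T, StateIndex.LIVER_B,
                      StateIndex.LIVER_T, StateIndex.REST]
        assert res.states[-1, tissue_idx].sum() <= 1e-6 * dose
        assert res.excreted_urinary()[-1] + res.excreted_faecal()[-1] <= 1e-6 * dose
        assert res.states[-1, StateIndex.BLOOD] == pytest.approx(dose, rel=1e-6)

    def test_enterohepatic_loop_prolongs_half_life(self, rat_params, rat_phys):
        scn = single_oral(40_000.0, species="rat")
        grid = np.linspace(0.0, 84 * 24.0, 600)
        halves = {}
        for f_reab in (0.0, 0.95):
            res = simulate(scn, rat_params.with_(f_reab=f_reab), rat_phys,
                           84 * 24.0, grid)
            halves[f_reab] = terminal_half_life(res, (14.0, 56.0))
        assert halves[0.0] < halves[0.95]

    def test_metabolite_pathway_off_in_rat_configuration(self, rat_oral_40mgkg,
                                                         rat_params, rat_phys):
        """With kbile = 0 no metabolite forms and the reconversion efficiency
        is irrelevant: the species difference reduces to parameters."""
        assert np.all(rat_oral_40mgkg.states[:, StateIndex.LIVER_MET_CUM] == 0.0)
        scn = single_oral(1000.0, species="rat")
        grid = np.linspace(0.0, 14 * 24.0, 100)
        a = simulate(scn, rat_params, rat_phys, 14 * 24.0, grid)
        b = simulate(scn, rat_params.with_(f_reconv=0.95), rat_phys,
                     14 * 24.0, grid)
        np.testing.assert_allclose(a.states, b.states, rtol=1e-9, atol=1e-12)

    def test_human_forms_biliary_metabolite(self, calibrated_human, human_phys):
        res = simulate(single_oral(100.0, species="human"), calibrated_human,
                       human_phys, 30 * 24.0)
        assert res.states[-1, StateIndex.LIVER_MET_CUM] > 0.0

    def test_approach_to_plateau_at_five_half_lives(self, calibrated_human,
                                                    human_phys):
        """Blood at 5 terminal half-lives sits in [93%, 100%] of the plateau."""
        dose = 0.007
        c5 = steady_state_concentrations(dose, calibrated_human, human_phys,
                                         exposure_days=655.0)
        c20 = steady_state_concentrations(dose, calibrated_human, human_phys,
                                          exposure_days=2620.0)
        frac = c5.concentrations["blood_total"] / c20.concentrations["blood_total"]
        assert 0.93 <= frac <= 1.0

    def test_discrete_daily_boluses_match_continuous_rate(self, rat_phys,
                                                          one_compartment_setup):
        params, _ = one_compartment_setup
        params = params.with_(k_urine=0.0033)  # ~2-day half-life, fast to SS
        means = {}
        for discrete in (False, True):
            scn = repeated_daily_oral(100.0, 0.0, 30 * HOURS_PER_DAY,
                                      species="rat",
                                      discrete_daily_boluses=discrete)
            res = simulate(scn, params, rat_phys, 30 * HOURS_PER_DAY,
                           np.linspace(0.0, 30 * 24.0, 30 * 48))
            last_day = res.time_h >= 29 * 24.0
            means[discrete] = np.trapezoid(res.blood_concentration()[last_day],
                                           res.time_h[last_day]) / 24.0
        assert means[True] == pytest.approx(means[False], rel=0.02)


class TestSteadyState:
    def test_zero_dose_gives_zeros(self, human_params, human_phys):
        ss = steady_state_concentrations(0.0, human_params, human_phys,
                                         exposure_days=10.0)
        assert all(v == 0.0 for v in ss.concentrations.values())
        assert ss.converged

    def test_liver_to_adipose_sequestration_ratio(self, calibrated_human,
                                                  human_phys):
        """Hepatic CDBP sequestration yields the unusual liver/fat ratio."""
        ss = steady_state_concentrations(0.007, calibrated_human, human_phys)
        ratio = ss.concentrations["liver"] / ss.concentrations["adipose"]
        assert ratio >= 5.0
        assert ratio <= 10.0
        assert ss.converged

    def test_low_dose_linearity(self, calibrated_human, human_phys):
        d = 0.05
        c1 = steady_state_concentrations(d, calibrated_human, human_phys)
        c2 = steady_state_concentrations(2 * d, calibrated_human, human_phys)
        assert (c2.concentrations["blood_total"]
                == pytest.approx(2 * c1.concentrations["blood_total"], rel=0.01))


def test_tidy_output_schema(rat_oral_40mgkg):
    df = rat_oral_40mgkg.to_dataframe()
    assert set(df.columns) == {"time_days", "compartment", "quantity", "value"}
    assert "conc_ug_per_L" in set(df["quantity"])
    ledger = df[df["quantity"] == "mass_balance_rel_error"]
    assert (ledger["value"] <= 1e-6).all()
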