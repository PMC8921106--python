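import numpy as np
import pytest

from cdpbpk import (physiology_at_age, rat_default, human_default,
                    calibrate_human_scale, simulate, single_oral)


@pytest.fixture(scope="session")
def rat_phys():
    return physiology_at_age("rat")


@pytest.fixture(scope="session")
def human_phys():
    return physiology_at_age("human")


@pytest.fixture(scope="session")
def rat_params():
    return rat_default()


@pytest.fixture(scope="session")
def human_params():
    return human_default()


@pytest.fixture(scope="session")
def calibrated_human(human_params, human_phys):
    """Human parameters pinned to the two-anchor scale calibration."""
    return calibrate_human_scale(human_params, human_phys)


@pytest.fixture(scope="session")
def rat_oral_40mgkg(rat_params, rat_phys):
    """Single 40 mg/kg bw oral gavage in the rat, followed for 182 days."""
    scenario = single_oral(40_000.0, species="rat")
    grid = np.linspace(0.0, 182 * 24.0, 1200)
    return simulate(scenario, rat_params, rat_phys, 182 * 24.0, grid)


@pytest.fixture(scope="session")
def recovery_fit(rat_params, rat_phys):
    """Parameter-recovery fit on a seeded synthetic dataset.

    Generates pseudo-observations from known parameters (10% relative
    noise), then re-estimates biliary clearance and the adipose partition
    coefficient starting from deliberately wrong values.
    """
    from cdpbpk import fit
    from cdpbpk.fixtures import generate_timecourse_fixture

    truth = rat_params
    obs = generate_timecourse_fixture("oral_40mgkg_182d", truth,
                                      sigma_rel=0.10, seed=3)
    scenario = single_oral(40_000.0, species="rat")
    start = truth.with_(cl_bile=truth.cl_bile * 1.4,
                        p_adipose=truth.p_adipose * 0.7)
    fitted, report = fit({"cl_bile": (1e-4, 0.05), "p_adipose": (50.0, 2000.0)},
                         [(obs, scenario)], start, rat_phys, maxiter=80)
    return truth, fitted, report


@pytest.fixture(scope="session")
def one_compartment_setup(rat_phys):
    """Degenerate parameterization collapsing the model to one compartment.

    All partitions 1, permeabilities fast, no binding, urinary clearance the
    only elimination: blood kinetics must follow a mono-exponential with
    rate k_urine / V_total.
    """
    params = rat_default().with_(
        bind=0.0, p_brain=1.0, p_skin=1.0, p_adipose=1.0, p_liver=1.0,
        p_rest=1.0, pa_brain=20.0, pa_skin=20.0, pa_adipose=20.0,
        pa_liver=20.0, cl_bile=0.0, k_ent=0.0, libmaxcd1=0.0, k_urine=0.001)
    v_total = sum(rat_phys.volume_fractions.values()) * rat_phys.body_weight_kg
    return params, v_total
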