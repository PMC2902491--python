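"""Shared fixtures.

The replicated-study fixtures (parameter recovery, robustness scenarios)
are session-scoped because they are the expensive part of the suite; all
sizes and seeds are fixed here so every test sees the same runs.
"""

import numpy as np
import pytest

import snhurdle as sh
from snhurdle.quadrature import QuadratureRule
from snhurdle.simulation import SimulationScenario, run_scenario

# truth used for parameter-recovery checks: the generating design matches the
# study layout (rare binary covariate, intercept+slope in both parts)
RECOVERY_TRUTH = sh.ParameterSet(
    beta1=[-1.0, 2.5],
    beta2=[0.3, 0.75],
    sigma=0.6,
    delta=-0.8,
    s11=1.0,
    s22=0.2,
    s12=0.2,
)


@pytest.fixture(scope="session")
def small_data():
    """Small probit/log-SN dataset (40 subjects x 8 occasions)."""
    return sh.simulate_probit_logsn(RECOVERY_TRUTH, 40, 8, p_x=0.2, seed=11)


@pytest.fixture(scope="session")
def small_fit_pair(small_data):
    """Skew-normal fit and nested delta=0 fit on the same small dataset."""
    rule = QuadratureRule(n_points=7, adaptive=True)
    fit_sn = sh.fit_mle(small_data, rule=rule)
    fit_ln = sh.fit_mle(small_data, rule=rule, fix_delta=0.0)
    return fit_sn, fit_ln


@pytest.fixture(scope="session")
def recovery_archive():
    """50 replicates of the probit/log-SN model at the study design size."""
    ests = []
    for r in range(50):
        data = sh.simulate_probit_logsn(RECOVERY_TRUTH, 200, 50, p_x=0.03, seed=1000 + r)
        fit = sh.fit_mle(data, compute_se=False)
        if fit.converged:
            ests.append(dict(zip(fit.param_names, fit.estimates)))
    return ests


@pytest.fixture(scope="session")
def scenario_i_study():
    """Negatively skewed log-beta scenario, 50 replicates."""
    return run_scenario(SimulationScenario(n_reps=50, seed=1))


@pytest.fixture(scope="session")
def scenario_ii_study():
    """Symmetric log-beta scenario, 25 replicates."""
    return run_scenario(SimulationScenario(a=100.0, b=100.0, n_reps=25, seed=1))
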