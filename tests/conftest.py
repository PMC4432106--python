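"""Shared fixtures.

The replicate study of the three-month one-compartment scenario is
expensive (50 FOCE-I fits), so it is computed once per session and
shared between the acceptance tests and the statistical property
tests.
"""

from __future__ import annotations

import pytest

import toxkinsim as tk


@pytest.fixture(scope="session")
def model_a_spec():
    return tk.ModelSpec(tk.ModelId.ONE_CMT)


@pytest.fixture(scope="session")
def model_a_pop():
    return tk.model_a_population()


@pytest.fixture(scope="session")
def three_month_design():
    return tk.build_cohort_design("3_MONTHS")


@pytest.fixture(scope="session")
def week_dataset(model_a_spec, model_a_pop):
    """One simulated 1-week replicate (model A), reused across tests."""
    design = tk.build_cohort_design("1_WEEK")
    return tk.simulate_trial(design, model_a_spec, model_a_pop, 20150414)


# ---------------------------------------------------------------------------
# The shared scaled replicate study: 3-month cohort, model A, 30 mg/kg,
# 50 replicates.  Used by the acceptance tests (bias/precision bounds,
# convergence bookkeeping) and by parameter-recovery and method-ranking
# property tests.
# ---------------------------------------------------------------------------

N_REPLICATES = 50
STUDY_SEED = 20150414


@pytest.fixture(scope="session")
def three_month_study():
    cfg = tk.ScenarioConfig(
        model_id=tk.ModelId.ONE_CMT,
        duration=tk.Duration.THREE_MONTHS,
        dose_group=30.0,
        n_replicates=N_REPLICATES,
        master_seed=STUDY_SEED,
    )
    return tk.run_study(cfg)


@pytest.fixture(scope="session")
def model_family_studies():
    """Small 1-week model-based studies for the three disposition
    families, used for the nonlinearity-increases-bias rank check.
    The Michaelis–Menten fits carry an ODE solve inside the
    likelihood, so this scenario is scaled down (3+3 animals per dose
    group, 5 replicates, reduced outer iteration budget)."""
    out = {}
    for model_id in (tk.ModelId.ONE_CMT, tk.ModelId.ONE_CMT_MM,
                     tk.ModelId.TWO_CMT):
        cfg = tk.ScenarioConfig(
            model_id=model_id,
            duration=tk.Duration.ONE_WEEK,
            dose_group=30.0,
            n_replicates=5,
            master_seed=STUDY_SEED,
            methods=("MODEL",),
            measures=("auc24", "cmax24"),
            do_covariance=False,
            design_overrides={"toxicity_n": 3},
            fit_options={"outer_maxiter": 40, "max_restarts": 1},
        )
        out[model_id] = tk.run_study(cfg)
    return out
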