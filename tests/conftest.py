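import pytest

import aircausal as ac
from aircausal.simulate import implied_moments, learning_nodes


@pytest.fixture(scope="session")
def default_cfg():
    return ac.default_config()


@pytest.fixture(scope="session")
def small_cohort():
    """Modest synthetic cohort for cheap structural tests."""
    return ac.apply_log_transforms(ac.generate_cohort(ac.default_config(n=2000, seed=7)))


@pytest.fixture(scope="session")
def big_cohort():
    """Large synthetic cohort for marginal/calibration checks."""
    return ac.apply_log_transforms(ac.generate_cohort(ac.default_config(n=50_000, seed=2024)))


@pytest.fixture(scope="session")
def implied(default_cfg):
    """Exact population moments of the default generator."""
    return implied_moments(default_cfg)


@pytest.fixture(scope="session")
def recovery_runs():
    """The recovery protocol: 10 synthetic cohorts (n=20,000, seeds 1-10),
    constrained structure learning and effect decomposition per outcome."""
    runs = {"log_tac": [], "log_tac_p": []}
    for seed in range(1, 11):
        cohort = ac.apply_log_transforms(ac.generate_cohort(ac.default_config(n=20_000, seed=seed)))
        for outcome in runs:
            pdag = ac.learn_pdag(
                cohort.data,
                alpha=0.05,
                constraints=ac.default_constraints(outcome),
                nodes=learning_nodes(outcome),
            )
            runs[outcome].append((pdag, ac.decompose(pdag, cohort, outcome=outcome)))
    return runs
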