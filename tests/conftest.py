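import numpy as np
import pytest

import resistpkpd as rp
from resistpkpd.synthetic import canonical_population, default_design, generate_study
from resistpkpd.synthetic import true_pk_parameters


@pytest.fixture(scope="session")
def erl_pk():
    return rp.params.ERLOTINIB_PK


@pytest.fixture(scope="session")
def gef_pk():
    return rp.params.GEFITINIB_PK


@pytest.fixture(scope="session")
def res_params():
    """Canonical resistance parameters, high-dose erlotinib configuration."""
    return rp.params.resistance_parameters()


@pytest.fixture(scope="session")
def high_dose_regimen():
    """14 daily 100 mg/kg erlotinib doses from day 3 (the study schedule)."""
    return rp.daily_regimen(3.0, 14, 100.0, compound="erlotinib")


@pytest.fixture(scope="session")
def grid30():
    return np.linspace(0.0, 30.0, 601)


@pytest.fixture(scope="session")
def small_study():
    """Small deterministic-population study with residual noise (seeded)."""
    pop = canonical_population(omega_scale=0.0).scaled(k2_high=None,
                                                       ksr_high=None)
    design = default_design(2)
    table, bundle = generate_study(design, pop, model="base", seed=11)
    return design, pop, table, bundle


@pytest.fixture(scope="session")
def small_study_pk(small_study):
    _, _, _, bundle = small_study
    return true_pk_parameters(bundle)
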