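import pytest

import clozapk as cz


@pytest.fixture(scope="session")
def final_pop() -> cz.PopulationParameters:
    """Published final population model (reference 70 kg adult)."""
    return cz.PopulationParameters()


@pytest.fixture(scope="session")
def typical_ind(final_pop) -> cz.IndividualParams:
    """Typical 70 kg subject without zopiclone, no random effect."""
    tv = cz.typical_params(final_pop, cz.CovariateVector(weight=70.0, zop=0))
    return cz.individual_params(tv, 0.0)


@pytest.fixture(scope="session")
def small_dataset(final_pop) -> cz.Dataset:
    """Five-subject enriched-design cohort simulated from the final model."""
    return cz.simulate_dataset(
        final_pop, cz.enriched_design(n_subjects=5, p_zop=0.4, seed=101)
    )


@pytest.fixture(scope="session")
def recovery_fit(final_pop):
    """One medium parameter-recovery experiment shared across tests:
    n=80 enriched-design subjects simulated from the final model, refit
    from neutral initial values."""
    ds = cz.simulate_dataset(
        final_pop, cz.enriched_design(n_subjects=80, p_zop=0.25, seed=42)
    )
    init = cz.PopulationParameters(
        cl_std=20.0, v_std=200.0, theta_zop=0.0, omega_cl=0.3, sigma_prop=0.2
    )
    res = cz.fit(ds, init=init)
    return ds, res
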