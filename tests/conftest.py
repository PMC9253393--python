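import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True)
settings.load_profile("reproducible")

from radlymph import attribution as attr
from radlymph import modeling, synthetic
from radlymph.preprocess import encode


@pytest.fixture(scope="session")
def small_cohort():
    """A 250-patient synthetic cohort with the default planted effects."""
    cfg = synthetic.default_config(n_patients=250, seed=7, missingness_rate=0.02)
    return synthetic.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    cohort, _, _ = small_cohort
    return encode(cohort, synthetic.default_schema())


@pytest.fixture(scope="session")
def fitted_iterations(small_matrix):
    """Three fast-path bootstrap iterations on the small cohort."""
    return modeling.run_bootstrap(small_matrix, B=3, seed=11, mode="fast")


@pytest.fixture(scope="session")
def attribution_bundle(small_matrix, fitted_iterations):
    mats, outcomes, feats = [], [], []
    for it in fitted_iterations:
        Xte = small_matrix.X.iloc[it.plan.test]
        mats.append(attr.per_instance_attributions(it.model, Xte))
        outcomes.append(small_matrix.y.to_numpy()[it.plan.test])
        feats.append(Xte)
    return mats, outcomes, feats
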