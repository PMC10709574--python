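import warnings

import pytest

from leukotype import classifier, preprocessing, simulate


@pytest.fixture(scope="session")
def default_cohort():
    """One default-scale synthetic cohort, shared across the session."""
    return simulate.simulate_cohort(simulate.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def dnam_split(default_cohort):
    """Variance-filtered methylation matrix plus design/hold-out split."""
    dnam = preprocessing.filter_cpgs(default_cohort.dnam, 0.01)
    design, holdout = preprocessing.stratified_split(
        default_cohort.labels, 0.33, seed=1
    )
    return dnam, design, holdout


@pytest.fixture(scope="session")
def dnam_model(dnam_split):
    """Two-step DNAm model trained on the design set of the shared cohort."""
    dnam, design, _ = dnam_split
    ids = [s for s in dnam.sample_ids if s in design.labels]
    X = dnam.subset_samples(ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return classifier.train_subtype_model(
            X.values, dnam.feature_ids, design.subset(ids), modality="dnam", seed=1
        )


@pytest.fixture(scope="session")
def dnam_holdout_calls(dnam_model, dnam_split):
    dnam, _, holdout = dnam_split
    ids = [s for s in dnam.sample_ids if s in holdout.labels]
    X = dnam.subset_samples(ids)
    return classifier.predict_subtype(dnam_model, X.values, dnam.feature_ids, ids)
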