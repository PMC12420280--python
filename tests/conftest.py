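import pytest

from deepcatcr import (CDR3Encoder, DeepCaTCRClassifier, FixtureSpec,
                       default_projection, fixture_projection,
                       generate_labeled_dataset)


@pytest.fixture(scope="session")
def fixture_proj():
    return fixture_projection()


@pytest.fixture(scope="session")
def default_proj():
    return default_projection()


@pytest.fixture(scope="session")
def planted_spec():
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def small_dataset(planted_spec, default_proj):
    """400+400 planted-motif sequences plus their encodings."""
    seqs, y = generate_labeled_dataset(400, 400, planted_spec, seed=7)
    X = CDR3Encoder(default_proj).fit_transform(seqs)
    return seqs, X, y


@pytest.fixture(scope="session")
def trained_model(planted_spec, default_proj):
    """One fitted classifier shared across scoring / motif tests.

    Trained on the planted-motif task with an extra ambiguous-motif class
    labelled 50/50, so its scores support both the planted-fraction and the
    matched-mean cohort experiments.
    """
    seqs, y = generate_labeled_dataset(1200, 1200, planted_spec, seed=7,
                                       n_ambiguous=600)
    X = CDR3Encoder(default_proj).fit_transform(seqs)
    clf = DeepCaTCRClassifier(random_state=0, max_epochs=400, patience=20,
                              projection=default_proj)
    clf.fit(X, y)
    return clf
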