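import pytest

from stillkit.synthetic_cohort import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic study shared by read-only tests."""
    return simulate_cohort(SimConfig(rng_seed=1))


@pytest.fixture(scope="session")
def cohort_dir(cohort, tmp_path_factory):
    """The same study written out in every on-disk format."""
    d = tmp_path_factory.mktemp("cohort")
    cohort.write(d)
    return d


@pytest.fixture(scope="session")
def panel_genes(cohort):
    return set().union(
        *(cohort.panels[p] for p in ("chip", "autoinflammation", "interferonopathy"))
    )
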