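import pytest

from pbcnet.synthetic import SyntheticConfig, generate_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """One default-configuration synthetic universe shared across tests."""
    return generate_bundle(SyntheticConfig(rng_seed=11))


@pytest.fixture(scope="session")
def small_bundle():
    """A small, fast universe for structural checks."""
    cfg = SyntheticConfig(
        n_genes=200, attachment_m=2, module_size=25,
        n_seeds_early=4, n_seeds_late=4, n_seeds_us=8,
        n_annotation_sets=20, n_planted_sets=3,
        set_size_range=(5, 20), rng_seed=5,
    )
    return generate_bundle(cfg)


@pytest.fixture()
def fixture_dir(tmp_path, small_bundle):
    """Small bundle written to disk in the pipeline's file dialects."""
    from pbcnet.synthetic import write_fixture_bundle

    write_fixture_bundle(tmp_path / "fix", small_bundle)
    return tmp_path / "fix"
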