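import pytest

from decimine.synthetic_data import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def noiseless_scenario(tmp_path_factory):
    """Fixture scenario with zero decoy and ambiguity rates: mining
    recovery against the manifest must be exact."""
    config = ScenarioConfig(seed=1, decoy_synonym_rate=0.0, ambiguous_article_rate=0.0)
    outdir = tmp_path_factory.mktemp("scenario_noiseless")
    paths, truth = generate_scenario(config, outdir)
    return config, paths, truth


@pytest.fixture(scope="session")
def hub_scenario(tmp_path_factory):
    """60-gene scenario with a planted hub (degree 15, publication
    multiplier 10) over a sparse random interaction background."""
    config = ScenarioConfig(
        seed=2,
        n_articles=(100, 100),
        n_genes=(30, 30),
        n_shared_genes=0,
        decoy_synonym_rate=0.0,
        ambiguous_article_rate=0.0,
    )
    outdir = tmp_path_factory.mktemp("scenario_hub")
    paths, truth = generate_scenario(config, outdir)
    return config, paths, truth
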