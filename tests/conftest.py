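import pytest

from regvar import pipeline, synthetic

# fixed study-conditions fixture: 1 Mb genome, 3 TFs x 10 planted sites,
# 50 disrupting + 150 benign (75 in-peak / 75 outside) SNPs
FIXTURE_SEED = 20240917


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("fixture")
    synthetic.generate_fixture(d, seed=FIXTURE_SEED)
    return d


@pytest.fixture(scope="session")
def fixture_truth(fixture_dir):
    return synthetic.SyntheticTruth.from_json(fixture_dir / "truth.json")


@pytest.fixture(scope="session")
def fixture_run(fixture_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    config = pipeline.fixture_config(fixture_dir, seed=FIXTURE_SEED)
    config.n_sims_eqtl = 2000
    return pipeline.run_all(config, out)
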