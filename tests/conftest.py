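import pytest

from pipetarget.pipeline import RunConfig, run_all
from pipetarget.synthetic_fixtures import FixtureConfig, generate


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic input bundle with planted targets (seed 1)."""
    out = tmp_path_factory.mktemp("bundle")
    return generate(FixtureConfig(seed=1), out)


@pytest.fixture(scope="session")
def pipeline_run(bundle, tmp_path_factory):
    """One full pipeline run over the default bundle, shared across tests."""
    run_dir = tmp_path_factory.mktemp("run")
    cfg = RunConfig.from_manifest(bundle, seed=1, n_perm_lpa=2000,
                                  n_perm_crosstalk=300)
    results = run_all(cfg, run_dir)
    return {"manifest": bundle, "results": results, "run_dir": run_dir,
            "config": cfg}
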