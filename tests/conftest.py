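import pytest


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full demo (fixture generation + pipeline) shared by the tests."""
    from saltnet.pipeline import run_demo

    outdir = tmp_path_factory.mktemp("demo")
    manifest = run_demo(str(outdir), seed=42)
    return outdir, manifest


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A compact synthetic fixture bundle with ground truth."""
    from saltnet.synthio import SyntheticScenario, build_fixture

    outdir = tmp_path_factory.mktemp("fixture")
    scenario = SyntheticScenario(seed=7)
    bundle = build_fixture(scenario, str(outdir))
    return outdir, scenario, bundle
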