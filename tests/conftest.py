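import pytest

from orpscan.pipeline import run_screen
from orpscan.synth import SynthConfig, generate_bundle, proteomes_by_genome


@pytest.fixture(scope="session")
def default_cfg() -> SynthConfig:
    """The default desk-scale study condition (25 opsins, 10 decoys,
    10 genomes, background rate 0.05, seed 7)."""
    return SynthConfig()


@pytest.fixture(scope="session")
def bundle(default_cfg):
    return generate_bundle(default_cfg)


@pytest.fixture(scope="session")
def screen_result(bundle):
    """Full pipeline run over the default bundle (shared: the screen is the
    expensive step)."""
    prots = proteomes_by_genome(bundle["records"], bundle["proteome_truth"])
    return run_screen(prots, bundle["features"])
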