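import numpy as np
import pytest

from indelmark.config import PipelineConfig
from indelmark.pipeline import run_pipeline
from indelmark.simgen import MutationModel, PanelConfig, make_species_panel


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


@pytest.fixture(scope="session")
def mini_panel_config() -> PanelConfig:
    """Desk-scale panel: one 400-kb chromosome, 2 cultivars + 3 wild
    species x 2 accessions."""
    return PanelConfig(n_chromosomes=1, chrom_length=400_000,
                       n_wild_species=3, accessions_per_species=2,
                       repeat_array_len=20_000)


@pytest.fixture(scope="session")
def mini_config() -> PipelineConfig:
    return PipelineConfig(bait_interval_bp=100_000)


@pytest.fixture(scope="session")
def mini_panel(mini_panel_config):
    return make_species_panel(mini_panel_config, seed=11)


@pytest.fixture(scope="session")
def mini_result(mini_panel, mini_config):
    return run_pipeline(mini_config, mini_panel.reference,
                        mini_panel.others)


@pytest.fixture(scope="session")
def default_panel_run():
    """One full-scale run of the default study panel (shared by the
    heavier acceptance checks)."""
    panel = make_species_panel(PanelConfig(), seed=0)
    result = run_pipeline(PipelineConfig(), panel.reference, panel.others)
    return panel, result
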