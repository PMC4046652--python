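import numpy as np
import pytest

from allosnp import SimulationConfig


@pytest.fixture(scope="session")
def tiny_config():
    """A desk-scale study: one homoeologous pair, six inbred accessions."""
    return SimulationConfig(
        seed=11,
        n_accessions=6,
        chrom_plan=[("A", 25_000), ("C", 25_000)],
        repeat_families=[(150, 6)],
        snp_rate=5e-4,
        n_genes=6,
        per_accession_depth=[10.0] * 6,
        minor_count_spectrum=[0.4, 0.3, 0.3],
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_config):
    """Reference, truth, gene models, panel and reads for the tiny study."""
    from allosnp.pipeline import simulate_inputs

    reference, truth, models, go_map, panel, readsets = simulate_inputs(tiny_config)
    return {
        "config": tiny_config,
        "reference": reference,
        "truth": truth,
        "models": models,
        "go_map": go_map,
        "panel": panel,
        "readsets": readsets,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
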