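import dataclasses

import pytest

import synplot as sp

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def rice_truth(tmp_path_factory):
    """Desk-scale two-genome fixture (os x sb), written to disk once."""
    out = tmp_path_factory.mktemp("fixture")
    return sp.rice_sorghum_like(seed=FIXTURE_SEED, out_dir=out)


@pytest.fixture(scope="session")
def rice_dataset(rice_truth):
    genes = sp.parse_gene_positions(rice_truth.annotation_path)
    genomes = sp.build_genome_models(genes)
    blocks = sp.parse_collinearity(rice_truth.collinearity_path)
    return sp.join_and_validate(genomes, blocks, "strict")


@pytest.fixture
def config():
    return sp.PlotConfig()


def config_for(plot_type: str, **kw) -> sp.PlotConfig:
    return dataclasses.replace(sp.PlotConfig(plot_type=plot_type), **kw)
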