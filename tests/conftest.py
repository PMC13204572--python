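import pytest
from hypothesis import settings

from breedvar import synthdata

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def panel():
    """The packaged 46-SNP validation panel table."""
    return synthdata.validation_panel_fixture()


@pytest.fixture(scope="session")
def sim_config():
    return synthdata.SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def variant_tables(sim_config):
    models = synthdata.gen_gene_models(sim_config)
    tables, truth = synthdata.gen_variant_tables(sim_config, models)
    return models, tables, truth


@pytest.fixture()
def minimal_vcf(tmp_path):
    """Tiny hand-written VCF: one biallelic site, one multi-allelic site."""
    path = tmp_path / "mini.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "1\t100\trs1\tA\tG\t.\t.\tDP=10;MQ=40\n"
        "1\t200\t.\tC\tG,T\t.\t.\tDP=8;MQ=35\n"
    )
    return path
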