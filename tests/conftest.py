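import pytest

from mitopirna import pipeline, simdata

#: compact cohort for fast tests: shallow libraries, 20 kb nuclear contigs,
#: thinner background pools; the mitochondrial genome stays full size
SMALL = dict(
    reads_per_sample=4000,
    nuclear_contigs=(("chr1", 20000), ("chr2", 20000)),
    n_mito_bg_loci=120,
    n_nuclear_bg_loci=250,
    n_noise=50,
    n_nu_pirnas=20,
    n_nu_mirnas=8,
    decoy_db_entries=20,
)


@pytest.fixture(scope="session")
def small_cfg() -> simdata.SimConfig:
    return simdata.SimConfig(seed=11, **SMALL)


@pytest.fixture(scope="session")
def small_run(small_cfg, tmp_path_factory) -> pipeline.PipelineResult:
    return pipeline.run_all(small_cfg, tmp_path_factory.mktemp("small_run"))


@pytest.fixture(scope="session")
def cohort_run(tmp_path_factory) -> pipeline.PipelineResult:
    """Study-design-sized cohort: 12 samples x 100k reads, zero NUMT divergence."""
    cfg = simdata.SimConfig(seed=42, reads_per_sample=100000)
    return pipeline.run_all(cfg, tmp_path_factory.mktemp("cohort"))
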