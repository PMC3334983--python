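import pytest
from hypothesis import HealthCheck, settings

from exoscreen.pipeline import PipelineConfig, run_pipeline
from exoscreen.simulate import CohortConfig, simulate_cohort

settings.register_profile(
    "suite", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")

# a fast, fully featured cohort used by the simulator unit tests
SMALL_COHORT = dict(
    n_genes=12, codons_min=120, codons_max=200, sites_per_sample=150,
    known_pool_size=300, novel_pool_size=120, control_only_pool_size=150,
    offtarget_per_sample=8, indels_per_sample=5, indel_pool_size=60,
    planted_positions_per_gene=12,
)


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """Default-scale synthetic cohort, written to disk once per session."""
    out = tmp_path_factory.mktemp("sim")
    return simulate_cohort(CohortConfig(seed=7), str(out))


@pytest.fixture(scope="session")
def pipeline_config(cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("reports")
    p = cohort.paths
    return PipelineConfig(
        vcf=p["vcf"], targets=p["targets"], models=p["models"],
        reference=p["reference"], dbsnp=p["catalog_DBSNP"],
        catalogs={name: p[f"catalog_{name}"] for name in ("ASW", "YRI", "CEU")},
        out_dir=str(out), groups=cohort.config.groups)


@pytest.fixture(scope="session")
def pipeline_result(pipeline_config):
    """Full pipeline run over the session cohort."""
    return run_pipeline(pipeline_config)
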