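import pytest
from hypothesis import settings

from paneltriage import CohortSpec, PipelineConfig, generate_cohort

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")
from paneltriage.pipeline import run_bundle


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig(seed=1)


@pytest.fixture(scope="session")
def default_bundle(cfg):
    """Full-size synthetic cohort at the default study conditions (seed 1)."""
    return generate_cohort(cfg, seed=1)


@pytest.fixture(scope="session")
def default_result(default_bundle, cfg):
    return run_bundle(default_bundle, cfg)


def small_spec() -> CohortSpec:
    """A fast cohort: same structure, two orders of magnitude smaller."""
    spec = CohortSpec()
    spec.group_sizes = {
        "FCCTX": 12, "unselected": 30, "young_onset": 15,
        "pMMR": 6, "dMMR": 8, "control": 9,
    }
    spec.n_qc_fail = 2
    spec.tier1_spectrum = {
        "nonsense": 4, "frameshift": 5, "splice_site": 2,
        "initiator_codon": 1, "stop_loss": 1,
    }
    spec.n_missense = 40
    spec.n_pathogenic_side = 4
    spec.n_benign_side = 8
    spec.n_freq_benign = 4
    spec.n_vus_damaging = 10
    spec.n_inframe_indel = 3
    spec.n_synonymous = 10
    spec.n_intronic = 10
    spec.n_maf_excluded = 6
    spec.n_low_dp = 3
    spec.n_low_gq = 3
    return spec


@pytest.fixture(scope="session")
def small_bundle(cfg):
    return generate_cohort(cfg, small_spec(), seed=11)


@pytest.fixture(scope="session")
def small_result(small_bundle, cfg):
    return run_bundle(small_bundle, cfg)
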