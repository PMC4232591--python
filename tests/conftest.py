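import pytest

from nemaclock.align import blosum62
from nemaclock.pipeline import (
    PipelineConfig,
    build_domain_profiles,
    build_family_hmms,
)
from nemaclock.synthetic import make_benchmark


@pytest.fixture(scope="session")
def matrix():
    return blosum62()


@pytest.fixture(scope="session")
def small_cfg():
    """A miniature study design for unit tests (fast, same code paths)."""
    return PipelineConfig(
        seed=7,
        n_families=3,
        n_species=4,
        n_decoys=60,
        calib_decoys=250,
        calib_decoy_length=120,
        upstream_len=600,
        bootstrap_n=50,
    )


@pytest.fixture(scope="session")
def small_bench(small_cfg):
    return make_benchmark(
        n_families=small_cfg.n_families,
        n_species=small_cfg.n_species,
        n_decoys=small_cfg.n_decoys,
        seed=small_cfg.seed,
        upstream_len=small_cfg.upstream_len,
    )


@pytest.fixture(scope="session")
def small_models(small_bench, small_cfg):
    hmms, msas = build_family_hmms(small_bench, small_cfg, seed=8)
    domains = build_domain_profiles(small_bench, small_cfg, seed=9)
    return hmms, msas, domains
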