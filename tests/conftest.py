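"""Shared fixtures: one small synthetic genome reused across module tests."""

import pytest

from plantkinome.profiles import default_profile_set
from plantkinome.synthetic import generate_domain_hits, generate_genome


@pytest.fixture(scope="session")
def profile_set():
    return default_profile_set()


@pytest.fixture(scope="session")
def tiny_bundle(tmp_path_factory, profile_set):
    """Small genome: one near tandem array, one 30 kb-gap array, TEs, decoys."""
    out = tmp_path_factory.mktemp("genome")
    return generate_genome(
        n_chromosomes=4,
        n_genes=24,
        tandem_spec=[(3, 5_000, 0.98), (2, 30_000, 0.98)],
        te_density=30.0,
        seed=11,
        out_dir=out,
        profile_set=profile_set,
    )


@pytest.fixture(scope="session")
def tiny_hits(tiny_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("hits") / "hits.domtbl"
    return generate_domain_hits(tiny_bundle, out, noise_spec=0.5, seed=12)
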