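"""Shared fixtures: compact synthetic studies generated once per session."""

import pytest

from enhancerlink import pipeline
from enhancerlink.simulate import SyntheticSpec, generate


def small_spec(seed: int = 7, noise: bool = True) -> SyntheticSpec:
    """A 2 x 1 Mb genome that keeps per-test runtime around a second."""
    return SyntheticSpec(
        seed=seed,
        n_chroms=2,
        chrom_length=1_000_000,
        n_genes=30,
        n_enhancers=45,
        n_silent_sites=40,
        n_domains=6,
        library_size=400_000,
        noise=noise,
    )


@pytest.fixture(scope="session")
def small_truth(tmp_path_factory):
    out = tmp_path_factory.mktemp("synthetic_small")
    return generate(small_spec(), out)


@pytest.fixture(scope="session")
def small_bundle(small_truth, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline_small")
    config = pipeline.config_for_synthetic(small_truth, out)
    return pipeline.run_all(config)


@pytest.fixture(scope="session")
def small_nf(tmp_path_factory):
    """Noise-free variant: counts are exact expectations."""
    out = tmp_path_factory.mktemp("synthetic_small_nf")
    truth = generate(small_spec(seed=13, noise=False), out)
    res = tmp_path_factory.mktemp("pipeline_small_nf")
    bundle = pipeline.run_all(pipeline.config_for_synthetic(truth, res))
    return truth, bundle
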