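import numpy as np
import pytest

from lungsig.simulate import (
    default_ms_profiles,
    default_rs_profiles,
    draw_exposures,
    generate_reference,
    simulate_catalog,
)


@pytest.fixture(scope="session")
def small_reference(tmp_path_factory):
    """A 2-contig random reference (200 kb each) with .fai index."""
    d = tmp_path_factory.mktemp("ref")
    return generate_reference(d / "ref.fa", n_contigs=2, contig_length=200_000, seed=11)


@pytest.fixture(scope="session")
def ms_truth_profiles():
    return default_ms_profiles()


@pytest.fixture(scope="session")
def rs_truth_profiles():
    return default_rs_profiles()


@pytest.fixture(scope="session")
def standard_catalog(ms_truth_profiles):
    """The standard synthetic mutation catalog: 92 samples, ~2000
    mutations each, three well-separated signatures, fixed seed."""
    rng = np.random.default_rng(2024)
    exposures = draw_exposures(rng, 92, 2000)
    catalog = simulate_catalog(ms_truth_profiles, exposures, seed=2025)
    return catalog, exposures
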