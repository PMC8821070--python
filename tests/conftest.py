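import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cpgmeth import MixtureSpec, generate_mixture, oe_profile, shuffle_mononucleotide

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: the standard synthetic study condition: balanced two-class mixture,
#: depleted class at O/E 0.6 vs 1.0, GC 0.42 — the scenario the method
#: is built to detect, with d = 0.4 as ground truth
STANDARD_SPEC = MixtureSpec(
    n_cds=5000, frac_low=0.5, oe_low=0.6, oe_high=1.0, gc_content=0.42, seed=20240917
)


@pytest.fixture(scope="session")
def standard_mixture():
    """Records + labels of the standard bimodal synthetic species."""
    return generate_mixture(STANDARD_SPEC)


@pytest.fixture(scope="session")
def standard_profile(standard_mixture):
    records, _ = standard_mixture
    return oe_profile(records, species="synthetic_bimodal")


@pytest.fixture(scope="session")
def shuffled_profile(standard_mixture):
    """O/E profile of the same records after per-record shuffling."""
    records, _ = standard_mixture
    shuffled = [shuffle_mononucleotide(r, seed=71) for r in records]
    return oe_profile(shuffled, species="synthetic_shuffled")
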