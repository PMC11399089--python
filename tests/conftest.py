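import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ico2():
    from evensurf.mesh import make_icosphere

    return make_icosphere(2)


@pytest.fixture(scope="session")
def small_cohort():
    """Three mildly distorted subjects on an ico-8 sphere (642 vertices)."""
    from evensurf.synthetic import DistortionSpec, make_cohort

    spec = DistortionSpec(ico_order=8, alpha=0.3, smooth_passes=4, jitter=0.1, seed=7)
    return make_cohort(spec, 3)


@pytest.fixture(scope="session")
def tiny_candidates(small_cohort):
    """Candidate set small enough for brute-force loss oracles."""
    from evensurf.sampling import LossConfig, build_candidate_set

    return build_candidate_set(
        small_cohort, template_ico=2, candidate_ico=8, config=LossConfig(d_thr=60.0)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
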