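import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dopaflux.efba import solve_entropic_fba  # noqa: E402
from dopaflux.toy import STUDY_DEMANDS, build_variants  # noqa: E402


@pytest.fixture(scope="session")
def variants():
    return build_variants()


@pytest.fixture(scope="session")
def min_demand_solutions(variants):
    """Entropic solutions of all four variants at the minimum maintenance demand."""
    out = {}
    for key, model in variants.items():
        mm = model.copy()
        mm.reaction(model.atpm_id).lower_bound = STUDY_DEMANDS["minimum"]
        out[key] = (mm, solve_entropic_fba(mm))
    return out
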