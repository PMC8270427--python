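import pytest

from cwddat import scenarios
from cwddat.engine import EngineParameters, GuildParameterSet, GUILD_NAMES


@pytest.fixture(scope="session")
def default_params() -> EngineParameters:
    return scenarios.default_parameters()


@pytest.fixture(scope="session")
def hugo_report():
    """The calibrated 30-year Hugo run (seed 42), shared across test modules."""
    return scenarios.run_hugo(seed=42)


def make_params(**overrides) -> EngineParameters:
    """A small, explicit parameter set for engine unit tests.

    All guilds default to zero rate and no temperature threshold; individual
    guilds are activated via ``overrides`` like ``fungi={'k_base': 0.2}``.
    Scalar engine coefficients may be overridden by name.
    """
    guilds = {}
    for name in GUILD_NAMES:
        kw = dict(
            name=name, k_base=0.0, T_opt_C=20.0, T_sigma_C=10.0,
            T_threshold_C=None, substrate_multiplier={1: 1.0, 2: 1.0},
            colonization_lag_d=0.0, resource_decline=0.0, fragmentation_share=0.0,
        )
        kw.update(overrides.pop(name, {}))
        guilds[name] = GuildParameterSet(**kw)
    scalars = dict(size_exponent=0.0, reference_diameter_cm=15.0,
                   standing_multiplier=1.0, doc_leach_coeff=0.0, poc_coeff=0.0,
                   forest_floor_k=0.0, doc_retention=1.0, carbon_fraction=0.492)
    scalars.update(overrides)
    return EngineParameters(guilds=guilds, **scalars)


@pytest.fixture
def simple_params():
    return make_params()
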