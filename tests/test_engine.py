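import math

import numpy as np
import pytest

from cwddat.climate import SiteDescription, synthesize_climate
from cwddat.domain_core import Position, SpeciesGroup
from cwddat.engine import (
    CarbonLedger,
    EngineParameters,
    Forcing,
    GUILD_NAMES,
    GuildParameterSet,
    SubCohort,
    calibrate_defaults,
    guild_shares,
    simulate,
    step,
)
from conftest import make_params

SANTEE = SiteDescription(name="Santee", latitude_deg=33.1482, longitude_deg=-79.791,
                         elevation_m=8.0, MAT_C=18.6, MAP_mm=1673.9, LAI_m2_m2=2.5)


def constant_forcing(n_days: int, tmean: float = 20.0, index: float = 0.6) -> Forcing:
    return Forcing(
        tmean_C=np.full(n_days, tmean),
        moisture_index={pos: np.full(n_days, index) for pos in Position},
    )


def constant_climate(years: int, tmean: float = 20.0):
    import pandas as pd
    n = years * 366
    dates = pd.date_range("2000-01-01", periods=n)
    from cwddat.climate import ClimateSeries
    return ClimateSeries(pd.DataFrame({
        "date": dates, "tmin_C": tmean - 1.0, "tmax_C": tmean + 1.0,
        "precip_mm": np.zeros(n)}))


def one_log(mass=100.0, position=Position.DOWNED, diameter=15.0,
            species=SpeciesGroup.SOFTWOOD, label="log"):
    return SubCohort(label=label, position=position, species=species,
                     diameter_cm=diameter, initial_c=mass)


class TestStepAndClosedForm:
    def test_zero_rates_leave_everything_unchanged(self, simple_params):
        subs = [one_log()]
        masses = np.array([100.0])
        ledger = CarbonLedger(initial_c=100.0, cwd_mass=100.0)
        new, led, gl = step(masses, ledger, subs, 20.0,
                            {p: 0.6 for p in Position}, 0.5, simple_params)
        assert new[0] == 100.0
        assert led.conservation_error() == 0.0
        assert all(v == 0.0 for v in gl.values())
        assert sum(led.respiration.values()) == 0.0

    def test_single_guild_year_matches_exponential(self):
        """365 daily steps at constant modifiers compound to exp(-k)."""
        params = make_params(fungi={"k_base": 0.3, "T_opt_C": 20.0})
        subs = [one_log()]
        masses = np.array([100.0])
        ledger = CarbonLedger(initial_c=100.0, cwd_mass=100.0)
        for d in range(365):
            masses, ledger, _ = step(masses, ledger, subs, 20.0,
                                     {p: 0.6 for p in Position}, d + 0.5, params)
        assert masses[0] == pytest.approx(100.0 * math.exp(-0.3), abs=1e-6)

    def test_negative_parameters_rejected_at_construction(self):
        with pytest.raises(ValueError):
            GuildParameterSet(name="fungi", k_base=-0.1, T_opt_C=25, T_sigma_C=10)


class TestSimulate:
    def test_zero_rate_cohort_remains_intact(self, simple_params):
        climate = synthesize_climate(SANTEE, years=3, seed=1)
        traj = simulate([one_log()], climate, simple_params, years=3)
        assert np.all(traj.remaining_fraction == 1.0)

    def test_constant_climate_matches_daily_compounding_oracle(self):
        """With fixed modifiers the trajectory equals brute-force daily
        compounding of the closed-form rate, to better than 1e-6 of M0."""
        params = make_params(fungi={"k_base": 0.25, "T_opt_C": 22.0},
                             termites={"k_base": 0.1, "T_opt_C": 22.0,
                                       "resource_decline": 0.2})
        forcing = constant_forcing(5 * 365, tmean=22.0, index=0.6)
        climate = constant_climate(5, tmean=22.0)
        traj = simulate([one_log()], climate, params, years=5, forcing=forcing)

        # independent oracle: naive daily loop from the rate definition
        m = 1.0
        oracle = []
        for d in range(5 * 365):
            age_y = (d + 0.5) / 365.0
            r = 0.25 + 0.1 * math.exp(-0.2 * age_y)
            m *= math.exp(-r / 365.0)
            if (d + 1) % 365 == 0:
                oracle.append(m)
        assert np.max(np.abs(traj.remaining_fraction - np.array(oracle))) < 1e-6

    def test_simulate_equals_step_loop(self, default_params):
        """The vectorised path and the single-day kernel agree to rounding."""
        climate = synthesize_climate(SANTEE, years=1, seed=5)
        subs = [one_log(60.0), one_log(40.0, position=Position.STANDING,
                                       diameter=25.0, label="snag")]
        forcing = Forcing.from_climate(climate, SANTEE.LAI_m2_m2)
        traj = simulate(subs, climate, default_params, years=1, forcing=forcing)

        masses = np.array([s.initial_c for s in subs])
        ledger = CarbonLedger(initial_c=100.0, cwd_mass=100.0)
        for d in range(365):
            midx = {p: forcing.moisture_index[p][d] for p in Position}
            masses, ledger, _ = step(masses, ledger, subs, forcing.tmean_C[d],
                                     midx, d + 0.5, default_params)
        rec = traj.records[0]
        assert masses.sum() / 100.0 == pytest.approx(rec.remaining_fraction, abs=1e-12)
        assert ledger.doc_produced == pytest.approx(rec.ledger.doc_produced, abs=1e-9)
        assert ledger.fragment_mass == pytest.approx(rec.ledger.fragment_mass, abs=1e-9)
        assert ledger.poc == pytest.approx(rec.ledger.poc, abs=1e-12)
        for g in (*GUILD_NAMES, "forest_floor"):
            assert ledger.respiration[g] == pytest.approx(rec.ledger.respiration[g], abs=1e-9)

    def test_climate_shorter_than_horizon_rejected(self, default_params):
        climate = synthesize_climate(SANTEE, years=2, seed=1)
        with pytest.raises(ValueError, match="shorter"):
            simulate([one_log()], climate, default_params, years=5)

    def test_empty_substrate_rejected(self, default_params):
        climate = synthesize_climate(SANTEE, years=1, seed=1)
        with pytest.raises(ValueError, match="empty"):
            simulate([], climate, default_params, years=1)


class TestCarbonConservation:
    def test_conservation_under_random_parameters(self):
        """initial C == cwd + fragments + respiration + DOC + POC at every
        annual snapshot, for randomly drawn parameter sets."""
        rng = np.random.default_rng(11)
        climate = synthesize_climate(SANTEE, years=3, seed=2)
        subs = [one_log(80.0), one_log(20.0, position=Position.STANDING, label="s")]
        for _ in range(8):
            overrides = {
                name: {
                    "k_base": float(rng.uniform(0.0, 0.8)),
                    "T_opt_C": float(rng.uniform(15.0, 30.0)),
                    "resource_decline": float(rng.uniform(0.0, 0.5)),
                    "colonization_lag_d": float(rng.uniform(0.0, 400.0)),
                    "fragmentation_share": float(rng.uniform(0.0, 0.5)),
                }
                for name in GUILD_NAMES
            }
            params = make_params(
                **overrides,
                doc_leach_coeff=float(rng.uniform(0.0, 0.05)),
                poc_coeff=float(rng.uniform(0.0, 0.01)),
                forest_floor_k=float(rng.uniform(0.0, 2.0)),
                size_exponent=float(rng.uniform(0.0, 0.8)),
            )
            traj = simulate(subs, climate, params, years=3)
            for rec in traj.records:
                assert rec.ledger.conservation_error() < 1e-9

    def test_annual_shares_sum_to_one_when_loss_positive(self, hugo_report):
        for rec in hugo_report.trajectory.records:
            if rec.annual_loss > 0:
                assert sum(rec.annual_shares.values()) == pytest.approx(1.0)


class TestStructuralEffects:
    def test_remaining_mass_non_increasing(self, hugo_report):
        rem = hugo_report.trajectory.remaining_fraction
        assert np.all(np.diff(rem) <= 0)

    def test_standing_retains_more_than_downed(self, default_params):
        climate = synthesize_climate(SANTEE, years=6, seed=4)
        down = one_log(100.0, Position.DOWNED, label="down")
        stand = one_log(100.0, Position.STANDING, label="stand")
        traj = simulate([down, stand], climate, default_params, years=6)
        for rec in traj.records:
            assert rec.subcohort_remaining[1] >= rec.subcohort_remaining[0]

    def test_larger_diameter_decays_slower(self, default_params):
        climate = synthesize_climate(SANTEE, years=4, seed=4)
        small = one_log(100.0, diameter=8.0, label="small")
        large = one_log(100.0, diameter=40.0, label="large")
        traj = simulate([small, large], climate, default_params, years=4)
        assert default_params.size_exponent > 0
        for rec in traj.records:
            assert rec.subcohort_remaining[1] > rec.subcohort_remaining[0]

    def test_termite_share_declines_with_resource_depletion(self):
        params = make_params(
            fungi={"k_base": 0.2, "T_opt_C": 20.0},
            termites={"k_base": 0.3, "T_opt_C": 20.0, "resource_decline": 0.4},
        )
        climate = constant_climate(5)
        traj = simulate([one_log()], climate, params, years=5,
                        forcing=constant_forcing(5 * 365))
        s1 = traj.records[0].annual_shares["termites"]
        s5 = traj.records[4].annual_shares["termites"]
        assert s5 < s1

    def test_single_guild_takes_full_share(self):
        params = make_params(fungi={"k_base": 0.2, "T_opt_C": 20.0})
        climate = constant_climate(2)
        traj = simulate([one_log()], climate, params, years=2,
                        forcing=constant_forcing(2 * 365))
        shares = guild_shares(traj, 2)
        assert shares["fungi"] == pytest.approx(1.0)
        assert shares["termites"] == 0.0

    def test_zero_loss_shares_undefined(self, simple_params):
        climate = constant_climate(1)
        traj = simulate([one_log()], climate, simple_params, years=1,
                        forcing=constant_forcing(365))
        with pytest.raises(ValueError, match="no mass loss"):
            guild_shares(traj, 1)


class TestCalibrateDefaults:
    def test_satisfied_targets_return_base(self, simple_params):
        base = make_params(fungi={"k_base": 0.2, "T_opt_C": 20.0})

        def scenario(params):
            return {"k": params.guilds["fungi"].k_base}

        best, loss = calibrate_defaults(scenario, [("k", 0.2, 1.0)],
                                        {"guilds.fungi.k_base": (0.01, 1.0)},
                                        base=base)
        assert best.guilds["fungi"].k_base == pytest.approx(0.2)
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_recovers_rate_for_single_target(self):
        """1-D calibration: hit remaining fraction 0.5 at year 5."""
        base = make_params(fungi={"k_base": 0.5, "T_opt_C": 20.0})
        climate = constant_climate(5)
        forcing = constant_forcing(5 * 365)

        def scenario(params):
            traj = simulate([one_log()], climate, params, years=5, forcing=forcing)
            return {"rem5": traj.final.remaining_fraction}

        best, loss = calibrate_defaults(scenario, [("rem5", 0.5, 1.0)],
                                        {"guilds.fungi.k_base": (0.01, 1.0)},
                                        base=base, maxiter=200)
        assert scenario(best)["rem5"] == pytest.approx(0.5, abs=0.01)

    def test_infinite_bounds_rejected(self, simple_params):
        with pytest.raises(ValueError, match="bounds"):
            calibrate_defaults(lambda p: {"x": 0.0}, [("x", 1.0, 1.0)],
                               {"guilds.fungi.k_base": (0.0, math.inf)},
                               base=simple_params)


def test_parameters_json_round_trip(tmp_path, default_params):
    path = tmp_path / "params.json"
    default_params.to_json(path)
    loaded = EngineParameters.from_json(path)
    assert loaded == default_params


def test_guild_names_are_fixed(simple_params):
    with pytest.raises(ValueError, match="guilds"):
        EngineParameters(guilds={"fungi": simple_params.guilds["fungi"]})
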