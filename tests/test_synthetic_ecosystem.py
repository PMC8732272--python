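import copy
import io
import math

import numpy as np
import pytest

from tracerlake.data_model import IsotopeChannel, SPIKE_CHANNELS, Species
from tracerlake.errors import ValidationError
from tracerlake.synthetic_ecosystem import (
    SimConfig,
    config_from_dict,
    config_to_dict,
    default_config,
    generate_decay_series,
    population_turnover_experiment,
    simulate,
    spike_mass_balance,
)
from tracerlake.data_model import fish_to_frame, samples_to_frame


def _dataset_bytes(dataset) -> bytes:
    buf = io.StringIO()
    samples_to_frame(dataset.samples).to_csv(buf, index=False)
    fish_to_frame(dataset.fish).to_csv(buf, index=False)
    return buf.getvalue().encode()


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        a = simulate(default_config(), seed=11)
        b = simulate(default_config(), seed=11)
        assert _dataset_bytes(a.dataset) == _dataset_bytes(b.dataset)
        assert a.ledger == b.ledger

    def test_different_seed_differs(self):
        a = simulate(default_config(), seed=11)
        b = simulate(default_config(), seed=12)
        assert _dataset_bytes(a.dataset) != _dataset_bytes(b.dataset)


class TestMassBalance:
    def test_ledger_closes_default(self, sim_result):
        assert spike_mass_balance(sim_result.ledger) < 1e-9

    def test_ledger_closes_noiseless(self, noiseless_sim):
        assert spike_mass_balance(noiseless_sim.ledger) < 1e-9

    def test_no_additions_after_cessation(self, sim_result):
        rows = [r for r in sim_result.ledger if r["channel"] == "lake_spike"]
        by_year = {r["year"]: r["added_cum_ng"] for r in rows}
        assert by_year[2015] == by_year[2007]
        assert by_year[2007] > by_year[2001] > 0

    def test_tampered_ledger_detected(self, sim_result):
        bad = [dict(r) for r in sim_result.ledger]
        bad[5]["water_pool_ng"] *= 1.001
        with pytest.raises(ValidationError):
            spike_mass_balance(bad)

    def test_pools_non_negative(self, sim_result):
        for r in sim_result.ledger:
            assert r["water_pool_ng"] >= 0
            assert r["sediment_pool_ng"] >= 0
            assert r["fish_pool_ng"] >= 0
            assert r["losses_cum_ng"] >= 0


class TestForcing:
    def test_zero_load_means_zero_spike_everywhere(self):
        res = simulate(default_config(lake_load_rate=0.0), seed=2)
        for s in res.dataset.samples:
            for ch in SPIKE_CHANNELS:
                assert s.conc[ch] == 0.0
        for f in res.dataset.fish:
            for ch in SPIKE_CHANNELS:
                assert f.conc_dw[ch] == 0.0

    def test_ambient_unaffected_by_load(self):
        res = simulate(default_config(lake_load_rate=0.0, obs_noise_cv=0.0), seed=2)
        ambient = res.truth[("water", IsotopeChannel.AMBIENT)]
        assert all(v > 0 for v in ambient.values())

    def test_ambient_stationary(self, noiseless_sim):
        # fish uptake nibbles at the ambient water pool, so stationarity is
        # approximate: tight relative spread, no systematic trend
        ambient = noiseless_sim.truth[("water", IsotopeChannel.AMBIENT)]
        values = np.array(list(ambient.values()))
        assert (values.max() - values.min()) / values.mean() < 0.02
        from tracerlake.tracer_metrics import AnnualSeries, phase_trend_test

        series = AnnualSeries("water", IsotopeChannel.AMBIENT, dict(ambient))
        res = phase_trend_test(series, sorted(ambient))
        # slope negligible relative to the mean level
        assert abs(res.slope) * len(ambient) / values.mean() < 0.02


class TestCalibration:
    """Configured-behaviour regressions for the simulator defaults."""

    def test_water_spike_three_year_decline(self, noiseless_sim):
        w = noiseless_sim.truth[("water", IsotopeChannel.LAKE_SPIKE)]
        ratio = w[2010] / w[2007]
        assert ratio == pytest.approx(0.19, abs=0.03)

    def test_sediment_declines_slower(self, noiseless_sim):
        s = noiseless_sim.truth[("sediment", IsotopeChannel.LAKE_SPIKE)]
        w = noiseless_sim.truth[("water", IsotopeChannel.LAKE_SPIKE)]
        assert s[2010] / s[2007] == pytest.approx(0.65, abs=0.05)
        assert s[2010] / s[2007] > w[2010] / w[2007]

    def test_zooplankton_decline_intermediate(self, noiseless_sim):
        z = noiseless_sim.truth[("zooplankton", IsotopeChannel.LAKE_SPIKE)]
        assert z[2010] / z[2007] == pytest.approx(0.34, abs=0.06)

    def test_peak_percent_increase_ordering(self, noiseless_sim):
        t = noiseless_sim.truth

        def pct(comp):
            return 100 * t[(comp, IsotopeChannel.LAKE_SPIKE)][2007] / t[
                (comp, IsotopeChannel.AMBIENT)
            ][2007]

        assert pct("water") == pytest.approx(60.0, abs=8.0)
        assert pct("sediment") == pytest.approx(30.0, abs=6.0)
        assert pct("sediment") < pct("zooplankton") < pct("water")

    def test_upland_small_wetland_below_dl(self, noiseless_sim):
        for f in noiseless_sim.dataset.fish:
            amb = f.conc_dw[IsotopeChannel.AMBIENT]
            if amb <= 0:
                continue
            assert f.conc_dw[IsotopeChannel.WETLAND_SPIKE] < 0.005 * amb
            assert f.conc_dw[IsotopeChannel.UPLAND_SPIKE] < 0.05 * amb


class TestConfig:
    def test_diet_weights_must_sum_to_one(self):
        cfg = default_config()
        cfg.species[Species.NORTHERN_PIKE].diet = {"forage_fish": 0.5}
        with pytest.raises(ValidationError):
            simulate(cfg, seed=0)

    def test_mortality_bounds(self):
        cfg = default_config()
        cfg.species[Species.NORTHERN_PIKE].mortality = 1.0
        with pytest.raises(ValidationError):
            simulate(cfg, seed=0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            simulate(default_config(methylation_yield=-0.1), seed=0)

    def test_transfer_fractions_bounded(self):
        with pytest.raises(ValidationError):
            simulate(default_config(water_settling=0.9, water_loss=0.2), seed=0)

    def test_unknown_override_rejected(self):
        with pytest.raises(ValidationError):
            default_config(not_a_field=1)

    def test_dict_round_trip(self):
        cfg = default_config(obs_noise_cv=0.07, seed=5)
        back = config_from_dict(config_to_dict(cfg))
        assert config_to_dict(back) == config_to_dict(cfg)


class TestDecaySeriesFixture:
    def test_zero_noise_exact(self):
        x, y = generate_decay_series(2.0, 0.3, 0.0, range(2, 9), seed=0)
        assert np.allclose(y, 2.0 * np.exp(-0.3 * x))

    def test_determinism(self):
        _, y1 = generate_decay_series(2.0, 0.3, 0.2, range(2, 9), seed=9)
        _, y2 = generate_decay_series(2.0, 0.3, 0.2, range(2, 9), seed=9)
        assert np.array_equal(y1, y2)

    def test_mean_one_noise(self):
        # law of large numbers: the mean over many seeds tracks the curve
        x0 = 3.0
        truth = 2.0 * math.exp(-0.3 * x0)
        cv = 0.2
        values = [
            generate_decay_series(2.0, 0.3, cv, [x0], seed)[1][0] for seed in range(1000)
        ]
        se = truth * cv / math.sqrt(1000)
        assert abs(np.mean(values) - truth) < 3 * se

    def test_negative_cv_rejected(self):
        with pytest.raises(ValidationError):
            generate_decay_series(2.0, 0.3, -0.1, [1.0], 0)

    def test_invalid_amplitude(self):
        with pytest.raises(ValidationError):
            generate_decay_series(0.0, 0.3, 0.1, [1.0], 0)


@pytest.fixture(scope="module")
def turnover_experiment():
    return population_turnover_experiment(seed=3)


class TestTurnoverMechanism:
    def test_turnover_drives_population_recovery(self, turnover_experiment):
        assert turnover_experiment["turnover_on_norm_burden"] is not None
        assert turnover_experiment["turnover_on_norm_burden"] < 1.0

    def test_frozen_individuals_never_lose_burden(self, turnover_experiment):
        assert turnover_experiment["turnover_off_min_individual_increment"] >= -1e-9

    def test_long_lived_species_declines_slower(self, turnover_experiment):
        assert turnover_experiment["whitefish_norm_burden"] > turnover_experiment["pike_norm_burden"]


class TestObservationModel:
    def test_recaptures_present(self, sim_result):
        pike = [f for f in sim_result.dataset.fish if f.species is Species.NORTHERN_PIKE]
        t0_ids = {f.fish_id for f in pike if f.year == 2007 and f.fish_id}
        recaptured = {
            f.fish_id for f in pike if f.year > 2007 and f.fish_id in t0_ids
        }
        assert len(recaptured) >= 3

    def test_all_concentrations_non_negative(self, sim_result):
        for s in sim_result.dataset.samples:
            assert all(v >= 0 for v in s.conc.values())
        for f in sim_result.dataset.fish:
            assert all(v >= 0 for v in f.conc_dw.values())

    def test_age_classes_consistent(self, sim_result):
        for f in sim_result.dataset.fish:
            if f.age_years == 0:
                assert f.age_class.value == "YOY"

    def test_spike_burden_requires_addition(self, sim_result):
        # in the first addition year top predators have not yet accumulated
        # spike via the (lagged) food web, and ambient is well established
        for f in sim_result.dataset.fish:
            assert f.conc_dw[IsotopeChannel.AMBIENT] > 0
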