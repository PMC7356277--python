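import numpy as np
import pandas as pd
import pytest

from radeff import (
    ParameterRanges,
    TrialConfig,
    beta_cover,
    generate_canopy_observations,
    generate_design,
    generate_harvest,
    generate_trial,
    generate_truth,
    simulate_growth,
)
from radeff.imaging import cover_from_mixture, segment_canopy_cover
from radeff.synthetic import DEFAULT_ENDMEMBERS
from radeff.weather import thermal_time


class TestDesign:
    def test_reference_layout(self):
        d = generate_design(20, 4, 4, 5, seed=3)
        e = d.entries
        assert len(e) == 36
        checks = e[e["is_check"]]
        for chk in checks["accession"].unique():
            assert sorted(checks.loc[checks["accession"] == chk, "block"]) == [1, 2, 3, 4]
        assert e.groupby("block").size().eq(9).all()

    def test_minimal_design(self):
        d = generate_design(1, 1, 1, 1, seed=0)
        assert len(d.entries) == 2

    @pytest.mark.parametrize("seed", [0, 7])
    def test_each_test_accession_once(self, seed):
        d = generate_design(20, 4, 4, 5, seed=seed)
        news = d.entries[~d.entries["is_check"]]
        assert news["accession"].value_counts().eq(1).all()

    def test_indivisible_layout_rejected(self):
        with pytest.raises(ValueError, match="must equal"):
            generate_design(19, 4, 4, 5, seed=0)


class TestTruth:
    def test_draws_inside_ranges(self):
        d = generate_design(20, 4, 4, 5, seed=1)
        truths = generate_truth(d, seed=2)
        rng = ParameterRanges()
        for t in truths.values():
            assert rng.rue[0] <= t.rue_true <= rng.rue[1]
            assert rng.tu[0] <= t.gompertz.tu <= rng.tu[1]
            assert rng.hi[0] <= t.gompertz.a_max <= rng.hi[1]
            assert rng.ndvi_slp[0] <= t.ndvi_slp_true <= rng.ndvi_slp[1]

    def test_collapsed_ranges_give_identical_accessions(self):
        d = generate_design(4, 2, 2, 2, seed=1)
        pt = ParameterRanges(
            rue=(2.0, 2.0), tu=(450.0, 450.0), hi=(0.8, 0.8), b=(0.01, 0.01),
            cc_max=(0.8, 0.8), te=(1000.0, 1000.0), tm_frac=(0.5, 0.5),
            ndvi_slp=(-0.004, -0.004), a_mean=(20.0, 20.0), delta_leaf=(22.0, 22.0),
        )
        truths = generate_truth(d, pt, seed=9)
        vals = {(t.rue_true, t.gompertz.tu, t.beta.cc_max) for t in truths.values()}
        assert len(vals) == 1
        t = next(iter(truths.values()))
        assert t.rue_true == 2.0 and t.gompertz.tu == 450.0

    def test_determinism_contract(self):
        d = generate_design(4, 2, 2, 2, seed=1)
        a = generate_truth(d, seed=5)
        b = generate_truth(d, seed=5)
        c = generate_truth(d, seed=6)
        assert a == b
        assert any(a[k] != c[k] for k in a)

    def test_empty_design_rejected(self):
        d = generate_design(1, 1, 1, 1, seed=0)
        object.__setattr__(d, "entries", d.entries.iloc[:0])
        with pytest.raises(ValueError, match="no accessions"):
            generate_truth(d, seed=0)


class TestCanopyObservations:
    def _truth(self, seed=4):
        d = generate_design(1, 1, 1, 1, seed=seed)
        return next(iter(generate_truth(d, seed=seed).values()))

    def test_noiseless_plot_means_invert_exactly(self, flat_weather):
        truth = self._truth()
        obs = generate_canopy_observations(truth, flat_weather, noise_sd=0.0, seed=0)
        em = DEFAULT_ENDMEMBERS
        cc_rec = cover_from_mixture(obs.table["nir"].to_numpy(), em.veg[2], em.soil[2])
        assert cc_rec == pytest.approx(obs.table["cc_true"].to_numpy(), abs=1e-12)

    def test_raster_segmentation_within_pixel_quantum(self, flat_weather):
        truth = self._truth()
        obs = generate_canopy_observations(
            truth, flat_weather, noise_sd=0.0, seed=0, raster_shape=(32, 32)
        )
        for k, dap in enumerate(obs.table["dap"]):
            cc = segment_canopy_cover(obs.rasters[int(dap)], 0.3)
            assert abs(cc - obs.table["cc_true"].iloc[k]) <= 1.0 / (32 * 32) + 1e-12

    def test_zero_cover_is_pure_soil(self, flat_weather):
        truth = self._truth()
        obs = generate_canopy_observations(
            truth, flat_weather, flight_daps=[1], noise_sd=0.0, seed=0
        )
        row = obs.table.iloc[0]
        assert row["cc_true"] == pytest.approx(0.0, abs=2e-3)
        assert (row[["green", "red", "nir"]].to_numpy()
                == pytest.approx(np.array(DEFAULT_ENDMEMBERS.soil), abs=1e-3))

    def test_thirteen_weekly_flights_rise_then_fall(self, flat_weather):
        truth = self._truth()
        obs = generate_canopy_observations(truth, flat_weather, noise_sd=0.0, seed=0)
        assert len(obs.table) == 13
        ndvi = ((obs.table["nir"] - obs.table["red"])
                / (obs.table["nir"] + obs.table["red"])).to_numpy()
        peak = np.argmax(ndvi)
        assert 0 < peak < 12
        assert ndvi[0] < ndvi[peak] and ndvi[-1] < ndvi[peak]

    def test_reflectances_bounded(self, flat_weather):
        truth = self._truth()
        obs = generate_canopy_observations(truth, flat_weather, noise_sd=0.2, seed=1)
        assert obs.table[["green", "red", "nir"]].to_numpy().min() >= 0
        assert obs.table[["green", "red", "nir"]].to_numpy().max() <= 1

    def test_flight_beyond_weather_rejected(self, flat_weather):
        with pytest.raises(ValueError, match="beyond weather"):
            generate_canopy_observations(
                self._truth(), flat_weather, flight_daps=[200], seed=0
            )


class TestHarvest:
    def _truth(self):
        d = generate_design(1, 1, 1, 1, seed=2)
        return next(iter(generate_truth(d, seed=2).values()))

    def test_noiseless_equals_simulation(self, flat_weather):
        truth = self._truth()
        obs = generate_harvest(truth, flat_weather, 121, noise_cv=0.0, seed=0)
        sim = simulate_growth(flat_weather, truth.beta, truth.rue_true,
                              truth.gompertz, 121)
        assert obs["ty_obs"].iloc[-1] == pytest.approx(sim.ty_sim)
        assert obs["tb_obs"].iloc[-1] == pytest.approx(sim.tb)
        assert (obs["ty_obs"] == obs["ty_true"]).all()

    def test_monte_carlo_cv_recovery(self, flat_weather):
        truth = self._truth()
        vals = np.array(
            [
                generate_harvest(truth, flat_weather, 121, noise_cv=0.1,
                                 seed=s, obs_daps=[121])["ty_obs"].iloc[0]
                for s in range(200)
            ]
        )
        cv = vals.std(ddof=1) / vals.mean()
        assert abs(cv - 0.1) < 0.03

    def test_strictly_positive(self, flat_weather):
        truth = self._truth()
        for s in range(20):
            obs = generate_harvest(truth, flat_weather, 121, noise_cv=0.5, seed=s)
            assert (obs["ty_obs"] > 0).all()


class TestFullTrial:
    def test_same_seed_identical_bundle(self):
        cfg = TrialConfig(n_new=4, n_checks=2, n_blocks=2, new_per_block=2, seed=3)
        a, b = generate_trial(cfg), generate_trial(cfg)
        pd.testing.assert_frame_equal(a.weather, b.weather)
        pd.testing.assert_frame_equal(a.design.entries, b.design.entries)
        assert a.truths == b.truths
        for pid in a.canopy:
            pd.testing.assert_frame_equal(a.canopy[pid].table, b.canopy[pid].table)
            pd.testing.assert_frame_equal(a.harvest[pid], b.harvest[pid])

    def test_bundle_shapes(self, noisy_trial):
        assert len(noisy_trial.design.entries) == 36
        assert len(noisy_trial.truths) == 24
        assert all(len(o.table) == 13 for o in noisy_trial.canopy.values())
        assert len(noisy_trial.physiology) == 36

    def test_senescence_delay_couples_to_rue(self, noisy_trial):
        slp = np.array([t.ndvi_slp_true for t in noisy_trial.truths.values()])
        r = np.array([t.rue_true for t in noisy_trial.truths.values()])
        assert np.corrcoef(slp, r)[0, 1] > 0.3
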