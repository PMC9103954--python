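"""Tests of the synthetic-study generators: determinism, invariants and the
statistical structure the downstream models assume."""

import numpy as np
import pandas as pd
import pytest

import steamhybrid as sh
from steamhybrid.synthetic import BUFFER_RADII, TruthParams


class TestNetwork:
    def test_cardinality_and_domain(self):
        sites = sh.generate_network(130, seed=1)
        assert len(sites) == 130
        assert sites["site_id"].is_unique
        assert sites["x"].between(0, 50_000).all() and sites["y"].between(0, 50_000).all()

    def test_determinism(self):
        a = sh.generate_network(50, seed=7)
        b = sh.generate_network(50, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_all_background_boundary(self):
        sites = sh.generate_network(20, frac_background=1.0, seed=2)
        assert (sites["site_type"] == "background").all()

    @pytest.mark.parametrize("bad", [0, 1, -3])
    def test_invalid_site_count(self, bad):
        with pytest.raises(ValueError):
            sh.generate_network(bad, seed=0)


class TestCovariates:
    def test_buffer_monotonicity_rowwise(self):
        sites = sh.generate_network(100, seed=3)
        cov = sh.generate_covariates(sites, seed=4)
        for a, b in zip(BUFFER_RADII, BUFFER_RADII[1:]):
            assert (cov[f"TRAFMLOAD_{b}"] >= cov[f"TRAFMLOAD_{a}"]).all()
            assert (cov[f"ROADLENGTH_{b}"] >= cov[f"ROADLENGTH_{a}"]).all()

    def test_determinism(self):
        sites = sh.generate_network(30, seed=5)
        pd.testing.assert_frame_equal(
            sh.generate_covariates(sites, seed=9), sh.generate_covariates(sites, seed=9)
        )

    def test_traffic_sites_have_larger_traffic_load(self):
        sites = sh.generate_network(200, frac_background=0.5, seed=7)
        cov = sh.generate_covariates(sites, seed=7).merge(sites, on="site_id")
        means = cov.groupby("site_type")["TRAFMLOAD_300"].mean()
        assert means["traffic"] > means["background"]

    def test_inverse_distance_nonnegative(self):
        sites = sh.generate_network(50, seed=8)
        cov = sh.generate_covariates(sites, seed=8)
        assert (cov["INVDIST_ROAD"] >= 0).all()
        assert not cov.isna().any().any()


class TestMeteorology:
    def test_row_per_day_and_invariants(self):
        dates = pd.date_range("2009-01-01", periods=365)
        met = sh.generate_meteorology(dates, seed=1)
        assert len(met) == 365
        assert met["rel_humidity"].between(0, 100).all()
        assert met["cloud"].between(0, 8).all()
        assert (met["wind_speed"] > 0).all()
        assert not met.isna().any().any()

    def test_ar_zero_gives_uncorrelated_detrended_temperature(self):
        dates = pd.date_range("2009-01-01", periods=1825)
        met = sh.generate_meteorology(dates, seed=2, ar=0.0)
        doy = dates.dayofyear.to_numpy()
        season = -np.cos(2 * np.pi * (doy - 15) / 365.25)
        resid = met["temperature"].to_numpy() - (11.0 + 7.5 * season)
        rho = np.corrcoef(resid[:-1], resid[1:])[0, 1]
        assert abs(rho) < 0.1

    def test_determinism(self):
        dates = pd.date_range("2010-01-01", periods=100)
        pd.testing.assert_frame_equal(
            sh.generate_meteorology(dates, seed=3), sh.generate_meteorology(dates, seed=3)
        )


class TestMeasurements:
    def _tiny(self, params, n_sites=12, n_days=40, seed=0):
        sites = sh.generate_network(n_sites, seed=seed)
        cov = sh.generate_covariates(sites, seed=seed + 1)
        meteo = sh.generate_meteorology(pd.date_range("2009-01-01", periods=n_days), seed=seed + 2)
        panel, truth = sh.generate_measurements(sites, cov, meteo, params, seed=seed + 3)
        return sites, cov, meteo, panel, truth

    def test_degenerate_generator_is_exact(self):
        """noise->0, no spatial field, identity link, one linear covariate:
        the measurement is exactly coefficient*covariate + temporal terms."""
        params = TruthParams(
            linear_effects={"URBAN_300": 2.0},
            smooth_effects={},
            spatial_sd=0.0,
            dow_offsets=(0.1,) * 7,
            season_amplitude=0.0,
            intercept=5.0,
            noise_sd=1e-12,
            link="identity",
        )
        sites, cov, meteo, panel, truth = self._tiny(params)
        expected = 5.0 + 0.1 + 2.0 * cov.set_index("site_id").loc[panel["site_id"], "URBAN_300"].to_numpy()
        np.testing.assert_allclose(panel["concentration"], expected, atol=1e-8)

    def test_log_link_positivity_and_uniqueness(self, small_study):
        panel = small_study["panel"]
        assert (panel["concentration"] > 0).all()
        assert not panel.duplicated(["site_id", "date", "pollutant"]).any()

    def test_variance_accounting(self):
        """Total model-scale variance matches the analytic sum of independent
        component variances (spatial + seasonal + day-of-week + noise)."""
        dow = (0.0, 0.1, 0.1, 0.1, 0.1, 0.0, -0.2)
        amp, sp_sd, noise = 0.2, 0.3, 0.25
        params = TruthParams(
            linear_effects={},
            smooth_effects={},
            spatial_sd=sp_sd,
            spatial_range=2_000.0,  # short range: sites nearly independent
            dow_offsets=dow,
            season_amplitude=amp,
            noise_sd=noise,
        )
        sites = sh.generate_network(300, seed=11)
        cov = sh.generate_covariates(sites, seed=12)
        meteo = sh.generate_meteorology(pd.date_range("2009-01-01", periods=365), seed=13)
        # average over replicate draws: the spatial-field sample variance at
        # 300 sites wobbles ~12% between single draws
        v_emp = np.mean(
            [
                np.log(sh.generate_measurements(sites, cov, meteo, params, seed=s)[0]["concentration"]).var()
                for s in (11, 12, 13, 14, 15)
            ]
        )
        d = np.asarray(dow)
        v_dow = d.var()
        v_analytic = sp_sd**2 + amp**2 / 2 + v_dow + noise**2
        assert v_emp == pytest.approx(v_analytic, rel=0.10)

    def test_truth_surface_is_noise_free_center(self):
        sites, cov, meteo, panel, truth = self._tiny(TruthParams(noise_sd=0.3), n_sites=40, n_days=60, seed=5)
        ratio = np.log(panel["concentration"]) - np.log(truth["truth"])
        assert abs(ratio.mean()) < 0.02
        assert ratio.std() == pytest.approx(0.3, rel=0.05)

    def test_overflow_guard(self):
        params = TruthParams(intercept=50.0)
        with pytest.raises(ValueError, match="log link"):
            self._tiny(params)


class TestAuxPredictions:
    def test_identity_when_unbiased(self, small_study):
        aux = sh.generate_aux_predictions(small_study["truth"], small_study["sites"], seed=1)
        np.testing.assert_allclose(aux["prediction"], small_study["truth"]["truth"])

    def test_constant_bias_shifts_mean(self, small_study):
        aux = sh.generate_aux_predictions(
            small_study["truth"], small_study["sites"], bias_const=3.0, seed=1
        )
        diff = aux["prediction"] - small_study["truth"]["truth"]
        assert diff.mean() == pytest.approx(3.0, abs=1e-9)

    def test_determinism_and_positivity(self, small_study):
        kw = dict(bias_sd=2.0, noise_sd=4.0, seed=42)
        a = sh.generate_aux_predictions(small_study["truth"], small_study["sites"], **kw)
        b = sh.generate_aux_predictions(small_study["truth"], small_study["sites"], **kw)
        pd.testing.assert_frame_equal(a, b)
        assert (a["prediction"] > 0).all()


def test_truthparams_invariants():
    with pytest.raises(ValueError):
        TruthParams(noise_sd=0.0)
    with pytest.raises(ValueError):
        TruthParams(spatial_range=-1.0)
    with pytest.raises(ValueError):
        TruthParams(link="probit")
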