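"""Tests of the combination models: nesting in the LUR, no-information
channels, error averaging, channel symmetry and the ensemble combiner."""

import numpy as np
import pandas as pd
import pytest

import steamhybrid as sh
from steamhybrid.hybrid import EnsembleGAM, HybridLUR, StackedGAM, predict_hybrid
from steamhybrid.lur import Candidate, STLandUseRegression
from steamhybrid.synthetic import TruthParams

POOL = [
    Candidate("TRAFMLOAD_300", sign="positive"),
    Candidate("URBAN_300", sign="positive"),
    Candidate("temperature"),
    Candidate("wind_speed"),
]
OPTS = dict(candidates=POOL, spatial_basis=5, n_splines=6)


@pytest.fixture(scope="module")
def study():
    sites = sh.generate_network(25, seed=31)
    cov = sh.generate_covariates(sites, seed=32)
    meteo = sh.generate_meteorology(pd.date_range("2009-01-01", periods=70), seed=33)
    panel, truth = sh.generate_measurements(sites, cov, meteo, TruthParams(), seed=34)
    frame = sh.make_model_frame(panel, sites, cov, meteo)
    aux = sh.generate_aux_predictions(truth, sites, bias_sd=3.0, noise_sd=4.0, seed=35)
    frame = frame.merge(
        aux.rename(columns={"prediction": "aux_dispersion"})[["site_id", "date", "aux_dispersion"]],
        on=["site_id", "date"],
    )
    return {"frame": frame, "truth": truth, "sites": sites}


class TestHybrid1:
    def test_no_channel_nests_to_standalone_lur(self, study):
        """With all auxiliary channels removed the hybrid is the ST-LUR."""
        frame = study["frame"]
        y = frame["concentration"].to_numpy()
        lur = STLandUseRegression(**OPTS).fit(frame, y)
        hyb = HybridLUR(aux_channels=(), **OPTS).fit(frame, y)
        np.testing.assert_allclose(lur.predict(frame), hyb.predict(frame), rtol=1e-10)

    def test_constant_channel_is_no_information(self, study):
        """A constant auxiliary channel adds nothing: fit equals the nested
        LUR's (the degenerate smooth is dropped with a warning)."""
        frame = study["frame"].copy()
        frame["aux_dispersion"] = 42.0
        y = frame["concentration"].to_numpy()
        with pytest.warns(UserWarning, match="constant"):
            hyb = HybridLUR(aux_channels=("aux_dispersion",), **OPTS).fit(frame, y)
        lur = STLandUseRegression(**OPTS).fit(frame, y)
        assert hyb.adj_r2_ == pytest.approx(lur.adj_r2_, abs=1e-9)
        np.testing.assert_allclose(hyb.predict(frame), lur.predict(frame), rtol=1e-8)

    def test_missing_aux_rows_raise(self, study):
        frame = study["frame"].copy()
        frame.loc[frame.index[:5], "aux_dispersion"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            HybridLUR(aux_channels=("aux_dispersion",), **OPTS).fit(
                frame, frame["concentration"].to_numpy()
            )

    def test_informative_channel_improves_fit(self, study):
        """aux = truth + modest noise raises adjusted R² over the same model
        without the channel (base models, no selection interplay)."""
        frame = study["frame"]
        y = frame["concentration"].to_numpy()
        lur = STLandUseRegression(select=False, spatial_basis=5).fit(frame, y)
        hyb = HybridLUR(aux_channels=("aux_dispersion",), select=False, spatial_basis=5).fit(frame, y)
        assert hyb.adj_r2_ > lur.adj_r2_ + 0.05


class TestHybrid2:
    def test_perfect_single_channel(self, study):
        frame = study["frame"].copy()
        y = frame["concentration"].to_numpy()
        frame["ch"] = y
        m = StackedGAM(channels=("ch",)).fit(frame, y)
        assert m.model_.r2 > 0.999

    def test_noise_channel_is_shrunk(self):
        """Adding a pure-noise channel barely changes held-out performance."""
        rng = np.random.default_rng(44)
        n = 1500
        truth = rng.uniform(10, 60, n)
        y = truth + rng.normal(0, 3, n)
        df = pd.DataFrame({"good": truth + rng.normal(0, 2, n), "noise": rng.uniform(10, 60, n)})
        tr, te = np.arange(n) < 1000, np.arange(n) >= 1000
        r2 = {}
        for chans in [("good",), ("good", "noise")]:
            m = StackedGAM(channels=chans).fit(df[tr], y[tr])
            p = m.predict(df[te])
            r2[chans] = np.corrcoef(p, y[te])[0, 1] ** 2
        assert abs(r2[("good",)] - r2[("good", "noise")]) < 0.02

    def test_error_averaging_beats_single_channels(self):
        """Channels = truth + independent equal-variance errors: the stack's
        held-out RMSE beats each single channel in >= 9/10 replicates."""
        wins = 0
        for rep in range(10):
            rng = np.random.default_rng(500 + rep)
            n = 1200
            truth = rng.uniform(10, 60, n)
            y = truth + rng.normal(0, 2, n)
            df = pd.DataFrame(
                {"a": truth + rng.normal(0, 5, n), "b": truth + rng.normal(0, 5, n)}
            )
            tr, te = np.arange(n) < 800, np.arange(n) >= 800
            m = StackedGAM(channels=("a", "b")).fit(df[tr], y[tr])
            rmse = lambda p: np.sqrt(np.mean((p - y[te]) ** 2))
            stack = rmse(m.predict(df[te]))
            singles = min(rmse(df.loc[te, "a"]), rmse(df.loc[te, "b"]))
            wins += stack < singles
        assert wins >= 9

    def test_channel_order_symmetry(self, study):
        frame = study["frame"].copy()
        y = frame["concentration"].to_numpy()
        rng = np.random.default_rng(7)
        frame["c1"] = y * (1 + rng.normal(0, 0.05, len(y)))
        frame["c2"] = frame["aux_dispersion"]
        p1 = StackedGAM(channels=("c1", "c2")).fit(frame, y).predict(frame)
        p2 = StackedGAM(channels=("c2", "c1")).fit(frame, y).predict(frame)
        np.testing.assert_allclose(p1, p2, atol=1e-8)

    def test_identity_like_smooths_average_agreeing_channels(self):
        """Where channels agree and the smooths are identity-like, the stack
        prediction is close to the common channel value."""
        rng = np.random.default_rng(9)
        n = 1000
        truth = rng.uniform(20, 40, n)
        y = truth + rng.normal(0, 1, n)
        df = pd.DataFrame({"a": truth, "b": truth})
        m = StackedGAM(channels=("a", "b")).fit(df, y)
        p = m.predict(pd.DataFrame({"a": [30.0], "b": [30.0]}))
        assert p[0] == pytest.approx(30.0, abs=1.0)

    def test_misaligned_channels_raise(self, study):
        frame = study["frame"].copy()
        frame.loc[frame.index[0], "aux_dispersion"] = np.nan
        with pytest.raises(ValueError, match="misaligned"):
            StackedGAM(channels=("aux_dispersion",)).fit(frame, frame["concentration"].to_numpy())


class TestEnsemble:
    def _spatial_data(self, seed=0, n=1200):
        rng = np.random.default_rng(seed)
        x, ycoord = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
        truth = 30 + 10 * np.sin(3 * x) * np.cos(2 * ycoord)
        y = truth + rng.normal(0, 1.5, n)
        return pd.DataFrame({"x": x, "y": ycoord}), truth, y, rng

    def test_identical_channels_reproduce_channel(self):
        """Two identical channels that carry the full signal: the combined
        prediction equals that channel up to smooth-fit tolerance."""
        df, truth, y, rng = self._spatial_data(1)
        df["p1"] = truth
        df["p2"] = truth
        y = truth + rng.normal(0, 0.05, len(df))
        m = EnsembleGAM(channels=("p1", "p2")).fit(df, y)
        rel = np.abs(m.predict(df) - df["p1"]) / np.abs(df["p1"])
        assert rel.max() < 1e-3

    def test_requires_two_channels(self):
        df, truth, y, _ = self._spatial_data(2)
        df["p1"] = truth
        with pytest.raises(ValueError, match=">= 2"):
            EnsembleGAM(channels=("p1",)).fit(df, y)

    def test_spatially_varying_skill_stacking(self):
        """Channels good in different halves of the domain: the combiner with
        its coordinate smooth matches or beats the best single channel."""
        wins = 0
        for rep in range(10):
            df, truth, y, rng = self._spatial_data(100 + rep)
            n = len(df)
            noise_a = np.where(df["x"] < 0.5, 1.0, 6.0)
            noise_b = np.where(df["x"] < 0.5, 6.0, 1.0)
            df["a"] = truth + rng.normal(0, 1, n) * noise_a
            df["b"] = truth + rng.normal(0, 1, n) * noise_b
            tr, te = np.arange(n) < 800, np.arange(n) >= 800
            m = EnsembleGAM(channels=("a", "b")).fit(df[tr], y[tr])
            r2 = lambda p: np.corrcoef(p, y[te])[0, 1] ** 2
            best_single = max(r2(df.loc[te, "a"]), r2(df.loc[te, "b"]))
            wins += r2(m.predict(df[te])) >= best_single - 0.01
        assert wins >= 9

    def test_coordinate_smooth_shrinks_without_spatial_structure(self):
        """Response depends only on the channels; the coordinates are pure
        noise, so the bivariate smooth's edf shrinks toward its minimum
        (the dimension of the tensor penalty's null space)."""
        rng = np.random.default_rng(5)
        n = 1200
        df = pd.DataFrame({"x": rng.uniform(0, 1, n), "y": rng.uniform(0, 1, n)})
        signal = rng.uniform(20, 50, n)
        resp = signal + rng.normal(0, 1.0, n)
        df["a"] = signal + rng.normal(0, 0.5, n)
        df["b"] = signal + rng.normal(0, 0.5, n)
        m = EnsembleGAM(channels=("a", "b")).fit(df, resp)
        # tensor penalty null space has dimension 3; REML keeps only a little
        # more than that on pure noise, far below the spatially-informed case
        assert m.edf_by_term_["te(x,y)"] < 5.0
        df2, truth2, y2, rng2 = self._spatial_data(6)
        df2["a"] = y2 + rng2.normal(0, 3, len(df2))
        df2["b"] = y2 + rng2.normal(0, 3, len(df2))
        m2 = EnsembleGAM(channels=("a", "b")).fit(df2, y2)
        assert m2.edf_by_term_["te(x,y)"] > m.edf_by_term_["te(x,y)"] + 2


def test_cross_validated_learner_predictions_are_heldout(study):
    """The learner-zoo convenience routine returns one held-out prediction per
    row and channel, grouped by site."""
    from sklearn.neighbors import KNeighborsRegressor
    from sklearn.tree import DecisionTreeRegressor

    from steamhybrid.hybrid import cross_validated_learner_predictions

    frame = study["frame"].iloc[:700]
    y = frame["concentration"].to_numpy()
    learners = {
        "pred_knn": (KNeighborsRegressor(), {"n_neighbors": [5, 10]}),
        "pred_tree": (DecisionTreeRegressor(random_state=0), {"max_depth": [3, 5]}),
    }
    preds = cross_validated_learner_predictions(
        frame, y, features=["x", "y", "temperature", "TRAFMLOAD_300"],
        groups=frame["site_id"].to_numpy(), learners=learners, n_folds=3, seed=1,
    )
    assert list(preds.columns) == ["pred_knn", "pred_tree"]
    assert len(preds) == len(frame)
    assert np.isfinite(preds.to_numpy()).all()
    # held-out predictions at unseen sites retain some positive association
    assert np.corrcoef(preds["pred_knn"], y)[0, 1] > 0.05


def test_predict_hybrid_empty_newdata(study):
    frame = study["frame"]
    y = frame["concentration"].to_numpy()
    m = StackedGAM(channels=("aux_dispersion",)).fit(frame, y)
    out = predict_hybrid(m, frame.iloc[:0])
    assert len(out) == 0
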