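"""Second-stage combination models.

Three ways of merging independent exposure-assessment methods:

* :class:`HybridLUR` ("hybrid 1") — the ST-LUR with a penalized-spline smooth
  of each auxiliary prediction channel (dispersion-like, ensemble-ML-like)
  forced into the base model; with no channels it reduces exactly to the
  standalone ST-LUR.
* :class:`StackedGAM` ("hybrid 2") — a Gaussian GAM of the concentration on a
  penalized-spline transform of each method's predictions (cross-validated
  for methods that saw the response, raw for the dispersion channel), with
  smoothness chosen by GCV.  The smooths let each method's weight vary along
  the concentration range.
* :class:`EnsembleGAM` — the machine-learning combiner: one REML smooth per
  learner-prediction channel plus a bivariate smooth of the coordinates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import GridSearchCV

from ._pspline import AdditiveModel, SplineTerm, TensorTerm
from .lur import STLandUseRegression

__all__ = [
    "HybridLUR",
    "StackedGAM",
    "EnsembleGAM",
    "fit_hybrid1",
    "fit_hybrid2",
    "fit_ensemble",
    "predict_hybrid",
    "cross_validated_learner_predictions",
]


class HybridLUR(STLandUseRegression):
    """ST-LUR with auxiliary prediction channels as forced smooth covariates.

    ``aux_channels`` names columns of the model frame holding auxiliary
    concentration predictions aligned with the panel rows.  With
    ``aux_channels=[]`` the estimator is the standalone ST-LUR (identical
    code path, identical fit).
    """

    def __init__(
        self,
        aux_channels: tuple[str, ...] = ("aux_dispersion",),
        candidates=None,
        link: str = "log",
        gain_threshold: float = 0.01,
        criterion: str = "reml",
        spatial_basis: int = 6,
        n_splines: int = 8,
        select: bool = True,
        forced_terms: list | None = None,
        max_terms: int = 12,
        year_factor: bool = True,
        min_sites: int = 10,
        min_days: int = 30,
    ):
        self.aux_channels = aux_channels
        super().__init__(
            candidates=candidates,
            link=link,
            gain_threshold=gain_threshold,
            criterion=criterion,
            spatial_basis=spatial_basis,
            n_splines=n_splines,
            select=select,
            forced_terms=forced_terms,
            max_terms=max_terms,
            year_factor=year_factor,
            min_sites=min_sites,
            min_days=min_days,
        )

    def _base_terms(self, X: pd.DataFrame):
        terms = super()._base_terms(X)
        for ch in self.aux_channels:
            if ch not in X.columns:
                missing = [c for c in self.aux_channels if c not in X.columns]
                raise ValueError(f"auxiliary channel column(s) missing from frame: {missing}")
            terms.append(SplineTerm(ch, n_splines=self.n_splines))
        return terms

    def fit(self, X: pd.DataFrame, y):
        for ch in self.aux_channels:
            if ch in X.columns and X[ch].isna().any():
                gaps = X.loc[X[ch].isna(), ["site_id", "date"]].head()
                raise ValueError(f"auxiliary channel {ch!r} has missing rows, e.g.\n{gaps}")
        return super().fit(X, y)


class StackedGAM(RegressorMixin, BaseEstimator):
    """GCV-penalized additive stack of method predictions (hybrid 2).

    Fits the measured concentration (untransformed) as a sum of univariate
    penalized-spline transforms, one per input channel.
    """

    def __init__(self, channels: tuple[str, ...] = ("lur_cv", "dispersion"), n_splines: int = 10):
        self.channels = channels
        self.n_splines = n_splines

    def fit(self, X: pd.DataFrame, y) -> "StackedGAM":
        if len(self.channels) == 0:
            raise ValueError("at least one channel required")
        missing = [c for c in self.channels if c not in X.columns]
        if missing:
            raise ValueError(f"channel column(s) missing: {missing}")
        if X[list(self.channels)].isna().any().any():
            raise ValueError("channels misaligned: missing values after alignment")
        # channel order must not matter: sort term construction canonically
        terms = [SplineTerm(c, n_splines=self.n_splines) for c in sorted(self.channels)]
        self.model_ = AdditiveModel(terms, criterion="gcv").fit(X, np.asarray(y, dtype=float))
        self.edf_by_channel_ = {
            c: self.model_.edf_by_term[f"s({c})"] for c in self.channels
        }
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if len(X) == 0:
            return np.empty(0)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return self.model_.predict(X)


class EnsembleGAM(RegressorMixin, BaseEstimator):
    """Combiner GAM over >= 2 learner-prediction channels + coordinate smooth."""

    def __init__(
        self,
        channels: tuple[str, ...] = ("pred_gbm", "pred_rf"),
        coords: tuple[str, str] = ("x", "y"),
        n_splines: int = 10,
        spatial_basis: int = 5,
    ):
        self.channels = channels
        self.coords = coords
        self.n_splines = n_splines
        self.spatial_basis = spatial_basis

    def fit(self, X: pd.DataFrame, y) -> "EnsembleGAM":
        if len(self.channels) < 2:
            raise ValueError("ensemble combiner needs >= 2 learner channels")
        terms = [SplineTerm(c, n_splines=self.n_splines) for c in sorted(self.channels)]
        terms.append(TensorTerm(*self.coords, n_splines=self.spatial_basis))
        self.model_ = AdditiveModel(terms, criterion="reml").fit(X, np.asarray(y, dtype=float))
        self.edf_by_term_ = dict(self.model_.edf_by_term)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if len(X) == 0:
            return np.empty(0)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return self.model_.predict(X)


def cross_validated_learner_predictions(
    X: pd.DataFrame,
    y: np.ndarray,
    features: list[str],
    groups: np.ndarray,
    learners: dict | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Held-out (leave-site-out) predictions from a small grid-searched
    learner zoo, for feeding the ensemble combiner.

    ``learners`` maps channel name -> (estimator, param_grid); defaults to
    gradient boosting, random forest and k-nearest-neighbour regressors with
    small hyper-parameter grids selected on CV mean-squared error.
    """
    from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
    from sklearn.neighbors import KNeighborsRegressor

    if learners is None:
        learners = {
            "pred_gbm": (
                GradientBoostingRegressor(random_state=seed),
                {"n_estimators": [50, 100], "max_depth": [2, 3]},
            ),
            "pred_rf": (
                RandomForestRegressor(random_state=seed, n_jobs=1),
                {"n_estimators": [100], "max_depth": [6, None]},
            ),
            "pred_knn": (KNeighborsRegressor(), {"n_neighbors": [5, 10, 20]}),
        }
    rng = np.random.default_rng(seed)
    uniq = np.array(sorted(pd.unique(groups)))
    perm = rng.permutation(len(uniq))
    fold_of = {g: i % n_folds for g, i in zip(uniq[perm], range(len(uniq)))}
    fold_idx = np.array([fold_of[g] for g in groups])
    out = pd.DataFrame(index=X.index)
    feats = X[features].to_numpy()
    y = np.asarray(y, dtype=float)
    for name, (est, grid) in learners.items():
        preds = np.empty(len(X))
        for f in range(n_folds):
            tr, te = fold_idx != f, fold_idx == f
            gs = GridSearchCV(est, grid, cv=3, scoring="neg_mean_squared_error", n_jobs=1)
            gs.fit(feats[tr], y[tr])
            preds[te] = gs.predict(feats[te])
        out[name] = preds
    return out


def fit_hybrid1(panel, sites, covariates, meteo, aux: pd.DataFrame, **options) -> HybridLUR:
    """Fit hybrid 1 from raw tables; ``aux`` is a long AuxPredictionPanel."""
    from .lur import make_model_frame

    frame = make_model_frame(panel, sites, covariates, meteo)
    channels = []
    for ch, sub in aux.groupby("channel"):
        col = f"aux_{ch}"
        frame = frame.merge(
            sub.rename(columns={"prediction": col})[["site_id", "date", col]],
            on=["site_id", "date"],
            how="left",
        )
        channels.append(col)
    est = HybridLUR(aux_channels=tuple(channels), **options)
    est.fit(frame, frame["concentration"].to_numpy())
    est.frame_ = frame
    return est


def fit_hybrid2(panel, lur_cv_pred, dispersion_pred, ml_cv_pred=None, **options) -> StackedGAM:
    """Fit hybrid 2 from aligned prediction panels (site_id, date, prediction)."""
    frame = panel[["site_id", "date", "concentration"]].copy()
    channels = {"lur_cv": lur_cv_pred, "dispersion": dispersion_pred}
    if ml_cv_pred is not None:
        channels["ml_cv"] = ml_cv_pred
    for name, ch in channels.items():
        frame = frame.merge(
            ch.rename(columns={"prediction": name})[["site_id", "date", name]],
            on=["site_id", "date"],
            how="left",
        )
        if frame[name].isna().any():
            raise ValueError(f"channel {name!r} misaligned with panel")
    est = StackedGAM(channels=tuple(channels), **options)
    est.fit(frame, frame["concentration"].to_numpy())
    est.frame_ = frame
    return est


def fit_ensemble(panel, learner_preds: pd.DataFrame, coords: pd.DataFrame, **options) -> EnsembleGAM:
    """Fit the ensemble combiner; ``learner_preds`` holds >= 2 held-out
    prediction columns aligned with panel rows, ``coords`` site coordinates."""
    frame = panel[["site_id", "date", "concentration"]].copy()
    frame = pd.concat([frame.reset_index(drop=True), learner_preds.reset_index(drop=True)], axis=1)
    frame = frame.merge(coords[["site_id", "x", "y"]], on="site_id", how="left")
    chans = tuple(learner_preds.columns)
    est = EnsembleGAM(channels=chans, **options)
    est.fit(frame, frame["concentration"].to_numpy())
    est.frame_ = frame
    return est


def predict_hybrid(model, newdata: pd.DataFrame) -> pd.DataFrame:
    """Concentration-scale predictions for any fitted combination model."""
    out = newdata[["site_id", "date"]].copy() if {"site_id", "date"} <= set(newdata.columns) else pd.DataFrame(index=newdata.index)
    out["prediction"] = model.predict(newdata)
    return out
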