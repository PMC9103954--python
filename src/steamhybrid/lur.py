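"""Semiparametric spatio-temporal land-use regression (ST-LUR).

The model regresses (log-transformed, except for an ozone-like pollutant)
daily concentrations on land-use/traffic covariates entering linearly or as
penalized splines, smooth meteorology effects, calendar terms and a bivariate
penalized spatial smooth of the site coordinates.  Explanatory variables are
chosen by forward selection: at each step every unused candidate is tried in
its better-fitting form (linear vs spline, decided by adjusted-R²), the best
candidate is added if it raises adjusted-R² by more than 0.01 absolute and —
for spatial covariates — its linear coefficient conforms to the pre-declared
direction of effect; otherwise selection stops.  Spline smoothness is chosen
by REML, so adjusted-R² uses the smoothers' effective degrees of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, RegressorMixin

from ._pspline import AdditiveModel, FactorTerm, LinearTerm, SplineTerm, TensorTerm, Term

logger = logging.getLogger(__name__)

__all__ = ["Candidate", "STLandUseRegression", "make_model_frame", "default_candidates", "fit_st_lur", "predict_st_lur"]

SPATIAL_PREFIXES = ("TRAFMLOAD", "ROADLENGTH", "INVDIST", "URBAN", "TRAFINT")


@dataclass
class Candidate:
    """A selectable covariate: allowed functional forms and sign constraint."""

    name: str
    forms: tuple[str, ...] = ("linear", "spline")
    sign: str | None = None  # 'positive' | 'negative'; linear spatial terms only

    def make_term(self, form: str, n_splines: int) -> Term:
        if form == "linear":
            return LinearTerm(self.name, sign=self.sign)
        if form == "spline":
            return SplineTerm(self.name, n_splines=n_splines)
        if form == "factor":
            return FactorTerm(self.name)
        raise ValueError(f"unknown form {form!r}")


@dataclass
class SelectionStep:
    name: str
    form: str
    adj_r2: float
    gain: float
    coef_sign: float | None = None


def make_model_frame(
    panel: pd.DataFrame,
    sites: pd.DataFrame,
    covariates: pd.DataFrame,
    meteo: pd.DataFrame,
) -> pd.DataFrame:
    """Merge panel rows with site coordinates, covariates, meteorology and
    calendar columns (year, dow, day_count) into one modelling frame."""
    df = panel.merge(sites[["site_id", "x", "y"]], on="site_id", how="left")
    if df["x"].isna().any():
        bad = df.loc[df["x"].isna(), "site_id"].unique()
        raise ValueError(f"sites missing coordinates: {list(bad)[:5]}")
    df = df.merge(covariates, on="site_id", how="left")
    df = df.merge(meteo, on="date", how="left")
    dates = pd.DatetimeIndex(df["date"])
    df["year"] = dates.year
    df["dow"] = dates.dayofweek
    df["day_count"] = dates.dayofyear.astype(float)
    return df


def default_candidates(frame: pd.DataFrame) -> list[Candidate]:
    """Candidate pool mirroring the four covariate categories: buffer land
    use/traffic (sign-constrained positive), meteorology, calendar terms."""
    cands: list[Candidate] = []
    for col in frame.columns:
        if any(col.startswith(p) for p in SPATIAL_PREFIXES):
            cands.append(Candidate(col, forms=("linear", "spline"), sign="positive"))
    for col in ("temperature", "rel_humidity", "wind_speed", "pressure", "cloud", "wind_direction"):
        if col in frame.columns:
            cands.append(Candidate(col, forms=("linear", "spline")))
    if "dow" in frame.columns:
        cands.append(Candidate("dow", forms=("factor",)))
    if "day_count" in frame.columns:
        cands.append(Candidate("day_count", forms=("linear", "spline")))
    return cands


class STLandUseRegression(RegressorMixin, BaseEstimator):
    """Forward-selected semiparametric ST-LUR, sklearn-style.

    Parameters
    ----------
    candidates : list of Candidate or None
        Selectable covariates; ``None`` derives a default pool from the
        training frame's columns.
    link : {'log', 'identity'}
        Response transform; concentrations must be positive under ``'log'``.
    gain_threshold : float
        Absolute adjusted-R² gain a candidate must add to be retained.
    criterion : {'reml', 'gcv'}
        Smoothness-selection criterion for all penalized splines.
    spatial_basis : int
        Marginal basis size of the bivariate spatial tensor smooth.
    n_splines : int
        Basis size of univariate candidate splines.
    select : bool
        If False, fit the base model plus ``forced_terms`` only.
    forced_terms : list of (name, form) or Term
        Terms always present in addition to the spatial smooth and year
        indicators (e.g. known-structure fits or auxiliary smooths).
    year_factor : bool
        Include study-year indicator variables whenever the panel spans more
        than one calendar year (always retained, never selected away).
    """

    def __init__(
        self,
        candidates: list[Candidate] | None = None,
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
        self.candidates = candidates
        self.link = link
        self.gain_threshold = gain_threshold
        self.criterion = criterion
        self.spatial_basis = spatial_basis
        self.n_splines = n_splines
        self.select = select
        self.forced_terms = forced_terms
        self.max_terms = max_terms
        self.year_factor = year_factor
        self.min_sites = min_sites
        self.min_days = min_days

    # -- internals --------------------------------------------------------

    def _base_terms(self, X: pd.DataFrame) -> list[Term]:
        terms: list[Term] = [TensorTerm("x", "y", n_splines=self.spatial_basis)]
        if self.year_factor and "year" in X.columns and X["year"].nunique() > 1:
            terms.append(FactorTerm("year"))
        for ft in self.forced_terms or []:
            if isinstance(ft, Term):
                terms.append(ft)
            else:
                name, form = ft
                terms.append(Candidate(name).make_term(form, self.n_splines))
        return terms

    def _transform_y(self, y: np.ndarray) -> np.ndarray:
        if self.link == "log":
            if np.any(y <= 0):
                raise ValueError("log link requires strictly positive concentrations")
            return np.log(y)
        return np.asarray(y, dtype=float)

    def _warm_rho(self, fit, extra_penalized: int) -> np.ndarray:
        return np.concatenate([fit.log_lambda, np.full(extra_penalized, 2.0)])

    # -- sklearn API ------------------------------------------------------

    def fit(self, X: pd.DataFrame, y) -> "STLandUseRegression":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a model frame DataFrame (see make_model_frame)")
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if "site_id" in X.columns and X["site_id"].nunique() < self.min_sites:
            raise ValueError(f"need >= {self.min_sites} sites")
        if "date" in X.columns and X["date"].nunique() < self.min_days:
            raise ValueError(f"need >= {self.min_days} days")
        if self.link not in ("log", "identity"):
            raise ValueError("link must be 'log' or 'identity'")
        z = self._transform_y(y)

        terms = self._base_terms(X)
        fit = AdditiveModel(terms, criterion=self.criterion).fit(X, z)
        path: list[SelectionStep] = [SelectionStep("(base)", "-", fit.adj_r2, float("nan"))]

        if self.select:
            pool = list(self.candidates) if self.candidates is not None else default_candidates(X)
            in_model = {t.name for t in terms} | {getattr(t, "col", None) for t in terms}
            pool = [c for c in pool if c.name not in in_model and c.name in X.columns]
            while pool and (len(terms) - len(self._base_terms(X))) < self.max_terms:
                best: tuple[float, Candidate, str, object] | None = None
                for cand in pool:
                    for form in cand.forms:
                        term = cand.make_term(form, self.n_splines)
                        rho0 = self._warm_rho(fit, 1 if term.penalized else 0)
                        try:
                            trial = AdditiveModel(terms + [term], criterion=self.criterion).fit(
                                X, z, rho0=rho0
                            )
                        except (linalg.LinAlgError, np.linalg.LinAlgError):
                            logger.warning("candidate %s (%s) skipped: singular design", cand.name, form)
                            continue
                        if form == "linear" and cand.sign in ("positive", "negative"):
                            s = trial.coef_sign(cand.name)
                            want = 1.0 if cand.sign == "positive" else -1.0
                            if s * want < 0:
                                continue
                        gain = trial.adj_r2 - fit.adj_r2
                        if best is None or gain > best[0]:
                            best = (gain, cand, form, trial)
                if best is None or best[0] <= self.gain_threshold:
                    break
                gain, cand, form, trial = best
                terms = terms + [cand.make_term(form, self.n_splines)]
                terms[-1] = trial.blocks[-1].term  # keep the prepared instance
                fit = trial
                pool = [c for c in pool if c.name != cand.name]
                path.append(SelectionStep(cand.name, form, fit.adj_r2, gain))
                logger.info("selected %s (%s): adj-R2 %.4f (+%.4f)", cand.name, form, fit.adj_r2, gain)

        self.model_ = fit
        self.terms_ = fit.blocks
        self.selection_path_ = path
        self.adj_r2_ = fit.adj_r2
        self.residual_sd_ = float(np.sqrt(fit.sigma2))
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted")
        if len(X) == 0:
            return np.empty(0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            eta = self.model_.predict(X)
        return np.exp(eta) if self.link == "log" else eta

    def coef_table(self) -> pd.DataFrame:
        """Original-scale coefficients and SEs of linear terms in the fit."""
        return self.model_.coef_table()


def fit_st_lur(panel, sites, covariates, meteo, **options) -> STLandUseRegression:
    """Convenience wrapper: build the model frame and fit the estimator."""
    frame = make_model_frame(panel, sites, covariates, meteo)
    est = STLandUseRegression(**options)
    est.fit(frame, frame["concentration"].to_numpy())
    est.frame_ = frame
    return est


def predict_st_lur(model: STLandUseRegression, points, dates, covariates, meteo) -> pd.DataFrame:
    """Predict concentrations at arbitrary points x dates."""
    grid = points[["site_id"]].merge(pd.DataFrame({"date": dates}), how="cross")
    panel = grid.assign(pollutant="", concentration=np.nan)
    frame = make_model_frame(panel, points, covariates, meteo)
    out = grid[["site_id", "date"]].copy()
    out["prediction"] = model.predict(frame)
    return out
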