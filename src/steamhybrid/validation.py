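"""Leave-site-out cross-validation and the overall/temporal/spatial
performance decomposition.

Sites — not rows — are partitioned into k folds so held-out predictions are
made at locations the model never saw.  Overall fit is the squared Pearson
correlation between pooled held-out predictions and observations on the
concentration scale; temporal validity regresses daily deviations from
site-year annual means (predicted on observed, pooled over sites); spatial
validity regresses site-year annual-mean predictions on annual-mean
observations across sites.  Mean bias is observed minus predicted throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "assign_site_folds",
    "crossval",
    "overall_metrics",
    "temporal_validity_r2",
    "spatial_validity_r2",
    "CVResult",
]


def assign_site_folds(sites: pd.DataFrame, k: int = 10, seed: int = 0) -> pd.Series:
    """Random balanced site -> fold (1..k) partition, reproducible by seed."""
    ids = sites["site_id"].to_numpy() if isinstance(sites, pd.DataFrame) else np.asarray(sites)
    n = len(ids)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of sites ({n})")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k), start=1):
        folds[chunk] = f
    return pd.Series(folds, index=ids, name="fold")


@dataclass
class CVResult:
    """Held-out predictions and the three-way performance decomposition."""

    predictions: pd.DataFrame  # site_id, date, observed, predicted, fold
    r2: float
    rmse: float
    mean_bias: float
    temporal_r2: float
    spatial_r2: float
    folds: pd.Series = field(repr=False, default=None)
    seed: int | None = None

    def summary(self) -> dict:
        return {
            "cv_r2": self.r2,
            "rmse": self.rmse,
            "mean_bias": self.mean_bias,
            "temporal_r2": self.temporal_r2,
            "spatial_r2": self.spatial_r2,
        }


def overall_metrics(observed, predicted, r2_method: str = "corr") -> dict:
    """Pooled R², RMSE and mean bias (observed - predicted)."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if len(o) != len(p) or len(o) == 0:
        raise ValueError("observed and predicted must be aligned and nonempty")
    if o.std() == 0 or p.std() == 0:
        raise ValueError("R^2 undefined: zero variance input")
    if r2_method == "corr":
        r2 = float(stats.pearsonr(o, p).statistic ** 2)
    elif r2_method == "ss":
        r2 = 1.0 - float(((o - p) ** 2).sum() / ((o - o.mean()) ** 2).sum())
    else:
        raise ValueError("r2_method must be 'corr' or 'ss'")
    return {
        "r2": r2,
        "rmse": float(np.sqrt(np.mean((o - p) ** 2))),
        "mean_bias": float(np.mean(o - p)),
    }


def _annual_deviations(panel: pd.DataFrame, value: str) -> pd.DataFrame:
    df = panel.copy()
    df["year"] = pd.DatetimeIndex(df["date"]).year
    grp = df.groupby(["site_id", "year"])[value]
    df["annual_mean"] = grp.transform("mean")
    df["n_days"] = grp.transform("size")
    return df


def temporal_validity_r2(observed: pd.DataFrame, predicted: pd.DataFrame, per_site: bool = False) -> float:
    """R² of daily predicted deviations from site-year annual means regressed
    on the corresponding observed deviations (pooled over sites by default)."""
    obs = _annual_deviations(observed.rename(columns={observed.columns[-1]: "value"}), "value")
    pre = _annual_deviations(predicted.rename(columns={predicted.columns[-1]: "value"}), "value")
    m = obs.merge(pre, on=["site_id", "date"], suffixes=("_obs", "_pred"))
    m = m[m["n_days_obs"] > 1]
    if (single := observed.groupby("site_id").size() == 1).any():
        logger.warning("skipping %d single-day site(s) in temporal validity", int(single.sum()))
    m["dx"] = m["value_obs"] - m["annual_mean_obs"]
    m["dy"] = m["value_pred"] - m["annual_mean_pred"]
    if per_site:
        vals = []
        for _, g in m.groupby("site_id"):
            if g["dx"].std() > 0 and g["dy"].std() > 0:
                vals.append(float(stats.pearsonr(g["dx"], g["dy"]).statistic ** 2))
        return float(np.mean(vals))
    return float(stats.pearsonr(m["dx"], m["dy"]).statistic ** 2)


def spatial_validity_r2(observed: pd.DataFrame, predicted: pd.DataFrame) -> float:
    """R² of the cross-site regression of annual-mean predicted on annual-mean
    observed concentrations (site-year pairs pooled for multi-year panels)."""
    if observed["site_id"].nunique() < 3:
        raise ValueError("spatial validity needs >= 3 sites")
    obs = _annual_deviations(observed.rename(columns={observed.columns[-1]: "value"}), "value")
    pre = _annual_deviations(predicted.rename(columns={predicted.columns[-1]: "value"}), "value")
    ao = obs.groupby(["site_id", "year"])["annual_mean"].first()
    ap = pre.groupby(["site_id", "year"])["annual_mean"].first()
    m = pd.concat([ao, ap], axis=1, keys=["obs", "pred"]).dropna()
    return float(stats.pearsonr(m["obs"], m["pred"]).statistic ** 2)


def crossval(
    recipe,
    frame: pd.DataFrame,
    y=None,
    k: int = 10,
    seed: int = 0,
    folds: pd.Series | None = None,
) -> CVResult:
    """Leave-site-out k-fold CV of a model-fitting recipe.

    ``recipe`` is an sklearn-style estimator (cloned per fold via
    get_params/set_params); ``frame`` the full model frame with ``site_id``,
    ``date`` and ``concentration`` columns (or ``y`` given separately).
    """
    from sklearn.base import clone

    if y is None:
        y = frame["concentration"].to_numpy()
    y = np.asarray(y, dtype=float)
    sites = frame[["site_id"]].drop_duplicates()
    if folds is None:
        folds = assign_site_folds(sites, k=k, seed=seed)
    fold_of_row = frame["site_id"].map(folds).to_numpy()
    preds = np.full(len(frame), np.nan)
    for f in sorted(pd.unique(folds)):
        tr = fold_of_row != f
        te = ~tr
        est = clone(recipe)
        try:
            est.fit(frame.loc[tr], y[tr])
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"model fit failed on fold {f}: {exc}") from exc
        preds[te] = est.predict(frame.loc[te])
    out = frame[["site_id", "date"]].copy()
    out["observed"] = y
    out["predicted"] = preds
    out["fold"] = fold_of_row
    m = overall_metrics(out["observed"], out["predicted"])
    t_r2 = temporal_validity_r2(
        out[["site_id", "date", "observed"]], out[["site_id", "date", "predicted"]]
    )
    s_r2 = spatial_validity_r2(
        out[["site_id", "date", "observed"]], out[["site_id", "date", "predicted"]]
    )
    return CVResult(
        predictions=out,
        r2=m["r2"],
        rmse=m["rmse"],
        mean_bias=m["mean_bias"],
        temporal_r2=t_r2,
        spatial_r2=s_r2,
        folds=folds,
        seed=seed,
    )
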