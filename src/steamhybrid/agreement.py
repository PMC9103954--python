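"""Method-agreement statistics: Lin's concordance correlation coefficient,
Pearson correlation, and Bland–Altman mean difference with 95% limits of
agreement, evaluated at the spatial level (per-location annual means) and the
temporal level (daily area-wide mean series).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["lins_ccc", "bland_altman", "spatial_temporal_agreement", "AgreementResult"]


def lins_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    ccc = 2*cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2), with
    population (1/n) moments per Lin's original definition.  Penalizes both
    imprecision (scatter) and location/scale shift, so |ccc| <= |r|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("x and y must be nonempty and equal-length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    vx, vy = x.var(), y.var()  # numpy default: population (1/n)
    if vx == 0 and vy == 0:
        raise ValueError("CCC undefined: both inputs are constant")
    cxy = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2 * cxy / (vx + vy + (x.mean() - y.mean()) ** 2))


def bland_altman(x, y) -> dict:
    """Mean difference and 95% limits of agreement mean(d) +/- 1.96*sd(d),
    with the n-1 sample SD of the paired differences d = x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need >= 2 aligned pairs")
    d = x - y
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    return {"mean_diff": md, "loa_low": md - 1.96 * sd, "loa_high": md + 1.96 * sd}


@dataclass
class AgreementResult:
    level: str  # 'spatial' | 'temporal'
    n: int
    ccc: float
    pearson_r: float
    mean_diff: float
    loa_low: float
    loa_high: float

    def to_dict(self) -> dict:
        return asdict(self)


def _agreement(x: np.ndarray, y: np.ndarray, level: str) -> AgreementResult:
    ba = bland_altman(x, y)
    return AgreementResult(
        level=level,
        n=len(x),
        ccc=lins_ccc(x, y),
        pearson_r=float(stats.pearsonr(x, y).statistic),
        **ba,
    )


def spatial_temporal_agreement(
    panel_a: pd.DataFrame,
    panel_b: pd.DataFrame,
    value: str = "prediction",
    temporal_mode: str = "area_mean",
) -> tuple[AgreementResult, AgreementResult]:
    """Agreement between two prediction panels at two levels.

    Spatial: per-location annual means compared across locations (pooled over
    years for multi-year panels).  Temporal: the daily area-wide mean series
    of the two methods compared day by day (``temporal_mode='pooled'``
    compares all (location, day) pairs instead).
    """
    key = ["site_id", "date"] if "site_id" in panel_a.columns else ["area_id", "date"]
    loc = key[0]
    m = panel_a.merge(panel_b, on=key, suffixes=("_a", "_b"))
    if len(m) != len(panel_a) or len(m) != len(panel_b):
        raise ValueError("panels are not aligned on locations x dates")
    va, vb = f"{value}_a", f"{value}_b"
    yr = pd.DatetimeIndex(m["date"]).year
    ann = m.groupby([m[loc], yr])[[va, vb]].mean()
    spatial = _agreement(ann[va].to_numpy(), ann[vb].to_numpy(), "spatial")
    if temporal_mode == "area_mean":
        daily = m.groupby("date")[[va, vb]].mean()
        temporal = _agreement(daily[va].to_numpy(), daily[vb].to_numpy(), "temporal")
    elif temporal_mode == "pooled":
        temporal = _agreement(m[va].to_numpy(), m[vb].to_numpy(), "temporal")
    else:
        raise ValueError("temporal_mode must be 'area_mean' or 'pooled'")
    return spatial, temporal
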