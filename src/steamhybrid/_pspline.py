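"""Penalized-spline additive model engine.

Gaussian additive models built from linear terms, factor (dummy) terms,
univariate P-splines and bivariate tensor-product P-splines.  Smoothing
parameters are chosen by restricted maximum likelihood (REML) or generalized
cross-validation (GCV); per-term effective degrees of freedom come from the
trace of the hat matrix, which is what the adjusted-R² used by the forward
selection needs.

The construction follows the standard P-spline recipe: cubic B-spline bases on
equally spaced knots with a second-order difference penalty, sum-to-zero
centring constraints absorbed by a null-space reparameterisation so every
smooth is identifiable next to the intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.interpolate import BSpline

__all__ = [
    "LinearTerm",
    "FactorTerm",
    "SplineTerm",
    "TensorTerm",
    "AdditiveModel",
    "AdditiveFit",
]


def _bspline_design(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    """Dense B-spline design matrix; x is clipped to the knot span."""
    lo, hi = knots[degree], knots[-degree - 1]
    xc = np.clip(x, lo, hi)
    return BSpline.design_matrix(xc, knots, degree).toarray()


def _uniform_knots(lo: float, hi: float, n_splines: int, degree: int) -> np.ndarray:
    if hi <= lo:
        hi = lo + 1.0
    n_interior = n_splines - degree - 1
    step = (hi - lo) / (n_interior + 1)
    inner = np.linspace(lo, hi, n_interior + 2)
    left = lo - step * np.arange(degree, 0, -1)
    right = hi + step * np.arange(1, degree + 1)
    return np.concatenate([left, inner, right])


def _diff_penalty(k: int, order: int = 2) -> np.ndarray:
    d = np.diff(np.eye(k), n=order, axis=0)
    return d.T @ d


def _centering_transform(colmeans: np.ndarray) -> np.ndarray:
    """Null-space basis Z with colmeans @ Z = 0 (sum-to-zero constraint)."""
    c = colmeans.reshape(-1, 1)
    q, _ = np.linalg.qr(c, mode="complete")
    return q[:, 1:]


class Term:
    """Abstract design-block builder. Subclasses fill `k_` and transforms."""

    name: str
    penalized: bool = False

    def prepare(self, df: pd.DataFrame) -> None:  # pragma: no cover - abstract
        raise NotImplementedError

    def design(self, df: pd.DataFrame) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def penalty(self) -> np.ndarray | None:
        return None

    def _col(self, df: pd.DataFrame, name: str) -> np.ndarray:
        if name not in df.columns:
            raise KeyError(f"required covariate {name!r} missing from data")
        v = np.asarray(df[name], dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"covariate {name!r} contains non-finite values")
        return v


class LinearTerm(Term):
    def __init__(self, col: str, sign: str | None = None):
        self.col = col
        self.sign = sign  # 'positive' | 'negative' | None, checked by selection
        self.name = col

    def prepare(self, df: pd.DataFrame) -> None:
        v = self._col(df, self.col)
        self.center_ = float(v.mean())
        sd = float(v.std())
        self.scale_ = sd if sd > 0 else 1.0
        self.k_ = 1

    def design(self, df: pd.DataFrame) -> np.ndarray:
        v = self._col(df, self.col)
        return ((v - self.center_) / self.scale_)[:, None]


class FactorTerm(Term):
    """Dummy coding, first observed level as reference."""

    def __init__(self, col: str):
        self.col = col
        self.name = col

    def prepare(self, df: pd.DataFrame) -> None:
        if self.col not in df.columns:
            raise KeyError(f"required covariate {self.col!r} missing from data")
        self.levels_ = list(pd.unique(df[self.col]))
        self.k_ = max(len(self.levels_) - 1, 0)

    def design(self, df: pd.DataFrame) -> np.ndarray:
        vals = df[self.col]
        unseen = set(pd.unique(vals)) - set(self.levels_)
        if unseen:
            raise ValueError(f"unseen level(s) {sorted(map(str, unseen))} for factor {self.col!r}")
        out = np.zeros((len(df), self.k_))
        for j, lev in enumerate(self.levels_[1:]):
            out[:, j] = (vals == lev).to_numpy(dtype=float)
        return out


class SplineTerm(Term):
    """Centred univariate cubic P-spline."""

    penalized = True

    def __init__(self, col: str, n_splines: int = 10, degree: int = 3, diff_order: int = 2):
        self.col = col
        self.n_splines = n_splines
        self.degree = degree
        self.diff_order = diff_order
        self.name = f"s({col})"

    def prepare(self, df: pd.DataFrame) -> None:
        v = self._col(df, self.col)
        if v.max() == v.min():
            # constant column carries no information; contribute nothing
            warnings.warn(f"covariate {self.col!r} is constant; smooth dropped", stacklevel=2)
            self.degenerate_ = True
            self.k_ = 0
            return
        self.degenerate_ = False
        self.knots_ = _uniform_knots(float(v.min()), float(v.max()), self.n_splines, self.degree)
        b = _bspline_design(v, self.knots_, self.degree)
        self.Z_ = _centering_transform(b.mean(axis=0))
        s = _diff_penalty(self.n_splines, self.diff_order)
        self.S_ = self.Z_.T @ s @ self.Z_
        self.k_ = self.Z_.shape[1]

    def design(self, df: pd.DataFrame) -> np.ndarray:
        v = self._col(df, self.col)
        if self.degenerate_:
            return np.empty((len(v), 0))
        lo, hi = self.knots_[self.degree], self.knots_[-self.degree - 1]
        if v.min() < lo - 1e-12 or v.max() > hi + 1e-12:
            warnings.warn(
                f"values of {self.col!r} outside the fitted range "
                f"[{lo:.4g}, {hi:.4g}]; clamped to the boundary basis",
                stacklevel=2,
            )
        return _bspline_design(v, self.knots_, self.degree) @ self.Z_

    def penalty(self) -> np.ndarray:
        return self.S_


class TensorTerm(Term):
    """Centred bivariate tensor-product P-spline (isotropic single penalty).

    Used for the spatial smooth h(x, y); the single smoothing parameter
    multiplies S_x (x) I + I (x) S_y, appropriate when both coordinates share
    units (planar metres here).
    """

    penalized = True

    def __init__(self, xcol: str, ycol: str, n_splines: int = 6, degree: int = 3, diff_order: int = 2):
        self.xcol, self.ycol = xcol, ycol
        self.n_splines = n_splines
        self.degree = degree
        self.diff_order = diff_order
        self.name = f"te({xcol},{ycol})"

    def _marginal(self, df: pd.DataFrame, col: str, knots: np.ndarray) -> np.ndarray:
        return _bspline_design(self._col(df, col), knots, self.degree)

    def prepare(self, df: pd.DataFrame) -> None:
        x = self._col(df, self.xcol)
        y = self._col(df, self.ycol)
        self.kx_ = _uniform_knots(float(x.min()), float(x.max()), self.n_splines, self.degree)
        self.ky_ = _uniform_knots(float(y.min()), float(y.max()), self.n_splines, self.degree)
        bx = _bspline_design(x, self.kx_, self.degree)
        by = _bspline_design(y, self.ky_, self.degree)
        raw = _row_kron(bx, by)
        self.Z_ = _centering_transform(raw.mean(axis=0))
        m = self.n_splines
        s1 = _diff_penalty(m, self.diff_order)
        s = np.kron(s1, np.eye(m)) + np.kron(np.eye(m), s1)
        self.S_ = self.Z_.T @ s @ self.Z_
        self.k_ = self.Z_.shape[1]

    def design(self, df: pd.DataFrame) -> np.ndarray:
        bx = self._marginal(df, self.xcol, self.kx_)
        by = self._marginal(df, self.ycol, self.ky_)
        return _row_kron(bx, by) @ self.Z_

    def penalty(self) -> np.ndarray:
        return self.S_


def _row_kron(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a[:, :, None] * b[:, None, :]).reshape(a.shape[0], -1)


@dataclass
class _Block:
    term: Term
    sl: slice
    S: np.ndarray | None = None
    rank: int = 0
    logdet_plus: float = 0.0


@dataclass
class AdditiveFit:
    """Fitted Gaussian additive model (result object of :class:`AdditiveModel`)."""

    terms: list[Term]
    blocks: list[_Block] = field(repr=False)
    beta: np.ndarray = field(repr=False)
    log_lambda: np.ndarray
    cov: np.ndarray = field(repr=False)
    edf_by_term: dict[str, float] = field(default_factory=dict)
    edf_total: float = 0.0
    sigma2: float = float("nan")
    rss: float = float("nan")
    adj_r2: float = float("nan")
    r2: float = float("nan")
    nobs: int = 0
    criterion: str = "reml"

    def design(self, df: pd.DataFrame) -> np.ndarray:
        cols = [np.ones((len(df), 1))]
        cols += [b.term.design(df) for b in self.blocks]
        return np.hstack(cols)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        if len(df) == 0:
            return np.empty(0)
        return self.design(df) @ self.beta

    def term_effect(self, df: pd.DataFrame, name: str) -> np.ndarray:
        for b in self.blocks:
            if b.term.name == name:
                return b.term.design(df) @ self.beta[b.sl]
        raise KeyError(name)

    def coef_table(self) -> pd.DataFrame:
        """Original-scale coefficients and standard errors of linear terms."""
        rows = []
        for b in self.blocks:
            t = b.term
            if isinstance(t, LinearTerm):
                i = b.sl.start
                rows.append(
                    {
                        "term": t.name,
                        "coef": self.beta[i] / t.scale_,
                        "se": float(np.sqrt(self.cov[i, i])) / t.scale_,
                    }
                )
        return pd.DataFrame(rows)

    def coef_sign(self, name: str) -> float:
        for b in self.blocks:
            if b.term.name == name and isinstance(b.term, LinearTerm):
                return float(np.sign(self.beta[b.sl.start]))
        raise KeyError(name)


class AdditiveModel:
    """Gaussian additive model with REML/GCV smoothness selection.

    Parameters
    ----------
    terms : sequence of Term
        Design blocks; an intercept is always prepended.
    criterion : {'reml', 'gcv'}
        Smoothing-parameter selection criterion.
    """

    LOG_LAMBDA_BOUNDS = (-7.0, 16.0)

    def __init__(self, terms: Sequence[Term], criterion: str = "reml"):
        if criterion not in ("reml", "gcv"):
            raise ValueError("criterion must be 'reml' or 'gcv'")
        self.terms = list(terms)
        self.criterion = criterion

    # -- assembly ---------------------------------------------------------

    def _assemble(self, df: pd.DataFrame) -> tuple[np.ndarray, list[_Block]]:
        blocks: list[_Block] = []
        cols = [np.ones((len(df), 1))]
        pos = 1
        for t in self.terms:
            t.prepare(df)
            x = t.design(df)
            k = x.shape[1]
            if k == 0:
                continue
            b = _Block(term=t, sl=slice(pos, pos + k))
            if t.penalized:
                s = t.penalty()
                ev = np.linalg.eigvalsh(s)
                tol = max(ev.max(), 1.0) * 1e-10
                pos_ev = ev[ev > tol]
                b.S = s
                b.rank = len(pos_ev)
                b.logdet_plus = float(np.log(pos_ev).sum())
            blocks.append(b)
            cols.append(x)
            pos += k
        return np.hstack(cols), blocks

    # -- criterion evaluation ---------------------------------------------

    @staticmethod
    def _penalty_total(p: int, blocks: list[_Block], rho: np.ndarray) -> np.ndarray:
        s = np.zeros((p, p))
        j = 0
        for b in blocks:
            if b.S is not None:
                s[b.sl, b.sl] += np.exp(rho[j]) * b.S
                j += 1
        return s

    def _objective(self, rho, xtx, xty, yty, n, blocks, pen_blocks):
        p = xtx.shape[0]
        a = xtx + self._penalty_total(p, blocks, rho)
        ridge = 1e-10 * max(np.trace(xtx) / p, 1.0)
        try:
            c, low = linalg.cho_factor(a + ridge * np.eye(p), lower=True)
        except linalg.LinAlgError:
            try:
                c, low = linalg.cho_factor(a + 1e-4 * np.trace(a) / p * np.eye(p), lower=True)
            except linalg.LinAlgError:
                return 1e30
        beta = linalg.cho_solve((c, low), xty)
        rss = float(yty - 2 * beta @ xty + beta @ xtx @ beta)
        rss = max(rss, 1e-300)
        if self.criterion == "gcv":
            tr_h = float(np.trace(linalg.cho_solve((c, low), xtx)))
            denom = max(n - tr_h, 1e-8)
            return n * rss / denom**2
        pen = 0.0
        m_null = p
        logdet_s = 0.0
        j = 0
        for b in blocks:
            if b.S is not None:
                bb = beta[b.sl]
                pen += np.exp(rho[j]) * float(bb @ b.S @ bb)
                m_null -= b.rank
                logdet_s += b.rank * rho[j] + b.logdet_plus
                j += 1
        n1 = n - m_null
        logdet_a = 2.0 * float(np.log(np.diag(c)).sum())
        return n1 * np.log(max(rss + pen, 1e-300)) + logdet_a - logdet_s

    # -- fitting -----------------------------------------------------------

    def fit(self, df: pd.DataFrame, y: np.ndarray, rho0: np.ndarray | None = None) -> AdditiveFit:
        y = np.asarray(y, dtype=float)
        n = len(y)
        if len(df) != n:
            raise ValueError("df and y have different lengths")
        x, blocks = self._assemble(df)
        p = x.shape[1]
        if n <= p - sum(b.rank for b in blocks if b.S is not None):
            raise ValueError("more unpenalized coefficients than observations")
        xtx = x.T @ x
        xty = x.T @ y
        yty = float(y @ y)
        n_pen = sum(1 for b in blocks if b.S is not None)

        lo, hi = self.LOG_LAMBDA_BOUNDS
        if n_pen == 0:
            rho = np.empty(0)
        else:
            if rho0 is not None and len(rho0) == n_pen:
                start = np.clip(np.asarray(rho0, dtype=float), lo, hi)
            else:
                start = np.full(n_pen, 2.0)
            obj = lambda r: self._objective(np.clip(r, lo, hi), xtx, xty, yty, n, blocks, n_pen)
            if n_pen == 1:
                res = optimize.minimize_scalar(lambda r: obj(np.array([r])), bounds=(lo, hi), method="bounded")
                rho = np.array([res.x])
            else:
                res = optimize.minimize(
                    obj, start, method="Nelder-Mead",
                    options={"xatol": 0.05, "fatol": 1e-7, "maxiter": 200 * n_pen},
                )
                rho = np.clip(res.x, lo, hi)

        a = xtx + self._penalty_total(p, blocks, rho)
        # tiny adaptive ridge keeps the factorization viable under exact
        # collinearity (degenerate designs); ~1e-10 relative perturbation
        ridge = 1e-10 * max(np.trace(xtx) / p, 1.0)
        for _ in range(6):
            try:
                c, low = linalg.cho_factor(a + ridge * np.eye(p), lower=True)
                break
            except linalg.LinAlgError:
                ridge *= 100.0
        else:
            raise linalg.LinAlgError("singular design (collinear terms)")
        beta = linalg.cho_solve((c, low), xty)
        a_inv_xtx = linalg.cho_solve((c, low), xtx)
        edf_cols = np.diag(a_inv_xtx)
        edf_total = float(edf_cols.sum())
        resid = y - x @ beta
        rss = float(resid @ resid)
        sigma2 = rss / max(n - edf_total, 1.0)
        cov = sigma2 * linalg.cho_solve((c, low), np.eye(p))
        tss = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - rss / tss if tss > 0 else float("nan")
        adj_r2 = (
            1.0 - (rss / max(n - edf_total, 1.0)) / (tss / (n - 1)) if tss > 0 and n > 1 else float("nan")
        )
        edf_by_term = {"(intercept)": float(edf_cols[0])}
        for b in blocks:
            edf_by_term[b.term.name] = float(edf_cols[b.sl].sum())
        return AdditiveFit(
            terms=self.terms,
            blocks=blocks,
            beta=beta,
            log_lambda=rho,
            cov=cov,
            edf_by_term=edf_by_term,
            edf_total=edf_total,
            sigma2=sigma2,
            rss=rss,
            adj_r2=adj_r2,
            r2=r2,
            nobs=n,
            criterion=self.criterion,
        )
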