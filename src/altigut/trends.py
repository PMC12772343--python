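"""Altitude-response trend models and feature screens.

Four model families are fitted against altitude (or any continuous
predictor):

* simple linear regression (OLS);
* continuous piecewise-linear regression with 1-2 breakpoints psi,
  estimated by exhaustive grid search minimising RSS;
* natural cubic regression splines with knots at x-quantiles, the knot
  count selected by generalised cross-validation
  GCV = n * RSS / (n - tr(H))^2;
* cubic polynomial regression on an orthogonalised basis.

Feature screens compute per-feature Spearman correlations with altitude
and Benjamini-Hochberg adjusted p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

DEFAULT_KNOT_CANDIDATES = tuple(range(3, 11))


@dataclass
class TrendFit:
    """One fitted gradient model."""

    model: str  # linear | piecewise | spline | cubic
    coefficients: np.ndarray
    r2: float
    p_value: float
    rss: float
    n: int
    edf: float
    breakpoints: tuple = ()
    knots: tuple = ()
    gcv: float | None = None
    x_range: tuple = (0.0, 1.0)
    _predict: Callable = field(default=None, repr=False, compare=False)

    def predict(self, x) -> np.ndarray:
        return self._predict(np.asarray(x, dtype=float))

    def argmax(self, n_grid: int = 2001) -> float:
        """Location of the fitted curve's maximum over the observed x-range."""
        grid = np.linspace(self.x_range[0], self.x_range[1], n_grid)
        return float(grid[np.argmax(self.predict(grid))])

    def argmin(self, n_grid: int = 2001) -> float:
        grid = np.linspace(self.x_range[0], self.x_range[1], n_grid)
        return float(grid[np.argmin(self.predict(grid))])

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "coefficients": np.asarray(self.coefficients, dtype=float).tolist(),
            "breakpoints_psi": list(self.breakpoints),
            "knots": list(self.knots),
            "r2": self.r2,
            "p_value": self.p_value,
            "gcv": self.gcv,
            "edf": self.edf,
            "rss": self.rss,
            "n": self.n,
        }


def _as_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def fit_linear(x, y) -> TrendFit:
    """Ordinary least squares y ~ x with slope t-test."""
    x, y = _as_xy(x, y)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; linear fit undefined")
    res = stats.linregress(x, y)
    yhat = res.intercept + res.slope * x
    rss = float(((y - yhat) ** 2).sum())
    coeffs = np.array([res.intercept, res.slope])
    return TrendFit(
        model="linear",
        coefficients=coeffs,
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        rss=rss,
        n=n,
        edf=2.0,
        x_range=(float(x.min()), float(x.max())),
        _predict=lambda g, a=res.intercept, b=res.slope: a + b * g,
    )


def _piecewise_design(x: np.ndarray, psis: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for p in psis:
        cols.append(np.maximum(0.0, x - p))
    return np.column_stack(cols)


def _breakpoint_grid(x: np.ndarray) -> np.ndarray:
    xr = float(np.ptp(x))
    step = min(25.0, xr / 200.0)
    lo = x.min() + 0.10 * xr
    hi = x.max() - 0.10 * xr
    return np.arange(lo, hi + 0.5 * step, step)


def fit_piecewise(x, y, k_breakpoints: int = 1) -> TrendFit:
    """Continuous piecewise-linear fit with k in {1, 2} breakpoints.

    Breakpoints are found by exhaustive search over a grid restricted to
    the central 80% of the x-range (step = min(25, range/200); for k=2
    the breakpoints must be at least 10% of the range apart), minimising
    RSS.  Significance is an F-test against the plain linear fit.
    """
    x, y = _as_xy(x, y)
    k = int(k_breakpoints)
    n = x.size
    if k not in (1, 2):
        raise ValueError("k_breakpoints must be 1 or 2")
    if n < 10 + 2 * k:
        raise ValueError(f"need at least {10 + 2 * k} points for k={k}")
    if np.ptp(x) == 0:
        raise ValueError("x has zero span")
    grid = _breakpoint_grid(x)
    if grid.size == 0:
        raise ValueError("no admissible breakpoint grid point")
    if k == 1:
        cand = grid[:, None]
    else:
        xr = float(np.ptp(x))
        i, j = np.meshgrid(np.arange(grid.size), np.arange(grid.size), indexing="ij")
        mask = (grid[j] - grid[i]) >= 0.10 * xr
        cand = np.column_stack([grid[i[mask]], grid[j[mask]]])
        if cand.size == 0:
            raise ValueError("no admissible breakpoint pair on grid")

    # standardised coordinates keep the batched normal equations well
    # conditioned; psi candidates map back to the original scale
    mu, sd = float(x.mean()), float(x.std())
    z = (x - mu) / sd
    yc = y - y.mean()
    cand_z = (cand - mu) / sd
    p = 2 + k
    m = cand.shape[0]
    X = np.empty((m, n, p))
    X[:, :, 0] = 1.0
    X[:, :, 1] = z
    for c in range(k):
        X[:, :, 2 + c] = np.maximum(0.0, z[None, :] - cand_z[:, c, None])
    G = np.einsum("mnp,mnq->mpq", X, X)
    # tiny ridge keeps degenerate candidates (no data beyond psi) solvable
    G += 1e-10 * n * np.eye(p)
    b = np.einsum("mnp,n->mp", X, yc)
    beta = np.linalg.solve(G, b[..., None])[..., 0]
    rss_all = float((yc**2).sum()) - np.einsum("mp,mp->m", beta, b)
    best = int(np.argmin(rss_all))
    psis = tuple(float(v) for v in cand[best])

    Xb = _piecewise_design(x, np.asarray(psis))
    coef, _, _, _ = np.linalg.lstsq(Xb, y, rcond=None)
    resid = y - Xb @ coef
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0

    lin = fit_linear(x, y)
    df_extra = 2 * k  # one slope change + one breakpoint per segment boundary
    df_resid = n - (2 + 2 * k)
    if rss <= 0:
        p_value = 0.0
    else:
        F = ((lin.rss - rss) / df_extra) / (rss / df_resid)
        p_value = float(stats.f.sf(max(F, 0.0), df_extra, df_resid))

    def _pred(g, c=coef, ps=np.asarray(psis)):
        return _piecewise_design(np.atleast_1d(g), ps) @ c

    return TrendFit(
        model="piecewise",
        coefficients=coef,
        r2=r2,
        p_value=p_value,
        rss=rss,
        n=n,
        edf=float(2 + 2 * k),
        breakpoints=psis,
        x_range=(float(x.min()), float(x.max())),
        _predict=_pred,
    )


def select_breakpoint_count(x, y, k_max: int = 2) -> int:
    """Smallest adequate breakpoint count by BIC (2 + 2k mean parameters
    plus the variance); k increases only while BIC improves by > 2."""
    x, y = _as_xy(x, y)
    n = x.size

    def bic(rss: float, k: int) -> float:
        rss = max(rss, 1e-300)
        return n * np.log(rss / n) + (3 + 2 * k) * np.log(n)

    best_k = 0
    current = bic(fit_linear(x, y).rss, 0)
    for k in range(1, k_max + 1):
        if n < 10 + 2 * k:
            break
        try:
            cand = bic(fit_piecewise(x, y, k).rss, k)
        except ValueError:
            break
        if cand < current - 2.0:
            best_k, current = k, cand
        else:
            break
    return best_k


def natural_cubic_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (truncated-power form) with K knots.

    Columns: 1, x, and K-2 natural basis functions; linear beyond the
    boundary knots.  Basis dimension equals the number of knots.
    """
    knots = np.asarray(knots, dtype=float)
    K = knots.size
    if K < 3:
        raise ValueError("need at least 3 knots")

    def cube(v):
        return np.maximum(v, 0.0) ** 3

    xiK, xiK1 = knots[-1], knots[-2]

    def d(j):
        return (cube(x - knots[j]) - cube(x - xiK)) / (xiK - knots[j])

    dlast = d(K - 2)
    cols = [np.ones_like(x), x] + [d(j) - dlast for j in range(K - 2)]
    return np.column_stack(cols)


def fit_spline_gcv(x, y, candidate_knot_counts: Sequence[int] = DEFAULT_KNOT_CANDIDATES) -> TrendFit:
    """Natural cubic regression spline; knot count chosen by GCV.

    Knots are placed at equally spaced quantiles of x (boundary knots at
    the extremes).  Each candidate count is fitted by least squares;
    GCV = n*RSS/(n - tr(H))^2 with tr(H) the basis rank; the fit with
    the smallest GCV wins.  The reported edf is tr(H) - 1 (the smooth
    term's degrees of freedom, excluding the intercept); significance is
    an approximate F-test against the intercept-only model.
    """
    x, y = _as_xy(x, y)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 points")
    counts = sorted({int(c) for c in candidate_knot_counts})
    if not counts or counts[0] < 3 or counts[-1] > 10:
        raise ValueError("candidate knot counts must lie in 3..10")

    # standardise x for numerical conditioning of the cubic terms
    mu, sd = float(x.mean()), float(x.std())
    if sd == 0:
        raise ValueError("x is constant")
    z = (x - mu) / sd
    tss = float(((y - y.mean()) ** 2).sum())

    best = None
    for K in counts:
        knots_z = np.quantile(z, np.linspace(0, 1, K))
        if np.unique(knots_z).size < K:
            continue
        B = natural_cubic_basis(z, knots_z)
        coef, _, rank, sv = np.linalg.lstsq(B, y, rcond=None)
        if rank < B.shape[1] or (sv.size and sv[0] / sv[-1] > 1e10):
            continue  # ill-conditioned candidate
        resid = y - B @ coef
        rss = float(resid @ resid)
        tr_h = float(rank)
        gcv = n * rss / (n - tr_h) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, K, knots_z, coef, rss, tr_h)
    if best is None:
        raise ValueError("all spline bases ill-conditioned; try fewer knots")

    gcv, K, knots_z, coef, rss, tr_h = best
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    df1 = tr_h - 1.0
    df2 = n - tr_h
    if tss <= rss or rss <= 0:
        p_value = 1.0 if rss > 0 else 0.0
    else:
        F = ((tss - rss) / df1) / (rss / df2)
        p_value = float(stats.f.sf(F, df1, df2))

    def _pred(g, c=coef, kz=knots_z, m=mu, s=sd):
        return natural_cubic_basis((np.atleast_1d(g) - m) / s, kz) @ c

    return TrendFit(
        model="spline",
        coefficients=coef,
        r2=r2,
        p_value=p_value,
        rss=rss,
        n=n,
        edf=df1,
        knots=tuple(float(k * sd + mu) for k in knots_z),
        gcv=float(gcv),
        x_range=(float(x.min()), float(x.max())),
        _predict=_pred,
    )


def fit_cubic(x, y) -> TrendFit:
    """Degree-3 polynomial OLS on a standardised (orthogonalised) basis."""
    x, y = _as_xy(x, y)
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 points")
    mu, sd = float(x.mean()), float(x.std())
    if sd == 0:
        raise ValueError("x is constant")
    z = (x - mu) / sd
    V = np.vander(z, 4, increasing=True)
    Q, R = np.linalg.qr(V)
    gamma, _, _, _ = np.linalg.lstsq(Q, y, rcond=None)
    coef = np.linalg.solve(R, gamma)
    resid = y - V @ coef
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        r2, p_value = 0.0, 1.0
    elif rss <= 1e-12 * tss:
        r2, p_value = 1.0, 0.0
    else:
        r2 = 1.0 - rss / tss
        F = ((tss - rss) / 3.0) / (rss / (n - 4))
        p_value = float(stats.f.sf(F, 3, n - 4))

    def _pred(g, c=coef, m=mu, s=sd):
        return np.vander((np.atleast_1d(g) - m) / s, 4, increasing=True) @ c

    return TrendFit(
        model="cubic",
        coefficients=coef,
        r2=r2,
        p_value=p_value,
        rss=rss,
        n=n,
        edf=4.0,
        x_range=(float(x.min()), float(x.max())),
        _predict=_pred,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def spearman_rho_pvalues(X: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman rho of X (features x samples) against v, with
    two-sided p from the t approximation (average ranks for ties)."""
    n = v.size
    R = stats.rankdata(X, axis=1)
    rv = stats.rankdata(v)
    Rc = R - R.mean(axis=1, keepdims=True)
    rvc = rv - rv.mean()
    denom = np.sqrt((Rc**2).sum(axis=1) * (rvc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (Rc @ rvc) / denom
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return rho, p


def spearman_screen(table, altitude_vector, alpha: float = 0.05):
    """Screen every feature for a Spearman association with altitude.

    Returns a DataFrame (feature_id index) with rho, p_raw, p_adj
    (Benjamini-Hochberg across all testable features), and direction
    classified by the sign of rho at p_raw < alpha (p_adj is reported
    alongside for stricter use).  Constant features are flagged ``ns``
    with a note and excluded from the BH family.
    """
    import pandas as pd

    from .io_meta import AbundanceTable

    data = table.data if isinstance(table, AbundanceTable) else table
    v = np.asarray(altitude_vector, dtype=float)
    if v.size != data.shape[1]:
        raise ValueError("altitude vector does not match sample columns")
    if v.size < 5:
        raise ValueError("need at least 5 samples")
    X = data.to_numpy(dtype=float)
    const = np.ptp(X, axis=1) == 0

    out = pd.DataFrame(
        index=data.index.copy(),
        data={
            "rho": np.nan,
            "p_raw": np.nan,
            "p_adj": np.nan,
            "direction": "ns",
            "note": "",
        },
    )
    out.index.name = "feature_id"
    out.loc[const, "note"] = "constant feature; rho undefined"
    if (~const).any():
        rho, p = spearman_rho_pvalues(X[~const], v)
        p_bh = bh_adjust(np.clip(p, np.finfo(float).tiny, 1.0))
        idx = data.index[~const]
        out.loc[idx, "rho"] = rho
        out.loc[idx, "p_raw"] = p
        out.loc[idx, "p_adj"] = p_bh
        sig = p < alpha
        out.loc[idx[sig & (rho > 0)], "direction"] = "positive"
        out.loc[idx[sig & (rho < 0)], "direction"] = "negative"
    return out
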