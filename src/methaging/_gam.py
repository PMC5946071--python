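"""One-dimensional penalized-spline smoother used by entnorm and regions.

Wraps statsmodels' GLMGam with a B-spline basis.  The smoothing penalty is
chosen by generalized cross-validation over a fixed log-spaced grid, which is
deterministic and cheap.  The fitted smooth is returned as a plain callable:
spline evaluation inside the observed predictor range, linear extrapolation
beyond it.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import interp1d
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.tools.sm_exceptions import PerfectSeparationError

DEFAULT_ALPHAS = tuple(10.0 ** np.arange(-4, 7))


def fit_penalized_spline(x, y, df: int = 20, degree: int = 3,
                         alphas=DEFAULT_ALPHAS, max_points: int = 50_000,
                         n_grid: int = 256):
    """Fit y ~ s(x) with GCV-selected penalty; return an evaluable function.

    Returns ``(smooth, info)`` where ``smooth`` maps any array of x values to
    fitted y values and ``info`` records the selected alpha and effective df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if len(x) > max_points:
        step = len(x) / max_points
        idx = (np.arange(max_points) * step).astype(int)
        x, y = x[idx], y[idx]
    n = len(x)
    n_unique = len(np.unique(x))
    df_eff = int(min(df, max(4, n_unique - 1), n - 2))
    if n_unique < 5:
        # too few distinct predictor values for a spline: fall back to OLS line
        A = np.column_stack([np.ones(n), x])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        line = lambda z: coef[0] + coef[1] * np.asarray(z, dtype=float)
        return line, {"alpha": np.nan, "edf": 2.0, "fallback": "line"}

    basis = BSplines(x[:, None], df=[df_eff], degree=[degree])
    exog = np.ones((n, 1))
    lo, hi = x[0], x[-1]
    span = max(hi - lo, 1e-12)
    grid = np.linspace(lo + 1e-9 * span, hi - 1e-9 * span, n_grid)

    best = None
    for alpha in alphas:
        try:
            res = GLMGam(y, exog=exog, smoother=basis, alpha=[float(alpha)]).fit()
        except PerfectSeparationError:
            # data lie exactly on a curve the basis reproduces: unpenalized
            # least squares on the basis is the exact fit
            X = np.column_stack([exog, basis.basis])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            Xg = np.column_stack([np.ones(n_grid), basis.transform(grid[:, None])])
            fitted = Xg @ coef
            interp = interp1d(grid, fitted, kind="linear",
                              fill_value="extrapolate", assume_sorted=True)
            return (lambda z: np.asarray(interp(np.asarray(z, dtype=float)),
                                         dtype=float),
                    {"alpha": 0.0, "edf": float(X.shape[1]),
                     "fallback": "exact"})
        rss = float(((y - res.fittedvalues) ** 2).sum())
        edf = float(np.sum(res.edf))
        gcv = n * rss / (n - edf) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, alpha, res, edf)
    _, alpha, res, edf = best

    fitted = res.predict(exog=np.ones((n_grid, 1)), exog_smooth=grid[:, None])
    interp = interp1d(grid, fitted, kind="linear", fill_value="extrapolate",
                      assume_sorted=True)

    def smooth(z):
        z = np.asarray(z, dtype=float)
        return np.asarray(interp(z), dtype=float)

    return smooth, {"alpha": float(alpha), "edf": edf, "fallback": None}
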