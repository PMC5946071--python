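"""Per-site and global age regression with nonlinear model selection.

Significance of a site is decided on the untransformed linear model
``fraction ~ age + confounders`` with Benjamini-Hochberg control of the FDR.
Among significant sites, a grid of transformed models
``g(age) ~ fraction**p`` for ``g`` in {identity, ln} and ``p`` in a power
grid is compared by AIC to characterize the dynamics: late-life-accelerating
(strong negative powers of methylation), early-adulthood change (ln-age
response), or linear.

AIC comparability across response transforms requires the Jacobian of the
transform: for the ln-age response ``2 * sum(ln age_j)`` is added so that
likelihoods refer to the same data scale (disable with ``naive_aic=True``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_POWER_GRID = (-13, -5, -1, 1, 5, 13)
RESPONSES = ("age", "ln_age")
CLIP_EPS = 1e-4
TIE_DELTA = 2.0

DYN_LATE = "late_accelerating"
DYN_EARLY = "early_change"
DYN_LINEAR = "linear"


def _design(ages, confounders=None) -> np.ndarray:
    ages = np.asarray(ages, dtype=float)
    cols = [np.ones_like(ages), ages]
    if confounders is not None:
        C = np.atleast_2d(np.asarray(confounders, dtype=float))
        if C.shape[0] != len(ages):
            C = C.T
        cols.extend(C.T)
    return np.column_stack(cols)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name columns whose removal restores full column rank
        collinear = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X)
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")


def ols_many(Y: np.ndarray, X: np.ndarray, names: list[str] | None = None):
    """OLS of every row of ``Y`` (sites x n) on the shared design ``X`` (n x k).

    Returns dict with betas (s, k), rss (s,), se (s, k), t, p and residual df.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, k = X.shape
    if Y.shape[1] != n:
        raise ValueError("Y columns must match design rows")
    if n < k + 1:
        raise ValueError(f"need >= {k + 1} samples for {k} parameters, got {n}")
    _check_rank(X, names or [f"x{j}" for j in range(k)])
    XtX_inv = np.linalg.inv(X.T @ X)
    pinv = XtX_inv @ X.T
    betas = Y @ pinv.T
    resid = Y - betas @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    df = n - k
    sigma2 = rss / df
    se = np.sqrt(np.outer(sigma2, np.diag(XtX_inv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = betas / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # exact fits: zero residual variance -> p is 0 for nonzero effects, 1 otherwise
    zero_se = se == 0
    p[zero_se & (betas != 0)] = 0.0
    p[zero_se & (betas == 0)] = 1.0
    return {"betas": betas, "rss": rss, "se": se, "t": np.where(zero_se, np.inf * np.sign(betas), t), "p": p, "df": df}


def fit_linear_many(Y, ages, confounders=None) -> pd.DataFrame:
    """Row-wise OLS ``fraction ~ age (+ confounders)``; age coefficient stats."""
    names = ["intercept", "age"]
    if confounders is not None:
        C = np.atleast_2d(np.asarray(confounders, dtype=float))
        if C.shape[0] != len(np.asarray(ages)):
            C = C.T
        names += [f"confounder_{j}" for j in range(C.shape[1])]
    X = _design(ages, confounders)
    res = ols_many(Y, X, names)
    return pd.DataFrame(
        {
            "slope": res["betas"][:, 1],
            "intercept": res["betas"][:, 0],
            "se": res["se"][:, 1],
            "p": res["p"][:, 1],
        }
    )


def fit_site_linear(fractions, ages, confounders=None) -> tuple[float, float, float]:
    """OLS of one site's fractions on age (+ confounders).

    Returns ``(slope, intercept, p)`` for the age coefficient.
    """
    fractions = np.asarray(fractions, dtype=float)
    if np.isnan(fractions).any():
        raise ValueError("missing fractions; filter sites before fitting")
    row = fit_linear_many(fractions[None, :], ages, confounders).iloc[0]
    return float(row["slope"]), float(row["intercept"]), float(row["p"])


def adjust_pvalues(pvalues, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def _residualizer(ages, confounders):
    """QR-based projector removing intercept + confounders."""
    ages = np.asarray(ages, dtype=float)
    cols = [np.ones_like(ages)]
    if confounders is not None:
        C = np.atleast_2d(np.asarray(confounders, dtype=float))
        if C.shape[0] != len(ages):
            C = C.T
        cols.append(C)
    X0 = np.column_stack(cols)
    Q, _ = np.linalg.qr(X0)
    return Q, X0.shape[1]


def fit_transform_grid(fractions, ages, confounders=None,
                       grid=DEFAULT_POWER_GRID, responses=RESPONSES,
                       naive_aic: bool = False, tie_delta: float = TIE_DELTA,
                       eps: float = CLIP_EPS):
    """AIC over the transformed-model grid ``g(age) ~ m**p`` per site.

    Returns ``(models, aic, best_idx)`` where ``models`` is the list of
    ``(response, power)`` pairs, ``aic`` has shape (sites, n_models), and
    ``best_idx`` indexes the per-site lowest-AIC model, with any model tying
    the plain linear model ``(age, 1)`` within ``tie_delta`` resolved to it.
    """
    M = np.atleast_2d(np.asarray(fractions, dtype=float))
    ages = np.asarray(ages, dtype=float)
    n = len(ages)
    Q, k0 = _residualizer(ages, confounders)
    if n < k0 + 2:
        raise ValueError(f"need >= {k0 + 2} samples to fit the grid, got {n}")
    Mc = np.clip(M, eps, 1.0 - eps)

    models: list[tuple[str, int]] = [(r, int(p)) for r in responses for p in grid]
    aic = np.empty((M.shape[0], len(models)))
    k_params = k0 + 1
    for col, (resp, power) in enumerate(models):
        g = ages if resp == "age" else np.log(ages)
        e_g = g - Q @ (Q.T @ g)
        egg = e_g @ e_g
        P = Mc ** float(power)
        E = P - (P @ Q) @ Q.T
        num = E @ e_g
        den = np.einsum("ij,ij->i", E, E)
        with np.errstate(divide="ignore", invalid="ignore"):
            rss = egg - np.where(den > 0, num**2 / den, 0.0)
        rss = np.maximum(rss, 1e-300)
        a = n * np.log(rss / n) + 2 * k_params
        if resp == "ln_age" and not naive_aic:
            a = a + 2.0 * np.sum(np.log(ages))
        aic[:, col] = a

    best_idx = np.argmin(aic, axis=1)
    if ("age", 1) in models:
        lin = models.index(("age", 1))
        prefer_lin = aic[:, lin] - aic[np.arange(len(best_idx)), best_idx] < tie_delta
        best_idx = np.where(prefer_lin, lin, best_idx)
    return models, aic, best_idx


def classify_dynamics(best_response: str, best_power: int,
                      significant: bool = True) -> str:
    """Map a best-AIC model to a dynamics label.

    Strong negative methylation powers with an untransformed age response
    mark late-life acceleration; a ln-age response marks early-adulthood
    change; everything else is treated as linear dynamics.
    """
    if not significant:
        raise ValueError("dynamics are defined only for significant sites")
    if best_response == "ln_age":
        return DYN_EARLY
    if best_response == "age" and best_power <= -5:
        return DYN_LATE
    return DYN_LINEAR


def fit_all_sites(matrix_or_fractions, ages, confounders=None,
                  alpha: float = 0.05, grid=DEFAULT_POWER_GRID,
                  responses=RESPONSES, naive_aic: bool = False,
                  site_ids=None) -> pd.DataFrame:
    """Site-by-site age regression plus grid-based dynamics classification.

    Accepts a MethylomeMatrix or a (sites x samples) fraction array.  The
    transformed-model grid is evaluated only for significant sites (q <
    ``alpha``); dynamics of non-significant sites are 'none'.
    """
    from .core import MethylomeMatrix

    if isinstance(matrix_or_fractions, MethylomeMatrix):
        Y = matrix_or_fractions.fractions()
        if site_ids is None:
            site_ids = matrix_or_fractions.site_ids()
    else:
        Y = np.atleast_2d(np.asarray(matrix_or_fractions, dtype=float))
    if site_ids is None:
        site_ids = pd.RangeIndex(Y.shape[0]).astype(str)
    if np.isnan(Y).any():
        raise ValueError("fraction matrix contains missing values; filter first")

    lin = fit_linear_many(Y, ages, confounders)
    q = adjust_pvalues(lin["p"].to_numpy())
    sig = q < alpha
    direction = np.where(~sig, "none", np.where(lin["slope"] > 0, "gain", "loss"))

    best_response = np.array(["none"] * len(q), dtype=object)
    best_power = np.zeros(len(q), dtype=int)
    dynamics = np.array(["none"] * len(q), dtype=object)
    if sig.any():
        models, _aic, best = fit_transform_grid(
            Y[sig], ages, confounders, grid=grid, responses=responses,
            naive_aic=naive_aic,
        )
        resp = np.array([models[i][0] for i in best], dtype=object)
        powr = np.array([models[i][1] for i in best])
        best_response[sig] = resp
        best_power[sig] = powr
        dynamics[sig] = [classify_dynamics(r, p) for r, p in zip(resp, powr)]

    return pd.DataFrame(
        {
            "site_id": np.asarray(site_ids),
            "slope": lin["slope"].to_numpy(),
            "intercept": lin["intercept"].to_numpy(),
            "se": lin["se"].to_numpy(),
            "p": lin["p"].to_numpy(),
            "q": q,
            "direction": direction,
            "best_response": best_response,
            "best_power": best_power,
            "dynamics": dynamics,
        }
    )


def global_trend(matrix_or_fractions, ages, confounders=None) -> tuple[float, float]:
    """Regress per-sample mean methylation on age; returns (slope, p)."""
    from .core import MethylomeMatrix

    if isinstance(matrix_or_fractions, MethylomeMatrix):
        Y = matrix_or_fractions.fractions()
    else:
        Y = np.atleast_2d(np.asarray(matrix_or_fractions, dtype=float))
    means = np.nanmean(Y, axis=0)
    slope, _intercept, p = fit_site_linear(means, ages, confounders)
    return slope, p


def compare_site_set_means(set_a, set_b, fractions, n_perm: int = 9999,
                           seed: int = 0) -> tuple[float, float]:
    """Permutation test for the difference of lifespan-average methylation.

    The statistic is the difference between the mean (over sites) of the
    per-site lifespan-average methylation of set A and of set B.  The null
    is built by reassigning set labels over the union of the two sets.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    fractions = np.atleast_2d(np.asarray(fractions, dtype=float))
    set_a = np.asarray(set_a, dtype=int)
    set_b = np.asarray(set_b, dtype=int)
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("site sets must be non-empty")
    site_means = np.nanmean(fractions, axis=1)
    obs = site_means[set_a].mean() - site_means[set_b].mean()
    pool = np.concatenate([set_a, set_b])
    n_a = len(set_a)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        null = site_means[perm[:n_a]].mean() - site_means[perm[n_a:]].mean()
        if abs(null) >= abs(obs) - 1e-15:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(obs), float(p)
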