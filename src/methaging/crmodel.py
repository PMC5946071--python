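"""Decomposition of the calorie-restriction effect on the methylome.

Per site the model is

    m = b0 + b_age * age + b_IS * CR + b_TAT * (age - t0) * CR + confounders

where CR is the treatment indicator and t0 the treatment-start age.  b_IS is
the instantaneous shift at treatment start (the model's predicted CR-control
difference at age exactly t0); b_TAT is the extra per-month rate under
treatment (the cumulative effect).  Site-level significance of the joint CR
effect is the 2-df nested F-test against the age-only model; per-term IS/TAT
calls use the coefficient t-tests.  All p-values are BH-adjusted across
sites.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import agefit
from .core import CR


def _cr_design(ages, cr_flags, t0, confounders=None):
    ages = np.asarray(ages, dtype=float)
    cr = np.asarray(cr_flags, dtype=float)
    cols = [np.ones_like(ages), ages, cr, (ages - t0) * cr]
    names = ["intercept", "age", "IS", "TAT"]
    if confounders is not None:
        C = np.atleast_2d(np.asarray(confounders, dtype=float))
        if C.shape[0] != len(ages):
            C = C.T
        cols.append(C)
        names += [f"confounder_{j}" for j in range(C.shape[1])]
    return np.column_stack(cols), names


def fit_all_cr(fractions, ages, cr_flags, t0: float, confounders=None,
               site_ids=None) -> pd.DataFrame:
    """Fit the CR decomposition for every site (rows of ``fractions``).

    Returns one row per site with the age/IS/TAT coefficients, the nested
    F-test p of the joint CR effect, per-coefficient p-values, and their
    BH-adjusted counterparts.
    """
    F = np.atleast_2d(np.asarray(fractions, dtype=float))
    cr = np.asarray(cr_flags, dtype=bool)
    ages = np.asarray(ages, dtype=float)
    if cr.all() or not cr.any():
        raise ValueError("both control and CR samples are required")
    if (ages[cr] < t0).any():
        raise ValueError("CR samples younger than the treatment start t0")

    X_full, names = _cr_design(ages, cr, t0, confounders)
    full = agefit.ols_many(F, X_full, names)
    X_red = np.delete(X_full, [2, 3], axis=1)
    red = agefit.ols_many(F, X_red, [n for n in names if n not in ("IS", "TAT")])

    df_full = full["df"]
    rss_f = full["rss"]
    rss_r = red["rss"]
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = ((rss_r - rss_f) / 2.0) / (rss_f / df_full)
    p_f = stats.f.sf(f_stat, 2, df_full)
    exact = rss_f <= 1e-300
    p_f = np.where(exact & (rss_r > rss_f), 0.0, p_f)
    p_f = np.where(exact & (rss_r <= rss_f), 1.0, np.nan_to_num(p_f, nan=1.0))

    out = pd.DataFrame(
        {
            "site_id": np.asarray(site_ids) if site_ids is not None
            else np.arange(F.shape[0]).astype(str),
            "beta_age": full["betas"][:, 1],
            "beta_IS": full["betas"][:, 2],
            "beta_TAT": full["betas"][:, 3],
            "f_stat": f_stat,
            "p_F": p_f,
            "p_IS": full["p"][:, 2],
            "p_TAT": full["p"][:, 3],
        }
    )
    out["q_F"] = agefit.adjust_pvalues(out["p_F"].to_numpy())
    out["q_IS"] = agefit.adjust_pvalues(out["p_IS"].to_numpy())
    out["q_TAT"] = agefit.adjust_pvalues(out["p_TAT"].to_numpy())
    return out


def fit_site_cr(fractions, ages, cr_flags, t0: float, confounders=None) -> dict:
    """Single-site convenience wrapper around :func:`fit_all_cr`."""
    row = fit_all_cr(np.asarray(fractions, float)[None, :], ages, cr_flags,
                     t0, confounders).iloc[0]
    return row.to_dict()


def coefficient_correlation(coef_a, coef_b) -> tuple[float, float]:
    """Pearson correlation between two site-aligned coefficient vectors."""
    a = np.asarray(coef_a, dtype=float)
    b = np.asarray(coef_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coefficient vectors must be site-aligned")
    if len(a) < 3:
        raise ValueError("need >= 3 shared sites for a correlation")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def endpoint_comparison(fractions, sheet: pd.DataFrame, control_slopes,
                        cr_slopes=None, oldest_age: float | None = None) -> dict:
    """CR-minus-control methylation difference at the oldest shared age.

    Returns the per-site difference of group means plus its Pearson
    correlation with the control-cohort aging slopes and, when given, with
    the CR-cohort slopes.  Degenerate (constant) difference vectors yield
    NaN correlations, reported as undefined rather than raising.
    """
    F = np.atleast_2d(np.asarray(fractions, dtype=float))
    ages = sheet["age"].to_numpy(dtype=float)
    is_cr = (sheet["group"] == CR).to_numpy()
    if oldest_age is None:
        cr_ages = set(ages[is_cr]) & set(ages[~is_cr])
        if not cr_ages:
            raise ValueError("no age shared between control and CR groups")
        oldest_age = max(cr_ages)
    at_age = ages == oldest_age
    if not (at_age & is_cr).any() or not (at_age & ~is_cr).any():
        raise ValueError(f"missing a group at age {oldest_age}")
    delta = F[:, at_age & is_cr].mean(axis=1) - F[:, at_age & ~is_cr].mean(axis=1)

    def _corr(x, y):
        x = np.asarray(x, float)
        if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
            return float("nan"), float("nan")
        return coefficient_correlation(x, y)

    r_ctrl, p_ctrl = _corr(control_slopes, delta)
    out = {"oldest_age": float(oldest_age), "delta": delta,
           "r_control_slope": r_ctrl, "p_control_slope": p_ctrl}
    if cr_slopes is not None:
        r_cr, p_cr = _corr(cr_slopes, delta)
        out["r_cr_slope"] = r_cr
        out["p_cr_slope"] = p_cr
    return out


def cr_summary(cr_fit: pd.DataFrame, age_fit: pd.DataFrame,
               alpha: float = 0.05) -> dict:
    """Headline CR readouts: significant-site counts and coefficient
    correlations between aging, IS and TAT over the relevant selections.

    The aging coefficients come from the control-only regression
    (``age_fit``); correlations are computed on the site selections the
    figure panels use: aging-and-IS significant, aging-and-TAT significant,
    IS-and-TAT significant.
    """
    merged = cr_fit.merge(age_fit[["site_id", "slope", "q"]], on="site_id",
                          suffixes=("", "_age"))
    sig_age = merged["q"] < alpha
    sig_f = merged["q_F"] < alpha
    sig_is = merged["q_IS"] < alpha
    sig_tat = merged["q_TAT"] < alpha

    def _sel_corr(mask, col_a, col_b):
        sub = merged[mask]
        if len(sub) < 3:
            return float("nan"), float("nan"), int(len(sub))
        r, p = coefficient_correlation(sub[col_a], sub[col_b])
        return r, p, int(len(sub))

    r_is, p_is, n_is = _sel_corr(sig_age & sig_is, "slope", "beta_IS")
    r_tat, p_tat, n_tat = _sel_corr(sig_age & sig_tat, "slope", "beta_TAT")
    r_it, p_it, n_it = _sel_corr(sig_is & sig_tat, "beta_IS", "beta_TAT")
    return {
        "n_sites": int(len(merged)),
        "n_sig_F": int(sig_f.sum()),
        "frac_sig_F": float(sig_f.mean()),
        "n_sig_IS": int(sig_is.sum()),
        "n_sig_TAT": int(sig_tat.sum()),
        "overlap": {
            "age_only": int((sig_age & ~sig_is & ~sig_tat).sum()),
            "age_IS": int((sig_age & sig_is & ~sig_tat).sum()),
            "age_TAT": int((sig_age & ~sig_is & sig_tat).sum()),
            "IS_TAT": int((~sig_age & sig_is & sig_tat).sum()),
            "all_three": int((sig_age & sig_is & sig_tat).sum()),
        },
        "r_age_IS": r_is, "p_age_IS": p_is, "n_age_IS": n_is,
        "r_age_TAT": r_tat, "p_age_TAT": p_tat, "n_age_TAT": n_tat,
        "r_IS_TAT": r_it, "p_IS_TAT": p_it, "n_IS_TAT": n_it,
    }
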