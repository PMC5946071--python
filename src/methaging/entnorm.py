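"""Entropy normalization of per-site age trends.

The average-entropy effect couples a site's age slope to its baseline
methylation (its regression intercept): extreme sites drift toward 0.5, so
slope is, on average, a smooth function of intercept.  This module fits that
smooth (a penalized-spline GAM on the significant sites), predicts an
*expected slope* for every site from its intercept, subtracts
``age * expected_slope`` from the original methylation fractions (OMF) to
form the *residual methylation fraction* (RMF), refits the full age model on
the RMF, and classifies each site by how its observed change relates to the
entropy trajectory:

==============  =======================================================
resist          no OMF change, but RMF changes (site resists the drift)
follow_entropy  OMF changes, RMF does not (fully explained by the drift)
exceed_entropy  both change; same sign as, and larger than, expected
slower          both change; same sign as, but smaller than, expected
counter_entropy both change; direction opposite to the expected slope
stable          no change in either analysis
==============  =======================================================
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import agefit
from ._gam import fit_penalized_spline

MIN_SIG_SITES = 50

CATEGORIES = ("resist", "follow_entropy", "exceed_entropy",
              "slower_than_entropy", "counter_entropy", "stable")


def fit_expected_slope(intercepts, slopes, df: int = 20):
    """Smooth of slope against intercept over the significant sites.

    Returns ``(smooth, info)``; the smooth is evaluable at any intercept,
    with linear extrapolation beyond the fitted range.
    """
    intercepts = np.asarray(intercepts, dtype=float)
    slopes = np.asarray(slopes, dtype=float)
    if len(intercepts) < MIN_SIG_SITES:
        raise ValueError(
            f"need >= {MIN_SIG_SITES} significant sites to fit the "
            f"expected-slope smooth, got {len(intercepts)}"
        )
    return fit_penalized_spline(intercepts, slopes, df=df)


def compute_rmf(fractions, ages, expected_slope) -> np.ndarray:
    """RMF_ij = OMF_ij - age_j * expected_slope_i (not clipped)."""
    F = np.atleast_2d(np.asarray(fractions, dtype=float))
    ages = np.asarray(ages, dtype=float)
    es = np.asarray(expected_slope, dtype=float)
    if es.shape[0] != F.shape[0]:
        raise ValueError("one expected slope per site required")
    return F - np.outer(es, ages)


def classify_entropy_relation(omf_fit: pd.DataFrame, rmf_fit: pd.DataFrame,
                              expected_slope, alpha: float = 0.05) -> pd.DataFrame:
    """Per-site category from the OMF/RMF significance pattern.

    Both fit tables must be site-aligned (same ``site_id`` order) and carry
    ``slope`` and ``q`` columns computed at the same ``alpha``.
    """
    if not np.array_equal(omf_fit["site_id"].to_numpy(),
                          rmf_fit["site_id"].to_numpy()):
        raise ValueError("OMF and RMF fit tables have mismatched site ids")
    es = np.asarray(expected_slope, dtype=float)
    omf_sig = omf_fit["q"].to_numpy() < alpha
    rmf_sig = rmf_fit["q"].to_numpy() < alpha
    obs = omf_fit["slope"].to_numpy()

    category = np.empty(len(omf_fit), dtype=object)
    category[~omf_sig & ~rmf_sig] = "stable"
    category[~omf_sig & rmf_sig] = "resist"
    category[omf_sig & ~rmf_sig] = "follow_entropy"
    both = omf_sig & rmf_sig
    same_sign = np.sign(obs) == np.sign(es)
    category[both & ~same_sign] = "counter_entropy"
    category[both & same_sign & (np.abs(obs) > np.abs(es))] = "exceed_entropy"
    category[both & same_sign & (np.abs(obs) <= np.abs(es))] = "slower_than_entropy"

    return pd.DataFrame(
        {
            "site_id": omf_fit["site_id"].to_numpy(),
            "omf_significant": omf_sig,
            "rmf_significant": rmf_sig,
            "omf_slope": obs,
            "rmf_slope": rmf_fit["slope"].to_numpy(),
            "expected_slope": es,
            "category": category,
        }
    )


def run_entropy_normalization(fractions, ages, omf_fit: pd.DataFrame,
                              confounders=None, alpha: float = 0.05,
                              grid=agefit.DEFAULT_POWER_GRID,
                              spline_df: int = 20) -> dict:
    """Full entropy-normalization pass.

    The expected-slope smooth is fitted on significant sites only but
    evaluated for all sites.  The RMF is refit with the same age-regression
    machinery (linear significance + transformed-model grid) as the OMF.
    Returns expected slopes, the RMF matrix and fit table, the per-site
    classification, and the OMF/RMF overlap counts.
    """
    F = np.atleast_2d(np.asarray(fractions, dtype=float))
    sig = omf_fit["q"].to_numpy() < alpha
    smooth, info = fit_expected_slope(
        omf_fit.loc[sig, "intercept"], omf_fit.loc[sig, "slope"], df=spline_df,
    )
    expected = smooth(omf_fit["intercept"].to_numpy())
    rmf = compute_rmf(F, ages, expected)
    rmf_fit = agefit.fit_all_sites(
        rmf, ages, confounders, alpha=alpha, grid=grid,
        site_ids=omf_fit["site_id"].to_numpy(),
    )
    classes = classify_entropy_relation(omf_fit, rmf_fit, expected, alpha)
    omf_sig = classes["omf_significant"]
    rmf_sig = classes["rmf_significant"]
    overlap = {
        "omf_only": int((omf_sig & ~rmf_sig).sum()),
        "rmf_only": int((~omf_sig & rmf_sig).sum()),
        "both": int((omf_sig & rmf_sig).sum()),
        "neither": int((~omf_sig & ~rmf_sig).sum()),
    }
    return {
        "expected_slope": expected,
        "smooth_info": info,
        "rmf": rmf,
        "rmf_fit": rmf_fit,
        "classes": classes,
        "overlap": overlap,
    }
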