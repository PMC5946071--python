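"""Per-sample Shannon entropy of the methylome and its age trajectory.

The entropy of a sample over N sites with methylation fractions m_i is

    H = (1 / (N * ln 1/2)) * sum_i [ m_i ln m_i + (1 - m_i) ln(1 - m_i) ]

normalized so that H = 1 when every site is half-methylated and H = 0 when
every site is fully methylated or fully unmethylated.  H is invariant under
m -> 1 - m per site.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import xlogy

from . import agefit


def sample_entropy(fractions) -> float | np.ndarray:
    """Normalized Shannon entropy per sample.

    ``fractions`` is either one sample's fraction vector (1-D, returns a
    scalar) or a sites x samples matrix (returns one value per column).
    Boundary fractions (exactly 0 or 1) contribute zero, their continuity
    limit.
    """
    m = np.asarray(fractions, dtype=float)
    if m.size == 0:
        raise ValueError("empty site set")
    if np.nanmin(m) < 0 or np.nanmax(m) > 1:
        raise ValueError("fractions must lie in [0, 1]")
    scalar = m.ndim == 1
    if scalar:
        m = m[:, None]
    # xlogy carries the continuity limit m ln m -> 0 at the boundaries, so
    # exact 0/1 fractions contribute nothing and H(m) = H(1-m) holds exactly
    terms = xlogy(m, m) + xlogy(1 - m, 1 - m)
    h = terms.sum(axis=0) / (m.shape[0] * np.log(0.5))
    return float(h[0]) if scalar else h


def entropy_per_sample(matrix, site_mask=None) -> np.ndarray:
    """Entropy of each sample of a MethylomeMatrix over an optional site set."""
    frac = matrix.fractions()
    if site_mask is not None:
        frac = frac[np.asarray(site_mask)]
    if frac.shape[0] == 0:
        raise ValueError("empty site set")
    return sample_entropy(frac)


def entropy_vs_age(H, ages, confounders=None, grid=agefit.DEFAULT_POWER_GRID,
                   naive_aic: bool = False) -> dict:
    """Fit the entropy-age relation: linear trend plus transformed-model grid.

    Reuses the site-level machinery with entropy in place of methylation.
    Returns slope, p of the linear fit and the best-AIC (response, power).
    """
    H = np.asarray(H, dtype=float)
    if len(H) < 8:
        raise ValueError("need >= 8 samples for the entropy-age fit")
    slope, intercept, p = agefit.fit_site_linear(H, ages, confounders)
    models, aic, best = agefit.fit_transform_grid(
        H[None, :], ages, confounders, grid=grid, naive_aic=naive_aic,
    )
    resp, power = models[best[0]]
    return {
        "slope": slope,
        "intercept": intercept,
        "p": p,
        "best_response": resp,
        "best_power": power,
        "aic": dict(zip([f"{r}~m^{pw}" for r, pw in models], aic[0])),
    }


def entropy_permutation_compare(set_a, set_b, matrix, ages=None,
                                n_perm: int = 9999, seed: int = 0) -> dict:
    """Compare entropy between two site sets by site-label permutation.

    Statistic: mean over samples of H(set A) - H(set B).  The null relabels
    sites across the union.  Also reports the per-age-group entropy
    difference when ages are given.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    set_a = np.asarray(set_a, dtype=int)
    set_b = np.asarray(set_b, dtype=int)
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("site sets must be non-empty")
    frac = matrix.fractions()
    h_a = sample_entropy(frac[set_a])
    h_b = sample_entropy(frac[set_b])
    obs = float(np.mean(h_a - h_b))

    pool = np.concatenate([set_a, set_b])
    n_a = len(set_a)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        null = float(np.mean(sample_entropy(frac[perm[:n_a]])
                             - sample_entropy(frac[perm[n_a:]])))
        if abs(null) >= abs(obs) - 1e-15:
            count += 1
    p = (1 + count) / (1 + n_perm)

    out = {"delta_H": obs, "p": float(p)}
    if ages is not None:
        ages = np.asarray(ages, dtype=float)
        groups = pd.Series(h_a - h_b).groupby(ages).mean()
        out["delta_H_by_age"] = groups.to_dict()
    return out
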