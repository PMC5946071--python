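"""Region-level remodeling: assignment, normalized slopes, enrichment, tiers.

Sites are points assigned to labeled interval sets (CpG islands, shores,
shelves, promoters, exons, ...).  Region trends are summarized on the z-score
scale: each member site's fraction series is standardized across samples and
re-regressed on age, so a region's statistic counts *how many* sites change
and in which direction rather than how large the raw changes are.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from . import agefit
from .core import RegionSet

logger = logging.getLogger(__name__)


def _trees(region_set: RegionSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in region_set.intervals.groupby("chrom"):
        trees[str(chrom)] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(sub["start"], sub["end"])
        )
    return trees


def assign_sites(sites: pd.DataFrame, region_sets, strict: bool = True) -> pd.DataFrame:
    """Boolean membership of each site (by its start position) per label.

    ``region_sets`` is a mapping ``label -> RegionSet`` (or one RegionSet,
    whose ``label`` column partitions it).  Membership uses the half-open
    convention: position p is in [start, end) iff start <= p < end.
    """
    if isinstance(region_sets, RegionSet):
        region_sets = {
            lab: RegionSet(sub.reset_index(drop=True))
            for lab, sub in region_sets.intervals.groupby("label")
        }
    chroms = sites["chrom"].astype(str)
    pos = sites["start"].to_numpy()
    out = {}
    any_chrom_shared = False
    for label, rs in region_sets.items():
        trees = _trees(rs)
        member = np.zeros(len(sites), dtype=bool)
        for chrom, idx in chroms.groupby(chroms).groups.items():
            tree = trees.get(str(chrom))
            if tree is None:
                continue
            any_chrom_shared = True
            ii = np.asarray(idx)
            member[ii] = [bool(tree[int(p)]) for p in pos[ii]]
        out[label] = member
    total_intervals = sum(len(rs) for rs in region_sets.values())
    if strict and len(sites) and total_intervals and not any_chrom_shared:
        raise ValueError(
            "no chromosome name shared between sites and regions; "
            "check naming dialect (chr1 vs 1)"
        )
    return pd.DataFrame(out, index=sites.index)


def zscore_slopes(fractions, ages, confounders=None) -> np.ndarray:
    """Per-site age slopes of the z-scored fraction series.

    Constant sites (zero SD) get slope NaN and are excluded by callers.
    """
    F = np.atleast_2d(np.asarray(fractions, dtype=float))
    mu = F.mean(axis=1, keepdims=True)
    sd = F.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (F - mu) / sd
    ok = (sd[:, 0] > 0) & np.isfinite(sd[:, 0])
    slopes = np.full(F.shape[0], np.nan)
    if ok.any():
        slopes[ok] = agefit.fit_linear_many(Z[ok], ages, confounders)["slope"].to_numpy()
    return slopes


def region_slope(fractions, member_idx, ages, confounders=None,
                 n_boot: int = 1000, seed: int = 0) -> dict | None:
    """Mean z-scale slope of a region's member sites with a bootstrap CI.

    Returns None (with a logged warning) for regions with fewer than two
    usable member sites.  The CI is a site-level percentile bootstrap.
    """
    member_idx = np.asarray(member_idx, dtype=int)
    F = np.atleast_2d(np.asarray(fractions, dtype=float))[member_idx]
    slopes = zscore_slopes(F, ages, confounders)
    slopes = slopes[np.isfinite(slopes)]
    if len(slopes) < 2:
        logger.warning("region with < 2 usable sites skipped")
        return None
    mean = float(slopes.mean())
    rng = np.random.default_rng(seed)
    boots = rng.choice(slopes, size=(n_boot, len(slopes)), replace=True).mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {"mean_slope": mean, "ci_low": float(lo), "ci_high": float(hi),
            "n_sites": int(len(slopes))}


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test of [[a, b], [c, d]].

    Returns the cross-product (sample) odds ratio and the two-sided p-value
    computed by summing hypergeometric probabilities no larger than that of
    the observed table (with the customary 1 + 1e-7 relative slack).  An
    empty margin makes the odds ratio undefined (NaN, p = 1).
    """
    N = a + b + c + d
    K = a + b       # margin of the first row
    n = a + c       # margin of the first column
    if N == 0 or K == 0 or K == N or n == 0 or n == N:
        return float("nan"), 1.0
    if b * c == 0:
        oratio = float("inf") if a * d > 0 else float("nan")
    else:
        oratio = (a * d) / (b * c)
    support = np.arange(max(0, n - (N - K)), min(K, n) + 1)
    pmf = stats.hypergeom.pmf(support, N, K, n)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return oratio, min(p, 1.0)


def enrichment_fisher(membership: pd.DataFrame, directions) -> pd.DataFrame:
    """Enrichment of gain/loss sites inside each region label.

    ``membership`` is the boolean sites x labels frame from
    :func:`assign_sites`; ``directions`` holds 'gain'/'loss'/'none' per site.
    For every label and direction a 2x2 table {in region, out} x {direction,
    not} over all tested sites is scored; p-values are BH-adjusted across
    labels within each direction.
    """
    directions = np.asarray(directions)
    if len(directions) != len(membership):
        raise ValueError("one direction per site required")
    rows = []
    for direction in ("gain", "loss"):
        is_dir = directions == direction
        for label in membership.columns:
            inr = membership[label].to_numpy()
            a = int((inr & is_dir).sum())
            b = int((inr & ~is_dir).sum())
            c = int((~inr & is_dir).sum())
            d = int((~inr & ~is_dir).sum())
            oratio, p = fisher_exact_2x2(a, b, c, d)
            rows.append((label, direction, a, b, c, d, oratio, p))
    out = pd.DataFrame(rows, columns=["label", "direction", "a", "b", "c", "d",
                                      "odds_ratio", "p"])
    out["q"] = np.nan
    for direction in ("gain", "loss"):
        m = out["direction"] == direction
        out.loc[m, "q"] = agefit.adjust_pvalues(out.loc[m, "p"].to_numpy())
    return out


def cgi_sensitivity(fractions, ages, membership: pd.DataFrame,
                    tier_sets: dict[str, np.ndarray], confounders=None,
                    n_boot: int = 200, seed: int = 0) -> pd.DataFrame:
    """Region slopes after cumulative removal of CGI / shore / shelf sites.

    ``tier_sets`` maps tier names (in cumulative order, e.g. 'CGI',
    'CGI+shore', 'CGI+shore+shelf') to boolean site masks to exclude.
    Tier 'all' keeps every member site.
    """
    rows = []
    tiers = {"all": np.zeros(len(membership), dtype=bool), **tier_sets}
    for label in membership.columns:
        member = membership[label].to_numpy()
        for tier, excl in tiers.items():
            idx = np.flatnonzero(member & ~excl)
            res = region_slope(fractions, idx, ages, confounders,
                               n_boot=n_boot, seed=seed)
            if res is None:
                continue
            rows.append((label, tier, res["mean_slope"], res["ci_low"],
                         res["ci_high"], res["n_sites"]))
    return pd.DataFrame(rows, columns=["label", "tier", "mean_slope",
                                       "ci_low", "ci_high", "n_sites"])


def compare_slope_sets(slopes_a, slopes_b) -> tuple[float, float]:
    """Welch t-test between two groups of per-site slopes (e.g. homolog vs
    species-specific region members)."""
    t, p = stats.ttest_ind(np.asarray(slopes_a, float),
                           np.asarray(slopes_b, float), equal_var=False)
    return float(t), float(p)


def relative_position(pos, gene_start: int, gene_end: int, strand: str) -> float:
    """Metagene coordinate: 0 at the TSS, 1 at the gene end, strand-aware."""
    length = gene_end - gene_start
    if length <= 0:
        raise ValueError(f"zero-length gene [{gene_start}, {gene_end})")
    if strand == "-":
        return (gene_end - np.asarray(pos, dtype=float)) / length
    return (np.asarray(pos, dtype=float) - gene_start) / length


def metagene_profile(fractions, sites: pd.DataFrame, genes: pd.DataFrame,
                     ages, site_mask=None, n_grid: int = 121,
                     spline_df: int = 12) -> pd.DataFrame:
    """Smoothed methylation along the normalized gene coordinate per age group.

    Every site within a gene's window extended by one gene length on both
    sides maps to r in [-1, 2].  For each age group the mean methylation of
    the mapped site-gene pairs is smoothed along r with a penalized spline.
    ``genes`` needs columns chrom, start, end, strand (and optionally
    gene_id).
    """
    from ._gam import fit_penalized_spline

    F = np.atleast_2d(np.asarray(fractions, dtype=float))
    if site_mask is not None:
        keep = np.asarray(site_mask)
        F = F[keep]
        sites = sites.loc[keep].reset_index(drop=True)
    ages = np.asarray(ages, dtype=float)

    # collect (site index, r) pairs over all genes
    trees: dict[str, IntervalTree] = {}
    chroms = sites["chrom"].astype(str).to_numpy()
    pos = sites["start"].to_numpy()
    for chrom in np.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        trees[chrom] = IntervalTree.from_tuples(
            (int(p), int(p) + 1, int(i)) for i, p in zip(idx, pos[idx])
        )
    pair_site, pair_r = [], []
    for _, gene in genes.iterrows():
        length = int(gene["end"]) - int(gene["start"])
        if length <= 0:
            raise ValueError(f"zero-length gene at {gene['chrom']}:{gene['start']}")
        tree = trees.get(str(gene["chrom"]))
        if tree is None:
            continue
        for iv in tree[int(gene["start"]) - length: int(gene["end"]) + length]:
            r = relative_position(iv.begin, int(gene["start"]), int(gene["end"]),
                                  str(gene.get("strand", "+")))
            pair_site.append(iv.data)
            pair_r.append(float(r))
    if not pair_site:
        raise ValueError("no site falls in any gene window")
    pair_site = np.asarray(pair_site)
    pair_r = np.asarray(pair_r)

    r_grid = np.linspace(-1.0, 2.0, n_grid)
    rows = []
    for age in np.unique(ages):
        cols = ages == age
        vals = F[pair_site][:, cols].mean(axis=1)
        smooth, _ = fit_penalized_spline(pair_r, vals, df=spline_df)
        rows.append(pd.DataFrame({"age_group": age, "r": r_grid,
                                  "methylation": smooth(r_grid)}))
    return pd.concat(rows, ignore_index=True)
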