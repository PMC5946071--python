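"""Interval assignment, normalized region slopes, enrichment, tiers, metagene."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from methaging import regions
from methaging.core import RegionSet


def _regionset(rows, label="r"):
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end"])
                     .assign(label=label))


def _sites(positions, chrom="chr1"):
    positions = np.asarray(positions)
    return pd.DataFrame({"chrom": chrom, "start": positions,
                         "end": positions + 2})


class TestAssignSites:
    def test_half_open_boundaries(self):
        rs = _regionset([("chr1", 100, 200)])
        member = regions.assign_sites(_sites([100, 199, 200, 99]), {"r": rs})
        assert list(member["r"]) == [True, True, False, False]

    def test_multi_label_membership(self):
        sites = _sites([150])
        member = regions.assign_sites(
            sites, {"cgi": _regionset([("chr1", 100, 200)]),
                    "promoter": _regionset([("chr1", 140, 160)])})
        assert member.iloc[0].all()

    def test_chromosome_dialect_mismatch_raises(self):
        rs = _regionset([("1", 100, 200)])
        with pytest.raises(ValueError, match="dialect"):
            regions.assign_sites(_sites([150], chrom="chr1"), {"r": rs})

    def test_matches_quadratic_scan_oracle(self):
        rng = np.random.default_rng(0)
        pos = rng.integers(0, 1000, 300)
        starts = rng.integers(0, 950, 150)
        ends = starts + rng.integers(1, 50, 150)
        rs = RegionSet(pd.DataFrame({"chrom": "chrX", "start": starts,
                                     "end": ends, "label": "r"}))
        member = regions.assign_sites(_sites(pos, chrom="chrX"), {"r": rs})
        oracle = [any(s <= p < e for s, e in zip(starts, ends)) for p in pos]
        assert list(member["r"]) == oracle


class TestRegionSlope:
    def test_scale_invariance_of_zscored_slopes(self):
        rng = np.random.default_rng(1)
        ages = np.repeat([3.0, 12, 24, 35], 4)
        base = 0.3 + 0.004 * ages + rng.normal(0, 0.01, (6, 16))
        scaled = base * 0.1 + 0.5  # affine rescaling of every site
        r1 = regions.region_slope(base, np.arange(6), ages, seed=0)
        r2 = regions.region_slope(scaled, np.arange(6), ages, seed=0)
        assert r1["mean_slope"] == pytest.approx(r2["mean_slope"], abs=1e-12)
        assert r1["mean_slope"] > 0

    def test_mirror_sites_cancel(self):
        ages = np.repeat([3.0, 12, 24, 35], 3)
        gain = 0.3 + 0.004 * ages
        loss = 0.7 - 0.004 * ages
        F = np.vstack([np.tile(gain, (5, 1)), np.tile(loss, (5, 1))])
        res = regions.region_slope(F, np.arange(10), ages, seed=0)
        assert res["mean_slope"] == pytest.approx(0.0, abs=1e-10)

    def test_mean_of_member_slopes(self):
        ages = np.linspace(3, 35, 12)
        F = np.vstack([0.2 + 0.002 * ages, 0.2 + 0.01 * ages])
        res = regions.region_slope(F, [0, 1], ages, seed=0)
        z = regions.zscore_slopes(F, ages)
        assert res["mean_slope"] == pytest.approx(z.mean(), abs=1e-12)

    def test_single_usable_site_skipped(self, caplog):
        ages = np.linspace(3, 35, 8)
        F = np.vstack([0.2 + 0.002 * ages, np.full(8, 0.5)])
        assert regions.region_slope(F, [0, 1], ages) is None


def fisher_oracle_exact(a, b, c, d):
    """Two-sided Fisher p by exact rational hypergeometric enumeration."""
    N, K, n = a + b + c + d, a + b, a + c

    def pmf(k):
        return Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n))

    p_obs = pmf(a)
    cutoff = p_obs + p_obs / 10_000_000  # same 1e-7 relative slack
    total = sum(pmf(k) for k in range(max(0, n - (N - K)), min(K, n) + 1)
                if pmf(k) <= cutoff)
    return float(total)


class TestFisher:
    def test_cross_product_odds_ratio(self):
        oratio, p = regions.fisher_exact_2x2(8, 2, 20, 70)
        assert oratio == pytest.approx(14.0)
        assert p == pytest.approx(fisher_oracle_exact(8, 2, 20, 70), abs=1e-9)

    def test_proportional_table_or_one(self):
        oratio, p = regions.fisher_exact_2x2(10, 20, 30, 60)
        assert oratio == pytest.approx(1.0)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_empty_margin_undefined(self):
        oratio, p = regions.fisher_exact_2x2(0, 0, 5, 7)
        assert np.isnan(oratio) and p == 1.0

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 40, 4)
            if (a + b) * (c + d) * (a + c) * (b + d) == 0:
                continue
            oratio, p = regions.fisher_exact_2x2(a, b, c, d)
            o2, p2 = scipy_fisher([[a, b], [c, d]])
            assert p == pytest.approx(p2, abs=1e-9)
            assert oratio == pytest.approx(o2)

    def test_enrichment_frame_bh_within_direction(self):
        rng = np.random.default_rng(3)
        member = pd.DataFrame({"r1": rng.random(500) < 0.3,
                               "r2": rng.random(500) < 0.3})
        directions = rng.choice(["gain", "loss", "none"], 500)
        out = regions.enrichment_fisher(member, directions)
        assert set(out["direction"]) == {"gain", "loss"}
        assert ((out["q"] >= out["p"]) | out["q"].isna()).all()


class TestCgiTiers:
    def test_no_overlap_keeps_slope(self):
        ages = np.repeat([3.0, 12, 24, 35], 3)
        rng = np.random.default_rng(4)
        F = 0.3 + 0.004 * ages + rng.normal(0, 0.005, (8, 12))
        member = pd.DataFrame({"promoter": np.ones(8, dtype=bool)})
        tiers = {"minus_CGI": np.zeros(8, dtype=bool)}
        out = regions.cgi_sensitivity(F, ages, member, tiers, seed=0)
        by_tier = out.set_index("tier")["mean_slope"]
        assert by_tier["all"] == pytest.approx(by_tier["minus_CGI"], abs=1e-12)

    def test_cgi_driven_gain_flips_sign_on_removal(self):
        ages = np.repeat([3.0, 12, 24, 35], 3)
        gain = 0.2 + 0.006 * ages   # CGI members
        loss = 0.8 - 0.002 * ages   # non-CGI members
        F = np.vstack([np.tile(gain, (6, 1)), np.tile(loss, (4, 1))])
        member = pd.DataFrame({"promoter": np.ones(10, dtype=bool)})
        is_cgi = np.array([True] * 6 + [False] * 4)
        out = regions.cgi_sensitivity(F, ages, member, {"minus_CGI": is_cgi},
                                      seed=0)
        by_tier = out.set_index("tier")["mean_slope"]
        assert by_tier["all"] > 0 > by_tier["minus_CGI"]

    def test_emptied_region_skipped(self):
        ages = np.linspace(3, 35, 8)
        F = np.tile(0.2 + 0.004 * ages, (3, 1))
        member = pd.DataFrame({"promoter": np.ones(3, dtype=bool)})
        out = regions.cgi_sensitivity(F, ages, member,
                                      {"minus_CGI": np.ones(3, dtype=bool)},
                                      seed=0)
        assert list(out["tier"]) == ["all"]


class TestMetagene:
    @pytest.mark.parametrize("pos,strand,r", [
        (1000, "+", 0.0),    # TSS
        (2000, "+", 1.0),    # gene end
        (500, "+", -0.5),    # upstream by half a gene length
        (2000, "-", 0.0),    # minus strand: TSS at the high coordinate
        (1000, "-", 1.0),
    ])
    def test_relative_position(self, pos, strand, r):
        assert regions.relative_position(pos, 1000, 2000, strand) == pytest.approx(r)

    def test_zero_length_gene_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            regions.relative_position(5, 10, 10, "+")

    def test_profile_reflects_positional_gradient(self):
        # methylation rises linearly along the gene body; the smoothed profile
        # must be increasing in r for every age group
        rng = np.random.default_rng(5)
        ages = np.repeat([3.0, 35.0], 4)
        pos = np.arange(1000, 2001, 20)
        sites = _sites(pos)
        frac = np.clip(((pos - 1000) / 1000 * 0.6 + 0.2)[:, None]
                       + rng.normal(0, 0.01, (len(pos), len(ages))), 0, 1)
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [1000],
                              "end": [2000], "strand": ["+"]})
        prof = regions.metagene_profile(frac, sites, genes, ages)
        for _, sub in prof.groupby("age_group"):
            body = sub[(sub["r"] >= 0.05) & (sub["r"] <= 0.95)]
            vals = body.sort_values("r")["methylation"].to_numpy()
            assert vals[-1] > vals[0] + 0.3


class TestSlopeSetComparison:
    def test_separated_groups_detected(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.5, 0.1, 50)
        b = rng.normal(-0.5, 0.1, 50)
        t, p = regions.compare_slope_sets(a, b)
        assert t > 0 and p < 1e-10
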