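"""Site-selection filters applied before any modeling.

The chain mirrors conventional RRBS practice for aging cohorts: keep sites
present in all samples, drop sites with low coverage in too many samples of
any age group (or of the treated set), mask extreme-coverage entries and
SNP-overlapping sites, merge the two strands of each CpG, and finally drop
low-variance sites via the shorth rule: sites whose fraction SD falls below
the mean of the shortest interval covering half of all site SDs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CR, MethylomeMatrix, RegionSet


@dataclass
class FilterReport:
    n_input_sites: int
    n_after_common: int
    n_after_coverage: int
    n_after_outlier_snp: int = -1
    n_after_aggregation: int = -1
    n_after_shorth: int = -1
    shorth_threshold: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def intersect_common_sites(matrix: MethylomeMatrix) -> np.ndarray:
    """Boolean mask of sites observed (coverage >= 1) in every sample."""
    if matrix.n_samples < 1:
        raise ValueError("matrix has no samples")
    return (matrix.total > 0).all(axis=1)


def coverage_filter(matrix: MethylomeMatrix, group_labels,
                    cr_mask=None, min_cov: int = 10,
                    max_low_frac: float = 0.5) -> np.ndarray:
    """Mask of sites passing the soft coverage cutoff.

    A site is excluded if, within any age group — or within the treated (CR)
    sample set, evaluated as one extra group — the proportion of samples with
    coverage below ``min_cov`` strictly exceeds ``max_low_frac``.
    """
    group_labels = np.asarray(group_labels)
    if len(group_labels) != matrix.n_samples:
        raise ValueError("one group label per sample required")
    low = matrix.total < min_cov
    exclude = np.zeros(matrix.n_sites, dtype=bool)
    groups = [np.flatnonzero(group_labels == g) for g in pd.unique(group_labels)]
    if cr_mask is not None:
        cr_idx = np.flatnonzero(np.asarray(cr_mask, dtype=bool))
        if len(cr_idx):
            groups.append(cr_idx)
    for idx in groups:
        if len(idx) == 0:
            raise ValueError("empty sample group")
        exclude |= low[:, idx].mean(axis=1) > max_low_frac
    return ~exclude


def shorth_threshold(values: np.ndarray) -> float:
    """Mean of the shortest interval containing ceil(n/2) of the values.

    Ties among equally short windows resolve to the window with the lower
    mean, making the estimator deterministic.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n == 0:
        raise ValueError("no values")
    h = int(np.ceil(n / 2))
    widths = v[h - 1:] - v[: n - h + 1]
    shortest = widths.min()
    candidates = np.flatnonzero(widths == shortest)
    means = np.array([v[i:i + h].mean() for i in candidates])
    return float(means.min())


def shorth_sd_filter(matrix: MethylomeMatrix) -> tuple[np.ndarray, float]:
    """Keep sites whose per-site fraction SD is at least the shorth mean."""
    if matrix.n_samples < 2:
        raise ValueError("shorth filter needs >= 2 samples")
    sds = np.nanstd(matrix.fractions(), axis=1, ddof=1)
    thr = shorth_threshold(sds)
    return sds >= thr, thr


def aggregate_cpg_strands(matrix: MethylomeMatrix) -> MethylomeMatrix:
    """Merge plus/minus strand measurements of the same CpG.

    A plus-strand C at position p pairs with the minus-strand C at p+1;
    counts are summed over the merged record [p, p+2).  Unpaired sites are
    kept as single-strand CpG records.
    """
    sites = matrix.sites
    if "strand" not in sites.columns or (sites["strand"] == ".").all():
        return matrix
    key = sites["chrom"].astype(str) + ":" + sites["start"].astype(str)
    if key.duplicated().any():
        pos = key[key.duplicated()].iloc[0]
        raise ValueError(f"position collision at {pos}: more than one record per strand position")

    plus = sites["strand"] == "+"
    minus = sites["strand"] == "-"
    idx_by_key = {k: i for i, k in enumerate(key)}

    merged_rows, merged_meth, merged_total = [], [], []
    consumed = np.zeros(len(sites), dtype=bool)
    for i in np.flatnonzero(plus):
        mate_key = f"{sites['chrom'].iloc[i]}:{sites['start'].iloc[i] + 1}"
        j = idx_by_key.get(mate_key)
        if j is not None and minus.iloc[j]:
            consumed[i] = consumed[j] = True
            merged_rows.append((sites["chrom"].iloc[i], sites["start"].iloc[i],
                                sites["start"].iloc[i] + 2, "."))
            merged_meth.append(matrix.meth[i] + matrix.meth[j])
            merged_total.append(matrix.total[i] + matrix.total[j])
    for i in np.flatnonzero(~consumed):
        s = int(sites["start"].iloc[i])
        if plus.iloc[i]:
            span = (s, s + 2)
        elif minus.iloc[i]:
            span = (s - 1, s + 1)
        else:
            span = (s, int(sites["end"].iloc[i]))
        merged_rows.append((sites["chrom"].iloc[i], span[0], span[1], "."))
        merged_meth.append(matrix.meth[i])
        merged_total.append(matrix.total[i])

    out_sites = pd.DataFrame(merged_rows, columns=["chrom", "start", "end", "strand"])
    order = np.lexsort((out_sites["start"].to_numpy(),
                        out_sites["chrom"].to_numpy()))
    return MethylomeMatrix(
        sites=out_sites.iloc[order],
        meth=np.asarray(merged_meth)[order],
        total=np.asarray(merged_total)[order],
        samples=list(matrix.samples),
    )


def exclude_outliers_and_snps(matrix: MethylomeMatrix,
                              snp_regions: RegionSet | None = None,
                              cov_quantile: float = 0.999) -> MethylomeMatrix:
    """Mask extreme-coverage entries and drop SNP-overlapping sites.

    Entries with coverage strictly above the per-sample ``cov_quantile`` of
    observed coverages become unobserved (total set to 0).  Sites whose
    position overlaps any SNP interval are dropped entirely.
    """
    meth = matrix.meth.copy()
    total = matrix.total.copy()
    for j in range(matrix.n_samples):
        obs = total[:, j] > 0
        if not obs.any():
            continue
        thr = np.quantile(total[obs, j], cov_quantile)
        mask = obs & (total[:, j] > thr)
        total[mask, j] = 0
        meth[mask, j] = 0
    keep = np.ones(matrix.n_sites, dtype=bool)
    if snp_regions is not None and len(snp_regions):
        from .regions import assign_sites

        member = assign_sites(matrix.sites, {"snp": snp_regions}, strict=False)
        keep = ~member["snp"].to_numpy()
    return MethylomeMatrix(matrix.sites[keep], meth[keep], total[keep],
                           list(matrix.samples))


def run_preprocess(matrix: MethylomeMatrix, sheet: pd.DataFrame,
                   snp_regions: RegionSet | None = None,
                   min_cov: int = 10, max_low_frac: float = 0.5,
                   cov_quantile: float = 0.999,
                   ) -> tuple[MethylomeMatrix, FilterReport]:
    """Full filter chain: common -> coverage -> outlier/SNP -> strands -> shorth.

    The shorth variance filter runs last, after strand aggregation, so that
    variance is measured on the final CpG-level fractions.  Entries masked by
    the outlier rule can break the common-site property, so the intersection
    is re-applied after masking.
    """
    order = [matrix.samples.index(s) for s in sheet["sample_id"]]
    if order != list(range(matrix.n_samples)):
        matrix = matrix.subset_samples(sheet["sample_id"].tolist())
    ages = sheet["age"].to_numpy()
    cr_mask = (sheet["group"] == CR).to_numpy()

    n_input = matrix.n_sites
    matrix = matrix.subset_sites(intersect_common_sites(matrix))
    n_common = matrix.n_sites

    keep = coverage_filter(matrix, ages, cr_mask, min_cov, max_low_frac)
    matrix = matrix.subset_sites(keep)
    n_cov = matrix.n_sites

    matrix = exclude_outliers_and_snps(matrix, snp_regions, cov_quantile)
    matrix = matrix.subset_sites(intersect_common_sites(matrix))
    n_snp = matrix.n_sites

    matrix = aggregate_cpg_strands(matrix)
    n_agg = matrix.n_sites

    keep, thr = shorth_sd_filter(matrix)
    matrix = matrix.subset_sites(keep)

    report = FilterReport(
        n_input_sites=n_input,
        n_after_common=n_common,
        n_after_coverage=n_cov,
        n_after_outlier_snp=n_snp,
        n_after_aggregation=n_agg,
        n_after_shorth=matrix.n_sites,
        shorth_threshold=thr,
    )
    return matrix, report
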