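"""Core in-memory containers shared across the pipeline.

The central object is :class:`MethylomeMatrix`, a sites x samples pair of
integer count matrices (methylated reads, total reads) with genomic site
coordinates held 0-based half-open.  A total count of zero means the site was
not observed in that sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SITE_COLUMNS = ("chrom", "start", "end")

CONTROL = "control"
CR = "CR"


@dataclass
class MethylomeMatrix:
    """Methylated / total read counts for a set of CpG sites across samples.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom`` (str), ``start``, ``end`` (int,
        0-based half-open) and optionally ``strand`` ('+', '-' or '.').
    meth, total
        Integer arrays of shape ``(n_sites, n_samples)``.  ``total == 0``
        marks an unobserved entry.
    samples
        Sample identifiers, one per column.
    """

    sites: pd.DataFrame
    meth: np.ndarray
    total: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.meth = np.asarray(self.meth)
        self.total = np.asarray(self.total)
        if self.meth.shape != self.total.shape:
            raise ValueError("meth and total shapes differ")
        if self.meth.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"count shape {self.meth.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if (self.meth > self.total).any():
            raise ValueError("methylated count exceeds total coverage")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def fractions(self) -> np.ndarray:
        """Methylation fraction M / (M + U); NaN where unobserved."""
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.meth / self.total
        return np.where(self.total > 0, f, np.nan)

    def site_ids(self) -> pd.Index:
        return pd.Index(
            self.sites["chrom"].astype(str) + ":" + self.sites["start"].astype(str)
        )

    def subset_sites(self, mask_or_idx) -> "MethylomeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return MethylomeMatrix(
            sites=self.sites.iloc[idx],
            meth=self.meth[idx],
            total=self.total[idx],
            samples=list(self.samples),
        )

    def subset_samples(self, sample_ids: list[str]) -> "MethylomeMatrix":
        pos = [self.samples.index(s) for s in sample_ids]
        return MethylomeMatrix(
            sites=self.sites,
            meth=self.meth[:, pos],
            total=self.total[:, pos],
            samples=list(sample_ids),
        )


SAMPLE_SHEET_COLUMNS = ("sample_id", "age", "group", "t0")


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet and return it with canonical dtypes.

    Required columns: ``sample_id``, ``age`` (months, positive), ``group``
    (``control`` or ``CR``) and ``t0`` (treatment-start age, CR rows only;
    NaN for controls).  Any additional numeric columns are treated as
    confounders downstream.
    """
    missing = [c for c in ("sample_id", "age", "group") if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    sheet = sheet.copy()
    if "t0" not in sheet.columns:
        sheet["t0"] = np.nan
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    sheet["age"] = sheet["age"].astype(float)
    if (sheet["age"] <= 0).any():
        raise ValueError("ages must be positive (months)")
    bad = set(sheet["group"]) - {CONTROL, CR}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)} (expected control/CR)")
    cr = sheet["group"] == CR
    if cr.any():
        t0 = sheet.loc[cr, "t0"].astype(float)
        if t0.isna().any():
            raise ValueError("CR samples must carry a treatment-start age t0")
        if (t0.values >= sheet.loc[cr, "age"].values).any():
            raise ValueError("t0 must precede the age of every CR sample")
    return sheet


def confounder_matrix(sheet: pd.DataFrame, columns: list[str] | None = None) -> np.ndarray | None:
    """Extract confounder columns as a float matrix (or None if none given)."""
    if not columns:
        return None
    for c in columns:
        if c not in sheet.columns:
            raise ValueError(f"confounder column '{c}' not in sample sheet")
    X = sheet[list(columns)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("confounder columns contain missing values")
    return X


@dataclass
class RegionSet:
    """Labeled genomic intervals, 0-based half-open.

    ``intervals`` has columns chrom, start, end, strand, label.
    """

    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.intervals
        for col, default in (("strand", "."), ("label", "")):
            if col not in df.columns:
                df = df.assign(**{col: default})
        if len(df) and (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(
                f"interval with start >= end: {bad['chrom']}:{bad['start']}-{bad['end']}"
            )
        self.intervals = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def labels(self) -> list[str]:
        return sorted(self.intervals["label"].unique())
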