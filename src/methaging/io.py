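"""Readers and writers for the formats the pipeline touches.

Coverage files follow the bismark-coverage dialect: tab-separated
``chrom  start  end  methylation_percent  count_methylated  count_unmethylated``
with 1-based inclusive positions.  Internally all coordinates are 0-based
half-open; this module is the single conversion point.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import MethylomeMatrix, RegionSet, validate_sample_sheet

__all__ = [
    "read_coverage_file",
    "read_coverage_files",
    "write_coverage_file",
    "read_sample_sheet",
    "read_bed_regions",
    "read_region_dir",
    "read_fraction_matrix",
    "write_results",
    "load_config",
]

_COV_COLUMNS = ["chrom", "start", "end", "pct", "meth", "unmeth"]


def read_coverage_file(path) -> pd.DataFrame:
    """Parse one bismark-coverage file into a per-site count frame.

    Returns columns chrom, start, end (converted to 0-based half-open),
    meth, unmeth.  The methylation-percent column is ignored; fractions are
    recomputed from counts downstream.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=_COV_COLUMNS, comment="#",
            dtype={"chrom": str},
        )
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse as bismark coverage: {exc}") from exc
    for col in ("start", "end", "meth", "unmeth"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(vals.index[vals.isna()][0]) + 1
            raise ValueError(f"{path}: malformed {col} field at line {line}")
        df[col] = vals.astype(int)
    if (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
        line = int(df.index[(df["meth"] < 0) | (df["unmeth"] < 0)][0]) + 1
        raise ValueError(f"{path}: negative count at line {line}")
    dup = df.duplicated(subset=["chrom", "start"])
    if dup.any():
        line = int(df.index[dup][0]) + 1
        raise ValueError(f"{path}: duplicate site at line {line}")
    # bismark is 1-based inclusive; internal is 0-based half-open
    df["start"] = df["start"] - 1
    df = df.drop(columns=["pct"])
    return df


def read_coverage_files(paths, sample_ids=None) -> MethylomeMatrix:
    """Read one coverage file per sample into a MethylomeMatrix.

    Sites form the union over samples; unobserved entries get total = 0.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no coverage files given")
    if sample_ids is None:
        sample_ids = [p.stem for p in paths]
    frames = []
    for sid, p in zip(sample_ids, paths):
        df = read_coverage_file(p)
        df["sample"] = sid
        frames.append(df)
    long = pd.concat(frames, ignore_index=True)
    long["total"] = long["meth"] + long["unmeth"]
    meth = long.pivot_table(index=["chrom", "start", "end"], columns="sample",
                            values="meth", fill_value=0, aggfunc="first")
    total = long.pivot_table(index=["chrom", "start", "end"], columns="sample",
                             values="total", fill_value=0, aggfunc="first")
    meth = meth[sample_ids]
    total = total[sample_ids]
    sites = meth.index.to_frame(index=False)
    return MethylomeMatrix(
        sites=sites,
        meth=meth.to_numpy(dtype=np.int64),
        total=total.to_numpy(dtype=np.int64),
        samples=list(sample_ids),
    )


def write_coverage_file(path, matrix: MethylomeMatrix, sample_index: int) -> None:
    """Write one sample's observed sites in the bismark-coverage dialect."""
    total = matrix.total[:, sample_index]
    meth = matrix.meth[:, sample_index]
    obs = total > 0
    with np.errstate(invalid="ignore"):
        pct = np.where(obs, 100.0 * meth / np.maximum(total, 1), 0.0)
    df = pd.DataFrame(
        {
            "chrom": matrix.sites["chrom"],
            "start": matrix.sites["start"] + 1,  # back to 1-based inclusive
            "end": matrix.sites["end"],
            "pct": np.round(pct, 6),
            "meth": meth,
            "unmeth": total - meth,
        }
    )[obs]
    df.to_csv(path, sep="\t", header=False, index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    return validate_sample_sheet(sheet)


def read_bed_regions(path, label: str | None = None) -> RegionSet:
    """Read a BED3+ file (already 0-based half-open) into a RegionSet."""
    path = Path(path)
    if label is None:
        label = path.stem
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         dtype={0: str})
    except pd.errors.EmptyDataError:
        return RegionSet(pd.DataFrame(columns=["chrom", "start", "end", "strand", "label"]))
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs >= 3 columns")
    out = pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "start": df[1].astype(int),
            "end": df[2].astype(int),
            "strand": df[5].astype(str) if df.shape[1] >= 6 else ".",
            "label": label,
        }
    )
    return RegionSet(out)


def read_region_dir(directory) -> dict[str, RegionSet]:
    """Read every ``*.bed`` in a directory; labels are the file stems."""
    directory = Path(directory)
    beds = sorted(directory.glob("*.bed"))
    if not beds:
        raise ValueError(f"no .bed files in {directory}")
    return {p.stem: read_bed_regions(p) for p in beds}


def read_fraction_matrix(path) -> tuple[pd.DataFrame, list[str]]:
    """Generic sites x samples fraction table (values in [0, 1]).

    For array-style data without read counts; count-dependent filters do not
    apply to such input.  Returns (frame indexed by site id, sample list).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy(dtype=float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("fraction matrix values must lie in [0, 1]")
    return df, list(df.columns)


def write_matrix_tsv(path, matrix: MethylomeMatrix) -> None:
    """Write a MethylomeMatrix as one wide TSV (site columns + meth:/total: pairs)."""
    sites = matrix.sites.copy()
    if "strand" not in sites.columns:
        sites["strand"] = "."
    meth = pd.DataFrame(matrix.meth,
                        columns=[f"meth:{s}" for s in matrix.samples])
    total = pd.DataFrame(matrix.total,
                         columns=[f"total:{s}" for s in matrix.samples])
    df = pd.concat([sites.reset_index(drop=True), meth, total], axis=1)
    df.to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path) -> MethylomeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    meth_cols = [c for c in df.columns if c.startswith("meth:")]
    total_cols = [c for c in df.columns if c.startswith("total:")]
    samples = [c.split(":", 1)[1] for c in meth_cols]
    if samples != [c.split(":", 1)[1] for c in total_cols]:
        raise ValueError(f"{path}: meth:/total: sample columns disagree")
    site_cols = [c for c in ("chrom", "start", "end", "strand") if c in df.columns]
    return MethylomeMatrix(
        sites=df[site_cols],
        meth=df[meth_cols].to_numpy(dtype=np.int64),
        total=df[total_cols].to_numpy(dtype=np.int64),
        samples=samples,
    )


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_results(tables: dict[str, pd.DataFrame], out_dir,
                  metadata: dict | None = None) -> list[Path]:
    """Write result tables as TSV with a ``#``-prefixed run-metadata header.

    Column order is preserved; reruns with identical inputs produce
    byte-identical bodies (header carries config hash / seed / version).
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = dict(metadata or {})
    meta.setdefault("version", __version__)
    header = "".join(f"# {k}: {v}\n" for k, v in sorted(meta.items()))
    written = []
    for name, table in tables.items():
        path = out / f"{name}.tsv"
        body = table.to_csv(sep="\t", index=False)
        path.write_text(header + body)
        written.append(path)
    return written


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
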