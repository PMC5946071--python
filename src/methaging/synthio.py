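"""Synthetic aging / calorie-restriction RRBS cohort generator.

Produces methylated/total count matrices with known per-site ground truth so
every downstream stage (filtering, age regression, entropy, CR decomposition)
can be tested for recovery.  Site mean trajectories come from five families:

``stable``
    constant fraction ``m0``.
``linear``
    ``m(age) = m0 + slope * age``.
``late_accel``
    the inverse of the late-life acceleration law ``age = a + b * m**-13``,
    i.e. ``m(age) = ((age - a) / b) ** (-1/13)`` — changes concentrate near
    the end of life.
``early_change``
    ``m(age) = m0 + d * ln(age)`` — changes concentrate in early adulthood.
``entropy_drift``
    exponential shrinkage toward 0.5 at per-month rate ``kappa``:
    ``m(age) = 0.5 + (m0 - 0.5) * exp(-kappa * age)``.

Observed counts are coverage ~ NegativeBinomial (floored at 1 read) and
methylated reads ~ Binomial(coverage, latent fraction + Gaussian jitter).
All randomness descends from one cohort seed; each site draws from its own
deterministic substream, so a site's data do not depend on which other sites
are generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CONTROL, CR, MethylomeMatrix

CLIP_LO = 0.001
CLIP_HI = 0.999

CLASS_NAMES = ("stable", "linear", "late_accel", "early_change", "entropy_drift")

#: power of the late-life acceleration law age = a + b * m**POWER
LATE_ACCEL_POWER = -13

# Study-condition defaults: 16 age groups spanning adult lifespan (months)
DEFAULT_AGE_GROUPS = (3, 5, 7, 9, 11, 13, 15, 17, 19, 21, 23, 25, 27, 29, 32, 35)
DEFAULT_CR_AGE_GROUPS = (10, 16, 21, 27)

DEFAULT_CLASS_MIXTURE = {
    "stable": 0.79,
    "late_accel": 0.12,
    "linear": 0.04,
    "early_change": 0.02,
    "entropy_drift": 0.03,
}


@dataclass
class SiteClassSpec:
    """Parameters of one site's mean methylation trajectory."""

    class_name: str
    m0: float = 0.5
    slope: float = 0.0       # linear class: fraction per month
    a: float = 0.0           # late_accel: age = a + b * m**-13
    b: float = 0.0
    d: float = 0.0           # early_change: m = m0 + d * ln(age)
    kappa: float = 0.0       # entropy_drift: per-month shrinkage toward 0.5

    def __post_init__(self) -> None:
        if self.class_name not in CLASS_NAMES:
            raise ValueError(f"unknown site class '{self.class_name}'")
        if not 0.0 <= self.m0 <= 1.0:
            raise ValueError(f"m0={self.m0} outside [0, 1]")


@dataclass
class CRSpec:
    """Calorie-restriction effect on one site: step at onset plus extra rate.

    ``is_shift`` is the instantaneous fraction shift at treatment start
    ``t0``; ``tat_slope`` is the additional fraction change per month of
    treatment (time after treatment).
    """

    t0: float = 4.0
    is_shift: float = 0.0
    tat_slope: float = 0.0


@dataclass
class CRDesign:
    """Cohort-level CR arm: sampled ages and site-level effect generation.

    Per-site CR effects are coupled to the site's marginal aging slope:
    ``is_shift = is_coupling * slope + N(0, is_sd)`` and
    ``tat_slope = tat_coupling * slope + N(0, tat_sd)``.  The default
    coupling signs make the initial shift point in the direction of aging
    (positive coupling, in month-equivalents) and the cumulative effect
    oppose it (negative coupling), the structure reported for CR cohorts.
    """

    t0: float = 4.0
    age_groups: tuple = DEFAULT_CR_AGE_GROUPS
    n_per_group: int = 8
    is_coupling: float = 5.0
    tat_coupling: float = -0.3
    is_sd: float = 0.0
    tat_sd: float = 0.0


@dataclass
class CohortDesign:
    """Design of a synthetic cohort.

    Defaults emulate a mouse blood RRBS aging study: 16 age groups from 3 to
    35 months, 9 animals per group, coverage ~ NB(mean 30), per-sample
    Gaussian jitter SD 0.02 on the latent fraction, and a baseline fraction
    distribution that is bimodal near 0 and 1 with a mean slightly below 0.5.
    """

    age_groups: tuple = DEFAULT_AGE_GROUPS
    n_per_group: int = 9
    n_sites: int = 10_000
    class_mixture: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIXTURE))
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    noise_sd: float = 0.02
    seed: int = 0
    cr: CRDesign | None = None

    def __post_init__(self) -> None:
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mixture proportions sum to {total}, not 1")
        bad = set(self.class_mixture) - set(CLASS_NAMES)
        if bad:
            raise ValueError(f"unknown classes in mixture: {sorted(bad)}")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if self.n_sites < 1 or self.n_per_group < 1:
            raise ValueError("n_sites and n_per_group must be >= 1")
        if min(self.age_groups) <= 0:
            raise ValueError("ages must be positive")


def simulate_trajectory(spec: SiteClassSpec, ages) -> np.ndarray:
    """Latent mean methylation fraction at each age, clipped to [0.001, 0.999]."""
    ages = np.asarray(ages, dtype=float)
    if (ages <= 0).any():
        raise ValueError("ages must be positive")
    c = spec.class_name
    if c == "stable":
        m = np.full_like(ages, spec.m0)
    elif c == "linear":
        m = spec.m0 + spec.slope * ages
    elif c == "late_accel":
        if spec.b == 0:
            raise ValueError(f"late_accel site with b=0 (a={spec.a})")
        u = (ages - spec.a) / spec.b
        if (u <= 0).any():
            raise ValueError(
                f"late_accel law age = a + b*m**-13 undefined at ages "
                f"{ages[u <= 0].tolist()} for a={spec.a}, b={spec.b}"
            )
        m = u ** (1.0 / LATE_ACCEL_POWER)
    elif c == "early_change":
        m = spec.m0 + spec.d * np.log(ages)
    elif c == "entropy_drift":
        m = 0.5 + (spec.m0 - 0.5) * np.exp(-spec.kappa * ages)
    else:  # pragma: no cover - guarded in SiteClassSpec
        raise ValueError(c)
    return np.clip(m, CLIP_LO, CLIP_HI)


def late_accel_from_endpoints(age_lo, age_hi, m_lo, m_hi) -> tuple[float, float]:
    """Solve (a, b) of ``age = a + b * m**-13`` through two (age, m) points."""
    u_lo = m_lo ** float(LATE_ACCEL_POWER)
    u_hi = m_hi ** float(LATE_ACCEL_POWER)
    if u_lo == u_hi:
        raise ValueError("degenerate endpoints: m_lo == m_hi")
    b = (age_hi - age_lo) / (u_hi - u_lo)
    a = age_lo - b * u_lo
    return a, b


def apply_cr(latent: np.ndarray, ages, cr: CRSpec, treated=None) -> np.ndarray:
    """Add the CR step-plus-slope effect to treated samples past onset.

    ``latent`` is fractions per sample (last axis aligned with ``ages``).
    ``treated`` is a boolean mask per sample; default all treated.
    """
    ages = np.asarray(ages, dtype=float)
    latent = np.asarray(latent, dtype=float)
    if treated is None:
        treated = np.ones(ages.shape, dtype=bool)
    treated = np.asarray(treated, dtype=bool)
    eligible = treated & (ages >= cr.t0)
    effect = np.where(eligible, cr.is_shift + cr.tat_slope * (ages - cr.t0), 0.0)
    return np.clip(latent + effect, 0.0, 1.0)


def _mixture_counts(mixture: dict, n_sites: int) -> dict:
    """Deterministic largest-remainder allocation of sites to classes."""
    names = [c for c in CLASS_NAMES if mixture.get(c, 0.0) > 0]
    raw = np.array([mixture[c] * n_sites for c in names])
    counts = np.floor(raw).astype(int)
    rem = n_sites - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in range(rem):
        counts[order[i % len(names)]] += 1
    return dict(zip(names, counts))


def _draw_baseline(rng: np.random.Generator, mode: str) -> float:
    """Bimodal baseline fraction: 'low' near 0, 'high' near 1, 'any' mixture."""
    if mode == "any":
        # slight excess of the low mode -> genome slightly hypomethylated
        mode = "low" if rng.random() < 0.52 else "high"
    if mode == "low":
        return float(np.clip(rng.beta(1.0, 8.0), 0.02, 0.45))
    return float(np.clip(rng.beta(8.0, 1.0), 0.55, 0.98))


def _draw_site_params(rng: np.random.Generator, class_name: str,
                      age_lo: float, age_hi: float) -> SiteClassSpec:
    """Draw one site's trajectory parameters for the given class."""
    if class_name == "stable":
        return SiteClassSpec("stable", m0=_draw_baseline(rng, "any"))
    gain = rng.random() < 0.5
    if class_name == "linear":
        m0 = _draw_baseline(rng, "low" if gain else "high")
        mag = rng.uniform(0.005, 0.010)
        return SiteClassSpec("linear", m0=m0, slope=mag if gain else -mag)
    if class_name == "late_accel":
        delta = rng.uniform(0.15, 0.35)
        if gain:
            m_lo = rng.uniform(0.05, 0.30)
            m_hi = m_lo + delta
        else:
            m_lo = rng.uniform(0.70, 0.95)
            m_hi = m_lo - delta
        a, b = late_accel_from_endpoints(age_lo, age_hi, m_lo, m_hi)
        return SiteClassSpec("late_accel", m0=m_lo, a=a, b=b)
    if class_name == "early_change":
        m0 = _draw_baseline(rng, "low" if gain else "high")
        mag = rng.uniform(0.03, 0.08)
        return SiteClassSpec("early_change", m0=m0, d=mag if gain else -mag)
    if class_name == "entropy_drift":
        m0 = _draw_baseline(rng, "any")
        return SiteClassSpec("entropy_drift", m0=m0, kappa=rng.uniform(0.01, 0.04))
    raise ValueError(class_name)


def marginal_slope(spec: SiteClassSpec, age_lo: float, age_hi: float) -> float:
    """Lifespan-average rate of change (fraction / month) of a trajectory."""
    m = simulate_trajectory(spec, [age_lo, age_hi])
    return float((m[1] - m[0]) / (age_hi - age_lo))


def build_sample_sheet(design: CohortDesign) -> pd.DataFrame:
    rows = []
    k = 0
    for age in design.age_groups:
        for _ in range(design.n_per_group):
            rows.append((f"ctrl_{k:03d}", float(age), CONTROL, np.nan))
            k += 1
    if design.cr is not None:
        k = 0
        for age in design.cr.age_groups:
            for _ in range(design.cr.n_per_group):
                rows.append((f"cr_{k:03d}", float(age), CR, design.cr.t0))
                k += 1
    return pd.DataFrame(rows, columns=["sample_id", "age", "group", "t0"])


def sample_counts(latent: np.ndarray, design: CohortDesign,
                  site_rngs: list[np.random.Generator] | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Draw (meth, total) counts for latent fractions of shape (sites, samples).

    Coverage is negative-binomial with mean ``coverage_mean`` and size
    ``coverage_dispersion``, floored at one read; methylated reads are
    binomial in the jittered latent fraction.
    """
    latent = np.atleast_2d(np.asarray(latent, dtype=float))
    if latent.min() < 0 or latent.max() > 1:
        raise ValueError("latent fractions must lie in [0, 1]")
    if design.coverage_mean <= 0:
        raise ValueError("coverage_mean must be positive")
    n_sites, n_samples = latent.shape
    if site_rngs is None:
        ss = np.random.SeedSequence(design.seed)
        site_rngs = [np.random.default_rng(c) for c in ss.spawn(n_sites)]
    r = design.coverage_dispersion
    p_nb = r / (r + design.coverage_mean)
    meth = np.empty(latent.shape, dtype=np.int64)
    total = np.empty(latent.shape, dtype=np.int64)
    for i in range(n_sites):
        rng = site_rngs[i]
        cov = np.maximum(rng.negative_binomial(r, p_nb, size=n_samples), 1)
        frac = np.clip(latent[i] + rng.normal(0.0, design.noise_sd, size=n_samples), 0.0, 1.0)
        total[i] = cov
        meth[i] = rng.binomial(cov, frac)
    return meth, total


def generate_cohort(design: CohortDesign
                    ) -> tuple[MethylomeMatrix, pd.DataFrame, pd.DataFrame]:
    """Generate a full cohort: counts, sample sheet, and ground-truth table.

    Returns ``(matrix, sample_sheet, truth)``.  ``truth`` has one row per
    site: class name, trajectory parameters, marginal direction, and the CR
    effect parameters (zero when no CR arm is designed).
    """
    sheet = build_sample_sheet(design)
    ages = sheet["age"].to_numpy()
    treated = (sheet["group"] == CR).to_numpy()
    age_lo, age_hi = float(min(design.age_groups)), float(max(design.age_groups))

    ss = np.random.SeedSequence(design.seed)
    children = ss.spawn(design.n_sites + 1)
    master = np.random.default_rng(children[0])
    site_rngs = [np.random.default_rng(c) for c in children[1:]]

    counts = _mixture_counts(design.class_mixture, design.n_sites)
    class_of = np.concatenate([[name] * n for name, n in counts.items()])
    master.shuffle(class_of)

    specs = [_draw_site_params(master, c, age_lo, age_hi) for c in class_of]
    slopes = np.array([marginal_slope(s, age_lo, age_hi) for s in specs])

    crd = design.cr
    if crd is not None:
        is_shift = crd.is_coupling * slopes
        tat = crd.tat_coupling * slopes
        if crd.is_sd > 0:
            is_shift = is_shift + master.normal(0, crd.is_sd, design.n_sites)
        if crd.tat_sd > 0:
            tat = tat + master.normal(0, crd.tat_sd, design.n_sites)
        t0 = crd.t0
    else:
        is_shift = np.zeros(design.n_sites)
        tat = np.zeros(design.n_sites)
        t0 = np.nan

    latent = np.empty((design.n_sites, len(sheet)))
    for i, spec in enumerate(specs):
        traj = simulate_trajectory(spec, ages)
        if crd is not None:
            traj = apply_cr(traj, ages, CRSpec(t0, is_shift[i], tat[i]), treated)
        latent[i] = traj

    meth, total = sample_counts(latent, design, site_rngs=site_rngs)

    starts = 100 * np.arange(design.n_sites)
    sites = pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + 2, "strand": "+"}
    )
    matrix = MethylomeMatrix(sites, meth, total, sheet["sample_id"].tolist())

    truth = pd.DataFrame(
        {
            "site_id": matrix.site_ids(),
            "class_name": class_of,
            "m0": [s.m0 for s in specs],
            "slope": [s.slope for s in specs],
            "a": [s.a for s in specs],
            "b": [s.b for s in specs],
            "d": [s.d for s in specs],
            "kappa": [s.kappa for s in specs],
            "marginal_slope": slopes,
            "direction": np.where(
                class_of == "stable", "none", np.where(slopes > 0, "gain", "loss")
            ),
            "is_shift": is_shift,
            "tat_slope": tat,
        }
    )
    return matrix, sheet, truth


def write_cohort(out_dir, matrix: MethylomeMatrix, sheet: pd.DataFrame,
                 truth: pd.DataFrame) -> None:
    """Write per-sample bismark-coverage files, sample sheet and truth table."""
    from . import io as mio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for j, sid in enumerate(matrix.samples):
        mio.write_coverage_file(out / f"{sid}.cov", matrix, j)
    sheet.to_csv(out / "samples.tsv", sep="\t", index=False)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
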