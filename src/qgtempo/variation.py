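"""Coefficient-of-variation estimation and comparison.

The coefficient of variation, CV = s / x̄ (sample SD over sample mean),
standardizes variability by the mean and is the unit for comparing relative
trait variation across groups and species.  Facilities here:

* :func:`cv_estimate` — sample CV with the small-sample correction
  ``CV * (1 + 1/(4n))``, applied by default for n < 30.
* :func:`pooled_within_sex_cv` — CV from sex-stratified variances and a
  weighted grand mean, removing the contribution of sexual dimorphism.
* :func:`delta_cv` / :func:`delta_cv_ci` — difference of two group CVs in
  percentage points with a bootstrap (default) or asymptotic confidence
  interval.
* :func:`cv_percentile` — placement of a focal species' CV within a
  comparative species distribution.

CVs are stored as proportions internally and rendered as percent only in
output (hence ΔCV in percentage points).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import SpeciesCVTable, SpecimenTable, ValidationError

__all__ = [
    "CVEstimate",
    "DeltaCV",
    "CVPercentile",
    "cv_estimate",
    "pooled_within_sex_cv",
    "total_cv_from_rows",
    "delta_cv",
    "delta_cv_ci",
    "cv_percentile",
    "plot_cv_distribution",
]

#: below this sample size the (1 + 1/(4n)) correction is applied by default
SMALL_SAMPLE_N = 30


@dataclass(frozen=True)
class CVEstimate:
    cv: float
    n: int
    corrected: bool
    sex_pooling: str = "none"
    n_excluded_unknown_sex: int = 0


@dataclass(frozen=True)
class DeltaCV:
    """CV_A − CV_B in percentage points, with a confidence interval."""

    delta: float
    ci_low: float
    ci_high: float
    level: float
    method: str
    n_a: int
    n_b: int
    seed: int | None = None
    corrected: bool = False
    warning: str | None = None


@dataclass(frozen=True)
class CVPercentile:
    """Placement of a focal CV in a comparative species distribution."""

    percentile: float
    n_species: int
    cv_min: float
    cv_median: float
    cv_max: float


def _resolve_corrected(corrected: bool | None, n: int) -> bool:
    return (n < SMALL_SAMPLE_N) if corrected is None else bool(corrected)


def _raw_cv(values: np.ndarray) -> tuple[float, float, float]:
    mean = float(np.mean(values))
    if mean <= 0:
        raise ValidationError(f"CV needs a positive mean, got {mean}")
    sd = float(np.std(values, ddof=1))
    return sd / mean, mean, sd


def cv_estimate(values, corrected: bool | None = None) -> CVEstimate:
    """Sample coefficient of variation, optionally small-sample corrected.

    ``corrected=None`` (default) applies the (1 + 1/(4n)) correction for
    n < 30; pass True/False to force.  Requires n >= 2 and a positive mean.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValidationError(f"cv_estimate needs >= 2 values, got {x.size}")
    cv, _, _ = _raw_cv(x)
    n = len(x)
    use_corr = _resolve_corrected(corrected, n)
    if use_corr:
        cv *= 1 + 1 / (4 * n)
    return CVEstimate(cv=cv, n=n, corrected=use_corr)


def _sex_summaries(data) -> tuple[pd.DataFrame, int]:
    """Per-sex (n, mean, sd) rows and the count of excluded unknown-sex records."""
    if isinstance(data, SpecimenTable):
        df = data.records
        n_unknown = int((df["sex"] == "unknown").sum())
        known = df[df["sex"] != "unknown"]
        if known.empty:
            raise ValidationError("no known-sex specimens for within-sex pooling")
        g = known.groupby("sex")["value"]
        summ = pd.DataFrame(
            {"n": g.count(), "mean": g.mean(), "sd": g.std(ddof=1)}
        ).reset_index()
        return summ, n_unknown
    df = pd.DataFrame(data)
    df = df[df["sex"] != "pooled"]
    return df.loc[:, ["sex", "n", "mean", "sd"]].reset_index(drop=True), 0


def pooled_within_sex_cv(data, corrected: bool | None = None) -> CVEstimate:
    """CV from sex-stratified variances, controlling for sexual dimorphism.

    ``CV = sqrt( Σ_s (n_s−1) sd_s² / Σ_s (n_s−1) ) / ( Σ_s n_s mean_s / Σ_s n_s )``
    over sex classes s.  Accepts a :class:`SpecimenTable` (unknown-sex
    specimens are excluded, count reported) or the per-sex summary rows of a
    :class:`SpeciesCVTable` for one species.  At least one sex class must
    have n >= 2.
    """
    summ, n_unknown = _sex_summaries(data)
    ns = summ["n"].to_numpy(dtype=float)
    means = summ["mean"].to_numpy(dtype=float)
    sds = summ["sd"].to_numpy(dtype=float)
    if not (ns >= 2).any():
        raise ValidationError("within-sex pooling needs a sex class with n >= 2")
    w = ns - 1
    use = w > 0
    pooled_var = float(np.sum(w[use] * sds[use] ** 2) / np.sum(w[use]))
    grand_mean = float(np.sum(ns * means) / np.sum(ns))
    if grand_mean <= 0:
        raise ValidationError("within-sex pooling needs a positive grand mean")
    cv = math.sqrt(pooled_var) / grand_mean
    n_total = int(np.sum(ns))
    use_corr = _resolve_corrected(corrected, n_total)
    if use_corr:
        cv *= 1 + 1 / (4 * n_total)
    return CVEstimate(
        cv=cv,
        n=n_total,
        corrected=use_corr,
        sex_pooling="within_sex",
        n_excluded_unknown_sex=n_unknown,
    )


def total_cv_from_rows(rows, corrected: bool | None = None) -> CVEstimate:
    """Total-sample CV (dimorphism included) recombined from per-sex summaries.

    Total variance = (within-class SS + between-class SS) / (N − 1).
    """
    df = pd.DataFrame(rows)
    df = df[df["sex"] != "pooled"]
    ns = df["n"].to_numpy(dtype=float)
    means = df["mean"].to_numpy(dtype=float)
    sds = df["sd"].to_numpy(dtype=float)
    n_total = float(np.sum(ns))
    if n_total < 2:
        raise ValidationError("total CV needs n >= 2 overall")
    grand = float(np.sum(ns * means) / n_total)
    if grand <= 0:
        raise ValidationError("total CV needs a positive grand mean")
    ss_within = float(np.sum((ns - 1) * sds**2))
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    cv = math.sqrt((ss_within + ss_between) / (n_total - 1)) / grand
    use_corr = _resolve_corrected(corrected, int(n_total))
    if use_corr:
        cv *= 1 + 1 / (4 * n_total)
    return CVEstimate(cv=cv, n=int(n_total), corrected=use_corr)


def delta_cv(values_a, values_b, corrected: bool | None = None) -> DeltaCV:
    """Point estimate of CV_A − CV_B in percentage points (no interval)."""
    est_a = cv_estimate(values_a, corrected=corrected)
    est_b = cv_estimate(values_b, corrected=corrected)
    return DeltaCV(
        delta=(est_a.cv - est_b.cv) * 100.0,
        ci_low=math.nan,
        ci_high=math.nan,
        level=math.nan,
        method="point",
        n_a=est_a.n,
        n_b=est_b.n,
        corrected=est_a.corrected or est_b.corrected,
    )


def _boot_cvs(
    x: np.ndarray, n_boot: int, rng: np.random.Generator, corr: float
) -> tuple[np.ndarray, int]:
    """Bootstrap CV replicates; degenerate (non-positive-mean) resamples redrawn."""
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    samples = x[idx]
    means = samples.mean(axis=1)
    sds = samples.std(axis=1, ddof=1)
    n_redrawn = 0
    bad = means <= 0
    attempts = 0
    while bad.any():
        attempts += 1
        if attempts > 1000:
            raise ValidationError("bootstrap: too many degenerate (zero-mean) resamples")
        n_redrawn += int(bad.sum())
        redo = x[rng.integers(0, n, size=(int(bad.sum()), n))]
        means[bad] = redo.mean(axis=1)
        sds[bad] = redo.std(axis=1, ddof=1)
        bad = means <= 0
    return corr * sds / means, n_redrawn


def delta_cv_ci(
    values_a,
    values_b,
    method: str = "bootstrap",
    level: float = 0.95,
    n_boot: int = 10_000,
    seed: int | None = None,
    corrected: bool | None = None,
) -> DeltaCV:
    """CV_A − CV_B with a confidence interval, in percentage points.

    ``bootstrap`` (default): the two groups are resampled independently with
    replacement; the interval is the percentile interval of the ΔCV
    replicates, reproducible given ``seed``.  ``asymptotic``: a normal
    interval from the large-sample approximation
    ``var(CV) ≈ CV²(0.5 + CV²)/n`` per group, variances summed.
    """
    x_a = np.asarray(values_a, dtype=float)
    x_b = np.asarray(values_b, dtype=float)
    est_a = cv_estimate(x_a, corrected=corrected)
    est_b = cv_estimate(x_b, corrected=corrected)
    point = (est_a.cv - est_b.cv) * 100.0
    corr_a = 1 + 1 / (4 * est_a.n) if est_a.corrected else 1.0
    corr_b = 1 + 1 / (4 * est_b.n) if est_b.corrected else 1.0
    warning = None

    if method == "bootstrap":
        if n_boot < 1000:
            raise ValidationError("bootstrap needs n_boot >= 1000")
        rng = np.random.default_rng(seed)
        cv_a, redrawn_a = _boot_cvs(x_a, n_boot, rng, corr_a)
        cv_b, redrawn_b = _boot_cvs(x_b, n_boot, rng, corr_b)
        deltas = (cv_a - cv_b) * 100.0
        alpha = 1 - level
        lo, hi = np.quantile(deltas, [alpha / 2, 1 - alpha / 2])
        if redrawn_a + redrawn_b:
            warning = f"{redrawn_a + redrawn_b} degenerate resamples redrawn"
        if not (lo <= point <= hi):
            warning = ((warning + "; ") if warning else "") + (
                "percentile interval does not bracket the point estimate"
            )
            warnings.warn(warning, stacklevel=2)
    elif method == "asymptotic":
        if est_a.n < 5 or est_b.n < 5:
            raise ValidationError("asymptotic interval needs n >= 5 per sample")
        var = est_a.cv**2 * (0.5 + est_a.cv**2) / est_a.n
        var += est_b.cv**2 * (0.5 + est_b.cv**2) / est_b.n
        half = stats.norm.ppf(1 - (1 - level) / 2) * math.sqrt(var) * 100.0
        lo, hi = point - half, point + half
    else:
        raise ValidationError(f"unknown CI method {method!r}")

    return DeltaCV(
        delta=point,
        ci_low=float(lo),
        ci_high=float(hi),
        level=level,
        method=method,
        n_a=est_a.n,
        n_b=est_b.n,
        seed=seed,
        corrected=est_a.corrected or est_b.corrected,
        warning=warning,
    )


def species_cvs(
    comparative: SpeciesCVTable,
    sex_pooling: str = "within_sex",
    corrected: bool | None = None,
    min_n: int = 2,
) -> pd.Series:
    """Per-species CV from a comparative table, under the requested pooling."""
    if sex_pooling not in ("none", "within_sex"):
        raise ValidationError(f"unknown sex_pooling {sex_pooling!r}")
    out = {}
    for sp in comparative.species:
        rows = comparative.rows_for(sp)
        rows = rows[rows["n"] >= min_n]
        if rows.empty:
            continue
        try:
            if sex_pooling == "within_sex":
                est = pooled_within_sex_cv(rows, corrected=corrected)
            else:
                est = total_cv_from_rows(rows, corrected=corrected)
        except ValidationError:
            continue
        out[sp] = est.cv
    return pd.Series(out, name="cv", dtype=float)


def cv_percentile(
    focal_cv: float,
    comparative: SpeciesCVTable,
    sex_pooling: str = "within_sex",
    corrected: bool | None = None,
    min_n: int = 2,
) -> CVPercentile:
    """Empirical percentile of a focal CV among comparative species CVs.

    Uses the midpoint convention for ties:
    ``100 * (#below + 0.5 * #equal) / n_species``.
    """
    cvs = species_cvs(comparative, sex_pooling=sex_pooling, corrected=corrected, min_n=min_n)
    if len(cvs) < 2:
        raise ValidationError(
            f"comparative table yields {len(cvs)} species CVs; need >= 2"
        )
    vals = cvs.to_numpy()
    pct = 100.0 * (np.sum(vals < focal_cv) + 0.5 * np.sum(vals == focal_cv)) / len(vals)
    return CVPercentile(
        percentile=float(pct),
        n_species=len(vals),
        cv_min=float(vals.min()),
        cv_median=float(np.median(vals)),
        cv_max=float(vals.max()),
    )


def plot_cv_distribution(
    comparative: SpeciesCVTable,
    focal: dict[str, float] | None = None,
    sex_pooling: str = "within_sex",
    corrected: bool | None = None,
    path=None,
    ax=None,
):
    """Histogram of the comparative species CV distribution with focal ticks.

    Each entry of ``focal`` (label -> CV proportion) is drawn as a labelled
    vertical line.  Returns the matplotlib Axes; saves to ``path`` if given.
    """
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    cvs = species_cvs(comparative, sex_pooling=sex_pooling, corrected=corrected)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.hist(cvs.to_numpy() * 100, bins=15, color="0.7", edgecolor="0.3")
    for label, cv in (focal or {}).items():
        ax.axvline(cv * 100, linestyle="--")
        ax.annotate(label, (cv * 100, ax.get_ylim()[1] * 0.95), rotation=90,
                    ha="right", va="top", fontsize=8)
    ax.set_xlabel("CV (%)")
    ax.set_ylabel("number of species")
    ax.set_title(f"species CV distribution ({sex_pooling} pooling)")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
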