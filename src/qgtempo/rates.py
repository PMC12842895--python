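"""Per-generation rates of phenotypic evolution and rate–interval scaling.

Two rate scales are used throughout:

* the **haldane**, change in pooled phenotypic standard deviations per
  generation, ``(z2 - z1) / (s_p * g)``; and
* the **mean-standardized rate**, the per-generation change of the trait
  mean on the natural-log (proportional) scale, ``ln(z2/z1) / g``.

The log-rate/log-interval (LRI) regression of ``log10 |rate|`` on
``log10 interval`` classifies the mode of evolution by its slope: a
sustained directional trend yields slope 0 (rate independent of interval),
an unbiased random walk -0.5, and stasis -1 (net change independent of
interval, so rate falls as 1/interval).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import TraitSeries, ValidationError

__all__ = [
    "RateEstimate",
    "LRIFit",
    "net_divergence_log",
    "pooled_sd",
    "haldane_rate",
    "rate_interval_pairs",
    "lri_fit",
    "MODE_ANCHORS",
]

#: theoretical LRI slopes for each mode of evolution
MODE_ANCHORS = {"directional": 0.0, "random_walk": -0.5, "stasis": -1.0}


@dataclass(frozen=True)
class RateEstimate:
    """Per-generation rate of change over a stated interval, on both scales."""

    interval_generations: float
    delta_sd_units: float
    rate_haldanes: float
    delta_log_mean: float
    rate_mean_standardized: float


@dataclass(frozen=True)
class LRIFit:
    """OLS fit of log10(rate) on log10(interval) with a mode classification."""

    slope: float
    intercept: float
    n_pairs: int
    n_dropped_zero: int
    mode_call: str
    slope_interval: tuple[float, float]


def net_divergence_log(series: TraitSeries, from_bin: int, to_bin: int) -> float:
    """Net divergence ``ln(mean_to / mean_from)`` between two bins.

    Positive when the trait increased toward the more recent bin (for the
    canonical oldest-first ordering with ``from_bin`` older than ``to_bin``).
    """
    means = series.bins["mean"].to_numpy(dtype=float)
    m_from, m_to = means[from_bin], means[to_bin]
    if m_from <= 0 or m_to <= 0:
        raise ValidationError(
            f"net divergence needs positive means, got {m_from} and {m_to}"
        )
    return math.log(m_to / m_from)


def pooled_sd(sd_a: float, n_a: int, sd_b: float, n_b: int) -> float:
    """Pooled SD of two samples: sqrt of the (n-1)-weighted mean variance."""
    if n_a < 2 or n_b < 2:
        raise ValidationError(f"pooled_sd needs n >= 2 on both sides, got {n_a}, {n_b}")
    var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    return math.sqrt(var)


def haldane_rate(
    mean_from: float,
    mean_to: float,
    pooled_sd: float,
    interval_generations: float,
) -> RateEstimate:
    """Rate of evolution in haldanes, with the mean-standardized rate alongside.

    ``rate_haldanes = (mean_to - mean_from) / (pooled_sd * g)`` where the
    pooled SD is that of the two endpoint samples.  The mean-standardized
    fields use ``ln(mean_to/mean_from)`` over the same interval.
    """
    if not interval_generations > 0:
        raise ValidationError("interval_generations must be > 0")
    if not pooled_sd > 0:
        raise ValidationError("pooled_sd must be > 0")
    if mean_from <= 0 or mean_to <= 0:
        raise ValidationError("means must be > 0")
    delta_sd = (mean_to - mean_from) / pooled_sd
    dlog = math.log(mean_to / mean_from)
    return RateEstimate(
        interval_generations=float(interval_generations),
        delta_sd_units=delta_sd,
        rate_haldanes=delta_sd / interval_generations,
        delta_log_mean=dlog,
        rate_mean_standardized=dlog / interval_generations,
    )


def rate_interval_pairs(
    series: TraitSeries,
    scale: str = "mean_standardized",
    generation_time: float | None = None,
) -> pd.DataFrame:
    """Absolute rate over every ordered bin pair of a series.

    All pairwise intervals (not only adjacent bins) are used, since
    rate–interval scaling needs a spread of interval lengths.  On the
    ``haldanes`` scale, bins lacking an SD or with n < 2 are skipped because
    the haldane denominator pools the two endpoint SDs.

    Returns a DataFrame with columns ``interval_generations`` and ``rate``
    (absolute value on the requested scale).
    """
    if scale not in ("haldanes", "mean_standardized"):
        raise ValidationError(f"unknown rate scale {scale!r}")
    ages = series.ages_in_generations(generation_time)
    means = series.bins["mean"].to_numpy(dtype=float)
    sds = series.bins["sd"].to_numpy(dtype=float)
    ns = series.bins["n"].to_numpy(dtype=float)

    if scale == "haldanes":
        usable = np.flatnonzero(~np.isnan(sds) & (ns >= 2))
    else:
        usable = np.arange(len(means))
    if len(usable) < 2:
        raise ValidationError(f"need >= 2 usable bins, have {len(usable)}")

    rows = []
    for ai in range(len(usable)):
        for bi in range(ai + 1, len(usable)):
            i, j = usable[ai], usable[bi]
            interval = abs(ages[i] - ages[j])
            if interval == 0:
                continue
            if scale == "haldanes":
                sp = pooled_sd(sds[i], int(ns[i]), sds[j], int(ns[j]))
                if sp == 0:
                    rate = math.nan if means[i] != means[j] else 0.0
                else:
                    rate = abs(means[j] - means[i]) / (sp * interval)
            else:
                if means[i] <= 0 or means[j] <= 0:
                    raise ValidationError("mean-standardized rates need positive means")
                rate = abs(math.log(means[j] / means[i])) / interval
            rows.append((interval, rate))
    return pd.DataFrame(rows, columns=["interval_generations", "rate"])


def lri_fit(
    pairs: pd.DataFrame,
    classify_tolerance: float = 0.0,
    level: float = 0.95,
) -> LRIFit:
    """Fit the log-rate/log-interval regression and classify the mode.

    Pairs with rate <= ``classify_tolerance`` (and any non-finite rates) are
    dropped before taking logs; their count is reported in
    ``n_dropped_zero``.  The mode is the unique theoretical anchor slope
    (0 directional, -0.5 random walk, -1 stasis) contained in the
    ``level`` confidence interval of the slope; zero or several contained
    anchors yield ``"ambiguous"``.
    """
    intervals = pairs["interval_generations"].to_numpy(dtype=float)
    rates = pairs["rate"].to_numpy(dtype=float)
    keep = np.isfinite(rates) & (rates > classify_tolerance) & (intervals > 0)
    n_dropped = int(len(rates) - keep.sum())
    if keep.sum() < 3:
        raise ValidationError(
            f"LRI fit needs >= 3 positive-rate pairs, have {int(keep.sum())} "
            f"({n_dropped} zero/invalid dropped)"
        )
    x = np.log10(intervals[keep])
    y = np.log10(rates[keep])
    if np.ptp(x) == 0:
        raise ValidationError("LRI fit needs a spread of interval lengths")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(model.params[1])
    intercept = float(model.params[0])
    ci = model.conf_int(alpha=1 - level)
    lo, hi = float(ci[1][0]), float(ci[1][1])
    # numerical slack so exact (zero-residual) fits still contain their anchor
    eps = 1e-9 * (1.0 + abs(slope))
    contained = [m for m, a in MODE_ANCHORS.items() if lo - eps <= a <= hi + eps]
    mode = contained[0] if len(contained) == 1 else "ambiguous"
    return LRIFit(
        slope=slope,
        intercept=intercept,
        n_pairs=int(keep.sum()),
        n_dropped_zero=n_dropped,
        mode_call=mode,
        slope_interval=(lo, hi),
    )
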