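"""Neutral null models for phenotypic divergence and selection-gradient estimation.

Under pure random genetic drift with constant heritability, the
among-lineage variance of neutral evolutionary outcomes on the
mean-standardized (natural-log) scale after t generations is

    sigma^2_B = e * t / N_e

where e is the evolvability (mean-standardized additive genetic variance)
and N_e the effective population size: outcomes vary more when drift is
strong (small N_e) or genetic variation is abundant (large e).  A
mutation-drift-equilibrium null instead accumulates divergence at a
constant multiple of the mean-standardized mutational variance per
generation, ``factor * sigma^2_m * t``.

An observed divergence is compared with either null through its standard
score ``z = d / sigma_B`` and a normal tail probability.  Rearranging the
univariate, evolvability-standardized Lande equation gives the directional
selection gradient required to sustain a per-generation mean-standardized
rate: ``beta = rate / e`` — beta = 1 means selection as strong as selection
on fitness itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .data_model import MutationParams, PopulationParams, TraitSeries, ValidationError
from .rates import net_divergence_log

__all__ = [
    "NeutralityResult",
    "SelectionGradient",
    "drift_null_variance",
    "mutation_drift_null_variance",
    "neutral_divergence_test",
    "selection_gradient",
    "required_beta_over_interval",
]


@dataclass(frozen=True)
class NeutralityResult:
    """Outcome of a neutral-divergence test.

    ``z_score`` is signed (positive when the trait increased); one-tailed
    p-values are the upper tail P(Z >= z) of the standard normal, matching
    the convention of asking whether evolution was *too fast* in the
    observed direction; two-tailed p-values are 2 * P(Z >= |z|).
    """

    null_model: str
    null_variance: float
    observed_divergence: float
    z_score: float
    p_value: float
    tails: str


@dataclass(frozen=True)
class SelectionGradient:
    """Mean-standardized directional selection gradient beta = rate / e."""

    beta_mean_standardized: float
    rate_used: float
    evolvability_e: float


def drift_null_variance(params: PopulationParams, t_generations: float) -> float:
    """Variance of neutral divergence under constant-heritability drift: e*t/Ne."""
    if t_generations < 0:
        raise ValidationError("t_generations must be >= 0")
    return params.evolvability_e * t_generations / params.effective_size_Ne


def mutation_drift_null_variance(mut: MutationParams, t_generations: float) -> float:
    """Variance of neutral divergence under mutation-drift equilibrium.

    ``divergence_factor * sigma^2_m * t``; the accumulation factor is an
    explicit parameter of :class:`~qgtempo.data_model.MutationParams` and is
    reported alongside every result.
    """
    if t_generations < 0:
        raise ValidationError("t_generations must be >= 0")
    return mut.divergence_factor * mut.mutational_variance * t_generations


def neutral_divergence_test(
    observed_divergence: float,
    null_variance: float,
    tails: str = "two",
    null_model: str = "drift_constant_heritability",
) -> NeutralityResult:
    """Standard-score test of an observed divergence against a neutral null.

    One-tailed: p = P(Z >= z), the probability under the null of divergence
    at least as large in the observed direction.  Two-tailed: 2 * P(Z >= |z|).
    """
    if not null_variance > 0:
        raise ValidationError("null_variance must be > 0")
    if tails not in ("one", "two"):
        raise ValidationError(f"tails must be 'one' or 'two', got {tails!r}")
    z = observed_divergence / math.sqrt(null_variance)
    if tails == "one":
        p = float(stats.norm.sf(z))
    else:
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return NeutralityResult(
        null_model=null_model,
        null_variance=float(null_variance),
        observed_divergence=float(observed_divergence),
        z_score=float(z),
        p_value=p,
        tails=tails,
    )


def selection_gradient(rate_mean_standardized: float, evolvability_e: float) -> SelectionGradient:
    """Selection gradient needed to sustain a mean-standardized rate: beta = rate/e."""
    if not evolvability_e > 0:
        raise ValidationError("evolvability_e must be > 0")
    return SelectionGradient(
        beta_mean_standardized=rate_mean_standardized / evolvability_e,
        rate_used=float(rate_mean_standardized),
        evolvability_e=float(evolvability_e),
    )


def required_beta_over_interval(
    series: TraitSeries,
    from_bin: int,
    to_bin: int,
    params: PopulationParams,
) -> SelectionGradient:
    """Selection gradient implied by the net divergence between two bins.

    Composes the net log divergence, the interval length in generations
    (converted from years with ``params.generation_time`` if needed), and
    ``beta = rate / e``.
    """
    dlog = net_divergence_log(series, from_bin, to_bin)
    gt = params.generation_time if series.age_unit == "years" else None
    interval = series.interval_generations(from_bin, to_bin, generation_time=gt)
    if not interval > 0:
        raise ValidationError("interval between bins must be > 0 generations")
    return selection_gradient(dlog / interval, params.evolvability_e)
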