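"""Synthetic trait lineages and comparative tables for end-to-end testing.

The generators produce data with exactly the statistical structure the
analysis stages assume, so every stage can be exercised and calibrated
without an external dataset:

* :func:`simulate_mean_trajectory` — a per-generation log-mean path under
  one of four regimes.  Dynamics are simulated directly on the log-mean
  scale as a population-level diffusion (not individual-based reproduction):
  the neutral nulls are phrased as among-population variance formulas on
  that scale, and calibration needs thousands of replicates.

  - ``neutral_drift``: increments ~ Normal(0, e/N_e) per generation, so the
    final divergence has variance e·t/N_e — the drift-null generating moment.
  - ``directional``: deterministic increment e·β per generation plus the
    drift increment (N_e = inf disables drift).
  - ``mutation_drift``: increments ~ Normal(0, factor·σ²_m).
  - ``stasis``: independent mean-zero perturbations about a fixed value.

* :func:`sample_fossil_series` — bins a path at evenly spaced generations
  and draws lognormal individuals per bin with within-population CV,
  sexual dimorphism and multiplicative measurement error, emitting the
  (mean, SD, n) summaries a fossil compilation would.

* :func:`simulate_species_cv_table` — a comparative per-species, per-sex
  summary table (48 species by default) with a truth table for recovery
  tests.

Every generator is a pure function of its configuration including the seed;
sub-streams for trajectory vs. sampling noise are spawned from the one seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (
    MutationParams,
    PopulationParams,
    SpeciesCVTable,
    TraitSeries,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "simulate_mean_trajectory",
    "sample_fossil_series",
    "simulate_fossil_series",
    "simulate_species_cv_table",
]

REGIMES = ("neutral_drift", "directional", "mutation_drift", "stasis")

# fixed stream indices spawned from the one run seed
_TRAJECTORY_STREAM = 0
_SAMPLING_STREAM = 1


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic lineage experiment.

    Defaults mirror the hominin endocranial-volume setting: e = 0.009,
    N_e = 5000, 29-year generations, σ²_m = 4e-6 with accumulation factor 2,
    a 400 cm³ ancestral mean, 10% within-population CV, moderate dimorphism.
    """

    regime: str
    params: PopulationParams = PopulationParams(
        evolvability_e=0.009, effective_size_Ne=5000, generation_time=29.0
    )
    mut: MutationParams | None = None
    beta: float = 0.0
    t_generations: int = 74_000
    n_bins: int = 20
    n_per_bin: int = 10
    within_cv: float = 0.10
    dimorphism_ratio: float = 1.2
    sex_ratio: float = 0.5
    measurement_cv: float = 0.0
    stasis_sd: float = 0.02
    start_mean: float = 400.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValidationError(f"unknown regime {self.regime!r}; choose from {REGIMES}")
        if self.regime == "mutation_drift" and self.mut is None:
            raise ValidationError("mutation_drift regime requires MutationParams")
        if not self.t_generations >= self.n_bins >= 1:
            raise ValidationError(
                f"need t_generations >= n_bins >= 1, got t={self.t_generations}, "
                f"n_bins={self.n_bins}"
            )
        for name in ("within_cv", "sex_ratio", "measurement_cv"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValidationError(f"{name} must be in [0, 1), got {v}")
        if not self.dimorphism_ratio > 0:
            raise ValidationError("dimorphism_ratio must be > 0")
        if self.n_per_bin < 1:
            raise ValidationError("n_per_bin must be >= 1")
        if not self.start_mean > 0:
            raise ValidationError("start_mean must be > 0")
        if not self.stasis_sd >= 0:
            raise ValidationError("stasis_sd must be >= 0")


def _stream(seed: int | None, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(max(stream, 0) + 1)[stream])


def _increment_sd(config: SimulationConfig) -> float:
    if config.regime in ("neutral_drift", "directional"):
        ne = config.params.effective_size_Ne
        return 0.0 if math.isinf(ne) else math.sqrt(config.params.evolvability_e / ne)
    if config.regime == "mutation_drift":
        assert config.mut is not None
        return math.sqrt(config.mut.divergence_factor * config.mut.mutational_variance)
    return 0.0


def simulate_mean_trajectory(
    config: SimulationConfig, n_replicates: int | None = None
) -> np.ndarray:
    """Per-generation log-mean path(s) under the configured regime.

    Returns shape ``(t+1,)``, or ``(n_replicates, t+1)`` when replicates are
    requested (all replicates share the config seed's trajectory stream, so
    a given config is bit-identical on repeat).
    """
    rng = _stream(config.seed, _TRAJECTORY_STREAM)
    reps = 1 if n_replicates is None else int(n_replicates)
    t = config.t_generations
    start = math.log(config.start_mean)
    path = np.empty((reps, t + 1))
    path[:, 0] = start
    if config.regime == "stasis":
        if t:
            path[:, 1:] = start + rng.normal(0.0, config.stasis_sd, size=(reps, t))
    else:
        drift = config.params.evolvability_e * config.beta if config.regime == "directional" else 0.0
        sd = _increment_sd(config)
        if t:
            inc = rng.normal(drift, sd, size=(reps, t)) if sd > 0 else np.full((reps, t), drift)
            np.cumsum(inc, axis=1, out=inc)
            path[:, 1:] = start + inc
    return path[0] if n_replicates is None else path


def _lognormal_multiplier(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    s2 = math.log1p(cv**2)
    return rng.lognormal(mean=-s2 / 2, sigma=math.sqrt(s2), size=size)


def sample_fossil_series(
    path: np.ndarray, config: SimulationConfig, lineage_label: str = "synthetic"
) -> TraitSeries:
    """Bin a log-mean path into a fossil-style trait series.

    Bins sit at ``n_bins`` evenly spaced generations along the path; each
    draws ``n_per_bin`` individuals lognormally about the bin mean with CV
    ``within_cv``, sex structure from ``dimorphism_ratio``/``sex_ratio``
    (sex factors normalized so the expected overall mean equals the path
    mean), and multiplicative measurement error ``measurement_cv``.  Ages
    are generations before present, so the path start is the oldest bin.
    """
    path = np.asarray(path, dtype=float)
    t = len(path) - 1
    if config.n_bins > len(path):
        raise ValidationError(f"n_bins={config.n_bins} exceeds path length {len(path)}")
    rng = _stream(config.seed, _SAMPLING_STREAM)
    gens = np.unique(np.round(np.linspace(0, t, config.n_bins)).astype(int))

    d, p = config.dimorphism_ratio, config.sex_ratio
    f_female = 1.0 / ((1 - p) + p * d)
    f_male = d * f_female

    rows = []
    for g in gens:
        n = config.n_per_bin
        is_male = rng.random(n) < p
        sex_factor = np.where(is_male, f_male, f_female)
        values = (
            math.exp(path[g])
            * sex_factor
            * _lognormal_multiplier(rng, config.within_cv, n)
            * _lognormal_multiplier(rng, config.measurement_cv, n)
        )
        sd = float(np.std(values, ddof=1)) if n >= 2 else math.nan
        rows.append((float(t - g), float(np.mean(values)), sd, n))
    bins = pd.DataFrame(rows, columns=["age", "mean", "sd", "n"])
    return TraitSeries(lineage_label=lineage_label, bins=bins, age_unit="generations")


def simulate_fossil_series(config: SimulationConfig, lineage_label: str = "synthetic") -> TraitSeries:
    """Convenience composition: simulate a trajectory, then bin-sample it."""
    return sample_fossil_series(simulate_mean_trajectory(config), config, lineage_label)


def simulate_species_cv_table(
    n_species: int = 48,
    n_per_sex: tuple[int, int] = (10, 40),
    cv_median: float = 0.06,
    cv_sdlog: float = 0.35,
    dimorphism_range: tuple[float, float] = (1.0, 1.6),
    mean_median: float = 60.0,
    mean_sdlog: float = 1.2,
    seed: int | None = None,
) -> tuple[SpeciesCVTable, pd.DataFrame]:
    """Comparative per-species, per-sex summary table plus its truth table.

    Per species, a true within-sex CV is drawn from a lognormal (median
    ``cv_median``, log-SD ``cv_sdlog`` — primate endocranial CVs cluster
    around a few percent), a female mean from a wide lognormal spanning
    small-bodied to great-ape endocranial volumes, a male/female dimorphism
    ratio uniform over ``dimorphism_range`` and per-sex sample sizes uniform
    over ``n_per_sex``.  Individuals are drawn lognormally and summarized to
    (n, mean, sd) rows — two rows per species.  The truth table records the
    generating values for recovery tests.

    Returns ``(SpeciesCVTable, truth DataFrame)``.
    """
    if n_species < 2:
        raise ValidationError("n_species must be >= 2")
    lo, hi = n_per_sex
    if not (2 <= lo <= hi):
        raise ValidationError(f"degenerate n_per_sex range {n_per_sex}")
    d_lo, d_hi = dimorphism_range
    if not (0 < d_lo <= d_hi):
        raise ValidationError(f"degenerate dimorphism_range {dimorphism_range}")
    rng = np.random.default_rng(seed)

    rows, truth = [], []
    for i in range(n_species):
        sp = f"species_{i:03d}"
        true_cv = float(rng.lognormal(math.log(cv_median), cv_sdlog))
        mean_f = float(rng.lognormal(math.log(mean_median), mean_sdlog))
        dim = float(rng.uniform(d_lo, d_hi))
        sex_means = {"female": mean_f, "male": mean_f * dim}
        for sex, mu in sex_means.items():
            n = int(rng.integers(lo, hi + 1))
            values = mu * _lognormal_multiplier(rng, true_cv, n)
            rows.append((sp, sex, n, float(np.mean(values)), float(np.std(values, ddof=1))))
        truth.append((sp, true_cv, dim, mean_f, sex_means["male"]))

    table = SpeciesCVTable(rows=pd.DataFrame(rows, columns=["species", "sex", "n", "mean", "sd"]))
    truth_df = pd.DataFrame(
        truth, columns=["species", "true_cv", "dimorphism_ratio", "mean_female", "mean_male"]
    )
    return table, truth_df
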