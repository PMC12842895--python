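"""Domain types and tabular I/O shared by all pipeline stages.

Three tables flow through the package:

* :class:`TraitSeries` — per-time-bin summaries (age, mean, SD, n) of one
  continuous trait in one lineage, e.g. binned fossil endocranial volumes.
* :class:`SpecimenTable` — one row per individual (group, sex, trait value),
  the carrier for coefficient-of-variation work.
* :class:`SpeciesCVTable` — per-species, per-sex summary statistics for
  comparative CV placement across a clade.

Parameter bundles :class:`PopulationParams` (evolvability, effective size,
generation time) and :class:`MutationParams` (mean-standardized mutational
variance) feed the neutral null models.

All tables are CSV with a header row; ages may be years before present or
generations, converted by real division with the generation time.  The
canonical bin order is oldest first (descending age before present), because
divergence is reckoned ancestor-to-descendant.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "TraitSeries",
    "PopulationParams",
    "MutationParams",
    "SpecimenTable",
    "SpeciesCVTable",
    "read_trait_series",
    "read_specimen_table",
    "read_species_cv_table",
    "write_results",
]

SEX_LEVELS = ("female", "male", "unknown")
SPECIES_SEX_LEVELS = ("female", "male", "pooled")

TRAIT_SERIES_COLUMNS = ("age", "mean", "sd", "n")
SPECIMEN_COLUMNS = ("specimen_id", "group", "sex", "value")
SPECIES_CV_COLUMNS = ("species", "sex", "n", "mean", "sd")


class ValidationError(ValueError):
    """Raised when a table violates its schema; messages name row and column."""


def _coerce_numeric(df: pd.DataFrame, column: str, *, allow_blank: bool = False) -> pd.Series:
    """Convert a column to float, failing loudly on the first bad cell."""
    raw = df[column]
    coerced = pd.to_numeric(raw, errors="coerce")
    bad = coerced.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"row {i}, column '{column}': non-numeric value {raw.iloc[i]!r}"
        )
    if not allow_blank and coerced.isna().any():
        i = int(np.flatnonzero(coerced.isna().to_numpy())[0])
        raise ValidationError(f"row {i}, column '{column}': missing value")
    return coerced.astype(float)


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise ValidationError(f"{what}: missing column '{col}'")


# ---------------------------------------------------------------------------
# parameter bundles


@dataclass(frozen=True)
class PopulationParams:
    """Population-level parameters of the drift null.

    Parameters
    ----------
    evolvability_e:
        Mean-standardized additive genetic variance (dimensionless).  For
        human endocranial volume a literature value is ``0.009``.
    effective_size_Ne:
        Effective population size.  ``math.inf`` is accepted and disables
        drift in simulations.
    generation_time:
        Years per generation, used to convert ages in years to generations.
    """

    evolvability_e: float
    effective_size_Ne: float
    generation_time: float = 29.0

    def __post_init__(self) -> None:
        if not self.evolvability_e > 0:
            raise ValidationError("evolvability_e must be > 0")
        if not self.effective_size_Ne >= 1:
            raise ValidationError("effective_size_Ne must be >= 1")
        if not self.generation_time > 0:
            raise ValidationError("generation_time must be > 0")

    def years_to_generations(self, years: float) -> float:
        return years / self.generation_time


@dataclass(frozen=True)
class MutationParams:
    """Parameters of the mutation-drift null.

    ``mutational_variance`` is the mean-square standardized mutational
    variance arriving per generation (dimensionless; ~4e-6 for mass and
    body-composition traits in mice).  ``divergence_factor`` multiplies the
    per-generation accumulation of among-lineage divergence; the default 2
    corresponds to between-lineage divergence accumulating at twice the
    mutational variance per generation and is always reported in output.
    """

    mutational_variance: float
    divergence_factor: float = 2.0

    def __post_init__(self) -> None:
        if not self.mutational_variance > 0:
            raise ValidationError("mutational_variance must be > 0")
        if not self.divergence_factor > 0:
            raise ValidationError("divergence_factor must be > 0")


# ---------------------------------------------------------------------------
# TraitSeries


@dataclass
class TraitSeries:
    """Ordered per-bin summaries of one trait in one lineage.

    ``bins`` holds columns ``age, mean, sd, n``; ages are time before present
    in ``age_unit`` ("years" or "generations"), stored oldest first.  A
    missing SD is legal only for bins with n = 1; such bins are excluded from
    rate denominators that need a phenotypic SD.
    """

    lineage_label: str
    bins: pd.DataFrame
    age_unit: str = "generations"
    trait_scale: str = "raw"
    generation_time: float | None = None

    def __post_init__(self) -> None:
        if self.age_unit not in ("years", "generations"):
            raise ValidationError(f"unknown age_unit {self.age_unit!r}")
        if self.trait_scale not in ("raw", "natural_log"):
            raise ValidationError(f"unknown trait_scale {self.trait_scale!r}")
        df = pd.DataFrame(self.bins).reset_index(drop=True)
        _require_columns(df, TRAIT_SERIES_COLUMNS, "trait series")
        df = df.loc[:, list(TRAIT_SERIES_COLUMNS)]
        for col in ("age", "mean"):
            df[col] = _coerce_numeric(df, col)
        df["sd"] = _coerce_numeric(df, "sd", allow_blank=True)
        df["n"] = _coerce_numeric(df, "n")
        if (df["n"] < 1).any():
            i = int(np.flatnonzero((df["n"] < 1).to_numpy())[0])
            raise ValidationError(f"row {i}, column 'n': n must be >= 1, got {df['n'].iloc[i]}")
        dup = df["age"].duplicated()
        if dup.any():
            age = df["age"][dup].iloc[0]
            raise ValidationError(f"column 'age': duplicate age value {age}")
        neg_sd = df["sd"].notna() & (df["sd"] < 0)
        if neg_sd.any():
            i = int(np.flatnonzero(neg_sd.to_numpy())[0])
            raise ValidationError(f"row {i}, column 'sd': sd must be >= 0")
        missing_sd = df["sd"].isna() & (df["n"] >= 2)
        if missing_sd.any():
            i = int(np.flatnonzero(missing_sd.to_numpy())[0])
            raise ValidationError(
                f"row {i}, column 'sd': sd missing but n = {df['n'].iloc[i]:g} >= 2"
            )
        # canonical order: oldest first (largest age before present first)
        df = df.sort_values("age", ascending=False, kind="mergesort").reset_index(drop=True)
        self.bins = df

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def ages_in_generations(self, generation_time: float | None = None) -> np.ndarray:
        """Bin ages on the generation scale (real-valued division, no flooring)."""
        ages = self.bins["age"].to_numpy(dtype=float)
        if self.age_unit == "generations":
            return ages
        gt = generation_time if generation_time is not None else self.generation_time
        if gt is None or not gt > 0:
            raise ValidationError(
                "generation_time required to convert ages in years to generations"
            )
        return ages / gt

    def interval_generations(
        self, from_bin: int, to_bin: int, generation_time: float | None = None
    ) -> float:
        ages = self.ages_in_generations(generation_time)
        return float(abs(ages[from_bin] - ages[to_bin]))

    def to_csv(self, path: str | Path) -> None:
        self.bins.to_csv(path, index=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TraitSeries):
            return NotImplemented
        return (
            self.lineage_label == other.lineage_label
            and self.age_unit == other.age_unit
            and self.trait_scale == other.trait_scale
            and self.bins.shape == other.bins.shape
            and np.allclose(
                self.bins.to_numpy(dtype=float),
                other.bins.to_numpy(dtype=float),
                equal_nan=True,
            )
        )


def read_trait_series(
    path: str | Path,
    age_unit: str = "years",
    generation_time: float | None = None,
    lineage_label: str | None = None,
) -> TraitSeries:
    """Read a trait time series from a CSV with columns age, mean, sd, n."""
    df = pd.read_csv(path)
    _require_columns(df, TRAIT_SERIES_COLUMNS, str(path))
    label = lineage_label if lineage_label is not None else Path(path).stem
    return TraitSeries(
        lineage_label=label,
        bins=df,
        age_unit=age_unit,
        generation_time=generation_time,
    )


# ---------------------------------------------------------------------------
# SpecimenTable


@dataclass
class SpecimenTable:
    """One record per individual: specimen_id, group, sex, trait value."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records).reset_index(drop=True)
        _require_columns(df, SPECIMEN_COLUMNS, "specimen table")
        df = df.loc[:, list(SPECIMEN_COLUMNS)]
        if len(df):
            df["value"] = _coerce_numeric(df, "value")
            dup = df["specimen_id"].duplicated()
            if dup.any():
                sid = df["specimen_id"][dup].iloc[0]
                raise ValidationError(f"column 'specimen_id': duplicate id {sid!r}")
            bad_sex = ~df["sex"].isin(SEX_LEVELS)
            if bad_sex.any():
                i = int(np.flatnonzero(bad_sex.to_numpy())[0])
                raise ValidationError(
                    f"row {i}, column 'sex': expected one of {SEX_LEVELS}, got {df['sex'].iloc[i]!r}"
                )
        self.records = df

    def require_positive_values(self) -> None:
        """Enforce value > 0, a precondition of log-scale and CV work."""
        if len(self.records):
            bad = self.records["value"] <= 0
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(
                    f"row {i}, column 'value': non-positive value "
                    f"{self.records['value'].iloc[i]} not allowed for log/CV work"
                )

    def group_values(self, group: str) -> np.ndarray:
        sel = self.records["group"] == group
        if not sel.any():
            raise ValidationError(f"unknown group {group!r}")
        return self.records.loc[sel, "value"].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


def read_specimen_table(path: str | Path, require_positive: bool = False) -> SpecimenTable:
    df = pd.read_csv(path)
    _require_columns(df, SPECIMEN_COLUMNS, str(path))
    table = SpecimenTable(records=df)
    if require_positive:
        table.require_positive_values()
    return table


# ---------------------------------------------------------------------------
# SpeciesCVTable


@dataclass
class SpeciesCVTable:
    """Per-species, per-sex summary rows: species, sex, n, mean, sd."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.rows).reset_index(drop=True)
        _require_columns(df, SPECIES_CV_COLUMNS, "species CV table")
        df = df.loc[:, list(SPECIES_CV_COLUMNS)]
        if len(df):
            df["n"] = _coerce_numeric(df, "n")
            df["mean"] = _coerce_numeric(df, "mean")
            df["sd"] = _coerce_numeric(df, "sd", allow_blank=True)
            bad_sex = ~df["sex"].isin(SPECIES_SEX_LEVELS)
            if bad_sex.any():
                i = int(np.flatnonzero(bad_sex.to_numpy())[0])
                raise ValidationError(
                    f"row {i}, column 'sex': expected one of {SPECIES_SEX_LEVELS}, "
                    f"got {df['sex'].iloc[i]!r}"
                )
            if (df["mean"] <= 0).any():
                i = int(np.flatnonzero((df["mean"] <= 0).to_numpy())[0])
                raise ValidationError(f"row {i}, column 'mean': mean must be > 0")
            neg_sd = df["sd"].notna() & (df["sd"] < 0)
            if neg_sd.any():
                i = int(np.flatnonzero(neg_sd.to_numpy())[0])
                raise ValidationError(f"row {i}, column 'sd': sd must be >= 0")
        self.rows = df

    @property
    def species(self) -> list[str]:
        return list(dict.fromkeys(self.rows["species"]))

    def rows_for(self, species: str) -> pd.DataFrame:
        sel = self.rows["species"] == species
        if not sel.any():
            raise ValidationError(f"unknown species {species!r}")
        return self.rows.loc[sel]

    def to_csv(self, path: str | Path) -> None:
        self.rows.to_csv(path, index=False)


def read_species_cv_table(path: str | Path) -> SpeciesCVTable:
    df = pd.read_csv(path)
    _require_columns(df, SPECIES_CV_COLUMNS, str(path))
    return SpeciesCVTable(rows=df)


# ---------------------------------------------------------------------------
# generic result writing


def _flatten(obj: Any) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for f in dataclasses.fields(obj):
        value = getattr(obj, f.name)
        if isinstance(value, (tuple, list)) and len(value) == 2:
            out[f"{f.name}_low"], out[f"{f.name}_high"] = value
        elif dataclasses.is_dataclass(value) and not isinstance(value, type):
            for k, v in _flatten(value).items():
                out[f"{f.name}_{k}"] = v
        elif isinstance(value, pd.DataFrame):
            continue
        else:
            out[f.name] = value
    return out


def write_results(
    results: Any,
    path: str | Path,
    parameters: Mapping[str, Any] | None = None,
    seed: int | None = None,
) -> None:
    """Write any stage output as CSV plus a JSON run-metadata sidecar.

    Dataclass results become a one-row table (pair fields such as confidence
    bounds are split into ``_low``/``_high`` columns); DataFrames and the
    table types are written as-is.  The sidecar ``<path>.meta.json`` records
    the result type, parameters, seed, package version and timestamp.
    """
    from . import __version__

    path = Path(path)
    if isinstance(results, TraitSeries):
        results.to_csv(path)
    elif isinstance(results, (SpecimenTable, SpeciesCVTable)):
        results.to_csv(path)
    elif isinstance(results, pd.DataFrame):
        results.to_csv(path, index=False)
    elif dataclasses.is_dataclass(results) and not isinstance(results, type):
        pd.DataFrame([_flatten(results)]).to_csv(path, index=False)
    else:
        raise ValidationError(f"do not know how to write {type(results).__name__}")

    meta = {
        "result_type": type(results).__name__,
        "parameters": dict(parameters) if parameters else {},
        "seed": seed,
        "package_version": __version__,
        "written": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2, default=str))
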