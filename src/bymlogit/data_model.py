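"""Core data containers and I/O for individuals nested in areas.

Individual-level records carry a binary obesity outcome (BMI >= 25 kg/m^2),
categorical covariates and an area identifier; area-level records carry the
built-environment metrics (raw and tertiled).  Design matrices use dummy
coding with a declared reference category per covariate, matching the usual
odds-ratio-vs-reference presentation of epidemiological tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

GENDERS = ("male", "female")
AGE_GROUPS = ("19-39", "40-59", "60+")

__all__ = [
    "CovariateSchema",
    "IndividualRecord",
    "AreaCovariates",
    "MultilevelDataset",
    "DesignMatrices",
    "SchemaError",
    "RecordError",
    "DegenerateDesignError",
    "read_individuals",
    "write_individuals",
    "read_area_covariates",
    "encode_design",
    "dichotomize_bmi",
]


class SchemaError(ValueError):
    """A declared column or level is missing or inconsistent."""


class RecordError(ValueError):
    """An individual row failed validation; message names row and column."""


class DegenerateDesignError(ValueError):
    """A covariate has fewer than two observed levels."""


@dataclass(frozen=True)
class CovariateSchema:
    """Declaration of categorical covariates: levels and reference level.

    ``levels`` maps covariate name -> ordered category labels;
    ``reference`` maps covariate name -> the level dropped in dummy coding
    (defaults to the first declared level).
    """

    levels: Mapping[str, Sequence[str]]
    reference: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, levs in self.levels.items():
            if len(set(levs)) != len(levs) or len(levs) < 2:
                raise SchemaError(f"covariate {name!r} needs >= 2 distinct levels")
            ref = self.reference.get(name, levs[0])
            if ref not in levs:
                raise SchemaError(
                    f"reference {ref!r} not among levels of covariate {name!r}"
                )

    def ref(self, name: str) -> str:
        return self.reference.get(name, list(self.levels[name])[0])

    @property
    def names(self) -> list[str]:
        return list(self.levels)

    @classmethod
    def from_file(cls, path: str | Path) -> "CovariateSchema":
        """Load a schema from a JSON or YAML config file."""
        text = Path(path).read_text()
        cfg = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls(levels=cfg["levels"], reference=cfg.get("reference", {}))


@dataclass(frozen=True)
class IndividualRecord:
    area_id: str
    outcome: int
    covariates: Mapping[str, str]
    gender: str | None = None
    age_group: str | None = None

    def __post_init__(self) -> None:
        if self.outcome not in (0, 1):
            raise RecordError(f"outcome must be 0/1, got {self.outcome!r}")


@dataclass(frozen=True)
class AreaCovariates:
    area_id: str
    raw_values: Mapping[str, float] = field(default_factory=dict)
    tertiles: Mapping[str, str] = field(default_factory=dict)


@dataclass
class MultilevelDataset:
    """Individuals nested in areas.

    ``individuals`` has columns ``area_id``, ``outcome`` plus the declared
    covariates (and optionally ``gender``/``age_group`` strata columns);
    ``areas`` is the sorted list of area ids fixing the matrix ordering;
    ``area_covariates`` (optional) is indexed by area_id.
    """

    individuals: pd.DataFrame
    schema: CovariateSchema
    areas: list[str] = field(default_factory=list)
    area_covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        df = self.individuals
        if "area_id" not in df.columns or "outcome" not in df.columns:
            raise SchemaError("individuals need 'area_id' and 'outcome' columns")
        bad = ~df["outcome"].isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise RecordError(f"row {row}: outcome {df['outcome'].iloc[row]!r} not in {{0,1}}")
        for name, levs in self.schema.levels.items():
            if name not in df.columns:
                raise SchemaError(f"declared covariate {name!r} missing from individuals")
            bad = ~df[name].isin(list(levs))
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise RecordError(
                    f"row {row}, column {name!r}: unknown label {df[name].iloc[row]!r}"
                )
        # area ordering is the sorted id order, fixed before any matrix exists
        if not self.areas:
            self.areas = sorted(df["area_id"].astype(str).unique())
        unknown = set(df["area_id"].astype(str)) - set(self.areas)
        if unknown:
            raise SchemaError(f"records reference undeclared areas: {sorted(unknown)[:5]}")

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def n_records(self) -> int:
        return len(self.individuals)

    def area_sizes(self) -> pd.Series:
        """Per-area record counts n_i, indexed by area id (0 for empty areas)."""
        counts = self.individuals["area_id"].astype(str).value_counts()
        return counts.reindex(self.areas, fill_value=0)

    def area_index(self) -> np.ndarray:
        """Row -> position of the row's area in ``self.areas``."""
        pos = {a: k for k, a in enumerate(self.areas)}
        return self.individuals["area_id"].astype(str).map(pos).to_numpy(dtype=np.int64)

    @property
    def records(self) -> list[IndividualRecord]:
        covnames = self.schema.names
        out = []
        for _, row in self.individuals.iterrows():
            out.append(
                IndividualRecord(
                    area_id=str(row["area_id"]),
                    outcome=int(row["outcome"]),
                    covariates={c: row[c] for c in covnames},
                    gender=row.get("gender"),
                    age_group=row.get("age_group"),
                )
            )
        return out


@dataclass
class DesignMatrices:
    """Dummy-coded design: X (individual covariates), W (area covariates
    expanded to individual rows), the row->area index, and column labels."""

    X: np.ndarray
    W: np.ndarray
    area_index: np.ndarray
    x_names: list[str]
    w_names: list[str]

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


def dichotomize_bmi(height_m: float, weight_kg: float) -> int:
    """1 iff BMI = weight/height^2 >= 25.0 kg/m^2 (inclusive cut)."""
    if height_m <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return int(weight_kg / height_m**2 >= 25.0)


def read_individuals(
    path: str | Path,
    schema: CovariateSchema,
    areas: Sequence[str] | None = None,
) -> MultilevelDataset:
    """Read individuals.csv (area_id, outcome, covariate columns).

    Rows with missing values in declared columns are dropped with a logged
    warning; no imputation is performed.
    """
    df = pd.read_csv(path, dtype={"area_id": str})
    required = ["area_id", "outcome", *schema.names]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns in {path}: {missing}")
    incomplete = df[required].isna().any(axis=1)
    if incomplete.any():
        logger.warning(
            "dropping %d record(s) with missing values in declared columns",
            int(incomplete.sum()),
        )
        df = df.loc[~incomplete].reset_index(drop=True)
    try:
        df["outcome"] = df["outcome"].astype(int)
    except (TypeError, ValueError):
        coerced = pd.to_numeric(df["outcome"], errors="coerce")
        row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
        raise RecordError(f"row {row}: unparseable outcome {df['outcome'].iloc[row]!r}")
    return MultilevelDataset(
        individuals=df, schema=schema, areas=sorted(areas) if areas else []
    )


def write_individuals(ds: MultilevelDataset, path: str | Path) -> None:
    ds.individuals.to_csv(path, index=False)


def read_area_covariates(path: str | Path) -> pd.DataFrame:
    """Read areas.csv (area_id plus raw metric and/or tertile columns)."""
    df = pd.read_csv(path, dtype={"area_id": str})
    if "area_id" not in df.columns:
        raise SchemaError("areas.csv needs an 'area_id' column")
    return df.set_index("area_id")


def _dummy_block(
    values: pd.Series, levels: Sequence[str], ref: str, name: str
) -> tuple[np.ndarray, list[str]]:
    observed = set(values.unique())
    if len(observed) < 2:
        raise DegenerateDesignError(
            f"covariate {name!r} has a single observed level: {sorted(observed)}"
        )
    keep = [lv for lv in levels if lv != ref]
    cols = np.column_stack([(values == lv).to_numpy(dtype=float) for lv in keep])
    return cols, [f"{name}[{lv}]" for lv in keep]


def encode_design(
    ds: MultilevelDataset,
    individual_covariates: Sequence[str] = (),
    area_covariates: Sequence[str] = (),
    area_schema: CovariateSchema | None = None,
) -> DesignMatrices:
    """Dummy-code the declared covariates (reference level dropped).

    Each categorical covariate with K levels contributes K-1 indicator
    columns.  Area-level covariates are looked up in ``ds.area_covariates``
    and expanded to one value per individual row, so W columns are constant
    within an area.
    """
    n = ds.n_records
    x_blocks, x_names = [], []
    for name in individual_covariates:
        if name not in ds.schema.levels:
            raise SchemaError(f"individual covariate {name!r} not declared in schema")
        block, labels = _dummy_block(
            ds.individuals[name], ds.schema.levels[name], ds.schema.ref(name), name
        )
        x_blocks.append(block)
        x_names.extend(labels)
    X = np.column_stack(x_blocks) if x_blocks else np.zeros((n, 0))

    w_blocks, w_names = [], []
    if area_covariates:
        if ds.area_covariates is None:
            raise SchemaError("area covariates requested but dataset has none")
        per_row = ds.area_covariates.reindex(ds.individuals["area_id"].astype(str))
        for name in area_covariates:
            if name not in per_row.columns:
                raise SchemaError(f"area covariate {name!r} missing from area table")
            if area_schema is not None and name in area_schema.levels:
                levels: Sequence[str] = area_schema.levels[name]
                ref = area_schema.ref(name)
            else:
                levels = sorted(ds.area_covariates[name].unique())
                ref = levels[0]
            block, labels = _dummy_block(
                per_row[name].reset_index(drop=True), levels, ref, name
            )
            w_blocks.append(block)
            w_names.extend(labels)
    W = np.column_stack(w_blocks) if w_blocks else np.zeros((n, 0))

    return DesignMatrices(
        X=X, W=W, area_index=ds.area_index(), x_names=x_names, w_names=w_names
    )
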