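"""Outcome grading, feature schema, model-matrix encoding and group views.

The outcome is radiation-induced lymphopenia graded from the post-
radiotherapy absolute lymphocyte count per CTCAE v4.0: grade 1 starts at
counts below the laboratory lower limit of normal (LLN), grades 2-4 at
fixed cutpoints 800, 500 and 200 cells/uL. The binary endpoint used by all
models is grade >= 1.

Features belong to five named groups (clinical, tumor, blood,
radiotherapy, treatment). Categorical features are dummy-encoded against a
designated reference level (k levels -> k-1 indicator columns); continuous
features pass through unscaled, with missing values preserved so tree
learners can use their native missing handling, while penalized-regression
fitters use the complete-case view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

GROUPS = ("clinical", "tumor", "blood", "radiotherapy", "treatment")

#: CTCAE v4.0 absolute-lymphocyte-count cutpoints (cells/uL) for grades 2-4.
CTCAE_CUTPOINTS = (800.0, 500.0, 200.0)

#: Default laboratory lower limit of normal for lymphocytes, cells/uL.
DEFAULT_LLN = 1000.0


@dataclass(frozen=True)
class FeatureSpec:
    """One feature: its group, kind, and (for categoricals) levels.

    ``levels`` lists category levels with the reference level first.
    """

    name: str
    group: str
    kind: str  # "continuous" | "categorical"
    levels: tuple[str, ...] = ()
    units: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r} for {self.name!r}")
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical" and len(self.levels) < 2:
            raise ValueError(f"categorical {self.name!r} needs >=2 levels")

    @property
    def reference(self) -> str:
        return self.levels[0]


@dataclass
class FeatureSchema:
    """Ordered collection of :class:`FeatureSpec` with group partitioning."""

    features: list[FeatureSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in schema")

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def __getitem__(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def by_group(self, group: str) -> list[FeatureSpec]:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return [f for f in self.features if f.group == group]

    def continuous(self) -> list[str]:
        return [f.name for f in self.features if f.kind == "continuous"]

    def categorical(self) -> list[str]:
        return [f.name for f in self.features if f.kind == "categorical"]

    def column_name(self, feature: str, level: str) -> str:
        return f"{feature}={level}"

    def encoded_columns(self) -> list[str]:
        """Model-matrix column names: continuous + non-reference indicators."""
        cols: list[str] = []
        for f in self.features:
            if f.kind == "continuous":
                cols.append(f.name)
            else:
                cols.extend(self.column_name(f.name, lv) for lv in f.levels[1:])
        return cols

    def column_group(self, column: str) -> str:
        feature = column.split("=", 1)[0]
        return self[feature].group

    def to_yaml(self, path) -> None:
        payload = [
            {
                "name": f.name,
                "group": f.group,
                "kind": f.kind,
                "levels": list(f.levels),
                "units": f.units,
            }
            for f in self.features
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FeatureSchema":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            [
                FeatureSpec(
                    name=d["name"],
                    group=d["group"],
                    kind=d["kind"],
                    levels=tuple(d.get("levels") or ()),
                    units=d.get("units", ""),
                )
                for d in payload
            ]
        )


@dataclass
class ModelMatrix:
    """Encoded design matrix plus outcome, with explicit missingness.

    ``X`` holds continuous columns and 0/1 indicator columns (NaN where the
    source value is missing). ``complete_rows`` marks rows with no missing
    entries; penalized-regression fitters restrict to this view, tree
    learners consume all rows.
    """

    X: pd.DataFrame
    y: pd.Series
    schema: FeatureSchema

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            raise ValueError("X and y must share an index")
        all_missing = [c for c in self.X.columns if self.X[c].isna().all()]
        if all_missing:
            raise ValueError(f"all-missing columns: {all_missing}")

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    @property
    def complete_rows(self) -> pd.Series:
        return ~self.X.isna().any(axis=1)

    def complete_case(self) -> "ModelMatrix":
        keep = self.complete_rows
        return ModelMatrix(self.X.loc[keep], self.y.loc[keep], self.schema)

    def select_columns(self, columns: Sequence[str]) -> "ModelMatrix":
        return ModelMatrix(self.X[list(columns)], self.y, self.schema)


def grade_lymphopenia(count, lower_limit_normal: float = DEFAULT_LLN):
    """CTCAE v4.0 lymphopenia grade from a post-radiotherapy count (per uL).

    Grade 0 at counts at or above the LLN, grade 1 in [800, LLN), grade 2
    in [500, 800), grade 3 in [200, 500), grade 4 below 200. The binary
    lymphopenia endpoint is ``grade >= 1``. Accepts a scalar or array.
    """
    if lower_limit_normal <= CTCAE_CUTPOINTS[0]:
        raise ValueError("lower_limit_normal must exceed 800/uL")
    arr = np.asarray(count, dtype=float)
    if np.any(arr < 0):
        raise ValueError("lymphocyte counts must be non-negative")
    g2, g3, g4 = CTCAE_CUTPOINTS
    grade = np.select(
        [arr < g4, arr < g3, arr < g2, arr < lower_limit_normal],
        [4, 3, 2, 1],
        default=0,
    )
    return grade if np.ndim(count) else int(grade)


def encode(cohort: pd.DataFrame, schema: FeatureSchema, outcome: str = "lymphopenia") -> ModelMatrix:
    """Dummy-encode a cohort table into a :class:`ModelMatrix`.

    Reference levels are never emitted as columns; continuous features pass
    through unscaled; missing values stay missing (NaN) in both continuous
    and indicator columns. Unknown category levels are rejected by name.
    """
    missing_features = [f.name for f in schema if f.name not in cohort.columns]
    if missing_features:
        raise ValueError(f"cohort lacks schema features: {missing_features}")
    if outcome not in cohort.columns:
        raise ValueError(f"outcome column {outcome!r} not in cohort")

    cols: dict[str, np.ndarray] = {}
    for f in schema:
        series = cohort[f.name]
        if f.kind == "continuous":
            cols[f.name] = pd.to_numeric(series, errors="raise").to_numpy(dtype=float)
            continue
        observed = series.dropna().astype(str)
        unseen = sorted(set(observed) - set(f.levels))
        if unseen:
            raise ValueError(
                f"feature {f.name!r} has unseen level(s) {unseen}; "
                f"known levels: {list(f.levels)}"
            )
        is_na = series.isna().to_numpy()
        as_str = series.astype("object")
        for level in f.levels[1:]:
            ind = (as_str == level).to_numpy(dtype=float)
            ind[is_na] = np.nan
            cols[schema.column_name(f.name, level)] = ind

    X = pd.DataFrame(cols, index=cohort.index)
    y = pd.to_numeric(cohort[outcome]).astype(int)
    if set(y.unique()) - {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    if y.nunique() < 2:
        raise ValueError("outcome must contain both classes")
    return ModelMatrix(X, y, schema)


def decode(matrix: ModelMatrix, feature: str) -> pd.Series:
    """Invert the dummy encoding of one categorical feature.

    Rows with all indicators zero map to the reference level; missing
    indicators map to missing.
    """
    spec = matrix.schema[feature]
    if spec.kind != "categorical":
        raise ValueError(f"{feature!r} is not categorical")
    out = pd.Series(spec.reference, index=matrix.X.index, dtype="object")
    for level in spec.levels[1:]:
        col = matrix.X[matrix.schema.column_name(feature, level)]
        out[col == 1] = level
        out[col.isna()] = None
    return out


def split_groups(matrix: ModelMatrix, schema: FeatureSchema | None = None) -> dict[str, ModelMatrix]:
    """Partition a model matrix into the five column-disjoint group views.

    Every column must belong to a schema feature; the views' column sets
    union back to the full column set. An empty group yields an empty view.
    """
    schema = schema or matrix.schema
    views: dict[str, ModelMatrix] = {}
    assigned: list[str] = []
    for group in GROUPS:
        cols = [c for c in matrix.columns if schema.column_group(c) == group]
        assigned.extend(cols)
        views[group] = ModelMatrix(matrix.X[cols], matrix.y, schema)
    unassigned = set(matrix.columns) - set(assigned)
    if unassigned:
        raise ValueError(f"columns not covered by schema groups: {sorted(unassigned)}")
    return views
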