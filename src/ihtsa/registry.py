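"""Cohort data model for recipient-donor transplant registries.

One row per transplant: recipient covariates, donor covariates, follow-up
time in years and an all-cause death indicator.  Missing covariate cells are
carried as NaN; follow-up, death and transplant era are mandatory and may
never be missing (era is the stratifier for hot-deck imputation).

The module also builds the model design matrix: continuous variables are
standardized, multi-level categoricals are dichotomized to reference-coded
indicator columns, and recipient/donor weight and height ratios are derived.
Continuous columns carry a half-IQR increment, the perturbation step used
for counterfactual hazard ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ParseError",
    "TransformError",
    "Variable",
    "SCHEMA",
    "SCHEMA_BY_NAME",
    "PROTECTED_VARIABLES",
    "Cohort",
    "load_cohort",
    "write_cohort",
    "split_cohort",
    "half_iqr_increment",
    "ColumnSpec",
    "categorical_columns",
    "MODEL_DESIGN",
    "DesignMatrix",
    "build_design",
]


class SchemaError(ValueError):
    """CSV header or column inventory does not match the cohort schema."""


class ParseError(ValueError):
    """A cell cannot be parsed as the declared type."""


class TransformError(ValueError):
    """A cohort cannot be mapped through a fitted design matrix."""


# --------------------------------------------------------------------------
# Schema
# --------------------------------------------------------------------------

SEX_LEVELS = ("female", "male")
DIAGNOSIS_LEVELS = (
    "ischemic_cm",
    "non_ischemic_cm",
    "congenital",
    "graft_failure",
    "valvular",
    "other",
)
ERA_LEVELS = ("1991-1995", "1996-2000", "2001-2005", "2006-2010")
BLOOD_GROUPS = ("A", "AB", "B", "O")
HLADR_LEVELS = (0, 1, 2)


@dataclass(frozen=True)
class Variable:
    """One schema column.

    kind: 'continuous' (float, unit-bearing), 'indicator' (0/1) or
    'categorical' (fixed level set).  ``maskable`` marks cells that the
    missingness machinery may blank; follow-up, death and era are protected.
    """

    name: str
    kind: str
    unit: str | None = None
    levels: tuple = ()
    maskable: bool = True
    positive: bool = False  # value must be > 0 when present


SCHEMA: tuple[Variable, ...] = (
    Variable("recipient_age", "continuous", "years", positive=True),
    Variable("recipient_sex", "categorical", levels=SEX_LEVELS),
    Variable("recipient_height", "continuous", "cm", positive=True),
    Variable("recipient_weight", "continuous", "kg", positive=True),
    Variable("diagnosis", "categorical", levels=DIAGNOSIS_LEVELS),
    Variable("diabetes", "indicator"),
    Variable("hypertension", "indicator"),
    Variable("infection_2wk", "indicator"),
    Variable("antiarrhythmics", "indicator"),
    Variable("amiodarone", "indicator"),
    Variable("prior_transfusion", "indicator"),
    Variable("prior_transplant", "indicator"),
    Variable("prior_cardiac_surgery", "indicator"),
    Variable("icu", "indicator"),
    Variable("ventilator", "indicator"),
    Variable("ecmo", "indicator"),
    Variable("vad", "indicator"),
    Variable("era", "categorical", levels=ERA_LEVELS, maskable=False),
    Variable("spp", "continuous", "mmHg"),
    Variable("pvr", "continuous", "Wood units"),
    Variable("creatinine", "continuous", "umol/l"),
    Variable("bilirubin", "continuous", "mg/dl"),
    Variable("pra_gt10", "indicator"),
    Variable("hladr_mismatch", "categorical", levels=HLADR_LEVELS),
    Variable("recipient_bg", "categorical", levels=BLOOD_GROUPS),
    Variable("donor_age", "continuous", "years", positive=True),
    Variable("donor_sex", "categorical", levels=SEX_LEVELS),
    Variable("donor_height", "continuous", "cm", positive=True),
    Variable("donor_weight", "continuous", "kg", positive=True),
    Variable("ischemia_min", "continuous", "minutes"),
    Variable("codd_head_trauma", "indicator"),
    Variable("codd_cva", "indicator"),
    Variable("donor_bg", "categorical", levels=BLOOD_GROUPS),
    Variable("followup_years", "continuous", "years", maskable=False),
    Variable("death", "indicator", maskable=False),
)

SCHEMA_BY_NAME: dict[str, Variable] = {v.name: v for v in SCHEMA}
PROTECTED_VARIABLES = ("followup_years", "death", "era")
MANDATORY_COLUMNS = PROTECTED_VARIABLES

_CAT_LEVEL_STR = {
    name: {str(level): level for level in var.levels}
    for name, var in SCHEMA_BY_NAME.items()
    if var.kind == "categorical"
}


# --------------------------------------------------------------------------
# Cohort container
# --------------------------------------------------------------------------


@dataclass
class Cohort:
    """An ordered collection of transplant records backed by a DataFrame.

    Row order is stable so that seeded operations are reproducible.  Numeric
    columns (continuous + indicator) are float64 with NaN for missing;
    categorical columns are object-typed with None/NaN for missing.
    """

    df: pd.DataFrame
    name: str = "cohort"

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n(self) -> int:
        return len(self.df)

    def copy(self, name: str | None = None) -> "Cohort":
        return Cohort(self.df.copy(), name or self.name)

    def missing_mask(self) -> pd.DataFrame:
        """Boolean frame: True where a schema cell is missing."""
        cols = [v.name for v in SCHEMA]
        return self.df[cols].isna()

    def is_complete(self, variables: Iterable[str] | None = None) -> bool:
        cols = list(variables) if variables is not None else [v.name for v in SCHEMA]
        return not self.df[cols].isna().any().any()

    def validate(self) -> None:
        """Enforce the record invariants; raises SchemaError on violation."""
        df = self.df
        missing_cols = [v.name for v in SCHEMA if v.name not in df.columns]
        if missing_cols:
            raise SchemaError(f"cohort is missing schema columns: {missing_cols}")
        for col in MANDATORY_COLUMNS:
            if df[col].isna().any():
                raise SchemaError(f"mandatory column {col!r} contains missing values")
        fu = df["followup_years"].to_numpy(float)
        if (fu < 0).any():
            raise SchemaError("followup_years must be >= 0")
        death = df["death"].to_numpy(float)
        if not np.isin(death, (0.0, 1.0)).all():
            raise SchemaError("death must be 0 or 1 and never missing")
        for var in SCHEMA:
            if var.kind == "categorical":
                observed = df[var.name].dropna()
                bad = set(observed) - set(var.levels)
                if bad:
                    raise SchemaError(f"{var.name}: unknown levels {sorted(map(str, bad))}")
            elif var.kind == "indicator":
                vals = df[var.name].dropna().to_numpy(float)
                if not np.isin(vals, (0.0, 1.0)).all():
                    raise SchemaError(f"{var.name}: indicator values must be 0/1")
            elif var.positive:
                vals = df[var.name].dropna().to_numpy(float)
                if (vals <= 0).any():
                    raise SchemaError(f"{var.name}: values must be > 0 when present")


def _empty_frame(n: int) -> pd.DataFrame:
    data: dict[str, object] = {}
    for var in SCHEMA:
        if var.kind == "categorical":
            data[var.name] = pd.Series([None] * n, dtype=object)
        else:
            data[var.name] = np.full(n, np.nan)
    return pd.DataFrame(data)


# --------------------------------------------------------------------------
# CSV I/O
# --------------------------------------------------------------------------


def load_cohort(
    path: str | Path,
    name: str | None = None,
    allow_extra_columns: bool = False,
    validate: bool = True,
) -> Cohort:
    """Read a cohort from CSV (UTF-8, comma separated, empty cell = missing).

    The header must carry exactly the schema columns; unknown columns are
    rejected unless ``allow_extra_columns`` (pass-through, kept verbatim).
    Units are taken as schema-declared; no conversion is applied.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw.columns = [c.strip() for c in raw.columns]
    schema_names = [v.name for v in SCHEMA]
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory columns {missing}")
    absent = [c for c in schema_names if c not in raw.columns]
    if absent:
        raise SchemaError(f"{path.name}: missing schema columns {absent}")
    extra = [c for c in raw.columns if c not in schema_names]
    if extra and not allow_extra_columns:
        raise SchemaError(
            f"{path.name}: unknown columns {extra} (pass allow_extra_columns=True to keep)"
        )

    out: dict[str, object] = {}
    for var in SCHEMA:
        cells = raw[var.name].str.strip()
        if var.kind == "categorical":
            lut = _CAT_LEVEL_STR[var.name]
            parsed = []
            for i, cell in enumerate(cells):
                if cell == "":
                    parsed.append(None)
                elif cell in lut:
                    parsed.append(lut[cell])
                else:
                    raise ParseError(
                        f"{path.name}: row {i + 2}, column {var.name!r}: "
                        f"unknown level {cell!r}"
                    )
            out[var.name] = pd.Series(parsed, dtype=object)
        else:
            values = np.full(len(cells), np.nan)
            for i, cell in enumerate(cells):
                if cell == "":
                    continue
                try:
                    values[i] = float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path.name}: row {i + 2}, column {var.name!r}: "
                        f"non-numeric value {cell!r}"
                    ) from None
            out[var.name] = values
    df = pd.DataFrame(out)
    for c in extra:
        df[c] = raw[c]
    cohort = Cohort(df, name or path.stem)
    if validate:
        cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to CSV; missing cells become empty strings.

    Round-trips cell-for-cell with :func:`load_cohort` for well-formed data.
    """
    df = cohort.df.copy()
    for var in SCHEMA:
        if var.kind == "categorical":
            df[var.name] = df[var.name].map(lambda x: "" if x is None or x is np.nan else str(x))
        else:
            df[var.name] = df[var.name].map(
                lambda x: "" if pd.isna(x) else format(float(x), "g")
            )
    df.to_csv(path, index=False)


def split_cohort(
    cohort: Cohort, fractions: tuple[float, float] = (0.83, 0.17), seed: int = 0
) -> tuple[Cohort, Cohort]:
    """Seeded disjoint, exhaustive split into derivation / validation cohorts.

    Sizes are round(n * f_dc) and the remainder; identical seeds reproduce
    the identical partition.
    """
    f_dc, f_ivc = fractions
    if not (0 < f_dc < 1 and 0 < f_ivc < 1):
        raise ValueError("fractions must lie in (0, 1)")
    if abs(f_dc + f_ivc - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if cohort.n == 0:
        raise ValueError("cannot split an empty cohort")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(cohort.n)
    n_dc = int(round(cohort.n * f_dc))
    dc_idx = np.sort(perm[:n_dc])
    ivc_idx = np.sort(perm[n_dc:])
    dc = Cohort(cohort.df.iloc[dc_idx], f"{cohort.name}-dc")
    ivc = Cohort(cohort.df.iloc[ivc_idx], f"{cohort.name}-ivc")
    return dc, ivc


# --------------------------------------------------------------------------
# Half-IQR increments
# --------------------------------------------------------------------------


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def half_iqr_increment(values: Sequence[float] | np.ndarray) -> float:
    """Half the interquartile range, rounded to a printable step.

    Quartiles use the standard linear-interpolation (type-7) estimator.
    Values >= 1 round half-up to the nearest integer (creatinine quartiles
    88/132 give 22 umol/l; donor age 22/44 gives 11 years); sub-unit spreads
    round half-up at two significant figures so small-scale variables such
    as bilirubin or body-size ratios keep a usable step.  A zero spread
    returns 0 and marks the variable degenerate (excluded from hazard-ratio
    perturbation).
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("half_iqr_increment: all values missing")
    if arr.size < 4:
        raise ValueError("half_iqr_increment: need at least 4 observed values")
    q1, q3 = np.quantile(arr, [0.25, 0.75])  # linear interpolation
    h = (q3 - q1) / 2.0
    if h == 0:
        return 0.0
    if h >= 1:
        return _round_half_up(h, 0)
    decimals = -int(np.floor(np.log10(h))) + 1  # two significant figures
    return _round_half_up(h, decimals)


# --------------------------------------------------------------------------
# Design matrix
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ColumnSpec:
    """One design-matrix column.

    kind:
      'continuous'  -- the source variable itself, standardized
      'indicator'   -- a 0/1 source variable, passed through
      'level'       -- 1 if categorical source equals ``level``
      'ratio'       -- recipient source / donor source (standardized)
    """

    name: str
    source: str
    kind: str
    level: object | None = None
    denominator: str | None = None


def categorical_columns(variable: str, reference: object) -> list[ColumnSpec]:
    """Reference-coded indicator columns for a k-level categorical (k-1 columns)."""
    var = SCHEMA_BY_NAME[variable]
    if var.kind != "categorical":
        raise ValueError(f"{variable} is not categorical")
    if reference not in var.levels:
        raise ValueError(f"{reference!r} is not a level of {variable}")
    return [
        ColumnSpec(f"{variable}_{str(level).lower()}", variable, "level", level=level)
        for level in var.levels
        if level != reference
    ]


def _cont(name: str) -> ColumnSpec:
    return ColumnSpec(name, name, "continuous")


def _ind(name: str) -> ColumnSpec:
    return ColumnSpec(name, name, "indicator")


#: The default 43-column model inventory: 32 recipient columns followed by
#: 11 donor columns.  Reference levels: blood group AB (recipient) and A
#: (donor), era 1991-1995, HLA-DR 0/1 mismatches pooled, and diagnoses
#: valvular/other pooled into the reference.
MODEL_DESIGN: tuple[ColumnSpec, ...] = (
    # recipient
    _cont("recipient_age"),
    ColumnSpec("recipient_female", "recipient_sex", "level", level="female"),
    _cont("recipient_height"),
    _cont("recipient_weight"),
    ColumnSpec("dx_ischemic_cm", "diagnosis", "level", level="ischemic_cm"),
    ColumnSpec("dx_non_ischemic_cm", "diagnosis", "level", level="non_ischemic_cm"),
    ColumnSpec("dx_congenital", "diagnosis", "level", level="congenital"),
    ColumnSpec("dx_graft_failure", "diagnosis", "level", level="graft_failure"),
    _ind("diabetes"),
    _ind("hypertension"),
    _ind("infection_2wk"),
    _ind("antiarrhythmics"),
    _ind("amiodarone"),
    _ind("prior_transfusion"),
    _ind("prior_transplant"),
    _ind("prior_cardiac_surgery"),
    _ind("icu"),
    _ind("ventilator"),
    _ind("ecmo"),
    _ind("vad"),
    ColumnSpec("era_1996_2000", "era", "level", level="1996-2000"),
    ColumnSpec("era_2001_2005", "era", "level", level="2001-2005"),
    ColumnSpec("era_2006_2010", "era", "level", level="2006-2010"),
    _cont("spp"),
    _cont("pvr"),
    _cont("creatinine"),
    _cont("bilirubin"),
    _ind("pra_gt10"),
    ColumnSpec("hladr_2mm", "hladr_mismatch", "level", level=2),
    ColumnSpec("rbg_a", "recipient_bg", "level", level="A"),
    ColumnSpec("rbg_b", "recipient_bg", "level", level="B"),
    ColumnSpec("rbg_o", "recipient_bg", "level", level="O"),
    # donor
    _cont("donor_age"),
    ColumnSpec("donor_female", "donor_sex", "level", level="female"),
    _cont("donor_weight"),
    _cont("ischemia_min"),
    _ind("codd_head_trauma"),
    _ind("codd_cva"),
    ColumnSpec("dbg_b", "donor_bg", "level", level="B"),
    ColumnSpec("dbg_ab", "donor_bg", "level", level="AB"),
    ColumnSpec("dbg_o", "donor_bg", "level", level="O"),
    ColumnSpec("weight_ratio", "recipient_weight", "ratio", denominator="donor_weight"),
    ColumnSpec("height_ratio", "recipient_height", "ratio", denominator="donor_height"),
)


@dataclass
class DesignMatrix:
    """A fitted design transform plus the fit-time matrix.

    Continuous and ratio columns are standardized with the stored means and
    standard deviations, applied identically to new data.  ``increments``
    holds the half-IQR perturbation step for each continuous/ratio column in
    native units; degenerate (zero-spread) columns are listed separately.
    """

    columns: tuple[ColumnSpec, ...]
    column_names: tuple[str, ...]
    column_kinds: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    increments: dict[str, float]
    degenerate: tuple[str, ...]
    values: np.ndarray  # fit-time matrix, n x p

    @property
    def p(self) -> int:
        return len(self.column_names)

    def column_index(self, name: str) -> int:
        try:
            return self.column_names.index(name)
        except ValueError:
            raise KeyError(f"unknown design column {name!r}") from None

    def raw(self, cohort: Cohort) -> np.ndarray:
        """Unstandardized design values for a cohort (n x p)."""
        df = cohort.df
        n = len(df)
        out = np.empty((n, len(self.columns)))
        for j, col in enumerate(self.columns):
            if col.kind == "continuous":
                out[:, j] = df[col.source].to_numpy(float)
            elif col.kind == "indicator":
                out[:, j] = df[col.source].to_numpy(float)
            elif col.kind == "level":
                var = SCHEMA_BY_NAME[col.source]
                observed = df[col.source]
                bad = set(observed.dropna()) - set(var.levels)
                if bad:
                    raise TransformError(
                        f"{col.source}: unseen categorical level(s) {sorted(map(str, bad))}"
                    )
                if observed.isna().any():
                    raise TransformError(f"{col.source}: missing values at transform time")
                out[:, j] = (observed == col.level).to_numpy(float)
            elif col.kind == "ratio":
                num = df[col.source].to_numpy(float)
                den = df[col.denominator].to_numpy(float)
                out[:, j] = num / den
            else:  # pragma: no cover
                raise ValueError(f"unknown column kind {col.kind!r}")
        if np.isnan(out).any():
            bad_cols = [
                self.column_names[j] for j in np.unique(np.argwhere(np.isnan(out))[:, 1])
            ]
            raise TransformError(f"missing values in design columns: {bad_cols}")
        return out

    def transform(self, cohort: Cohort) -> np.ndarray:
        """Standardized design matrix for (possibly new) complete data."""
        out = self.raw(cohort)
        scaled = np.where(self.sds > 0, self.sds, 1.0)
        return (out - self.means) / scaled

    def standardize_increment(self, column: str) -> float:
        """The half-IQR step of ``column`` expressed in standardized units."""
        j = self.column_index(column)
        if self.column_kinds[j] == "indicator":
            return 1.0
        inc = self.increments.get(column, 0.0)
        sd = self.sds[j] if self.sds[j] > 0 else 1.0
        return inc / sd

    def to_dict(self) -> dict:
        return {
            "columns": [
                {
                    "name": c.name,
                    "source": c.source,
                    "kind": c.kind,
                    "level": c.level,
                    "denominator": c.denominator,
                }
                for c in self.columns
            ],
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "increments": self.increments,
            "degenerate": list(self.degenerate),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignMatrix":
        columns = tuple(
            ColumnSpec(
                c["name"], c["source"], c["kind"], level=c["level"], denominator=c["denominator"]
            )
            for c in d["columns"]
        )
        names = tuple(c.name for c in columns)
        kinds = tuple("indicator" if c.kind in ("indicator", "level") else "continuous" for c in columns)
        return cls(
            columns=columns,
            column_names=names,
            column_kinds=kinds,
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            increments={k: float(v) for k, v in d["increments"].items()},
            degenerate=tuple(d["degenerate"]),
            values=np.empty((0, len(columns))),
        )


def build_design(
    cohort: Cohort, columns: Sequence[ColumnSpec] = MODEL_DESIGN
) -> DesignMatrix:
    """Fit a design matrix on a complete (post-imputation) cohort.

    Indicator columns are left as 0/1; continuous and ratio columns are
    standardized to zero mean / unit variance and receive a half-IQR
    increment.  Increments of zero-spread columns are flagged degenerate.
    """
    columns = tuple(columns)
    names = tuple(c.name for c in columns)
    if len(set(names)) != len(names):
        raise ValueError("duplicate design column names")
    kinds = tuple(
        "indicator" if c.kind in ("indicator", "level") else "continuous" for c in columns
    )
    dm = DesignMatrix(
        columns=columns,
        column_names=names,
        column_kinds=kinds,
        means=np.zeros(len(columns)),
        sds=np.ones(len(columns)),
        increments={},
        degenerate=(),
        values=np.empty((0, len(columns))),
    )
    raw = dm.raw(cohort)
    means = np.zeros(len(columns))
    sds = np.ones(len(columns))
    increments: dict[str, float] = {}
    degenerate: list[str] = []
    for j, (col, kind) in enumerate(zip(columns, kinds)):
        if kind != "continuous":
            continue
        means[j] = raw[:, j].mean()
        sds[j] = raw[:, j].std()
        inc = half_iqr_increment(raw[:, j]) if len(raw) >= 4 else 0.0
        increments[col.name] = inc
        if inc == 0:
            degenerate.append(col.name)
    dm = replace(
        dm,
        means=means,
        sds=sds,
        increments=increments,
        degenerate=tuple(degenerate),
    )
    scaled = np.where(dm.sds > 0, dm.sds, 1.0)
    dm.values = (raw - dm.means) / scaled
    return dm
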