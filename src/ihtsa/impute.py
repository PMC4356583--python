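"""Era-stratified hot-deck ("probability") imputation.

Each missing cell is filled, independently per imputation, by a uniform
draw from the values observed for that variable among *other* records in
the same stratum (transplant era by default).  Repeating this M times
yields M complete cohorts; the survival ensemble trains one committee
member per imputed cohort, so imputation uncertainty is propagated through
predictions rather than through coefficient pooling.

Strata with no observed donor value for a variable fall back to a pooled
draw across strata; this is logged on the resulting set.  Nearest-neighbour
imputation and case-wise deletion are not implemented: both were evaluated
against this scheme historically and discarded (case-wise deletion
overfits the derivation data and generalizes poorly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import Cohort, SCHEMA, SCHEMA_BY_NAME, PROTECTED_VARIABLES

__all__ = ["ImputationError", "ImputationSet", "impute_probability", "missingness_report"]


class ImputationError(ValueError):
    """A variable has no observed values anywhere to draw from."""


@dataclass
class ImputationSet:
    """M complete cohorts that agree at every originally observed cell."""

    cohorts: list[Cohort]
    m: int
    strata: str
    seed: int
    fallback_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.m < 1 or len(self.cohorts) != self.m:
            raise ValueError("ImputationSet requires m >= 1 cohorts")

    def __iter__(self):
        return iter(self.cohorts)

    def __len__(self) -> int:
        return self.m


def impute_probability(
    cohort: Cohort, m: int = 10, stratify: str = "era", seed: int = 0
) -> ImputationSet:
    """Hot-deck imputation stratified by ``stratify`` (default transplant era).

    Draws are with replacement, independent across cells, imputations and
    variables.  Observed cells are untouched, so all M cohorts are
    identical wherever data was observed.  Identical seeds reproduce the
    identical set.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if stratify not in SCHEMA_BY_NAME:
        raise ValueError(f"unknown stratifier {stratify!r}")
    df = cohort.df
    if df[stratify].isna().any():
        raise ValueError(f"stratifier {stratify!r} must never be missing")
    strata = df[stratify]
    stratum_index = {level: np.flatnonzero((strata == level).to_numpy()) for level in strata.unique()}

    rng = np.random.default_rng(np.random.SeedSequence((seed, 101)))
    outputs = [df.copy() for _ in range(m)]
    fallback_log: list[str] = []

    for var in SCHEMA:
        if var.name in PROTECTED_VARIABLES or var.name == stratify:
            continue
        col = df[var.name]
        missing = col.isna().to_numpy()
        if not missing.any():
            continue
        observed_all = np.flatnonzero(~missing)
        if observed_all.size == 0:
            raise ImputationError(
                f"{var.name}: missing for every record in every stratum"
            )
        values = col.to_numpy()
        for level, idx in stratum_index.items():
            miss_idx = idx[missing[idx]]
            if miss_idx.size == 0:
                continue
            donors = idx[~missing[idx]]
            if donors.size == 0:
                donors = observed_all  # pooled fallback
                fallback_log.append(f"{var.name}@{level}: pooled draw (no stratum donors)")
            draws = rng.choice(values[donors], size=(m, miss_idx.size), replace=True)
            for k in range(m):
                outputs[k].loc[miss_idx, var.name] = draws[k]
    cohorts = [
        Cohort(out, name=f"{cohort.name}-imp{k}") for k, out in enumerate(outputs)
    ]
    return ImputationSet(cohorts, m=m, strata=stratify, seed=seed, fallback_log=fallback_log)


def missingness_report(cohort: Cohort, stratify: str = "era") -> pd.DataFrame:
    """Per-variable missing counts and fractions, pooled and by stratum.

    Returns a tidy frame with columns: variable, stratum ('all' for the
    pooled row), n, n_missing, fraction.
    """
    df = cohort.df
    rows = []
    levels = list(df[stratify].dropna().unique()) if stratify in df.columns else []
    for var in SCHEMA:
        miss = df[var.name].isna()
        rows.append(
            {
                "variable": var.name,
                "stratum": "all",
                "n": len(df),
                "n_missing": int(miss.sum()),
                "fraction": float(miss.mean()) if len(df) else 0.0,
            }
        )
        for level in levels:
            sel = df[stratify] == level
            sub = miss[sel]
            rows.append(
                {
                    "variable": var.name,
                    "stratum": str(level),
                    "n": int(sel.sum()),
                    "n_missing": int(sub.sum()),
                    "fraction": float(sub.mean()) if sel.any() else 0.0,
                }
            )
    return pd.DataFrame(rows)
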