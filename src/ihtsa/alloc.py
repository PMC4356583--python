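"""Seeded organ-allocation policy simulator.

A waiting list of NW recipients is drawn from a pool; donors stream in one
at a time.  Three policies are compared: a survival-model policy that gives
the organ to the ABO-compatible candidate with the best predicted median
survival of the hypothetical pair, a criterion-based clinical policy
(blood-group and weight matching with age-tier priorities and stricter
rules under pulmonary hypertension), and a random policy (uniform among
ABO-compatible candidates, the control).  A matched recipient leaves the
list and is replaced by a fresh recipient from the pool.

By default the policies run on separate copies of the list under common
random numbers (shared donor and replacement streams, independent
tie-break streams), so differences between policies are policy effects
rather than sampling noise; a ``mode='randomize'`` variant assigns each
donor to a single policy at random on one shared list, mirroring a
between-policy randomized design.

Hypothetical pairs substitute the donor's fields (age, sex, weight,
height, blood group, cause of death) into the candidate's record and
recompute the body-size ratios; cold ischemia time, unknown before
allocation, is fixed at the pool median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model import EnsembleModel, median_from_hazards
from .registry import Cohort

__all__ = [
    "ABO_COMPATIBLE",
    "abo_compatible",
    "clinical_priority",
    "PairPredictor",
    "allocate",
    "AllocationRun",
    "PolicyTrace",
    "run_simulation",
    "sensitivity_filter",
]

#: donor blood group -> compatible recipient groups (O universal donor,
#: AB universal recipient)
ABO_COMPATIBLE: dict[str, frozenset] = {
    "O": frozenset({"O", "A", "B", "AB"}),
    "A": frozenset({"A", "AB"}),
    "B": frozenset({"B", "AB"}),
    "AB": frozenset({"AB"}),
}


def abo_compatible(donor_bg: str, recipient_bg) -> np.ndarray | bool:
    """Standard ABO donor -> recipient compatibility."""
    if donor_bg not in ABO_COMPATIBLE:
        raise ValueError(f"invalid donor blood group {donor_bg!r}")
    allowed = ABO_COMPATIBLE[donor_bg]
    if isinstance(recipient_bg, str):
        if recipient_bg not in ABO_COMPATIBLE:
            raise ValueError(f"invalid recipient blood group {recipient_bg!r}")
        return recipient_bg in allowed
    rec = np.asarray(recipient_bg, dtype=object)
    bad = set(rec) - set(ABO_COMPATIBLE)
    if bad:
        raise ValueError(f"invalid recipient blood group(s) {sorted(map(str, bad))}")
    return np.isin(rec, list(allowed))


def _clinical_tiers(donor: pd.Series, recipients: pd.DataFrame) -> np.ndarray:
    """Tier per candidate: 1, 2, 3, or 0 for ineligible.

    Eligible requires ABO compatibility and |donor weight - recipient
    weight| <= 20% of recipient weight.  Under recipient PVR > 3.0 the
    donor must weigh 0-15% more than the recipient and female-to-male
    donation is barred.  Tier 1: identical blood group, both ages <= 35;
    tier 2: identical group, donor age < recipient age + 15; tier 3: any
    remaining eligible match.  Missing weight, age or PVR makes a
    candidate ineligible.
    """
    d_bg = donor["donor_bg"]
    d_w = float(donor["donor_weight"])
    d_age = float(donor["donor_age"])
    d_female = donor["donor_sex"] == "female"
    r_bg = recipients["recipient_bg"].to_numpy(object)
    r_w = recipients["recipient_weight"].to_numpy(float)
    r_age = recipients["recipient_age"].to_numpy(float)
    r_male = (recipients["recipient_sex"] == "male").to_numpy(bool)
    pvr = recipients["pvr"].to_numpy(float)

    known = ~(np.isnan(r_w) | np.isnan(r_age) | np.isnan(pvr))
    eligible = known & np.asarray(abo_compatible(d_bg, np.where(known, r_bg, "O")))
    eligible &= np.abs(d_w - r_w) <= 0.20 * r_w
    high_pvr = known & (pvr > 3.0)
    pvr_ok = (d_w >= r_w) & (d_w <= 1.15 * r_w) & ~(d_female & r_male)
    eligible &= ~high_pvr | pvr_ok

    identical = r_bg == d_bg
    tier = np.where(eligible, 3, 0)
    tier = np.where(eligible & identical & (d_age < r_age + 15), 2, tier)
    tier = np.where(eligible & identical & (d_age <= 35) & (r_age <= 35), 1, tier)
    return tier


def clinical_priority(donor: pd.Series, recipient: pd.Series):
    """Tier of one candidate under the clinical model: 1, 2, 3 or None."""
    tier = _clinical_tiers(donor, pd.DataFrame([recipient]))[0]
    return int(tier) if tier > 0 else None


class PairPredictor:
    """Fast predicted median survival for hypothetical recipient-donor pairs.

    Precomputes each committee member's raw design rows for the pool acting
    as recipients; scoring a donor against a candidate set only overwrites
    the donor-sourced columns and the body-size ratios before
    standardizing.
    """

    DONOR_SOURCES = (
        "donor_age",
        "donor_sex",
        "donor_height",
        "donor_weight",
        "ischemia_min",
        "codd_head_trauma",
        "codd_cva",
        "donor_bg",
    )

    def __init__(self, model: EnsembleModel, pool: Cohort):
        self.model = model
        df = pool.df
        self.ischemia_median = float(np.nanmedian(df["ischemia_min"].to_numpy(float)))
        self.r_weight = df["recipient_weight"].to_numpy(float)
        self.r_height = df["recipient_height"].to_numpy(float)
        self.d_weight = df["donor_weight"].to_numpy(float)
        self.d_height = df["donor_height"].to_numpy(float)

        dm0 = model.designs[0]
        self.donor_cols: list[int] = []
        self.ratio_cols: dict[str, int] = {}
        donor_col_values = []
        for j, col in enumerate(dm0.columns):
            if col.kind == "ratio":
                self.ratio_cols[col.name] = j
                continue
            if col.source in self.DONOR_SOURCES:
                self.donor_cols.append(j)
                if col.source == "ischemia_min":
                    donor_col_values.append(np.full(len(df), self.ischemia_median))
                elif col.kind == "level":
                    donor_col_values.append((df[col.source] == col.level).to_numpy(float))
                else:
                    donor_col_values.append(df[col.source].to_numpy(float))
        # pool record i viewed as a donor: its donor-sourced design values
        self.donor_values = np.column_stack(donor_col_values) if donor_col_values else None
        self.base_raw = [dm.raw(pool) for dm in model.designs]

    def medians(self, donor_idx: int, candidate_idx: np.ndarray) -> np.ndarray:
        cand = np.asarray(candidate_idx, dtype=int)
        hz = None
        for net, dm, raw in zip(self.model.members, self.model.designs, self.base_raw):
            X = raw[cand].copy()
            if self.donor_cols:
                X[:, self.donor_cols] = self.donor_values[donor_idx]
            if "weight_ratio" in self.ratio_cols:
                X[:, self.ratio_cols["weight_ratio"]] = (
                    self.r_weight[cand] / self.d_weight[donor_idx]
                )
            if "height_ratio" in self.ratio_cols:
                X[:, self.ratio_cols["height_ratio"]] = (
                    self.r_height[cand] / self.d_height[donor_idx]
                )
            sds = np.where(dm.sds > 0, dm.sds, 1.0)
            h = net.predict((X - dm.means) / sds)
            hz = h if hz is None else hz + h
        return median_from_hazards(hz / self.model.M, self.model.grid)


def allocate(
    donor: pd.Series,
    donor_idx: int,
    waitlist: np.ndarray,
    policy: str,
    pool: Cohort,
    rng: np.random.Generator,
    predictor: PairPredictor | None = None,
):
    """Pick a recipient (pool index) for one donor, or None.

    'ihtsa': ABO-compatible candidate maximizing predicted median survival
    of the hypothetical pair; 'clinical': lowest tier wins; 'random':
    uniform among ABO-compatible.  Equal priority resolves by a seeded
    random draw.  Returns (recipient_index or None, predicted_median or
    nan).
    """
    if len(waitlist) == 0:
        return None, np.nan
    recips = pool.df.iloc[waitlist]
    compat = np.asarray(abo_compatible(donor["donor_bg"], recips["recipient_bg"].to_numpy(object)))
    if policy == "ihtsa":
        if predictor is None:
            raise ValueError("ihtsa policy requires a trained model")
        cand = waitlist[compat]
        if cand.size == 0:
            return None, np.nan
        med = predictor.medians(donor_idx, cand)
        best = med == med.max()
        pick = int(rng.choice(np.flatnonzero(best)))
        return int(cand[pick]), float(med[pick])
    if policy == "clinical":
        tiers = _clinical_tiers(donor, recips)
        if (tiers == 0).all():
            return None, np.nan
        top = tiers == tiers[tiers > 0].min()
        pick = int(rng.choice(np.flatnonzero(top)))
        chosen = int(waitlist[pick])
        med = predictor.medians(donor_idx, np.array([chosen]))[0] if predictor else np.nan
        return chosen, float(med)
    if policy == "random":
        cand = waitlist[compat]
        if cand.size == 0:
            return None, np.nan
        chosen = int(rng.choice(cand))
        med = predictor.medians(donor_idx, np.array([chosen]))[0] if predictor else np.nan
        return chosen, float(med)
    raise ValueError(f"unknown policy {policy!r}")


@dataclass
class PolicyTrace:
    transplants: int = 0
    refusals: int = 0
    matches: list[dict] = field(default_factory=list)

    @property
    def predicted_medians(self) -> np.ndarray:
        return np.array([m["predicted_median"] for m in self.matches])


@dataclass
class AllocationRun:
    nw: int
    n_donor_draws: int
    seed: int
    mode: str
    policies: tuple[str, ...]
    traces: dict[str, PolicyTrace]
    truncated: bool = False


def run_simulation(
    pool: Cohort,
    nw: int,
    n_donor_draws: int,
    policies: Sequence[str] = ("ihtsa", "clinical", "random"),
    model: EnsembleModel | None = None,
    seed: int = 0,
    mode: str = "crn",
) -> AllocationRun:
    """Simulate organ allocation over a seeded donor stream.

    Each policy keeps its own copy of the waiting list (mode 'crn': shared
    donor/replacement streams; mode 'randomize': one shared list, each
    donor randomized to a single policy).  A matched recipient is replaced
    by the next unused recipient from a seeded replacement sequence; when
    the pool runs out, the run is truncated with a warning.
    """
    if pool.n <= nw:
        raise ValueError("pool must be larger than the waiting list")
    policies = tuple(policies)
    if "ihtsa" in policies and model is None:
        raise ValueError("ihtsa policy requires a trained model")
    if mode not in ("crn", "randomize"):
        raise ValueError(f"unknown mode {mode!r}")
    predictor = PairPredictor(model, pool) if model is not None else None

    ss = np.random.SeedSequence((seed, 505))
    donor_rng, list_rng, policy_rng, *tie_rngs = [
        np.random.default_rng(s) for s in ss.spawn(3 + len(policies))
    ]
    tie_rng = dict(zip(policies, tie_rngs))

    initial = list_rng.choice(pool.n, size=nw, replace=False)
    replacement_seq = list_rng.permutation(np.setdiff1d(np.arange(pool.n), initial))
    donor_stream = donor_rng.integers(0, pool.n, size=n_donor_draws)

    lists = {p: initial.copy() for p in policies}
    pointers = {p: 0 for p in policies}
    used = {p: set(initial.tolist()) for p in policies}
    traces = {p: PolicyTrace() for p in policies}
    truncated = False

    if mode == "randomize":
        assigned = policy_rng.choice(len(policies), size=n_donor_draws)

    for draw, donor_idx in enumerate(donor_stream):
        donor = pool.df.iloc[int(donor_idx)]
        active = (
            policies if mode == "crn" else (policies[assigned[draw]],)
        )
        for p in active:
            wl = lists[p]
            compat_exists = np.asarray(
                abo_compatible(donor["donor_bg"], pool.df["recipient_bg"].to_numpy(object)[wl])
            ).any()
            if not compat_exists:
                continue  # donor not offered (no blood-group match on the list)
            chosen, med = allocate(
                donor, int(donor_idx), wl, p, pool, tie_rng[p], predictor
            )
            if chosen is None:
                traces[p].refusals += 1
                continue
            traces[p].transplants += 1
            traces[p].matches.append(
                {
                    "draw": draw,
                    "donor": int(donor_idx),
                    "recipient": int(chosen),
                    "predicted_median": med,
                }
            )
            wl = wl[wl != chosen]
            # replace with the next pool recipient not yet seen by this policy
            ptr = pointers[p]
            while ptr < len(replacement_seq) and int(replacement_seq[ptr]) in used[p]:
                ptr += 1
            if ptr < len(replacement_seq):
                newcomer = int(replacement_seq[ptr])
                used[p].add(newcomer)
                wl = np.append(wl, newcomer)
                pointers[p] = ptr + 1
            else:
                truncated = True
                warnings.warn("replacement pool exhausted; run truncated", stacklevel=2)
            lists[p] = wl
    return AllocationRun(
        nw=nw,
        n_donor_draws=n_donor_draws,
        seed=seed,
        mode=mode,
        policies=policies,
        traces=traces,
        truncated=truncated,
    )


def _default_high_risk(df: pd.DataFrame) -> np.ndarray:
    flags = ["icu", "ventilator", "ecmo", "vad"]
    risk = np.zeros(len(df), dtype=bool)
    for f in flags:
        risk |= df[f].to_numpy(float) == 1
    return risk


def sensitivity_filter(
    pool: Cohort, exclude: Callable[[pd.DataFrame], np.ndarray] | None = None
) -> Cohort:
    """Drop high-risk candidates (default: ICU or life support — mechanical
    ventilation, ECMO or VAD — prior to transplant)."""
    predicate = exclude or _default_high_risk
    drop = np.asarray(predicate(pool.df), dtype=bool)
    if drop.all():
        raise ValueError("sensitivity filter removed every record")
    return Cohort(pool.df.loc[~drop], name=f"{pool.name}-lowrisk")
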