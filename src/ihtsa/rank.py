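"""Backward variable elimination ranked by concordance degradation.

Each round, the committee is trained with cross-validation on the active
variable set (Step I); then every non-mandatory variable is "omitted" in
turn by neutralizing its column at validation time — the standardized
column is set to its training mean — and the drop in validation C-index is
recorded (Step II).  The variable whose omission costs the least is
removed, and the procedure repeats until only the mandatory recipient-donor
match variables (blood group, body size, gender and age of both parties)
remain.  The elimination order, read backwards, is the importance ranking.

Neutral-value masking scores omissions against the Step-I model instead of
retraining one model per candidate per round (which would be quadratic in
the variable count); an exhaustive re-train mode is available for small
problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .impute import ImputationSet
from .metrics import harrell_c
from .model import TimeGrid, TrainConfig, build_time_grid, make_targets, median_from_hazards, train_network
from .registry import MODEL_DESIGN, ColumnSpec, build_design

__all__ = ["DEFAULT_MANDATORY", "RankingResult", "rank_variables", "select_model_size"]

#: The 13 recipient-donor match variables never entered into the ranking:
#: blood group (3 indicator columns per party), body size (weight, and
#: recipient height), gender and age of both recipient and donor.
DEFAULT_MANDATORY: tuple[str, ...] = (
    "recipient_age",
    "recipient_female",
    "recipient_height",
    "recipient_weight",
    "rbg_a",
    "rbg_b",
    "rbg_o",
    "donor_age",
    "donor_female",
    "donor_weight",
    "dbg_b",
    "dbg_ab",
    "dbg_o",
)


@dataclass
class RankingResult:
    """Outcome of the backward elimination.

    ``elimination_order`` runs from least to most important (first removed
    first).  ``c_trajectory[i]`` is the cross-validated C-index of the
    model after i removals (length = eliminations + 1).  ``removal_deltas``
    holds, for each eliminated variable, the per-fold C-index drops
    measured in the round it was removed.
    """

    elimination_order: list[str]
    c_trajectory: list[float]
    removal_deltas: dict[str, list[float]]
    mandatory_set: tuple[str, ...]

    def ranking(self) -> list[str]:
        """Variables from most to least important."""
        return list(reversed(self.elimination_order))


def rank_variables(
    imputation_set: ImputationSet,
    config: TrainConfig,
    mandatory: tuple[str, ...] = DEFAULT_MANDATORY,
    seed: int = 0,
    columns=MODEL_DESIGN,
    K: int = 25,
    grid: TimeGrid | None = None,
    mode: str = "mask",
) -> RankingResult:
    """Rank non-mandatory variables by backward elimination.

    mode 'mask' neutralizes candidate columns at validation time; mode
    'retrain' refits the committee per candidate (exhaustive).  Ties break
    by variable list order.
    """
    columns = tuple(columns)
    names = [c.name for c in columns]
    mandatory = tuple(mandatory)
    unknown = set(mandatory) - set(names)
    if unknown:
        raise ValueError(f"mandatory variables not in the design: {sorted(unknown)}")
    non_mandatory = [c for c in names if c not in mandatory]
    if not non_mandatory:
        raise ValueError("mandatory set equals the full variable set: nothing to rank")
    if mode not in ("mask", "retrain"):
        raise ValueError(f"unknown mode {mode!r}")

    cohorts = list(imputation_set)
    first = cohorts[0]
    t = first.df["followup_years"].to_numpy(float)
    d = first.df["death"].to_numpy(float)
    if grid is None:
        grid = build_time_grid(t, K)
    targets_all = make_targets(t, d, grid)

    designs = [build_design(c, columns) for c in cohorts]
    mats = [dm.values for dm in designs]
    # neutral value per member and column: the fit-time column mean
    # (zero for standardized columns, the prevalence for indicators)
    neutral = [X.mean(axis=0) for X in mats]

    rng = np.random.default_rng(np.random.SeedSequence((seed, 404)))
    perm = rng.permutation(len(t))
    folds = [perm[i :: config.folds] for i in range(config.folds)]

    active = list(names)
    elimination_order: list[str] = []
    c_trajectory: list[float] = []
    removal_deltas: dict[str, list[float]] = {}

    round_no = 0
    while True:
        cand = [v for v in active if v not in mandatory]
        cols = [names.index(v) for v in active]
        base_scores = []
        masked_scores = {v: [] for v in cand}
        for f, val_idx in enumerate(folds):
            train_mask = np.ones(len(t), dtype=bool)
            train_mask[val_idx] = False
            targets = make_targets(t[train_mask], d[train_mask], grid)
            nets = [
                train_network(
                    X[train_mask][:, cols],
                    targets,
                    config,
                    seed=seed + 10_000 * round_no + 100 * f + m,
                )
                for m, X in enumerate(mats)
            ]
            val_mats = [X[val_idx][:, cols] for X in mats]
            hz = _committee_hazards(nets, val_mats)
            base = harrell_c(median_from_hazards(hz, grid), t[val_idx], d[val_idx]).c
            base_scores.append(base)
            for v in cand:
                if mode == "mask":
                    j = active.index(v)
                    masked = []
                    for m, Xv in enumerate(val_mats):
                        Xm = Xv.copy()
                        Xm[:, j] = neutral[m][names.index(v)]
                        masked.append(Xm)
                    hz_v = _committee_hazards(nets, masked)
                else:
                    sub = [c for c in cols if c != names.index(v)]
                    nets_v = [
                        train_network(
                            X[train_mask][:, sub],
                            targets,
                            config,
                            seed=seed + 10_000 * round_no + 100 * f + m,
                        )
                        for m, X in enumerate(mats)
                    ]
                    hz_v = _committee_hazards(nets_v, [X[val_idx][:, sub] for X in mats])
                c_v = harrell_c(median_from_hazards(hz_v, grid), t[val_idx], d[val_idx]).c
                masked_scores[v].append(base - c_v)
        c_trajectory.append(float(np.mean(base_scores)))
        if not cand:
            break
        mean_delta = {v: float(np.mean(masked_scores[v])) for v in cand}
        # smallest performance loss goes first; ties by variable list order
        victim = min(cand, key=lambda v: (mean_delta[v], cand.index(v)))
        removal_deltas[victim] = [float(x) for x in masked_scores[victim]]
        elimination_order.append(victim)
        active.remove(victim)
        round_no += 1

    return RankingResult(
        elimination_order=elimination_order,
        c_trajectory=c_trajectory,
        removal_deltas=removal_deltas,
        mandatory_set=mandatory,
    )


def _committee_hazards(nets, mats):
    out = None
    for net, X in zip(nets, mats):
        h = net.predict(X)
        out = h if out is None else out + h
    return out / len(nets)


def select_model_size(result: RankingResult, tolerance: float = 0.002) -> list[str]:
    """Smallest variable subset within ``tolerance`` of the trajectory's
    best cross-validated C-index.

    ``c_trajectory[i]`` corresponds to the model after i eliminations, so
    the subset keeps the mandatory variables plus the non-mandatory
    variables not yet removed at that point.
    """
    traj = np.asarray(result.c_trajectory, dtype=float)
    if traj.size == 0:
        raise ValueError("empty trajectory")
    best = traj.max()
    eligible = np.flatnonzero(traj >= best - tolerance)
    i = int(eligible.max())  # most eliminations still within tolerance
    kept = result.elimination_order[i:]
    return list(result.mandatory_set) + kept
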