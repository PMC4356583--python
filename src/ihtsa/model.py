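"""Discrete-time hazard neural network and committee ensemble.

The survival model is a partial-logistic network in the Biganzoli style: a
single hidden layer of logistic units feeding K logistic output nodes, one
conditional hazard per time interval.  Follow-up is partitioned into K
right-open intervals (default 25) at equal-probability quantiles of the
observed follow-up times; a record dying in interval k contributes Bernoulli
targets for intervals 1..k (event at k), a record censored inside interval k
contributes targets for intervals 1..k-1 only.  Survival is the cumulative
product S_k = prod_{j<=k} (1 - h_j).

Training minimizes the masked cross-entropy (mean per at-risk
person-interval) plus an L2 weight-decay penalty on the weights (not the
biases), with full-batch resilient back-propagation (iRprop-).  Rprop adapts
a per-parameter step from gradient signs only, which makes it insensitive
to the loss scale and robust without a learning-rate schedule.  Duplicate
design/target rows are collapsed to weighted rows before training; the loss
is unchanged and saturated designs (few covariate patterns) train in
near-constant time regardless of cohort size.

Imputation uncertainty enters through the committee: one network is trained
per imputed cohort (member seed = base seed + member index) and the
ensemble hazard is the arithmetic mean of the member hazards.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .impute import ImputationSet
from .registry import Cohort, ColumnSpec, DesignMatrix, MODEL_DESIGN, build_design

__all__ = [
    "TimeGrid",
    "build_time_grid",
    "IntervalTargets",
    "make_targets",
    "TrainConfig",
    "TrainingError",
    "HazardNetwork",
    "train_network",
    "cross_validate",
    "EnsembleModel",
    "train_ensemble",
    "SurvivalCurve",
    "predict_curve",
    "ensemble_hazards",
    "median_survival",
    "survival_at",
    "median_from_hazards",
    "save_model",
    "load_model",
]


class TrainingError(RuntimeError):
    """Optimization produced a non-finite loss."""


# --------------------------------------------------------------------------
# Time grid and interval targets
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeGrid:
    """K right-open intervals [b_0, b_1), ..., [b_{K-1}, b_K] partitioning
    follow-up time, b_0 = 0; the final interval absorbs the tail."""

    boundaries: np.ndarray  # K+1 strictly increasing times, starts at 0

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        object.__setattr__(self, "boundaries", b)
        if b.ndim != 1 or len(b) < 2:
            raise ValueError("grid needs at least one interval")
        if b[0] != 0:
            raise ValueError("grid must start at 0")
        if not (np.diff(b) > 0).all():
            raise ValueError("grid boundaries must be strictly increasing")

    @property
    def K(self) -> int:
        return len(self.boundaries) - 1

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.boundaries)

    def interval_of(self, t) -> np.ndarray:
        """1-based interval containing time t (right-open; t >= b_K maps to
        K + 1, i.e. beyond the grid)."""
        t = np.asarray(t, dtype=float)
        return np.searchsorted(self.boundaries[1:], t, side="right") + 1


def build_time_grid(followup_years: Sequence[float] | Cohort, K: int = 25) -> TimeGrid:
    """Boundaries at the 1/K..(K-1)/K quantiles of observed follow-up, with
    0 prepended and the maximum follow-up as the final boundary.

    Duplicate quantiles (heavily tied follow-up) are merged with K reduced
    and a warning.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if isinstance(followup_years, Cohort):
        times = followup_years.df["followup_years"].to_numpy(float)
    else:
        times = np.asarray(followup_years, dtype=float)
    if times.size == 0:
        raise ValueError("no follow-up times")
    inner = np.quantile(times, np.arange(1, K) / K) if K > 1 else np.array([])
    bounds = np.concatenate(([0.0], inner, [times.max()]))
    merged = np.unique(bounds)
    if merged[-1] <= 0:
        merged = np.array([0.0, max(times.max(), 1e-12)])
    if len(merged) < len(bounds):
        warnings.warn(
            f"time grid merged to {len(merged) - 1} intervals (duplicate quantiles)",
            stacklevel=2,
        )
    return TimeGrid(merged)


@dataclass(frozen=True)
class IntervalTargets:
    """Discrete-time likelihood expansion of (followup, death) on a grid.

    ``n_at_risk[i]`` is the length k of the at-risk prefix {1..k};
    ``event_interval[i]`` is the 1-based event interval or 0 if censored.
    """

    n_at_risk: np.ndarray
    event_interval: np.ndarray
    grid: TimeGrid

    def matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """(R, D): at-risk mask and event indicator, both n x K floats."""
        K = self.grid.K
        cols = np.arange(1, K + 1)
        R = (cols[None, :] <= self.n_at_risk[:, None]).astype(float)
        D = (cols[None, :] == self.event_interval[:, None]).astype(float)
        return R, D


def make_targets(followup_years, death, grid: TimeGrid) -> IntervalTargets:
    """Map observed (time, event) pairs to per-interval Bernoulli targets.

    A death inside interval k is at risk in 1..k with the event at k (times
    at or beyond the last boundary are absorbed into interval K).  A record
    censored inside interval k is at risk in 1..k-1 and contributes no
    target for its partial interval; censoring exactly at a boundary counts
    every completed interval.
    """
    t = np.atleast_1d(np.asarray(followup_years, dtype=float))
    d = np.atleast_1d(np.asarray(death, dtype=float))
    if (t < 0).any():
        raise ValueError("followup_years must be >= 0")
    K = grid.K
    interval = grid.interval_of(t)  # 1..K+1
    n_at_risk = np.where(d == 1, np.minimum(interval, K), np.minimum(interval - 1, K))
    event_interval = np.where(d == 1, np.minimum(interval, K), 0)
    return IntervalTargets(n_at_risk.astype(int), event_interval.astype(int), grid)


# --------------------------------------------------------------------------
# Network and training
# --------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Architecture, optimizer and model-selection settings.

    ``hidden``/``decay`` are the operating point used by training;
    ``hidden_grid``/``decay_grid`` (defaulting to the single operating
    point) are scanned by cross-validation.  Rprop parameters follow the
    standard recommendations (eta+ 1.2, eta- 0.5, Delta0 0.01).
    """

    hidden: int = 18
    decay: float = 1e-4
    hidden_grid: tuple[int, ...] | None = None
    decay_grid: tuple[float, ...] | None = None
    folds: int = 5
    epochs: int = 400
    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta0: float = 0.01
    delta_min: float = 1e-6
    delta_max: float = 50.0
    patience: int = 40
    tol: float = 1e-7
    selection_metric: str = "c_index"  # or "loss"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.hidden_grid is not None and len(self.hidden_grid) == 0:
            raise ValueError("hidden_grid must be nonempty")
        if self.decay_grid is not None and len(self.decay_grid) == 0:
            raise ValueError("decay_grid must be nonempty")

    @property
    def hgrid(self) -> tuple[int, ...]:
        return self.hidden_grid or (self.hidden,)

    @property
    def dgrid(self) -> tuple[float, ...]:
        return self.decay_grid or (self.decay,)


@dataclass
class HazardNetwork:
    """One trained partial-logistic hazard network (p -> H -> K)."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    decay: float
    seed: int
    final_loss: float = np.nan

    @property
    def input_dim(self) -> int:
        return self.W1.shape[0]

    @property
    def hidden(self) -> int:
        return self.W1.shape[1]

    @property
    def K(self) -> int:
        return self.W2.shape[1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Per-interval conditional hazards, n x K, all in (0, 1)."""
        Z = expit(X @ self.W1 + self.b1)
        return expit(Z @ self.W2 + self.b2)


def _collapse_rows(X, R, D, w):
    """Merge identical (design, target) rows into weighted rows."""
    stacked = np.ascontiguousarray(np.hstack([X, R, D]))
    view = stacked.view([("", stacked.dtype)] * stacked.shape[1]).ravel()
    _, first, inverse = np.unique(view, return_index=True, return_inverse=True)
    if first.size > 0.5 * len(X):
        return X, R, D, w
    wsum = np.bincount(inverse, weights=w, minlength=first.size)
    return X[first], R[first], D[first], wsum


def train_network(
    X: np.ndarray,
    targets: IntervalTargets,
    config: TrainConfig,
    seed: int | None = None,
    sample_weight: np.ndarray | None = None,
    warm_start: HazardNetwork | None = None,
    epochs: int | None = None,
) -> HazardNetwork:
    """Fit one hazard network with full-batch iRprop-.

    The loss is the cross-entropy over at-risk person-intervals (mean per
    at-risk cell) plus ``decay * sum(weights^2)``; intervals outside the
    at-risk prefix are masked out.  Weights start from a seeded small
    uniform distribution (output biases at the logit of the pooled
    per-interval hazard, which removes most of the burn-in); ``warm_start``
    re-uses an existing network's weights, e.g. for bootstrap refits.
    Returns the parameters with the best loss seen.
    """
    R, D = targets.matrices()
    n, p = X.shape
    K = R.shape[1]
    H = config.hidden
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    if D.sum() == 0:
        raise ValueError("training requires at least one event")
    X, R, D, w = _collapse_rows(X, R, D, w)
    wR = w[:, None] * R
    N = wR.sum()
    lam = config.decay
    epochs = config.epochs if epochs is None else epochs

    if warm_start is not None:
        W1, b1 = warm_start.W1.copy(), warm_start.b1.copy()
        W2, b2 = warm_start.W2.copy(), warm_start.b2.copy()
        H = warm_start.hidden
    else:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        W1 = rng.uniform(-0.5, 0.5, size=(p, H)) / np.sqrt(max(p, 1))
        b1 = np.zeros(H)
        W2 = rng.uniform(-0.5, 0.5, size=(H, K)) / np.sqrt(H)
        pooled = (w[:, None] * D).sum(axis=0) / np.maximum(wR.sum(axis=0), 1.0)
        pooled = np.clip(pooled, 1e-4, 1 - 1e-4)
        b2 = np.log(pooled / (1 - pooled))

    params = [W1, b1, W2, b2]
    deltas = [np.full_like(q, config.delta0) for q in params]
    prev_grad = [np.zeros_like(q) for q in params]
    best = [q.copy() for q in params]
    best_loss = np.inf
    stall = 0
    eps = 1e-12

    for epoch in range(epochs):
        Z = expit(X @ W1 + b1)
        Hhat = expit(Z @ W2 + b2)
        Hc = np.clip(Hhat, eps, 1 - eps)
        ce = -(wR * (D * np.log(Hc) + (1 - D) * np.log(1 - Hc))).sum() / N
        loss = ce + lam * ((W1 * W1).sum() + (W2 * W2).sum())
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        if loss < best_loss - config.tol * max(1.0, abs(best_loss)):
            stall = 0
        else:
            stall += 1
        if loss < best_loss:
            best_loss = loss
            best = [q.copy() for q in params]
        if stall >= config.patience:
            break

        G2 = wR * (Hhat - D) / N  # d loss / d A2
        gW2 = Z.T @ G2 + 2 * lam * W2
        gb2 = G2.sum(axis=0)
        GZ = G2 @ W2.T
        G1 = GZ * Z * (1 - Z)
        gW1 = X.T @ G1 + 2 * lam * W1
        gb1 = G1.sum(axis=0)

        for q, g, delta, gp in zip(params, (gW1, gb1, gW2, gb2), deltas, prev_grad):
            s = gp * g
            np.minimum(np.where(s > 0, delta * config.eta_plus, delta), config.delta_max, out=delta)
            np.maximum(np.where(s < 0, delta * config.eta_minus, delta), config.delta_min, out=delta)
            g_eff = np.where(s < 0, 0.0, g)  # iRprop-: forget flipped gradients
            q -= np.sign(g_eff) * delta
            gp[...] = g_eff

    W1, b1, W2, b2 = best
    return HazardNetwork(
        W1=W1, b1=b1, W2=W2, b2=b2, decay=lam,
        seed=(config.seed if seed is None else seed), final_loss=best_loss,
    )


def train_network_batch(
    X: np.ndarray,
    R: np.ndarray,
    D: np.ndarray,
    weights: np.ndarray,
    config: TrainConfig,
    warm_start: HazardNetwork,
    epochs: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Train B reweighted replicates of one network simultaneously.

    All replicates share the (usually pattern-collapsed) rows X/R/D and
    differ only in their per-row weights (B x n), as in a nonparametric
    bootstrap.  Parameters carry a leading replicate axis and follow the
    same iRprop- updates as :func:`train_network`; the best-loss parameters
    per replicate are returned as (W1, b1, W2, b2) with shapes
    (B, p, H), (B, H), (B, H, K), (B, K).
    """
    B = weights.shape[0]
    lam = config.decay
    W1 = np.broadcast_to(warm_start.W1, (B,) + warm_start.W1.shape).copy()
    b1 = np.broadcast_to(warm_start.b1, (B,) + warm_start.b1.shape).copy()
    W2 = np.broadcast_to(warm_start.W2, (B,) + warm_start.W2.shape).copy()
    b2 = np.broadcast_to(warm_start.b2, (B,) + warm_start.b2.shape).copy()
    params = [W1, b1, W2, b2]
    deltas = [np.full_like(q, config.delta0) for q in params]
    prev_grad = [np.zeros_like(q) for q in params]
    best = [q.copy() for q in params]
    best_loss = np.full(B, np.inf)
    eps = 1e-12
    wR = weights[:, :, None] * R[None, :, :]  # B x n x K
    N = np.maximum(wR.sum(axis=(1, 2)), 1.0)

    for epoch in range(epochs):
        Z = expit(np.einsum("up,bph->buh", X, W1) + b1[:, None, :])
        Hhat = expit(np.einsum("buh,bhk->buk", Z, W2) + b2[:, None, :])
        Hc = np.clip(Hhat, eps, 1 - eps)
        ce = -(wR * (D[None] * np.log(Hc) + (1 - D[None]) * np.log(1 - Hc))).sum(axis=(1, 2)) / N
        loss = ce + lam * ((W1 * W1).sum(axis=(1, 2)) + (W2 * W2).sum(axis=(1, 2)))
        if not np.isfinite(loss).all():
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        improved = loss < best_loss
        if improved.any():
            best_loss = np.where(improved, loss, best_loss)
            for q, bq in zip(params, best):
                mask = improved.reshape((B,) + (1,) * (q.ndim - 1))
                np.copyto(bq, np.where(mask, q, bq))

        G2 = wR * (Hhat - D[None]) / N[:, None, None]
        gW2 = np.einsum("buh,buk->bhk", Z, G2) + 2 * lam * W2
        gb2 = G2.sum(axis=1)
        GZ = np.einsum("buk,bhk->buh", G2, W2)
        G1 = GZ * Z * (1 - Z)
        gW1 = np.einsum("up,buh->bph", X, G1) + 2 * lam * W1
        gb1 = G1.sum(axis=1)

        for q, g, delta, gp in zip(params, (gW1, gb1, gW2, gb2), deltas, prev_grad):
            s = gp * g
            np.minimum(np.where(s > 0, delta * config.eta_plus, delta), config.delta_max, out=delta)
            np.maximum(np.where(s < 0, delta * config.eta_minus, delta), config.delta_min, out=delta)
            g_eff = np.where(s < 0, 0.0, g)
            q -= np.sign(g_eff) * delta
            gp[...] = g_eff
    return tuple(best)


def predict_batch(params, X: np.ndarray) -> np.ndarray:
    """Hazards (B x n x K) of batched parameters on shared rows."""
    W1, b1, W2, b2 = params
    Z = expit(np.einsum("up,bph->buh", X, W1) + b1[:, None, :])
    return expit(np.einsum("buh,bhk->buk", Z, W2) + b2[:, None, :])


# --------------------------------------------------------------------------
# Cross-validation
# --------------------------------------------------------------------------


def _fold_indices(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [perm[i::folds] for i in range(folds)]


def select_grid_point(results: list[dict]) -> dict:
    """Best (hidden, decay) by mean score; ties break toward the smaller
    hidden count, then the larger decay."""
    return max(results, key=lambda r: (r["mean_score"], -r["hidden"], r["decay"]))


def cross_validate(
    X: np.ndarray,
    followup_years: np.ndarray,
    death: np.ndarray,
    grid: TimeGrid,
    config: TrainConfig,
) -> dict:
    """Seeded k-fold scan over (hidden, decay); refits on all data.

    The validation metric is Harrell's C of predicted median survival
    against observed outcomes (or negative validation loss).  Ties break
    toward the smaller hidden count, then the larger decay.  A fold without
    events triggers one reseeded repartition before failing.
    """
    from .metrics import harrell_c

    t = np.asarray(followup_years, dtype=float)
    d = np.asarray(death, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 202)))
    folds = _fold_indices(len(t), config.folds, rng)
    if any(d[idx].sum() == 0 for idx in folds):
        folds = _fold_indices(len(t), config.folds, rng)
        if any(d[idx].sum() == 0 for idx in folds):
            raise ValueError("a cross-validation fold has zero events")

    results = []
    for H in config.hgrid:
        for lam in config.dgrid:
            cand = replace(config, hidden=H, decay=lam, hidden_grid=None, decay_grid=None)
            scores = []
            for f, val_idx in enumerate(folds):
                train_mask = np.ones(len(t), dtype=bool)
                train_mask[val_idx] = False
                targets = make_targets(t[train_mask], d[train_mask], grid)
                net = train_network(
                    X[train_mask], targets, cand, seed=config.seed + 1000 * f
                )
                hz = net.predict(X[val_idx])
                if config.selection_metric == "loss":
                    vt = make_targets(t[val_idx], d[val_idx], grid)
                    R, D = vt.matrices()
                    Hc = np.clip(hz, 1e-12, 1 - 1e-12)
                    ce = -(R * (D * np.log(Hc) + (1 - D) * np.log(1 - Hc))).sum() / R.sum()
                    scores.append(-ce)
                else:
                    med = median_from_hazards(hz, grid)
                    scores.append(harrell_c(med, t[val_idx], d[val_idx]).c)
            results.append({"hidden": H, "decay": lam, "fold_scores": scores,
                            "mean_score": float(np.mean(scores))})
    best = select_grid_point(results)
    final_cfg = replace(
        config, hidden=best["hidden"], decay=best["decay"], hidden_grid=None, decay_grid=None
    )
    final = train_network(X, make_targets(t, d, grid), final_cfg, seed=config.seed)
    return {
        "hidden": best["hidden"],
        "decay": best["decay"],
        "results": results,
        "model": final,
    }


# --------------------------------------------------------------------------
# Ensemble
# --------------------------------------------------------------------------


@dataclass
class EnsembleModel:
    """Committee of hazard networks, one per imputed cohort.

    Each member carries its own design statistics (fit on its imputed
    cohort); all members share the time grid and column inventory.  The
    ensemble hazard is the arithmetic mean of member hazards, which keeps
    hazards in (0, 1) and is invariant to member order.
    """

    members: list[HazardNetwork]
    designs: list[DesignMatrix]
    grid: TimeGrid
    columns: tuple[ColumnSpec, ...]

    @property
    def M(self) -> int:
        return len(self.members)

    def member_design_matrices(self, cohort: Cohort) -> list[np.ndarray]:
        return [dm.transform(cohort) for dm in self.designs]

    def hazards(self, cohort: Cohort) -> np.ndarray:
        """Ensemble per-interval hazards for every record, n x K."""
        out = None
        for net, dm in zip(self.members, self.designs):
            h = net.predict(dm.transform(cohort))
            out = h if out is None else out + h
        return out / self.M

    def hazards_from_matrices(self, mats: Sequence[np.ndarray]) -> np.ndarray:
        out = None
        for net, Xm in zip(self.members, mats):
            h = net.predict(Xm)
            out = h if out is None else out + h
        return out / self.M

    def predict_median(self, cohort: Cohort) -> np.ndarray:
        return median_from_hazards(self.hazards(cohort), self.grid)


def train_ensemble(
    imputation_set: ImputationSet,
    config: TrainConfig,
    columns: Sequence[ColumnSpec] = MODEL_DESIGN,
    K: int = 25,
    grid: TimeGrid | None = None,
) -> EnsembleModel:
    """One committee member per imputed cohort; member seed = base + index.

    The time grid is built once from the first imputation's follow-up
    (follow-up is never imputed, so it is identical across members).
    """
    cohorts = list(imputation_set)
    first = cohorts[0]
    t = first.df["followup_years"].to_numpy(float)
    d = first.df["death"].to_numpy(float)
    if grid is None:
        grid = build_time_grid(t, K)
    targets = make_targets(t, d, grid)
    members, designs = [], []
    for m, cohort in enumerate(cohorts):
        dm = build_design(cohort, columns)
        try:
            net = train_network(dm.values, targets, config, seed=config.seed + m)
        except TrainingError as err:
            raise TrainingError(f"member {m}: {err}") from err
        members.append(net)
        designs.append(dm)
    return EnsembleModel(members=members, designs=designs, grid=grid, columns=tuple(columns))


# --------------------------------------------------------------------------
# Survival curves
# --------------------------------------------------------------------------


@dataclass
class SurvivalCurve:
    """Per-interval hazards and the implied survival step points."""

    hazards: np.ndarray  # K conditional hazards in (0, 1)
    grid: TimeGrid

    @property
    def survival(self) -> np.ndarray:
        """S_0 = 1 followed by S_k at each boundary (length K + 1)."""
        return np.concatenate(([1.0], np.cumprod(1.0 - self.hazards)))


def predict_curve(model: EnsembleModel, record) -> SurvivalCurve:
    """Ensemble survival curve for one record (a one-row cohort slice).

    Raises if any model variable is missing for the record.
    """
    if isinstance(record, Cohort):
        cohort = record
    else:
        import pandas as pd

        cohort = Cohort(pd.DataFrame([record]), name="record")
    hz = ensemble_hazards(model, cohort)
    return SurvivalCurve(hazards=hz[0], grid=model.grid)


def ensemble_hazards(model: EnsembleModel, cohort: Cohort) -> np.ndarray:
    return model.hazards(cohort)


def _tail_rate(hazards: np.ndarray, grid: TimeGrid) -> float:
    """Continuous-time rate equivalent of the final interval's hazard."""
    hK = min(float(hazards[-1]), 1 - 1e-12)
    return -np.log1p(-hK) / grid.widths[-1]


def median_survival(curve: SurvivalCurve, horizon_cap: float | None = None) -> tuple[float, bool]:
    """First time S crosses 0.5, linearly interpolated within the crossing
    interval.  If the curve never reaches 0.5 on the grid, extrapolates
    beyond it at the final interval's constant equivalent rate and flags the
    value; a zero tail rate caps at ``horizon_cap`` (default twice the grid
    end).  Returns (median_years, extrapolated)."""
    S = curve.survival
    b = curve.grid.boundaries
    below = np.flatnonzero(S <= 0.5)
    if below.size:
        k = below[0]
        if S[k] == 0.5:
            return float(b[k]), False
        t = b[k - 1] + (b[k] - b[k - 1]) * (S[k - 1] - 0.5) / (S[k - 1] - S[k])
        return float(t), False
    rate = _tail_rate(curve.hazards, curve.grid)
    cap = horizon_cap if horizon_cap is not None else 2.0 * float(b[-1])
    if rate <= 0:
        return cap, True
    t = b[-1] + np.log(S[-1] / 0.5) / rate
    return float(min(t, cap)), True


def survival_at(curve: SurvivalCurve, t: float) -> tuple[float, bool]:
    """Survival probability at time t (piecewise-linear between boundary
    survival points, consistent with median interpolation); t beyond the
    grid extrapolates at the tail rate and is flagged.  Returns
    (probability, extrapolated)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    S = curve.survival
    b = curve.grid.boundaries
    if t <= b[-1]:
        return float(np.interp(t, b, S)), False
    rate = _tail_rate(curve.hazards, curve.grid)
    return float(S[-1] * np.exp(-rate * (t - b[-1]))), True


def median_from_hazards(hazards: np.ndarray, grid: TimeGrid,
                        horizon_cap: float | None = None) -> np.ndarray:
    """Vectorized median survival for an n x K hazard matrix."""
    hz = np.atleast_2d(hazards)
    S = np.concatenate([np.ones((hz.shape[0], 1)), np.cumprod(1 - hz, axis=1)], axis=1)
    b = grid.boundaries
    cap = horizon_cap if horizon_cap is not None else 2.0 * float(b[-1])
    n, K1 = S.shape
    crossed = S <= 0.5
    any_cross = crossed.any(axis=1)
    k = np.where(any_cross, crossed.argmax(axis=1), K1 - 1)
    out = np.empty(n)
    # interior crossings
    idx = np.flatnonzero(any_cross)
    if idx.size:
        kk = k[idx]
        s_hi = S[idx, kk - 1]
        s_lo = S[idx, kk]
        frac = np.where(s_hi > s_lo, (s_hi - 0.5) / np.maximum(s_hi - s_lo, 1e-300), 0.0)
        out[idx] = b[kk - 1] + (b[kk] - b[kk - 1]) * frac
    # tail extrapolation
    idx = np.flatnonzero(~any_cross)
    if idx.size:
        hK = np.minimum(hz[idx, -1], 1 - 1e-12)
        rate = -np.log1p(-hK) / (b[-1] - b[-2])
        with np.errstate(divide="ignore"):
            t = b[-1] + np.log(S[idx, -1] / 0.5) / rate
        out[idx] = np.where(rate > 0, np.minimum(t, cap), cap)
    return out


def survival_probability(hazards: np.ndarray, grid: TimeGrid, t: float) -> np.ndarray:
    """Vectorized survival probability at time t for an n x K hazard matrix
    (piecewise-linear between boundary survival points; tail-rate
    extrapolation beyond the grid)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    hz = np.atleast_2d(hazards)
    S = np.concatenate([np.ones((hz.shape[0], 1)), np.cumprod(1 - hz, axis=1)], axis=1)
    b = grid.boundaries
    if t <= b[-1]:
        k = int(np.searchsorted(b, t, side="left"))
        if b[k] == t:
            return S[:, k]
        frac = (t - b[k - 1]) / (b[k] - b[k - 1])
        return S[:, k - 1] + (S[:, k] - S[:, k - 1]) * frac
    hK = np.minimum(hz[:, -1], 1 - 1e-12)
    rate = -np.log1p(-hK) / (b[-1] - b[-2])
    return S[:, -1] * np.exp(-rate * (t - b[-1]))


# --------------------------------------------------------------------------
# Serialization (versioned JSON, bit-exact reload)
# --------------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_model(model: EnsembleModel, path: str | Path) -> None:
    payload = {
        "format": "ihtsa-ensemble",
        "version": _FORMAT_VERSION,
        "grid": model.grid.boundaries.tolist(),
        "columns": [c.name for c in model.columns],
        "designs": [dm.to_dict() for dm in model.designs],
        "members": [
            {
                "W1": net.W1.tolist(),
                "b1": net.b1.tolist(),
                "W2": net.W2.tolist(),
                "b2": net.b2.tolist(),
                "decay": net.decay,
                "seed": net.seed,
                "final_loss": float(net.final_loss),
            }
            for net in model.members
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> EnsembleModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "ihtsa-ensemble" or payload.get("version") != _FORMAT_VERSION:
        raise ValueError(f"{path}: not a recognized model file")
    designs = [DesignMatrix.from_dict(d) for d in payload["designs"]]
    members = [
        HazardNetwork(
            W1=np.asarray(m["W1"], dtype=float),
            b1=np.asarray(m["b1"], dtype=float),
            W2=np.asarray(m["W2"], dtype=float),
            b2=np.asarray(m["b2"], dtype=float),
            decay=float(m["decay"]),
            seed=int(m["seed"]),
            final_loss=float(m["final_loss"]),
        )
        for m in payload["members"]
    ]
    grid = TimeGrid(np.asarray(payload["grid"], dtype=float))
    return EnsembleModel(
        members=members, designs=designs, grid=grid,
        columns=designs[0].columns if designs else (),
    )
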