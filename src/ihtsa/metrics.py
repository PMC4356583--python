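"""Discrimination and calibration metrics for survival predictions.

Harrell's concordance (with pair counts and an asymptotic CI), a paired
Somers'-D comparison of two concordance indices (jackknife covariance),
AUROC with the DeLong structural-component variance and the DeLong paired
test, the Hosmer-Lemeshow goodness-of-fit chi-square over risk deciles,
logistic recalibration (intercept/slope) of one-year mortality, and
Kaplan-Meier / log-rank wrappers.

Conventions: concordance scores are oriented so that a HIGHER score means
LONGER predicted survival; AUROC scores are oriented so that a higher score
means a MORE LIKELY positive (death) label.  Pairs with tied observed times
are not comparable; tied scores count one half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "ConcordanceResult",
    "harrell_c",
    "compare_c",
    "RocResult",
    "auroc",
    "delong_test",
    "one_year_labels",
    "hosmer_lemeshow",
    "HosmerLemeshowResult",
    "Recalibration",
    "recalibrate_logistic",
    "KaplanMeierEstimate",
    "kaplan_meier",
    "log_rank",
]


# --------------------------------------------------------------------------
# Harrell's C
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ConcordanceResult:
    c: float
    comparable_pairs: int
    concordant: int
    discordant: int
    tied: int
    ci_level: float
    ci_lower: float
    ci_upper: float


def _pair_counts(scores, times, events, chunk: int = 512):
    """Ordered-pair tallies and per-subject marginals.

    A pair is comparable iff the member with the strictly shorter observed
    time is an event; it is concordant when the longer-surviving member has
    the strictly higher score.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=float)
    n = len(s)
    conc = disc = tied = 0
    conc_i = np.zeros(n)
    disc_i = np.zeros(n)
    tied_i = np.zeros(n)
    pairs_i = np.zeros(n)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        comp = (t[lo:hi, None] < t[None, :]) & (d[lo:hi, None] == 1)
        diff = s[None, :] - s[lo:hi, None]
        c_blk = comp & (diff > 0)
        d_blk = comp & (diff < 0)
        e_blk = comp & (diff == 0)
        conc += int(c_blk.sum())
        disc += int(d_blk.sum())
        tied += int(e_blk.sum())
        conc_i[lo:hi] += c_blk.sum(axis=1)
        conc_i += c_blk.sum(axis=0)
        disc_i[lo:hi] += d_blk.sum(axis=1)
        disc_i += d_blk.sum(axis=0)
        tied_i[lo:hi] += e_blk.sum(axis=1)
        tied_i += e_blk.sum(axis=0)
        pairs_i[lo:hi] += comp.sum(axis=1)
        pairs_i += comp.sum(axis=0)
    return conc, disc, tied, conc_i, disc_i, tied_i, pairs_i


def harrell_c(scores, times, events, ci_level: float = 0.95) -> ConcordanceResult:
    """Harrell's concordance index for right-censored outcomes.

    ``scores``: higher predicts longer survival.  The CI uses the simple
    Noether-type asymptotic variance c(1-c)/pairs.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=float)
    if not (len(s) == len(t) == len(d)):
        raise ValueError("scores, times and events must have equal length")
    if d.sum() == 0:
        raise ValueError("concordance requires at least one event")
    conc, disc, tied, *_ = _pair_counts(s, t, d)
    pairs = conc + disc + tied
    if pairs == 0:
        raise ValueError("no comparable pairs")
    c = (conc + 0.5 * tied) / pairs
    se = np.sqrt(max(c * (1 - c), 0.0) / pairs)
    z = stats.norm.ppf(0.5 + ci_level / 2)
    return ConcordanceResult(
        c=float(c),
        comparable_pairs=int(pairs),
        concordant=int(conc),
        discordant=int(disc),
        tied=int(tied),
        ci_level=ci_level,
        ci_lower=float(max(c - z * se, 0.0)),
        ci_upper=float(min(c + z * se, 1.0)),
    )


def compare_c(scores_a, scores_b, times, events) -> float:
    """Two-sided p-value comparing two concordance indices on one cohort.

    Works on the Somers'-D scale (D = 2C - 1): the difference D_a - D_b is
    assessed with a leave-one-subject-out jackknife variance of the paired
    estimates.  Identical score vectors return p = 1.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=float)
    if np.array_equal(sa, sb):
        return 1.0
    n = len(t)

    def loo_d(scores):
        conc, disc, tied, ci, di, ei, pi = _pair_counts(scores, t, d)
        pairs = conc + disc + tied
        num = conc - disc  # D = (conc - disc) / pairs on comparable pairs
        num_i = num - (ci - di)
        pairs_i = pairs - pi
        with np.errstate(invalid="ignore", divide="ignore"):
            d_loo = np.where(pairs_i > 0, num_i / pairs_i, 0.0)
        return num / pairs if pairs else 0.0, d_loo

    Da, da_loo = loo_d(sa)
    Db, db_loo = loo_d(sb)
    theta = da_loo - db_loo
    var = (n - 1) / n * np.sum((theta - theta.mean()) ** 2)
    if var <= 0:
        return 1.0
    z = (Da - Db) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


# --------------------------------------------------------------------------
# AUROC and DeLong
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RocResult:
    auc: float
    variance: float
    n_pos: int
    n_neg: int
    v10: np.ndarray  # structural components (positives)
    v01: np.ndarray  # structural components (negatives)


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def auroc(scores, labels) -> RocResult:
    """Mann-Whitney AUROC with tie correction and DeLong variance.

    ``scores``: higher means more likely positive.  Both classes must be
    present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("auroc requires both classes present")
    rank_all = _midrank(np.concatenate([pos, neg]))
    rank_pos = _midrank(pos)
    rank_neg = _midrank(neg)
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    return RocResult(auc=float(auc), variance=float(var), n_pos=m, n_neg=n, v10=v10, v01=v01)


def delong_test(roc_a: RocResult, roc_b: RocResult) -> float:
    """DeLong two-sided test for two correlated AUROCs on the same records.

    The structural components of both curves must come from the same
    positives/negatives in the same order.  Identical components (equal
    scores) give p = 1.
    """
    if roc_a.n_pos != roc_b.n_pos or roc_a.n_neg != roc_b.n_neg:
        raise ValueError("delong_test requires paired curves on the same records")
    if np.array_equal(roc_a.v10, roc_b.v10) and np.array_equal(roc_a.v01, roc_b.v01):
        return 1.0
    m, n = roc_a.n_pos, roc_a.n_neg
    cov10 = np.cov(roc_a.v10, roc_b.v10, ddof=1)[0, 1] if m > 1 else 0.0
    cov01 = np.cov(roc_a.v01, roc_b.v01, ddof=1)[0, 1] if n > 1 else 0.0
    var = roc_a.variance + roc_b.variance - 2 * (cov10 / m + cov01 / n)
    if var <= 0:
        return 1.0
    z = (roc_a.auc - roc_b.auc) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def one_year_labels(times, events, horizon: float = 1.0):
    """One-year death labels: death within the horizon is 1, survival to
    the horizon is 0, censoring before the horizon without death is
    excluded.  Returns (labels, include_mask, n_excluded)."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=float)
    dead = (d == 1) & (t <= horizon)
    alive = t >= horizon
    include = dead | alive
    labels = dead.astype(float)
    return labels[include], include, int((~include).sum())


# --------------------------------------------------------------------------
# Calibration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class HosmerLemeshowResult:
    chi2: float
    dof: int
    p: float
    groups: int
    observed: np.ndarray
    expected: np.ndarray
    group_sizes: np.ndarray


def hosmer_lemeshow(pred, outcomes, g: int = 10) -> HosmerLemeshowResult:
    """Hosmer-Lemeshow goodness-of-fit over g equal-count risk groups.

    chi2 = sum (O - E)^2 / (E (1 - E/n_g)) with dof = g - 2; records with
    tied predictions stay in the lower group.  Groups whose expected count
    is zero are merged into their neighbor with a warning (dof adjusted).
    """
    p = np.asarray(pred, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    n = len(p)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("predictions must lie in [0, 1]")
    if n < 5 * g:
        raise ValueError(f"hosmer_lemeshow requires n >= 5g (n={n}, g={g})")
    order = np.argsort(p, kind="stable")
    group = np.floor(np.arange(n) * g / n).astype(int)
    # ties to the lower group: equal predictions share the first group seen
    sorted_p = p[order]
    for i in range(1, n):
        if sorted_p[i] == sorted_p[i - 1]:
            group[i] = group[i - 1]
    obs = np.bincount(group, weights=y[order], minlength=g)
    exp = np.bincount(group, weights=sorted_p, minlength=g)
    sizes = np.bincount(group, minlength=g).astype(float)
    keep = sizes > 0
    obs, exp, sizes = obs[keep], exp[keep], sizes[keep]
    # merge zero-expectation groups into the neighbor above
    while (exp == 0).any() and len(exp) > 1:
        i = int(np.flatnonzero(exp == 0)[0])
        j = i + 1 if i + 1 < len(exp) else i - 1
        warnings.warn("hosmer_lemeshow: merged a zero-expectation group", stacklevel=2)
        obs[j] += obs[i]
        exp[j] += exp[i]
        sizes[j] += sizes[i]
        obs = np.delete(obs, i)
        exp = np.delete(exp, i)
        sizes = np.delete(sizes, i)
    g_eff = len(exp)
    dof = g_eff - 2
    if dof < 1:
        raise ValueError("hosmer_lemeshow: fewer than 3 usable groups, test undefined")
    denom = exp * (1 - exp / sizes)
    denom = np.where(denom <= 0, np.nan, denom)
    chi2 = float(np.nansum((obs - exp) ** 2 / denom))
    return HosmerLemeshowResult(
        chi2=chi2,
        dof=dof,
        p=float(stats.chi2.sf(chi2, dof)),
        groups=g_eff,
        observed=obs,
        expected=exp,
        group_sizes=sizes,
    )


@dataclass(frozen=True)
class Recalibration:
    intercept: float
    slope: float
    separation: bool


def recalibrate_logistic(pred, outcomes) -> Recalibration:
    """Logistic recalibration of event probabilities.

    Fits outcome ~ logit(pred); perfect calibration gives intercept 0 and
    slope 1.  A constant predictor is degenerate and raises; complete
    separation falls back to a weakly penalized fit and is flagged.
    """
    import statsmodels.api as sm

    p = np.clip(np.asarray(pred, dtype=float), 1e-10, 1 - 1e-10)
    y = np.asarray(outcomes, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("recalibration requires both outcome classes")
    x = np.log(p / (1 - p))
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: constant predictions, slope undefined")
    Xd = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, Xd, family=sm.families.Binomial()).fit()
        params = fit.params
        separation = not np.all(np.isfinite(fit.bse)) or np.abs(params).max() > 50
    except Exception:
        separation = True
        params = None
    if separation:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, Xd, family=sm.families.Binomial()).fit_regularized(
                alpha=1e-4, L1_wt=0.0
            )
        params = fit.params
    return Recalibration(intercept=float(params[0]), slope=float(params[1]), separation=bool(separation))


# --------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class KaplanMeierEstimate:
    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0


def kaplan_meier(times, events, ci_level: float = 0.95) -> KaplanMeierEstimate:
    """Product-limit estimate with Greenwood confidence band."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=float)
    if (t < 0).any():
        raise ValueError("negative times")
    kmf = KaplanMeierFitter(alpha=1 - ci_level)
    kmf.fit(t, event_observed=d)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_
    return KaplanMeierEstimate(
        times=sf.index.to_numpy(float),
        survival=sf.iloc[:, 0].to_numpy(float),
        ci_lower=ci.iloc[:, 0].to_numpy(float),
        ci_upper=ci.iloc[:, 1].to_numpy(float),
    )


def log_rank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank statistic (1 dof) and p-value."""
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    da = np.asarray(events_a, dtype=float)
    db = np.asarray(events_b, dtype=float)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be nonempty")
    if da.sum() + db.sum() == 0:
        raise ValueError("log-rank requires at least one event")
    res = _ll_logrank(ta, tb, event_observed_A=da, event_observed_B=db)
    return float(res.test_statistic), float(res.p_value)
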