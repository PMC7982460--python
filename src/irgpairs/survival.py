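"""Survival machinery for the gene-pair risk model.

Covers the prognostic arm of the pipeline: univariate Cox screening of pair
indicators, lasso-Cox selection with repeated cross-validation, the linear
risk score, KM-weighted time-dependent ROC with an optimal (Youden) cutoff,
Kaplan–Meier / log-rank group comparison, multivariate Cox adjustment, and
maximally selected log-rank cutpoints for single genes.

The univariate screen uses an in-house Newton solver for the Efron partial
likelihood of a single binary covariate — the screen runs over hundreds of
pairs and a specialised solver keeps it fast; it is cross-checked against
lifelines and against direct numerical maximisation of the same likelihood
in the test suite.  Multivariate fits, KM curves and log-rank tests are
delegated to lifelines; the penalised path to scikit-survival's coxnet.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .pairs import PAIR_SEP, PairIndicatorMatrix, pair_indicators

__all__ = [
    "RiskModel",
    "TimeRocResult",
    "load_published_model",
    "univariate_cox_screen",
    "lasso_cox_select",
    "risk_score",
    "score_expression",
    "time_roc",
    "assign_risk_groups",
    "km_logrank",
    "multivariate_cox",
    "maxstat_cutpoint",
]


# ---------------------------------------------------------------------------
# risk model container


@dataclass
class RiskModel:
    """Ordered gene pairs with lasso-Cox coefficients and a dichotomization cutoff.

    ``pairs`` stores (irg1, irg2, coefficient) in the model's own orientation:
    the indicator multiplying each coefficient is 1 when irg1 > irg2 within a
    sample.  ``cutoff`` dichotomizes the risk score: strictly greater -> high risk.
    """

    pairs: list[tuple[str, str, float]]
    cutoff: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for a, b, c in self.pairs:
            if (a, b) in seen:
                raise ValueError(f"duplicate pair ({a}, {b}) in model")
            if not np.isfinite(c):
                raise ValueError(f"non-finite coefficient for pair ({a}, {b})")
            seen.add((a, b))
        if self.cutoff is not None and not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")

    @property
    def genes(self) -> list[str]:
        """Distinct genes appearing in the model, sorted."""
        return sorted({g for a, b, _ in self.pairs for g in (a, b)})

    @property
    def pair_names(self) -> list[str]:
        return [f"{a}{PAIR_SEP}{b}" for a, b, _ in self.pairs]

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([c for _, _, c in self.pairs])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pairs": [[a, b, c] for a, b, c in self.pairs],
            "cutoff": self.cutoff,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModel":
        with open(path) as fh:
            payload = json.load(fh)
        pairs = [(a, b, float(c)) for a, b, c in payload["pairs"]]
        return cls(pairs, payload.get("cutoff"), payload.get("provenance", ""))


def load_published_model() -> RiskModel:
    """The packaged published 16-pair colon-adenocarcinoma risk model."""
    ref = resources.files("irgpairs.data") / "published_prsm.json"
    with resources.as_file(ref) as path:
        return RiskModel.from_json(path)


# ---------------------------------------------------------------------------
# Efron partial likelihood, single covariate Newton solver


def _order_survival(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0 or event.sum() == 0:
        raise ValueError("no events in survival data")
    order = np.argsort(time, kind="mergesort")
    return time[order], event[order], order


def _tie_structure(time: np.ndarray, event: np.ndarray):
    """Group boundaries of tied event times on time-sorted data.

    Returns (starts of tied groups, death counts per group, indices of deaths
    ordered by group, reduceat boundaries into that death index array).
    """
    n = len(time)
    starts = np.flatnonzero(np.concatenate([[True], time[1:] != time[:-1]]))
    group_of = np.cumsum(np.concatenate([[0], (time[1:] != time[:-1]).astype(int)]))
    death_idx = np.flatnonzero(event == 1)
    d_per_group = np.bincount(group_of[death_idx], minlength=len(starts))
    death_bounds = np.concatenate([[0], np.cumsum(d_per_group)])[:-1]
    # reduceat rows for zero-death groups are garbage but always masked by
    # the d_per_group > r selections; clip so indices stay in range
    death_bounds = np.minimum(death_bounds, max(len(death_idx) - 1, 0))
    return starts, d_per_group, death_idx, death_bounds


def efron_loglik(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Efron-corrected Cox partial log-likelihood of linear predictor ``eta``."""
    return float(
        efron_loglik_many(np.asarray(eta, float)[:, None], time, event)[0]
    )


def efron_loglik_many(
    etas: np.ndarray, time: np.ndarray, event: np.ndarray
) -> np.ndarray:
    """Efron partial log-likelihood for each column-stacked linear predictor.

    ``etas`` is (n_samples, K); returns K log-likelihoods.  Vectorised so the
    cross-validation loop can evaluate a whole penalty path at once.
    """
    time, event, order = _order_survival(time, event)
    etas = np.asarray(etas, dtype=float)[order]
    w = np.exp(etas)  # (n, K)
    starts, d_per_group, death_idx, death_bounds = _tie_structure(time, event)
    suffix = np.cumsum(w[::-1], axis=0)[::-1]
    s_r = suffix[starts]  # (G, K)
    ll = etas[death_idx].sum(axis=0)
    if death_idx.size:
        sd = np.add.reduceat(w[death_idx], death_bounds, axis=0)  # (G, K)
    else:
        sd = np.zeros_like(s_r)
    max_d = int(d_per_group.max()) if len(d_per_group) else 0
    for r in range(max_d):
        sel = d_per_group > r
        frac = (r / d_per_group[sel])[:, None]
        ll -= np.log(s_r[sel] - frac * sd[sel]).sum(axis=0)
    return ll


def _cox_binary_newton(
    x: np.ndarray, time: np.ndarray, event: np.ndarray, tol: float = 1e-8
) -> tuple[float, float]:
    """Newton fit of a single-covariate Cox model (Efron ties).

    Returns (coefficient, standard error).  Raises on non-convergence or a
    degenerate (constant) covariate.
    """
    time, event, order = _order_survival(time, event)
    x = np.asarray(x, dtype=float)[order]
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")

    # group boundaries of tied times
    starts = [0]
    for i in range(1, len(time)):
        if time[i] != time[i - 1]:
            starts.append(i)
    starts.append(len(time))

    beta = 0.0
    for _ in range(60):
        w = np.exp(beta * x)
        wx = w * x
        wxx = wx * x
        s0 = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
        s1 = np.concatenate([np.cumsum(wx[::-1])[::-1], [0.0]])
        s2 = np.concatenate([np.cumsum(wxx[::-1])[::-1], [0.0]])
        grad = 0.0
        hess = 0.0
        for gi in range(len(starts) - 1):
            i, j = starts[gi], starts[gi + 1]
            deaths = np.arange(i, j)[event[i:j] == 1]
            d = len(deaths)
            if d == 0:
                continue
            sd0 = w[deaths].sum()
            sd1 = wx[deaths].sum()
            sd2 = wxx[deaths].sum()
            grad += x[deaths].sum()
            for r in range(d):
                f = r / d
                phi0 = s0[i] - f * sd0
                phi1 = s1[i] - f * sd1
                phi2 = s2[i] - f * sd2
                grad -= phi1 / phi0
                hess += phi2 / phi0 - (phi1 / phi0) ** 2
        if hess <= 0:
            raise ValueError("degenerate information (monotone likelihood)")
        step = grad / hess
        step = float(np.clip(step, -2.0, 2.0))
        beta += step
        if abs(grad) < tol:
            break
    else:
        raise ValueError("Newton iterations did not converge")
    return beta, float(1.0 / np.sqrt(hess))


def _cox_binary_newton_many(
    X: np.ndarray, time: np.ndarray, event: np.ndarray, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched Newton fits of single binary-covariate Cox models (Efron ties).

    ``X`` is (n_pairs, n_samples) of 0/1 indicators.  Returns (coef, se,
    valid); invalid rows had degenerate information or failed to converge.
    Exploits x^2 = x for binary covariates, so only two weighted suffix sums
    are needed per iteration.
    """
    time, event, order = _order_survival(time, event)
    X = np.asarray(X, dtype=float)[:, order]
    m, n = X.shape
    starts, d_per_group, death_idx, death_bounds = _tie_structure(time, event)
    max_d = int(d_per_group.max())
    x_death_sum = X[:, death_idx].sum(axis=1)

    beta = np.zeros(m)
    valid = np.ptp(X, axis=1) > 0
    converged = np.zeros(m, dtype=bool)
    hess = np.ones(m)
    for _ in range(60):
        w = np.exp(beta[:, None] * X)
        wx = w * X
        s0 = np.cumsum(w[:, ::-1], axis=1)[:, ::-1][:, starts]  # (m, G)
        s1 = np.cumsum(wx[:, ::-1], axis=1)[:, ::-1][:, starts]
        if death_idx.size:
            sd0 = np.add.reduceat(w[:, death_idx], death_bounds, axis=1)
            sd1 = np.add.reduceat(wx[:, death_idx], death_bounds, axis=1)
        else:
            sd0 = np.zeros_like(s0)
            sd1 = np.zeros_like(s1)
        grad = x_death_sum.copy()
        hess = np.zeros(m)
        for r in range(max_d):
            sel = d_per_group > r
            frac = r / d_per_group[sel]
            phi0 = s0[:, sel] - frac * sd0[:, sel]
            phi1 = s1[:, sel] - frac * sd1[:, sel]
            ratio = phi1 / phi0
            grad -= ratio.sum(axis=1)
            hess += (ratio * (1.0 - ratio)).sum(axis=1)  # phi2 = phi1 for binary x
        valid &= hess > 0
        step = np.zeros(m)
        np.divide(grad, hess, out=step, where=valid)
        step = np.clip(step, -2.0, 2.0)
        active = valid & ~converged
        beta[active] += step[active]
        converged |= np.abs(grad) < tol
        if not (valid & ~converged).any():
            break
    valid &= converged
    se = np.full(m, np.nan)
    se[valid] = 1.0 / np.sqrt(hess[valid])
    return beta, se, valid


def univariate_cox_screen(
    pim: PairIndicatorMatrix | pd.DataFrame,
    surv: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-pair univariate Cox fits; retain pairs with Wald p < alpha.

    ``surv`` needs columns ``time`` and ``event`` indexed by sample.  Pairs
    constant across the aligned samples are skipped with a warning (they
    should have been removed by the imbalance filter).
    """
    ind = pim.indicators if isinstance(pim, PairIndicatorMatrix) else pim
    samples = [s for s in ind.columns if s in surv.index]
    if len(samples) < ind.shape[1]:
        missing = set(ind.columns) - set(samples)
        raise KeyError(f"survival table missing samples: {sorted(missing)[:5]}")
    time = surv.loc[samples, "time"].to_numpy(float)
    event = surv.loc[samples, "event"].to_numpy(int)
    if event.sum() == 0:
        raise ValueError("no events in survival data")

    x_all = ind[samples].to_numpy(float)
    names = list(ind.index)
    coefs = np.empty(len(names))
    ses = np.empty(len(names))
    valid = np.empty(len(names), dtype=bool)
    chunk = 4000  # bounds the (pairs x samples) work arrays
    for lo in range(0, len(names), chunk):
        hi = min(lo + chunk, len(names))
        c, s, v = _cox_binary_newton_many(x_all[lo:hi], time, event)
        coefs[lo:hi], ses[lo:hi], valid[lo:hi] = c, s, v
    n_const = int((np.ptp(x_all, axis=1) == 0).sum())
    if n_const:
        warnings.warn(f"{n_const} constant pair(s) after alignment; skipped")
    n_degen = int((~valid).sum()) - n_const
    if n_degen > 0:
        warnings.warn(f"{n_degen} pair(s) with degenerate Cox fits; skipped")
    z = np.divide(coefs, ses, out=np.zeros_like(coefs), where=valid)
    p = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "coefficient": coefs,
            "hazard_ratio": np.exp(coefs),
            "se": ses,
            "p": p,
        },
        index=pd.Index(names, name="pair"),
    )[valid]
    return table[table["p"] < alpha].sort_values("p")


# ---------------------------------------------------------------------------
# lasso-Cox with repeated cross-validation


def lasso_cox_select(
    pim: PairIndicatorMatrix | pd.DataFrame,
    surv: pd.DataFrame,
    n_repeats: int = 1000,
    n_folds: int = 10,
    seed: int = 0,
    rule: str = "min",
    n_alphas: int = 30,
    alpha_min_ratio: float = 0.05,
    tol: float = 1e-6,
) -> RiskModel:
    """L1-penalised Cox selection with repeated cross-validated penalty choice.

    The penalty path comes from a coxnet fit on the full data; for each of
    ``n_repeats`` random fold assignments the cross-validated partial-
    likelihood deviance of every penalty is accumulated, and the penalty
    minimising the mean deviance (``rule='min'``; ``'1se'`` for the
    parsimonious variant) is refit on all samples.  Pairs with nonzero
    coefficients form the returned model (cutoff unset).
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    ind = pim.indicators if isinstance(pim, PairIndicatorMatrix) else pim
    samples = list(ind.columns)
    time = surv.loc[samples, "time"].to_numpy(float)
    event = surv.loc[samples, "event"].to_numpy(bool)
    if event.sum() < n_folds:
        raise ValueError(f"need at least {n_folds} events for {n_folds}-fold CV")
    X = ind.T.to_numpy(float)
    y = Surv.from_arrays(event=event, time=time)

    path = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, alpha_min_ratio=alpha_min_ratio, n_alphas=n_alphas, tol=tol
    )
    path.fit(X, y)
    alphas = path.alphas_

    rng = np.random.default_rng(seed)
    n = len(samples)
    dev = np.zeros((n_repeats * n_folds, len(alphas)))
    row = 0
    for _ in range(n_repeats):
        fold = rng.permutation(n) % n_folds
        for f in range(n_folds):
            train = fold != f
            m = CoxnetSurvivalAnalysis(
                l1_ratio=1.0, alphas=alphas, fit_baseline_model=False, tol=tol
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m.fit(X[train], y[train])
            etas = X @ m.coef_  # (n, n_alphas)
            # held-out deviance contribution = full-data minus train loglik
            ll_all = efron_loglik_many(etas, time, event.astype(int))
            ll_train = efron_loglik_many(
                etas[train], time[train], event[train].astype(int)
            )
            dev[row] = -2.0 * (ll_all - ll_train)
            row += 1
    mean_dev = dev.mean(axis=0)
    if rule == "min":
        best = int(np.argmin(mean_dev))
    elif rule == "1se":
        se = dev.std(axis=0, ddof=1) / np.sqrt(dev.shape[0])
        best_min = int(np.argmin(mean_dev))
        limit = mean_dev[best_min] + se[best_min]
        # alphas are decreasing: the largest penalty within one SE
        best = int(np.flatnonzero(mean_dev <= limit)[0])
    else:
        raise ValueError("rule must be 'min' or '1se'")

    final = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, alphas=[alphas[best]], fit_baseline_model=False, tol=tol
    )
    final.fit(X, y)
    coefs = final.coef_[:, 0]
    nz = np.flatnonzero(coefs)
    if nz.size == 0:
        warnings.warn("all coefficients zero at the chosen penalty; empty model")
    pairs = []
    for i in nz:
        a, b = ind.index[i].split(PAIR_SEP, 1)
        pairs.append((a, b, float(coefs[i])))
    return RiskModel(pairs, cutoff=None, provenance=f"lasso-Cox (rule={rule}, alpha={alphas[best]:.5g})")


# ---------------------------------------------------------------------------
# risk score


def risk_score(
    model: RiskModel, pim: PairIndicatorMatrix | pd.DataFrame
) -> pd.Series:
    """Linear risk score RS = sum_k coefficient_k * indicator_k per sample."""
    ind = pim.indicators if isinstance(pim, PairIndicatorMatrix) else pim
    missing = [p for p in model.pair_names if p not in ind.index]
    if missing:
        raise KeyError(f"model pairs absent from indicators: {missing}")
    block = ind.loc[model.pair_names].to_numpy(float)
    rs = model.coefficients @ block
    return pd.Series(rs, index=ind.columns, name="risk_score")


def score_expression(model: RiskModel, expr: pd.DataFrame) -> pd.Series:
    """Risk score straight from an expression matrix.

    Builds the indicators in the model's own (irg1, irg2) orientation, so the
    published coefficients keep their meaning on any cohort that measures the
    model genes.
    """
    ind = pair_indicators(expr, [(a, b) for a, b, _ in model.pairs])
    return risk_score(model, ind)


def assign_risk_groups(scores: pd.Series, cutoff: float) -> pd.Series:
    """Dichotomize: score strictly greater than cutoff -> 'high', else 'low'."""
    scores = pd.Series(scores)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    return pd.Series(
        np.where(scores.to_numpy() > cutoff, "high", "low"),
        index=scores.index,
        name="risk_group",
    )


# ---------------------------------------------------------------------------
# time-dependent ROC (cumulative cases / dynamic controls, KM-weighted)


@dataclass
class TimeRocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    best_cutoff: float
    horizon: float


def _km_survival_at(time: np.ndarray, event: np.ndarray, t: float) -> float:
    """Product-limit estimate S(t)."""
    order = np.argsort(time, kind="mergesort")
    time, event = time[order], event[order]
    s = 1.0
    n_at_risk = len(time)
    i = 0
    while i < len(time) and time[i] <= t:
        j = i
        d = 0
        while j < len(time) and time[j] == time[i]:
            d += event[j]
            j += 1
        if d:
            s *= 1.0 - d / n_at_risk
        n_at_risk -= j - i
        i = j
    return s


def time_roc(scores: pd.Series, surv: pd.DataFrame, horizon: float) -> TimeRocResult:
    """Time-dependent ROC at ``horizon`` (cumulative/dynamic, KM-weighted).

    Cases are samples with an observed event by the horizon; controls are
    samples still under observation beyond it.  Sensitivity and specificity
    at each observed score threshold use the Kaplan–Meier estimator within
    the thresholded stratum (the survivalROC "KM" construction), which
    reduces to the empirical ROC when there is no censoring.  The optimal
    cutoff maximises Youden's J; ties resolve to the lower threshold.
    """
    scores = pd.Series(scores)
    time = surv.loc[scores.index, "time"].to_numpy(float)
    event = surv.loc[scores.index, "event"].to_numpy(int)
    x = scores.to_numpy(float)

    n_cases = int(((time <= horizon) & (event == 1)).sum())
    n_controls = int((time > horizon).sum())
    if n_cases == 0:
        raise ValueError(f"no cases (events by t={horizon})")
    if n_controls == 0:
        raise ValueError(f"no controls (followed beyond t={horizon})")

    s_all = _km_survival_at(time, event, horizon)
    if s_all in (0.0, 1.0):
        raise ValueError("degenerate overall survival at the horizon")

    thresholds = np.unique(x)
    tpr = [1.0]
    fpr = [1.0]
    for c in thresholds:
        above = x > c
        p_above = above.mean()
        if above.any():
            s_c = _km_survival_at(time[above], event[above], horizon)
        else:
            s_c, p_above = 1.0, 0.0
        sens = (1.0 - s_c) * p_above / (1.0 - s_all)
        spec1 = s_c * p_above / s_all  # 1 - specificity
        tpr.append(float(np.clip(sens, 0.0, 1.0)))
        fpr.append(float(np.clip(spec1, 0.0, 1.0)))
    tpr = np.array(tpr)
    fpr = np.array(fpr)
    grid = np.concatenate([[-np.inf], thresholds])

    # Youden on the raw points; ties -> lowest threshold among finite ones
    j_stat = tpr - fpr
    finite = np.isfinite(grid)
    j_fin = j_stat[finite]
    c_fin = grid[finite]
    best_j = j_fin.max()
    best_cutoff = float(c_fin[np.isclose(j_fin, best_j)].min())

    # walk the curve from the highest threshold down (fpr increasing) and
    # monotonize both coordinates: without censoring this is exactly the
    # empirical ROC staircase, with censoring it irons out the slight
    # non-monotonicity the KM weighting can introduce
    f_path = np.maximum.accumulate(fpr[::-1])
    t_path = np.maximum.accumulate(tpr[::-1])
    f_sorted = np.concatenate([[0.0], f_path, [1.0]])
    t_sorted = np.concatenate([[0.0], t_path, [1.0]])
    auc = float(np.trapezoid(t_sorted, f_sorted))
    return TimeRocResult(f_sorted, t_sorted, grid, auc, best_cutoff, horizon)


# ---------------------------------------------------------------------------
# KM curves, log-rank, multivariate Cox, maxstat


def km_logrank(
    surv: pd.DataFrame, groups: pd.Series | np.ndarray
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan–Meier curves per group plus the log-rank test across groups."""
    groups = pd.Series(np.asarray(groups), index=surv.index)
    curves: dict[str, pd.DataFrame] = {}
    for g, sub in surv.groupby(groups):
        if len(sub) == 0:
            raise ValueError(f"group {g!r} has zero samples")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(g))
        curves[str(g)] = kmf.survival_function_
    if len(curves) < 2:
        raise ValueError("need at least 2 groups for a log-rank test")
    res = multivariate_logrank_test(surv["time"], groups, surv["event"])
    return curves, float(res.test_statistic), float(res.p_value)


def logrank_chi2(time: np.ndarray, event: np.ndarray, mask: np.ndarray) -> float:
    """Two-group log-rank chi-square by direct observed-vs-expected tabulation."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    mask = np.asarray(mask, bool)
    order = np.argsort(time, kind="mergesort")
    time, event, mask = time[order], event[order], mask[order]
    n = len(time)
    n1 = mask.sum()
    n_tot = n
    o_minus_e = 0.0
    var = 0.0
    i = 0
    while i < n:
        j = i
        d = d1 = 0
        while j < n and time[j] == time[i]:
            d += event[j]
            d1 += event[j] * mask[j]
            j += 1
        if d and n_tot > 1:
            e1 = d * n1 / n_tot
            v = d * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d) / (n_tot - 1)
            o_minus_e += d1 - e1
            var += v
        n1 -= mask[i:j].sum()
        n_tot -= j - i
        i = j
    if var == 0:
        return 0.0
    return float(o_minus_e**2 / var)


def multivariate_cox(
    surv: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Joint Cox fit (Efron ties) of the supplied covariates.

    Returns per covariate: coefficient, hazard ratio, 95% CI and Wald p.
    Non-numeric covariates must be encoded by the caller.
    """
    bad = [c for c in covariates.columns if not pd.api.types.is_numeric_dtype(covariates[c])]
    if bad:
        raise TypeError(f"non-numeric covariates need encoding first: {bad}")
    df = covariates.join(surv[["time", "event"]], how="inner")
    if df["event"].sum() < 10:
        warnings.warn("fewer than 10 events: multivariate fit will be unstable")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    summary = cph.summary
    return pd.DataFrame(
        {
            "coefficient": summary["coef"],
            "hazard_ratio": summary["exp(coef)"],
            "ci95_low": summary["exp(coef) lower 95%"],
            "ci95_high": summary["exp(coef) upper 95%"],
            "p": summary["p"],
        }
    )


def maxstat_cutpoint(
    values: pd.Series,
    surv: pd.DataFrame,
    quantile_window: tuple[float, float] = (0.1, 0.9),
) -> tuple[float, float]:
    """Maximally selected log-rank cutpoint of a continuous marker.

    Scans every observed value inside the quantile window as a candidate
    threshold (> cutpoint defines the upper group), computes the two-group
    log-rank chi-square at each, and returns the maximiser (ties -> lower
    cutpoint) together with the maximal statistic.
    """
    values = pd.Series(values)
    if len(values) < 10:
        raise ValueError("need at least 10 samples")
    time = surv.loc[values.index, "time"].to_numpy(float)
    event = surv.loc[values.index, "event"].to_numpy(int)
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    v = values.to_numpy(float)
    if np.ptp(v) == 0:
        raise ValueError("all marker values identical")
    lo, hi = np.quantile(v, quantile_window)
    candidates = np.unique(v[(v >= lo) & (v <= hi)])
    best_c, best_stat = None, -np.inf
    for c in candidates:
        mask = v > c
        if not mask.any() or mask.all():
            continue
        chi2 = logrank_chi2(time, event, mask)
        if chi2 > best_stat + 1e-12:
            best_c, best_stat = float(c), float(chi2)
    if best_c is None:
        raise ValueError("no admissible cutpoint in the quantile window")
    return best_c, best_stat
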