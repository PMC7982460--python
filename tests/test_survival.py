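"""Cox fits, lasso selection, risk scoring, time-dependent ROC, KM, maxstat."""

import json
import warnings

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test
from scipy.optimize import minimize_scalar
from sklearn.metrics import roc_auc_score

import irgpairs as ip
from irgpairs.pairs import PairIndicatorMatrix
from irgpairs.survival import (
    _cox_binary_newton,
    efron_loglik,
    logrank_chi2,
    maxstat_cutpoint,
    time_roc,
)


def _surv(times, events, index=None):
    idx = index if index is not None else [f"s{i}" for i in range(len(times))]
    return pd.DataFrame({"time": times, "event": events},
                        index=pd.Index(idx, name="sample_id"))


def _toy_cox_data(seed=5, n=80):
    rng = np.random.default_rng(seed)
    x = (rng.random(n) > 0.5).astype(float)
    t = rng.exponential(1.0 / (0.1 * np.exp(0.9 * x)))
    t = np.round(t, 6)  # tie-free with probability 1
    return x, t, np.ones(n, dtype=int)


# --- Cox solver -------------------------------------------------------------


def test_cox_coefficient_matches_generic_likelihood_optimizer():
    """Newton solution maximises the same partial likelihood found numerically."""
    x, t, e = _toy_cox_data()
    beta_newton, _ = _cox_binary_newton(x, t, e)
    res = minimize_scalar(
        lambda b: -efron_loglik(b * x, t, e), bounds=(-5, 5), method="bounded",
        options={"xatol": 1e-10},
    )
    assert beta_newton == pytest.approx(res.x, abs=1e-6)


def test_cox_matches_lifelines_with_ties():
    rng = np.random.default_rng(8)
    x = (rng.random(60) > 0.4).astype(float)
    t = rng.integers(1, 15, size=60).astype(float)  # heavy ties
    e = (rng.random(60) > 0.3).astype(int)
    beta, se = _cox_binary_newton(x, t, e)
    df = pd.DataFrame({"time": t, "event": e, "x": x})
    cph = CoxPHFitter().fit(df, "time", "event")
    assert beta == pytest.approx(cph.params_["x"], abs=1e-6)
    assert se == pytest.approx(cph.standard_errors_["x"], abs=1e-6)


def test_screen_retains_planted_pair_across_seeds():
    hits = 0
    for seed in range(20):
        spec = ip.CohortSpec(
            n_planted_pairs=1, planted_coefficients=(1.5,), seed=seed
        )
        c = ip.generate_cohort(spec)
        (ga, gb, _), = c.truth["planted_pairs"]
        first, second = sorted([ga, gb])
        pim = ip.build_pairs(c.expression, [ga, gb])
        table = ip.univariate_cox_screen(pim, c.clinical)
        name = f"{first}|{second}"
        if name in table.index:
            coef = table.loc[name, "coefficient"]
            # canonical order may flip the generator's orientation
            expected_sign = 1.0 if (first, second) == (ga, gb) else -1.0
            if np.sign(coef) == expected_sign:
                hits += 1
    assert hits >= 18


def test_screen_null_retention_near_alpha(cohort):
    rng = np.random.default_rng(33)
    n = cohort.clinical.shape[0]
    ind = pd.DataFrame(
        (rng.random((1000, n)) > 0.5).astype(np.int8),
        index=[f"n{i}|m{i}" for i in range(1000)],
        columns=cohort.clinical.index,
    )
    table = ip.univariate_cox_screen(ind, cohort.clinical, alpha=0.05)
    assert abs(len(table) / 1000 - 0.05) <= 0.02


def test_screen_error_paths():
    surv = _surv([1.0, 2.0], [0, 0])
    ind = pd.DataFrame([[0, 1]], index=["a|b"], columns=surv.index)
    with pytest.raises(ValueError, match="events"):
        ip.univariate_cox_screen(ind, surv)
    surv2 = _surv([1.0, 2.0], [1, 1])
    ind2 = pd.DataFrame([[1, 1]], index=["a|b"], columns=surv2.index)
    with pytest.warns(UserWarning, match="constant"):
        out = ip.univariate_cox_screen(ind2, surv2)
    assert out.empty


# --- lasso-Cox --------------------------------------------------------------


def test_lasso_selects_single_strong_pair(cohort):
    (ga, gb, _), = [p for p in cohort.truth["planted_pairs"][:1]]
    pim = ip.build_pairs(cohort.expression, [ga, gb])
    model = ip.lasso_cox_select(pim, cohort.clinical, n_repeats=5, n_folds=5, seed=0)
    assert len(model.pairs) == 1
    uni = ip.univariate_cox_screen(pim, cohort.clinical)
    assert np.sign(model.pairs[0][2]) == np.sign(uni.iloc[0]["coefficient"])


def test_lasso_duplicate_predictor_keeps_linear_predictor(cohort):
    (ga, gb, _), = [p for p in cohort.truth["planted_pairs"][:1]]
    pim = ip.build_pairs(cohort.expression, [ga, gb])
    single = ip.lasso_cox_select(pim, cohort.clinical, n_repeats=5, n_folds=5, seed=0)
    dup_ind = pd.concat([pim.indicators, pim.indicators.set_axis(["dupA|dupB"])])
    dup = ip.lasso_cox_select(dup_ind, cohort.clinical, n_repeats=5, n_folds=5, seed=0)
    eta_single = single.coefficients.sum() * pim.indicators.iloc[0]
    eta_dup = sum(c for _, _, c in dup.pairs) * pim.indicators.iloc[0]
    assert np.abs(eta_single - eta_dup).max() < 1e-3


# --- risk score and groups ---------------------------------------------------


def test_risk_score_linearity(published_model):
    model = published_model
    zeros = pd.DataFrame(0, index=model.pair_names, columns=["s1"])
    assert ip.risk_score(model, zeros)["s1"] == 0.0
    ones = pd.DataFrame(1, index=model.pair_names, columns=["s1"])
    total = ip.risk_score(model, ones)["s1"]
    assert total == pytest.approx(model.coefficients.sum())
    flipped = ones.copy()
    flipped.iloc[3, 0] = 0
    delta = total - ip.risk_score(model, flipped)["s1"]
    assert delta == pytest.approx(model.pairs[3][2])


def test_published_model_all_ones_score_matches_table_sum(published_model):
    """Independent oracle: sum the packaged JSON's coefficient column."""
    from importlib import resources

    raw = json.loads(
        (resources.files("irgpairs.data") / "published_prsm.json").read_text()
    )
    expected = sum(c for _, _, c in raw["pairs"])
    ones = pd.DataFrame(1, index=published_model.pair_names, columns=["s"])
    assert ip.risk_score(published_model, ones)["s"] == pytest.approx(expected)
    assert expected == pytest.approx(1.59)


def test_risk_score_missing_pair_errors(published_model):
    ind = pd.DataFrame(1, index=published_model.pair_names[:-1], columns=["s"])
    with pytest.raises(KeyError, match="CXCL13"):
        ip.risk_score(published_model, ind)


def test_risk_group_assignment_rules(published_model):
    cutoff = published_model.cutoff
    scores = pd.Series({"a": 1.2, "b": 0.5, "c": cutoff})
    groups = ip.assign_risk_groups(scores, cutoff)
    assert groups["a"] == "high" and groups["b"] == "low"
    assert groups["c"] == "low"  # strictly-greater convention
    assert (ip.assign_risk_groups(scores, 10.0) == "low").all()


# --- time-dependent ROC ------------------------------------------------------


def test_roc_uninformative_scores_give_half_auc():
    surv = _surv([1, 2, 3, 4, 5, 6.0], [1, 1, 1, 0, 0, 0])
    scores = pd.Series(1.0, index=surv.index)
    res = time_roc(scores, surv, horizon=3.5)
    assert res.auc == pytest.approx(0.5)


def test_roc_perfect_separator():
    surv = _surv([1, 2, 8, 9.0], [1, 1, 0, 0])
    scores = pd.Series([5.0, 6.0, 1.0, 2.0], index=surv.index)
    res = time_roc(scores, surv, horizon=5.0)
    assert res.auc == pytest.approx(1.0)
    assert 2.0 <= res.best_cutoff < 5.0


@pytest.mark.parametrize(
    "events, expected_auc",
    [({4, 5, 6}, 1.0), ({1, 4, 5}, None)],
)
def test_roc_equals_pairwise_concordance_when_uncensored(events, expected_auc):
    scores = pd.Series([1.0, 2, 3, 4, 5, 6], index=[f"s{i}" for i in range(6)])
    ev = np.array([1 if s in events else 0 for s in range(1, 7)])
    times = np.where(ev == 1, 2.0, 20.0)
    surv = _surv(times, np.ones(6, int), index=scores.index)
    res = time_roc(scores, surv, horizon=10.0)
    cases = scores[ev == 1]
    controls = scores[ev == 0]
    conc = np.mean([[c > d for d in controls] for c in cases])
    if expected_auc is not None:
        assert conc == pytest.approx(expected_auc)
    assert res.auc == pytest.approx(conc)


def test_roc_equals_empirical_roc_without_censoring(rng):
    n = 60
    scores = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
    risk = scores > 0.2
    times = np.where(rng.random(n) < 0.3 + 0.5 * risk, 2.0, 20.0)
    surv = _surv(times, np.ones(n, int), index=scores.index)
    res = time_roc(scores, surv, horizon=10.0)
    y = (times <= 10).astype(int)
    assert res.auc == pytest.approx(roc_auc_score(y, scores))


def test_roc_error_when_no_cases_or_controls():
    surv = _surv([1, 2, 3.0], [1, 1, 1])
    scores = pd.Series([1.0, 2, 3], index=surv.index)
    with pytest.raises(ValueError, match="controls"):
        time_roc(scores, surv, horizon=10.0)
    surv2 = _surv([11, 12, 13.0], [1, 1, 1])
    with pytest.raises(ValueError, match="cases"):
        time_roc(scores, surv2, horizon=10.0)


# --- KM / log-rank -----------------------------------------------------------


def test_km_identical_groups_null():
    surv = _surv([1, 2, 3, 4, 1, 2, 3, 4.0], [1, 1, 0, 1, 1, 1, 0, 1])
    groups = pd.Series(["a"] * 4 + ["b"] * 4, index=surv.index)
    _, chi2, p = ip.km_logrank(surv, groups)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_km_logrank_matches_hand_tabulation():
    # A: deaths at 1,2,3; B: deaths at 4,5,6 -> O_A=3, E_A=1.15, V=0.6775
    surv = _surv([1, 2, 3, 4, 5, 6.0], [1] * 6)
    groups = pd.Series(["A", "A", "A", "B", "B", "B"], index=surv.index)
    curves, chi2, p = ip.km_logrank(surv, groups)
    assert chi2 == pytest.approx((3 - 1.15) ** 2 / 0.6775, rel=1e-10)
    assert p < 0.05
    assert curves["A"].iloc[0, 0] == pytest.approx(1.0)  # S(0) = 1


def test_km_curves_are_monotone_step_functions(cohort):
    groups = pd.Series(
        np.where(np.arange(len(cohort.clinical)) % 2 == 0, "x", "y"),
        index=cohort.clinical.index,
    )
    curves, _, _ = ip.km_logrank(cohort.clinical, groups)
    for curve in curves.values():
        vals = curve.iloc[:, 0].to_numpy()
        assert (np.diff(vals) <= 1e-12).all()
        assert vals[-1] >= 0.0


def test_logrank_helper_matches_lifelines(rng):
    t = rng.exponential(10, 40)
    e = (rng.random(40) > 0.3).astype(int)
    mask = rng.random(40) > 0.5
    ours = logrank_chi2(t, e, mask)
    ref = logrank_test(t[mask], t[~mask], e[mask], e[~mask])
    assert ours == pytest.approx(ref.test_statistic, rel=1e-9)


# --- multivariate Cox --------------------------------------------------------


def test_multivariate_single_covariate_matches_univariate():
    x, t, e = _toy_cox_data(seed=9)
    surv = _surv(t, e)
    cov = pd.DataFrame({"x": x}, index=surv.index)
    table = ip.multivariate_cox(surv, cov)
    beta, se = _cox_binary_newton(x, t, e)
    # tolerance limited by lifelines' own convergence criterion
    assert table.loc["x", "coefficient"] == pytest.approx(beta, abs=1e-5)


def test_multivariate_noise_covariate_barely_moves_strong_signal():
    deltas = []
    for seed in range(10):
        c = ip.generate_cohort(ip.CohortSpec(seed=seed))
        rng = np.random.default_rng(seed + 100)
        eta = pd.Series(c.truth["linear_predictor"], index=c.clinical.index)
        cov1 = pd.DataFrame({"rs": eta})
        cov2 = cov1.assign(noise=rng.normal(size=len(eta)))
        t1 = ip.multivariate_cox(c.clinical, cov1)
        t2 = ip.multivariate_cox(c.clinical, cov2)
        deltas.append(abs(t1.loc["rs", "coefficient"] - t2.loc["rs", "coefficient"]))
    assert np.mean(deltas) < 0.05


def test_risk_score_stays_significant_after_group_adjustment():
    wins = 0
    for seed in range(20):
        c = ip.generate_cohort(ip.CohortSpec(seed=seed))
        eta = pd.Series(c.truth["linear_predictor"], index=c.clinical.index)
        cov = pd.DataFrame(
            {"rs": eta, "grp": (c.clinical.group == "right").astype(float)}
        )
        table = ip.multivariate_cox(c.clinical, cov)
        if table.loc["rs", "p"] < 0.05:
            wins += 1
    assert wins >= 18


def test_multivariate_rejects_non_numeric():
    surv = _surv([1, 2, 3, 4.0] * 5, [1, 0, 1, 1] * 5)
    cov = pd.DataFrame({"stage": ["I", "II"] * 10}, index=surv.index)
    with pytest.raises(TypeError, match="stage"):
        ip.multivariate_cox(surv, cov)


# --- maxstat ------------------------------------------------------------------


def test_maxstat_separating_bimodal_marker():
    rng = np.random.default_rng(2)
    low = rng.normal(0, 0.2, 20)
    high = rng.normal(5, 0.2, 20)
    values = pd.Series(np.r_[low, high], index=[f"s{i}" for i in range(40)])
    times = np.r_[rng.exponential(2, 20), rng.exponential(20, 20)]
    surv = _surv(times, np.ones(40, int), index=values.index)
    cut, stat = maxstat_cutpoint(values, surv)
    assert low.max() <= cut < high.min()
    assert stat > 10


def test_maxstat_matches_exhaustive_split_evaluation():
    rng = np.random.default_rng(4)
    values = pd.Series(rng.normal(size=12), index=[f"s{i}" for i in range(12)])
    times = rng.exponential(5, 12)
    surv = _surv(times, np.ones(12, int), index=values.index)
    cut, stat = maxstat_cutpoint(values, surv, quantile_window=(0.1, 0.9))
    lo, hi = np.quantile(values, (0.1, 0.9))
    best = (-np.inf, None)
    for c in sorted(values[(values >= lo) & (values <= hi)]):
        mask = values.to_numpy() > c
        if not mask.any() or mask.all():
            continue
        ref = logrank_test(
            times[mask], times[~mask],
            np.ones(mask.sum()), np.ones((~mask).sum()),
        ).test_statistic
        if ref > best[0] + 1e-12:
            best = (ref, c)
    assert stat == pytest.approx(best[0], rel=1e-9)
    assert cut == pytest.approx(best[1])


def test_maxstat_rejects_constant_marker():
    surv = _surv(np.arange(1.0, 13.0), np.ones(12, int))
    with pytest.raises(ValueError, match="identical"):
        maxstat_cutpoint(pd.Series(np.ones(12), index=surv.index), surv)


# --- model container ----------------------------------------------------------


def test_risk_model_json_roundtrip(tmp_path, published_model):
    path = tmp_path / "m.json"
    published_model.to_json(path)
    back = ip.RiskModel.from_json(path)
    assert back.pairs == published_model.pairs
    assert back.cutoff == published_model.cutoff


def test_risk_model_rejects_duplicates_and_nonfinite():
    with pytest.raises(ValueError, match="duplicate"):
        ip.RiskModel([("a", "b", 0.1), ("a", "b", 0.2)])
    with pytest.raises(ValueError, match="finite"):
        ip.RiskModel([("a", "b", float("nan"))])
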