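"""Cohort generator calibration and the statistical battery vs oracles."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

from coilpd import (
    CohortParams,
    cohort_frame,
    cutoff_performance,
    fisher_exact,
    generate_cohort,
    logistic_fit,
    mann_whitney_u,
    roc_analysis,
    spearman_rho,
)
from coilpd.cohort import RECANALIZED_DEFAULTS, STABLE_DEFAULTS, VariablePair
from coilpd.errors import DegenerateDataError, InputError, ParameterError
from oracles import auc_pair_fraction, concordance_u, fisher_p_enumeration, spearman_via_pearson_ranks


# -- generator --------------------------------------------------------------

def test_default_cohort_is_7_recanalized_of_50():
    for seed in (0, 1, 99):
        recs = generate_cohort(seed=seed)
        assert len(recs) == 50
        assert sum(r.group == "recanalized" for r in recs) == 7


def test_zero_sd_limit_collapses_to_group_means():
    def degen(gp):
        return dataclasses.replace(
            gp,
            pd=VariablePair(gp.pd.vm_mean, 0.0, gp.pd.rm_mean, 0.0, 0.5, "truncnorm"),
            pave=VariablePair(gp.pave.vm_mean, 0.0, gp.pave.rm_mean, 0.0, 0.5, "lognormal"),
            vin=VariablePair(gp.vin.vm_mean, 0.0, gp.vin.rm_mean, 0.0, 0.5, "lognormal"),
            max_size=(gp.max_size[0], 0.0),
            ver=(gp.ver[0], 0.0),
        )

    params = CohortParams(recanalized=degen(RECANALIZED_DEFAULTS), stable=degen(STABLE_DEFAULTS))
    f = cohort_frame(generate_cohort(params, seed=3))
    rec = f[f.group == "recanalized"]
    assert np.allclose(rec.pd_rm, 3.40) and np.allclose(rec.pd_vm, 3.60)
    assert np.allclose(rec.vin_rm, 0.54) and np.allclose(rec.max_size, 11.5)
    sta = f[f.group == "stable"]
    assert np.allclose(sta.pd_rm, 1.99) and np.allclose(sta.pave_vm, 4267.22)


def test_large_sample_means_match_configured_values():
    """Law-of-large-numbers check at n = 10^4 per group."""
    params = CohortParams(
        recanalized=dataclasses.replace(RECANALIZED_DEFAULTS, n=10_000),
        stable=dataclasses.replace(STABLE_DEFAULTS, n=10_000),
    )
    f = cohort_frame(generate_cohort(params, seed=5))
    for group, gp in (("recanalized", RECANALIZED_DEFAULTS), ("stable", STABLE_DEFAULTS)):
        sub = f[f.group == group]
        for col, (m, s) in (
            ("pd_rm", (gp.pd.rm_mean, gp.pd.rm_sd)),
            ("pd_vm", (gp.pd.vm_mean, gp.pd.vm_sd)),
            ("max_size", gp.max_size),
        ):
            se = s / np.sqrt(len(sub))
            # small positive bias from truncation at 0 is part of the model
            assert abs(sub[col].mean() - m) < 3 * se + 0.02 * m


def test_vm_rm_copula_hits_target_rank_correlation():
    params = CohortParams(stable=dataclasses.replace(STABLE_DEFAULTS, n=20_000))
    f = cohort_frame(generate_cohort(params, seed=2))
    sub = f[f.group == "stable"]
    rho = spearman_rho(sub.pd_vm, sub.pd_rm)["rho"]
    assert abs(rho - 0.70) < 0.03


def test_generator_deterministic_per_seed():
    a = cohort_frame(generate_cohort(seed=11))
    b = cohort_frame(generate_cohort(seed=11))
    pd.testing.assert_frame_equal(a, b)
    c = cohort_frame(generate_cohort(seed=12))
    assert not a.pd_rm.equals(c.pd_rm)


def test_generator_rejects_bad_parameters():
    with pytest.raises(ParameterError):
        CohortParams(
            recanalized=dataclasses.replace(RECANALIZED_DEFAULTS, n=0)
        ).validate()
    with pytest.raises(ParameterError):
        VariablePair(1.0, -0.1, 1.0, 0.1).validate()


def test_records_satisfy_pd_identity():
    f = cohort_frame(generate_cohort(seed=4))
    q = 0.5 * 1100.0 * f.vin_rm**2
    assert np.allclose(f.pmax_rm, f.pave_rm + f.pd_rm * q)


# -- Mann-Whitney -----------------------------------------------------------

def test_mann_whitney_u_matches_pair_counting_oracle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        x = rng.integers(0, 10, rng.integers(3, 9)).astype(float)
        y = rng.integers(0, 10, rng.integers(3, 9)).astype(float)
        if np.all(np.concatenate([x, y]) == x[0]):
            continue
        assert mann_whitney_u(x, y)["U"] == pytest.approx(concordance_u(x, y))


def test_mann_whitney_complete_separation_and_null():
    x = np.array([5.0, 6.0, 7.0])
    y = np.array([1.0, 2.0, 3.0, 4.0])
    r = mann_whitney_u(x, y)
    assert r["U"] == len(x) * len(y)
    assert r["p"] < 0.05 or len(x) * len(y) < 20  # tiny-n exact p may exceed
    same = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert same["p"] == 1.0
    with pytest.raises(DegenerateDataError):
        mann_whitney_u([2.0, 2.0], [2.0, 2.0])


# -- Fisher -----------------------------------------------------------------

@pytest.mark.parametrize(
    "table",
    [
        [[1, 0], [0, 1]],
        [[3, 3], [3, 3]],
        [[5, 1], [1, 6]],
        [[7, 0], [10, 33]],
        [[2, 9], [8, 1]],
    ],
)
def test_fisher_exact_matches_enumeration_oracle(table):
    assert fisher_exact(table) == pytest.approx(fisher_p_enumeration(table), rel=1e-9)


def test_fisher_exact_conventions():
    assert fisher_exact([[1, 0], [0, 1]]) == pytest.approx(1.0)
    assert fisher_exact([[4, 2], [4, 2]]) == pytest.approx(1.0)  # identical rows
    assert fisher_exact([[0, 0], [3, 5]]) == 1.0  # zero margin convention
    with pytest.raises(InputError):
        fisher_exact([[1.5, 2.0], [1.0, 1.0]])


# -- ROC --------------------------------------------------------------------

def test_auc_matches_pair_fraction_and_sklearn():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n = rng.integers(8, 30)
        scores = rng.integers(0, 8, n).astype(float)
        labels = rng.integers(0, 2, n).astype(bool)
        if labels.all() or not labels.any():
            continue
        r = roc_analysis(scores, labels)
        assert r.auc == pytest.approx(auc_pair_fraction(scores, labels), abs=1e-12)
        assert r.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_roc_degenerate_cases():
    r = roc_analysis([1.0, 2.0, 3.0, 10.0, 11.0], [False, False, False, True, True])
    assert r.auc == 1.0
    flat = roc_analysis([2.0] * 6, [True, False, True, False, False, True])
    assert flat.auc == pytest.approx(0.5)  # uninformative score, tie convention
    with pytest.raises(InputError):
        roc_analysis([1.0, 2.0], [True, True])


def test_roc_curve_is_monotone_in_threshold():
    rng = np.random.default_rng(4)
    scores = rng.normal(size=40)
    labels = rng.integers(0, 2, 40).astype(bool)
    r = roc_analysis(scores, labels)
    assert np.all(np.diff(r.sensitivity) <= 1e-12)  # ascending thresholds
    assert np.all(np.diff(r.specificity) >= -1e-12)


def test_cutoff_performance_published_examples():
    # a recanalized case scoring 3.43 lies above the 3.08 cutoff,
    # a stable case scoring 2.80 below it
    scores = np.array([3.43, 2.80])
    labels = np.array([True, False])
    perf = cutoff_performance(scores, labels, 3.08)
    assert perf["sensitivity"] == 1.0 and perf["specificity"] == 1.0
    low = cutoff_performance(np.array([1.0, 2.0, 0.5]), np.array([True, False, True]), 5.0)
    assert low["sensitivity"] == 0.0 and low["specificity"] == 1.0


# -- Spearman ---------------------------------------------------------------

def test_spearman_monotone_and_reverse():
    x = np.array([1.0, 2.5, 3.0, 7.0, 9.0])
    assert spearman_rho(x, np.exp(x))["rho"] == pytest.approx(1.0)
    assert spearman_rho(x, -(x**3))["rho"] == pytest.approx(-1.0)
    with pytest.raises(DegenerateDataError):
        spearman_rho(x, np.ones_like(x))


def test_spearman_with_ties_matches_pearson_on_ranks():
    rng = np.random.default_rng(5)
    for _ in range(10):
        x = rng.integers(0, 5, 12).astype(float)
        y = rng.integers(0, 5, 12).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            continue
        assert spearman_rho(x, y)["rho"] == pytest.approx(
            spearman_via_pearson_ranks(x, y), abs=1e-12
        )


# -- logistic regression ----------------------------------------------------

def test_logistic_null_covariate_or_near_one():
    rng = np.random.default_rng(6)
    n = 4000
    x = rng.normal(size=n)
    y = rng.integers(0, 2, n).astype(float)
    res = logistic_fit(pd.DataFrame({"x": x}), y, mode="univariate")["x"]
    lo, hi = res["CI95"]
    assert lo < 1.0 < hi


def test_logistic_recovers_known_coefficients_within_3se():
    rng = np.random.default_rng(7)
    n = 5000
    X = rng.normal(size=(n, 2))
    beta = np.array([0.5, -1.2])
    eta = -0.3 + X @ beta
    y = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    fit = logistic_fit(pd.DataFrame(X, columns=["a", "b"]), y, mode="multivariate")
    for name, b in zip(("a", "b"), beta):
        assert abs(fit[name]["beta"] - b) < 3 * fit[name]["se"]


def test_logistic_agrees_with_statsmodels():
    rng = np.random.default_rng(8)
    n = 800
    X = rng.normal(size=(n, 2))
    y = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-(0.4 * X[:, 0] - 0.8 * X[:, 1])))).astype(float)
    fit = logistic_fit(pd.DataFrame(X, columns=["a", "b"]), y, mode="multivariate")
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    assert fit["a"]["beta"] == pytest.approx(ref.params[1], rel=1e-5)
    assert fit["b"]["beta"] == pytest.approx(ref.params[2], rel=1e-5)
    assert fit["a"]["se"] == pytest.approx(ref.bse[1], rel=1e-4)


def test_multivariate_selection_excludes_pd_vm(caplog):
    f = cohort_frame(generate_cohort(seed=9))
    y = (f.group == "recanalized").to_numpy().astype(float)
    covs = f[["max_size", "ver", "pcom", "ruptured", "pd_vm", "pd_rm"]].astype(float)
    fit = logistic_fit(covs, y, mode="multivariate")
    inc = fit["_meta"]["included"]
    assert "pd_rm" in inc and "pd_vm" not in inc


def test_quasi_separation_triggers_ridge_fallback(caplog):
    import logging

    x = np.concatenate([np.zeros(20), np.ones(20)])
    y = x.copy()  # perfect separation
    with caplog.at_level(logging.WARNING, logger="coilpd.cohort"):
        fit = logistic_fit(pd.DataFrame({"x": x}), y, mode="univariate")["x"]
    assert np.isfinite(fit["OR"]) and fit["OR"] > 1.0
    assert any("quasi-separation" in r.message for r in caplog.records)
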