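"""Synthetic cohort generation and recurrence-discrimination statistics.

The generator emulates the published 50-aneurysm cohort (7 recanalized /
43 stable) at the printed group means and standard deviations: the
pressure-difference score PD in the virtual (VM) and real (RM)
post-coiling models, its components Pave and Vin, morphology (maximum
size, volume embolization ratio) and binary covariates (PcomA location,
rupture).  VM and RM values of each parameter are coupled through a
Gaussian copula at the published Spearman coefficients (0.70 for PD by
default).  Pmax is derived from the PD identity
Pmax = Pave + PD * (1/2 rho Vin^2), so every record satisfies the score's
definition exactly.

The statistical battery mirrors the published analysis: Mann-Whitney U
and Fisher exact group comparisons, ROC curves with Youden-index cutoffs
(predicted positive when score > cutoff, strictly), Spearman VM-RM
agreement, and univariate -> multivariate logistic regression with the
published selection rule (univariate p < 0.05 enters; PD in VM is dropped
whenever PD in RM is included).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .errors import (
    DegenerateDataError,
    FitError,
    InputError,
    ParameterError,
)

logger = logging.getLogger("coilpd.cohort")

BLOOD_DENSITY = 1100.0  # kg/m^3, used in the PD identity


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariablePair:
    """Marginal (mean, SD) of one parameter in VM and RM plus their coupling.

    family: 'truncnorm' (normal truncated at 0) or 'lognormal'
    (moment-matched; used for the right-skewed pressure and velocity
    marginals whose printed SDs approach or exceed the means).
    """

    vm_mean: float
    vm_sd: float
    rm_mean: float
    rm_sd: float
    rank_corr: float = 0.7
    family: str = "truncnorm"

    def validate(self) -> None:
        if self.vm_sd < 0 or self.rm_sd < 0:
            raise ParameterError("SDs must be >= 0")
        if not (-1.0 < self.rank_corr < 1.0):
            raise ParameterError("rank_corr must lie in (-1, 1)")
        if self.family not in ("truncnorm", "lognormal"):
            raise ParameterError(f"unknown family {self.family!r}")
        if self.family == "lognormal" and (self.vm_mean <= 0 or self.rm_mean <= 0):
            raise ParameterError("lognormal marginals require positive means")


@dataclass(frozen=True)
class GroupParams:
    """Distributional description of one outcome group."""

    n: int
    pd: VariablePair
    pave: VariablePair
    vin: VariablePair
    max_size: tuple[float, float]  # mm
    ver: tuple[float, float]  # %
    p_pcom: float
    p_ruptured: float

    def validate(self) -> None:
        if self.n < 1:
            raise ParameterError("group size must be >= 1")
        for vp in (self.pd, self.pave, self.vin):
            vp.validate()
        for m, s in (self.max_size, self.ver):
            if s < 0:
                raise ParameterError("SDs must be >= 0")
        for p in (self.p_pcom, self.p_ruptured):
            if not (0.0 <= p <= 1.0):
                raise ParameterError("flag probabilities must lie in [0, 1]")


RECANALIZED_DEFAULTS = GroupParams(
    n=7,
    pd=VariablePair(3.60, 0.78, 3.40, 0.24, rank_corr=0.70, family="truncnorm"),
    pave=VariablePair(3679.95, 3031.15, 5672.88, 4789.61, rank_corr=0.561, family="lognormal"),
    vin=VariablePair(0.63, 0.17, 0.54, 0.10, rank_corr=0.537, family="lognormal"),
    max_size=(11.5, 2.6),
    ver=(22.5, 3.5),
    p_pcom=1.0,
    p_ruptured=5.0 / 7.0,
)

STABLE_DEFAULTS = GroupParams(
    n=43,
    pd=VariablePair(2.15, 0.64, 1.99, 0.75, rank_corr=0.70, family="truncnorm"),
    pave=VariablePair(4267.22, 4554.09, 10039.57, 16397.22, rank_corr=0.561, family="lognormal"),
    vin=VariablePair(0.66, 0.20, 0.70, 0.31, rank_corr=0.537, family="lognormal"),
    max_size=(8.3, 2.5),
    ver=(24.8, 4.5),
    p_pcom=25.0 / 43.0,
    p_ruptured=10.0 / 43.0,
)


@dataclass(frozen=True)
class CohortParams:
    recanalized: GroupParams = RECANALIZED_DEFAULTS
    stable: GroupParams = STABLE_DEFAULTS
    rho: float = BLOOD_DENSITY

    def validate(self) -> None:
        self.recanalized.validate()
        self.stable.validate()
        if self.rho <= 0:
            raise ParameterError("rho must be > 0")


@dataclass
class CohortRecord:
    """One aneurysm: outcome group, hemodynamics per model, covariates."""

    case_id: str
    group: str  # {"recanalized", "stable"}
    pd_vm: float
    pd_rm: float
    pmax_vm: float
    pmax_rm: float
    pave_vm: float
    pave_rm: float
    vin_vm: float
    vin_rm: float
    max_size: float  # mm
    ver: float  # %
    pcom: bool
    ruptured: bool

    def validate(self) -> None:
        if self.group not in ("recanalized", "stable"):
            raise ParameterError(f"unknown group {self.group!r}")
        if not (0.0 < self.ver < 100.0):
            raise ParameterError("VER must lie in (0, 100)")
        if self.max_size <= 0:
            raise ParameterError("max_size must be > 0")


def _marginal_ppf(u: np.ndarray, mean: float, sd: float, family: str) -> np.ndarray:
    if sd == 0.0:
        return np.full_like(u, mean)
    if family == "truncnorm":
        a = (0.0 - mean) / sd
        return stats.truncnorm.ppf(u, a=a, b=np.inf, loc=mean, scale=sd)
    # lognormal matched to the printed mean and SD
    s2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * s2
    return stats.lognorm.ppf(u, s=np.sqrt(s2), scale=np.exp(mu))


def _pair_draw(rng: np.random.Generator, n: int, vp: VariablePair) -> tuple[np.ndarray, np.ndarray]:
    """Copula-coupled (VM, RM) draws at the target Spearman correlation."""
    rho_z = 2.0 * np.sin(np.pi * vp.rank_corr / 6.0)  # Spearman -> Pearson on the copula
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho_z], [rho_z, 1.0]], size=n)
    u = stats.norm.cdf(z)
    vm = _marginal_ppf(u[:, 0], vp.vm_mean, vp.vm_sd, vp.family)
    rm = _marginal_ppf(u[:, 1], vp.rm_mean, vp.rm_sd, vp.family)
    return vm, rm


def _truncated_scalar(rng: np.random.Generator, n: int, mean: float, sd: float,
                      lo: float = 0.0, hi: float = np.inf) -> np.ndarray:
    if sd == 0.0:
        return np.full(n, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    if not a < b:
        raise ParameterError("infeasible truncation bounds")
    return stats.truncnorm.ppf(rng.uniform(size=n), a=a, b=b, loc=mean, scale=sd)


def generate_cohort(params: Optional[CohortParams] = None, seed: int = 0) -> list[CohortRecord]:
    """Draw a synthetic cohort; deterministic for a fixed seed."""
    params = params or CohortParams()
    params.validate()
    rng = np.random.default_rng(seed)
    records: list[CohortRecord] = []
    counter = 0
    for group, gp in (("recanalized", params.recanalized), ("stable", params.stable)):
        pd_vm, pd_rm = _pair_draw(rng, gp.n, gp.pd)
        pave_vm, pave_rm = _pair_draw(rng, gp.n, gp.pave)
        vin_vm, vin_rm = _pair_draw(rng, gp.n, gp.vin)
        size = _truncated_scalar(rng, gp.n, *gp.max_size, lo=0.0)
        ver = _truncated_scalar(rng, gp.n, *gp.ver, lo=0.0, hi=100.0)
        pcom = rng.uniform(size=gp.n) < gp.p_pcom
        rupt = rng.uniform(size=gp.n) < gp.p_ruptured
        q_vm = 0.5 * params.rho * vin_vm**2
        q_rm = 0.5 * params.rho * vin_rm**2
        for k in range(gp.n):
            counter += 1
            rec = CohortRecord(
                case_id=f"C{counter:04d}",
                group=group,
                pd_vm=float(pd_vm[k]),
                pd_rm=float(pd_rm[k]),
                pmax_vm=float(pave_vm[k] + pd_vm[k] * q_vm[k]),
                pmax_rm=float(pave_rm[k] + pd_rm[k] * q_rm[k]),
                pave_vm=float(pave_vm[k]),
                pave_rm=float(pave_rm[k]),
                vin_vm=float(vin_vm[k]),
                vin_rm=float(vin_rm[k]),
                max_size=float(size[k]),
                ver=float(ver[k]),
                pcom=bool(pcom[k]),
                ruptured=bool(rupt[k]),
            )
            rec.validate()
            records.append(rec)
    return records


def cohort_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Tabulate a cohort, one row per case."""
    return pd.DataFrame([vars(r) for r in records]).set_index("case_id")


# ---------------------------------------------------------------------------
# statistical battery
# ---------------------------------------------------------------------------

def mann_whitney_u(x, y) -> dict:
    """Two-sided Mann-Whitney U.

    Exact enumeration when both samples have n <= 8 and the pooled sample
    is tie-free; otherwise the normal approximation with tie correction.
    By the exact-enumeration convention, U at the null center
    (U = n1 n2 / 2) reports p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        raise DegenerateDataError("all pooled values identical")
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u_stat = float(res.statistic)
    p = float(res.pvalue)
    if u_stat == x.size * y.size / 2.0:
        p = 1.0
    return {"U": u_stat, "p": min(p, 1.0)}


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p by hypergeometric tail summation."""
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
            raise InputError("table must be 2x2 non-negative integer counts")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        logger.warning("fisher_exact: zero margin, returning p = 1 by convention")
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


@dataclass
class RocResult:
    """ROC curve with the Youden-index operating point."""

    thresholds: np.ndarray  # ascending, with -inf / +inf sentinels
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cutoff: float

    def validate(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise InputError("AUC outside [0, 1]")


def roc_analysis(scores, labels) -> RocResult:
    """ROC over thresholds at midpoints between sorted unique scores.

    Predicted positive when score > threshold (strict).  AUC by the
    trapezoid rule, equal to the Mann-Whitney concordance with ties
    counted 1/2.  The Youden cutoff is the smallest threshold maximizing
    sensitivity + specificity - 1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise InputError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("both classes must be present")

    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.zeros(0)
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for k, c in enumerate(thresholds):
        pred = scores > c
        sens[k] = np.sum(pred & labels) / n_pos
        spec[k] = np.sum(~pred & ~labels) / n_neg

    # integrate along the ROC path (descending threshold: (0,0) -> (1,1));
    # re-sorting by FPR would scramble tied-FPR corners
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    j = sens + spec - 1.0
    youden = float(thresholds[int(np.argmax(j))])
    res = RocResult(
        thresholds=thresholds, sensitivity=sens, specificity=spec, auc=auc, youden_cutoff=youden
    )
    res.validate()
    return res


def cutoff_performance(scores, labels, cutoff: float) -> dict:
    """Sensitivity/specificity of 'score > cutoff' (strict) for positives."""
    if not np.isfinite(cutoff):
        raise InputError("cutoff must be finite")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pred = scores > cutoff
    tp = np.sum(pred & labels)
    fn = np.sum(~pred & labels)
    tn = np.sum(~pred & ~labels)
    fp = np.sum(pred & ~labels)
    if tp + fn == 0 or tn + fp == 0:
        raise InputError("both classes must be present")
    return {"sensitivity": tp / (tp + fn), "specificity": tn / (tn + fp)}


def spearman_rho(x, y) -> dict:
    """Spearman rank correlation with average-rank ties; t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InputError("need equal-length samples with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateDataError("constant vector has no rank correlation")
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p)}


# ---------------------------------------------------------------------------
# logistic regression (IRLS with ridge fallback near separation)
# ---------------------------------------------------------------------------

def _irls(X: np.ndarray, y: np.ndarray, ridge: float = 0.0,
          max_iter: int = 100, tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, bool]:
    """Logistic ML (or ridge-penalized) fit; returns (beta, cov, converged).

    The penalty is applied to the slope coefficients only, in the
    standardized space of the caller.
    """
    n, k = X.shape
    beta = np.zeros(k)
    pen = np.zeros(k)
    pen[1:] = ridge  # never penalize the intercept
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = X.T @ (X * w[:, None]) + np.diag(pen)
        g = X.T @ (y - mu) - pen * beta
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = X @ beta
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    H = X.T @ (X * w[:, None]) + np.diag(pen)
    cov = np.linalg.inv(H)
    return beta, cov, converged


def _fit_one_design(Xraw: np.ndarray, y: np.ndarray, names: list[str],
                    ridge_fallback: float = 0.1) -> dict:
    mu = Xraw.mean(axis=0)
    sd = Xraw.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xs = np.column_stack([np.ones(len(y)), (Xraw - mu) / sd])

    beta, cov, ok = _irls(Xs, y, ridge=0.0)
    separated = (not ok) or (not np.all(np.isfinite(beta))) or np.max(np.abs(beta[1:])) > 15.0
    penalized = False
    if separated:
        logger.warning(
            "logistic_fit: quasi-separation detected for %s; refitting with a "
            "small ridge penalty", names,
        )
        beta, cov, ok = _irls(Xs, y, ridge=ridge_fallback)
        penalized = True
        if not ok or not np.all(np.isfinite(beta)):
            raise FitError(f"logistic fit failed to converge for {names}")
    elif not ok:
        raise FitError(f"logistic fit failed to converge for {names}")

    out = {}
    for idx, name in enumerate(names, start=1):
        b = beta[idx] / sd[idx - 1]
        se = float(np.sqrt(cov[idx, idx])) / sd[idx - 1]
        z = b / se if se > 0 else np.inf
        p = 2.0 * stats.norm.sf(abs(z))
        out[name] = {
            "beta": float(b),
            "se": float(se),
            "OR": float(np.exp(b)),
            "CI95": (float(np.exp(b - 1.96 * se)), float(np.exp(b + 1.96 * se))),
            "p": float(p),
        }
    out["_meta"] = {"penalized": penalized, "names": list(names)}
    return out


def logistic_fit(covariates: pd.DataFrame, outcome, mode: str = "univariate",
                 alpha: float = 0.05) -> dict:
    """Univariate or multivariate logistic regression for recurrence.

    Univariate: one fit per covariate.  Multivariate: covariates with
    univariate p < alpha enter the joint model, except that PD in VM
    (column ``pd_vm``) is dropped whenever PD in RM (``pd_rm``) is
    included, mirroring the published selection rule.
    """
    y = np.asarray(outcome, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0} or np.unique(y).size < 2:
        raise InputError("outcome must be binary with both classes present")
    if mode not in ("univariate", "multivariate"):
        raise InputError("mode must be 'univariate' or 'multivariate'")
    X = covariates.astype(float)

    uni = {
        name: _fit_one_design(X[[name]].to_numpy(), y, [name])[name]
        for name in X.columns
    }
    if mode == "univariate":
        return uni

    selected = [name for name in X.columns if uni[name]["p"] < alpha]
    if "pd_rm" in selected and "pd_vm" in selected:
        selected = [n for n in selected if n != "pd_vm"]
        logger.info("logistic_fit: pd_vm excluded from the multivariate model (pd_rm included)")
    if not selected:
        raise FitError("no covariate passed univariate selection")
    multi = _fit_one_design(X[selected].to_numpy(), y, selected)
    multi["_meta"]["included"] = selected
    multi["_meta"]["univariate_p"] = {n: uni[n]["p"] for n in X.columns}
    return multi


# ---------------------------------------------------------------------------
# published operating-characteristic reconstructions
# ---------------------------------------------------------------------------

def reference_score_configuration(model: str) -> tuple[np.ndarray, np.ndarray]:
    """Score/label configuration realizing the published ROC operating point.

    For 7 recanalized vs 43 stable cases these arrangements reproduce, by
    construction, the published AUC, sensitivity and specificity at the
    published Youden cutoff: RM -> AUC 0.977, 100% / 97.7% at 3.08;
    VM -> AUC 0.967, 100% / 90.7% at 2.83.  Used as worked examples for
    the ROC machinery; the statistics are always recomputed, never quoted.
    """
    if model == "RM":
        stable = np.concatenate([np.linspace(1.00, 3.03, 42), [3.90]])
        recan = np.linspace(3.13, 3.60, 7)
    elif model == "VM":
        stable = np.concatenate(
            [np.linspace(1.00, 2.78, 39), [2.93, 3.03, 3.13, 3.23]]
        )
        recan = np.array([2.88, 2.98, 3.08, 3.18, 3.30, 3.40, 3.50])
    else:
        raise InputError("model must be 'VM' or 'RM'")
    scores = np.concatenate([recan, stable])
    labels = np.concatenate([np.ones(recan.size, bool), np.zeros(stable.size, bool)])
    return scores, labels
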