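"""Logistic risk models over genotype + plasma marker, and paired AUC tests.

Predictors available for PET-positivity risk models: the epsilon-4 carrier
indicator, the e2-only indicator (epsilon-2 allele without epsilon-4,
mirroring the cascade's categorical exclusion), and the reciprocal plasma
Abeta1-42 score (higher = more disease-like).  Fitting is plain maximum
likelihood by iteratively reweighted least squares with step-halving (no
regularization); complete separation is detected and flagged rather than
silently returned.

AUCs of two risk scores measured on the *same* subjects are correlated, so
they are compared with DeLong's paired nonparametric test built on
per-subject placement values; a seeded bootstrap comparator is included as
a sensitivity check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.special import expit

from .cohort_sim import Cohort

__all__ = [
    "PREDICTORS",
    "LogisticModel",
    "DelongResult",
    "fit_logistic",
    "risk_scores",
    "delong_compare",
    "bootstrap_compare",
]

#: canonical predictor order in design matrices
PREDICTORS = ("e4", "e2", "inv_abeta42")


def _design_matrix(cohort: Cohort, predictors: Sequence[str]) -> Tuple[np.ndarray, list]:
    df = cohort.to_frame()
    cols = {"intercept": np.ones(len(df))}
    for name in PREDICTORS:
        if name not in predictors:
            continue
        if name == "e4":
            cols["e4"] = df["e4_carrier"].to_numpy(dtype=float)
        elif name == "e2":
            cols["e2"] = df["e2_only"].to_numpy(dtype=float)
        else:
            ab42 = df["abeta42"].to_numpy(dtype=float)
            if np.isnan(ab42).any() or (ab42 <= 0).any():
                raise ValueError("inv_abeta42 requires positive abeta42 for all subjects")
            cols["inv_abeta42"] = 1.0 / ab42
    names = list(cols)
    return np.column_stack(list(cols.values())), names


@dataclass(frozen=True)
class LogisticModel:
    """Maximum-likelihood logistic fit of PET status on screening predictors."""

    coefficients: Dict[str, float]
    converged: bool
    iterations: int
    log_likelihood: float
    separated: bool = False

    @property
    def coef_vector(self) -> np.ndarray:
        return np.array(list(self.coefficients.values()))


def _log_likelihood(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    # numerically stable: -log(1 + exp(-eta)) for y=1, -log(1 + exp(eta)) for y=0
    return float(-np.sum(np.logaddexp(0.0, np.where(y, -eta, eta))))


def fit_logistic(
    cohort: Cohort,
    predictors: Sequence[str] = ("e4", "e2", "inv_abeta42"),
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticModel:
    """Fit PET positivity ~ predictors by IRLS (Newton with step-halving).

    Converges when the largest absolute coefficient change drops below
    ``tol``.  Log-likelihood is non-decreasing across iterations (the Newton
    step is halved until it does not decrease it).  Complete or
    quasi-complete separation manifests as non-convergence with diverging
    coefficients and is flagged via ``separated``/``converged``.
    """
    unknown = set(predictors) - set(PREDICTORS)
    if unknown:
        raise ValueError(f"unknown predictors {sorted(unknown)}; valid: {PREDICTORS}")
    df = cohort.to_frame()
    y = df["pet_positive"].to_numpy(dtype=bool)
    if y.all() or not y.any():
        raise ValueError("outcome has a single class; logistic fit undefined")
    X, names = _design_matrix(cohort, predictors)
    for j, name in enumerate(names):
        if name != "intercept" and np.ptp(X[:, j]) == 0:
            raise ValueError(f"predictor {name!r} is constant in this cohort")

    beta = np.zeros(X.shape[1])
    ll = _log_likelihood(beta, X, y)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        p = expit(X @ beta)
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        hess = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # halve until the log-likelihood does not decrease
        t = 1.0
        while t > 1e-12:
            candidate = beta + t * step
            ll_new = _log_likelihood(candidate, X, y)
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        delta = float(np.max(np.abs(candidate - beta)))
        beta, ll = candidate, ll_new
        if delta < tol:
            converged = True
            break

    p = expit(X @ beta)
    # separation signature: fitted probabilities pinned to the labels
    separated = bool(
        not converged
        and np.all(np.abs(p - y.astype(float)) < 1e-6)
    )
    return LogisticModel(
        coefficients=dict(zip(names, beta.tolist())),
        converged=converged,
        iterations=iterations,
        log_likelihood=ll,
        separated=separated,
    )


def risk_scores(model: LogisticModel, cohort: Cohort) -> np.ndarray:
    """Linear predictor per subject (monotone in fitted probability)."""
    predictors = [n for n in model.coefficients if n != "intercept"]
    X, names = _design_matrix(cohort, predictors)
    beta = np.array([model.coefficients[n] for n in names])
    return X @ beta


# --------------------------------------------------------------------------
# paired AUC comparison


@dataclass(frozen=True)
class DelongResult:
    """Paired comparison of two AUCs measured on the same subjects."""

    auc_a: float
    auc_b: float
    variance_a: float
    variance_b: float
    covariance: float
    z: float
    p_two_sided: float


def _placements(scores: np.ndarray, labels: np.ndarray) -> Tuple[float, np.ndarray, np.ndarray]:
    """AUC plus per-subject placement values (midrank construction).

    ``v10[i]`` is the fraction of negatives a positive subject outranks
    (ties count half); ``v01[j]`` the analogous quantity for negatives.
    The means of both vectors equal the AUC.
    """
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return auc, v10, v01


def delong_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[bool],
) -> DelongResult:
    """DeLong's test for two correlated AUCs on the same subjects.

    z = (AUC_a - AUC_b) / sqrt(var_a + var_b - 2 cov), with variances and
    covariance of the placement-value means; p is two-sided normal.
    Identical score vectors give z = 0, p = 1 by convention; a zero-variance
    difference with unequal AUCs is an error (degenerate placements).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if not (a.shape == b.shape == y.shape) or a.ndim != 1:
        raise ValueError("scores_a, scores_b and labels must be aligned 1-d arrays")
    m = int(y.sum())
    n = int(y.size - m)
    if m == 0 or n == 0:
        raise ValueError("labels contain a single class; AUC undefined")

    auc_a, v10_a, v01_a = _placements(a, y)
    auc_b, v10_b, v01_b = _placements(b, y)

    def _var(u: np.ndarray) -> float:
        return float(np.var(u, ddof=1)) if u.size > 1 else 0.0

    def _cov(u: np.ndarray, v: np.ndarray) -> float:
        return float(np.cov(u, v, ddof=1)[0, 1]) if u.size > 1 else 0.0

    var_a = _var(v10_a) / m + _var(v01_a) / n
    var_b = _var(v10_b) / m + _var(v01_b) / n
    cov = _cov(v10_a, v10_b) / m + _cov(v01_a, v01_b) / n

    denom_sq = var_a + var_b - 2.0 * cov
    diff = auc_a - auc_b
    if denom_sq <= 1e-300:
        if abs(diff) < 1e-15:
            z, p = 0.0, 1.0
        else:
            raise ValueError(
                "degenerate variance: placement values carry no sampling "
                "variability but the AUCs differ; z is undefined"
            )
    else:
        z = diff / float(np.sqrt(denom_sq))
        p = float(2.0 * stats.norm.sf(abs(z)))
    return DelongResult(
        auc_a=auc_a,
        auc_b=auc_b,
        variance_a=var_a,
        variance_b=var_b,
        covariance=cov,
        z=z,
        p_two_sided=p,
    )


def bootstrap_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[bool],
    n_boot: int = 2000,
    seed: int = 0,
) -> Dict[str, float]:
    """Seeded paired-bootstrap AUC comparison (sensitivity check for DeLong).

    Resamples subjects with replacement, recomputes both AUCs per resample,
    and returns a two-sided p-value for the observed difference against the
    centred bootstrap distribution, plus the bootstrap SE of the difference.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=bool)
    rng = np.random.default_rng(seed)
    auc_a, _, _ = _placements(a, y)
    auc_b, _, _ = _placements(b, y)
    observed = auc_a - auc_b
    diffs = np.empty(n_boot)
    k = 0
    while k < n_boot:
        idx = rng.integers(0, y.size, y.size)
        yy = y[idx]
        if yy.all() or not yy.any():
            continue  # resample lost a class; redraw
        da, _, _ = _placements(a[idx], yy)
        db, _, _ = _placements(b[idx], yy)
        diffs[k] = da - db
        k += 1
    se = float(np.std(diffs, ddof=1))
    if se == 0.0:
        p = 1.0 if observed == 0.0 else 0.0
    else:
        z = observed / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    return {
        "auc_a": auc_a,
        "auc_b": auc_b,
        "diff": observed,
        "se_boot": se,
        "p_two_sided": p,
    }
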