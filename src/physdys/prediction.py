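"""Mortality-prediction model comparison via LOOCV ROC/AUC.

Four nested logistic models for death during follow-up are compared: a
reference model with baseline covariates only ("none"), and models adding
the deficits index ("di"), the dysregulation score ("dm"), or both
("dm_di"). Every predicted probability is a *leave-one-out* probability:
the model scoring subject i is fitted on all subjects except i, so the AUC
estimates out-of-sample discrimination rather than in-sample fit.

AUC differences between a candidate and the reference model (dAUC) are
tested with the paired DeLong asymptotic method on the per-subject score
pairs; a cluster-aware variant bootstraps whole families instead.

The logistic fits use an unpenalised Newton solver with warm starts from
the full-data fit — exact maximum likelihood, but fast enough that n
leave-one-out refits cost little more than a handful of full fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "VARIANTS",
    "design_matrix",
    "fit_logistic",
    "loocv_scores",
    "roc_auc",
    "compare_auc",
    "compare_auc_clustered",
    "AUCComparison",
]

Z95 = 1.959963984540054

#: model variants: which of the dm / di columns enter on top of the base
VARIANTS = {"none": (), "di": ("di",), "dm": ("dm",), "dm_di": ("dm", "di")}


class SeparationError(RuntimeError):
    pass


@dataclass
class AUCComparison:
    """Paired comparison of a candidate model's AUC against a reference."""

    auc_variant: float
    auc_reference: float
    dauc: float
    se_dauc: float
    ci95: tuple
    p: float
    n: int
    n_events: int
    method: str = "delong"


def design_matrix(table: pd.DataFrame, covariates) -> np.ndarray:
    """Numeric design matrix with an intercept column prepended."""
    X = table[list(covariates)].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(X)), X])


def fit_logistic(X: np.ndarray, y: np.ndarray, beta0: np.ndarray | None = None,
                 tol: float = 1e-10, max_iter: int = 100) -> np.ndarray:
    """Unpenalised logistic MLE by Newton-Raphson with step halving.

    Raises :class:`SeparationError` on (quasi-)complete separation,
    detected as unbounded drift of the coefficients.
    """
    n, k = X.shape
    beta = np.zeros(k) if beta0 is None else beta0.copy()
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        g = X.T @ (y - p)
        if np.max(np.abs(g)) < tol * n:
            return beta
        w = p * (1.0 - p)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(k), g)
        except np.linalg.LinAlgError as err:
            raise SeparationError("singular information matrix") from err
        # step halving on the log-likelihood
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
        for _ in range(30):
            cand = beta + step
            eta_c = X @ cand
            ll_c = np.sum(y * eta_c - np.logaddexp(0.0, eta_c))
            if ll_c >= ll - 1e-12:
                break
            step *= 0.5
        beta = cand
        if np.max(np.abs(beta)) > 1e3:
            raise SeparationError("coefficients diverging (separation?)")
    eta = X @ beta
    if np.max(np.abs(X.T @ (y - expit(eta)))) > 1e-4 * n:
        raise SeparationError("logistic fit did not converge")
    return beta


def loocv_scores(table: pd.DataFrame, covariates, outcome_col: str = "death",
                 ) -> pd.Series:
    """Held-out predicted death probability for every subject.

    For subject i the logistic model is refitted on all rows except i
    (warm-started at the full-data solution, solved to convergence) and
    evaluated at i. Deterministic: folds are taken in row order.
    """
    df = table.dropna(subset=list(covariates) + [outcome_col])
    X = design_matrix(df, covariates)
    y = df[outcome_col].to_numpy(dtype=float)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("outcome has a single class")
    n = len(y)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("leave-one-out folds would be single-class")
    beta_full = fit_logistic(X, y)
    scores = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            beta_i = fit_logistic(X[mask], y[mask], beta0=beta_full)
        except SeparationError as err:
            raise SeparationError(f"separation in fold {i}: {err}") from err
        scores[i] = expit(X[i] @ beta_i)
        mask[i] = True
    return pd.Series(scores, index=df.index, name="loocv_score")


def roc_auc(scores, outcome) -> float:
    """Area under the ROC curve (Mann-Whitney concordance, ties at 1/2)."""
    y = np.asarray(outcome, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("outcome has a single class")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def roc_points(scores, outcome) -> pd.DataFrame:
    """ROC curve as (threshold, fpr, tpr) rows."""
    fpr, tpr, thr = roc_curve(np.asarray(outcome), np.asarray(scores))
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """Per-subject structural components of the AUC (DeLong).

    Returns (auc, v10 components over cases, v01 components over controls).
    """
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    all_r = _midrank(np.concatenate([pos, neg]))
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - r_pos) / n
    v01 = 1.0 - (all_r[m:] - r_neg) / m
    return auc, v10, v01


def compare_auc(variant_scores, reference_scores, outcome) -> AUCComparison:
    """Paired DeLong test for the AUC difference of two score vectors
    computed on the same subjects.

    dAUC = AUC(variant) - AUC(reference); the variance accounts for the
    correlation between the two score vectors through their per-subject
    structural components. Identical scores give dAUC = 0 with p = 1
    (degenerate-variance case).
    """
    s1 = np.asarray(variant_scores, dtype=float)
    s0 = np.asarray(reference_scores, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if s1.shape != s0.shape or s1.shape != y.shape:
        raise ValueError("score vectors and outcome must align")
    a1, v10_1, v01_1 = _delong_components(s1, y)
    a0, v10_0, v01_0 = _delong_components(s0, y)
    m, n = v10_1.size, v01_1.size
    s10 = np.cov(np.vstack([v10_1, v10_0]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_0]), ddof=1)
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    dauc = a1 - a0
    if var <= 0:
        se = 0.0
        p = 1.0 if dauc == 0 else 0.0
    else:
        se = float(np.sqrt(var))
        p = float(2 * stats.norm.sf(abs(dauc) / se))
    return AUCComparison(
        auc_variant=float(a1), auc_reference=float(a0), dauc=float(dauc),
        se_dauc=se, ci95=(dauc - Z95 * se, dauc + Z95 * se), p=p,
        n=int(y.size), n_events=int(m), method="delong")


def compare_auc_clustered(variant_scores, reference_scores, outcome,
                          clusters, n_boot: int = 2000,
                          seed: int = 0) -> AUCComparison:
    """dAUC inference robust to within-family correlation.

    The point estimate equals :func:`compare_auc`'s; the standard error
    comes from a seeded nonparametric bootstrap resampling whole clusters
    (families) with replacement.
    """
    base = compare_auc(variant_scores, reference_scores, outcome)
    s1 = np.asarray(variant_scores, dtype=float)
    s0 = np.asarray(reference_scores, dtype=float)
    y = np.asarray(outcome, dtype=float)
    cl = np.asarray(clusters)
    uniq = np.unique(cl)
    if uniq.size < 20:
        raise ValueError(f"need >= 20 clusters, got {uniq.size}")
    members = {c: np.flatnonzero(cl == c) for c in uniq}
    rng = np.random.default_rng(seed)
    daucs = []
    for _ in range(n_boot):
        pick = rng.choice(uniq, size=uniq.size, replace=True)
        idx = np.concatenate([members[c] for c in pick])
        yb = y[idx]
        if yb.min() == yb.max():
            continue
        daucs.append(roc_auc(s1[idx], yb) - roc_auc(s0[idx], yb))
    se = float(np.std(daucs, ddof=1))
    if se == 0:
        p = 1.0 if base.dauc == 0 else 0.0
    else:
        p = float(2 * stats.norm.sf(abs(base.dauc) / se))
    return AUCComparison(
        auc_variant=base.auc_variant, auc_reference=base.auc_reference,
        dauc=base.dauc, se_dauc=se,
        ci95=(base.dauc - Z95 * se, base.dauc + Z95 * se), p=p,
        n=base.n, n_events=base.n_events,
        method=f"cluster-bootstrap({n_boot})")
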