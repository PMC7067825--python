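"""Left-truncated Cox models with family-clustered variance, PH checks,
and conditional Kaplan-Meier curves.

Age is the analysis time scale: a subject enters the risk set at their
baseline age (delayed entry) and leaves at death or censoring, so all
comparisons are made among subjects alive at the same age. Standard errors
account for within-family correlation via the cluster-grouped sandwich
estimator with the family id as the cluster unit. Effect sizes for the
dysregulation score are reported as the hazard ratio per standard
deviation of the score in the analysed stratum.

The proportional-hazards diagnostic is a scaled-Schoenfeld-residual score
test against an identity time transform, computed directly on the
delayed-entry risk sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CoxFit",
    "fit_cox",
    "fit_cox_quartile",
    "test_proportional_hazards",
    "km_conditional",
    "exclude_early_deaths",
]

Z95 = 1.959963984540054


@dataclass
class CoxFit:
    """Cox partial-likelihood fit with naive and cluster-robust variance."""

    terms: list[str]
    coefficients: pd.Series
    robust_se: pd.Series
    naive_se: pd.Series | None
    p: pd.Series
    loglik: float
    n: int
    n_events: int
    n_dropped: int
    sd_dm: float | None = None
    hr_per_sd: tuple | None = None  # (hr, lo, hi) for the dm term
    hazard_ratios: pd.DataFrame | None = None
    _data: pd.DataFrame | None = field(default=None, repr=False)
    _cols: dict = field(default_factory=dict, repr=False)

    def summary_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "coef": self.coefficients,
            "robust_se": self.robust_se,
            "p": self.p,
            "hr": np.exp(self.coefficients),
            "ci_low": np.exp(self.coefficients - Z95 * self.robust_se),
            "ci_high": np.exp(self.coefficients + Z95 * self.robust_se),
        })
        if self.naive_se is not None:
            out.insert(1, "se", self.naive_se)
        return out


def _score_residuals(X: np.ndarray, beta: np.ndarray, entry: np.ndarray,
                     exit_: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Per-subject partial-likelihood score residuals with delayed entry.

    Breslow-form residuals (exact in the absence of ties, which are
    measure-zero on a continuous age scale):

        U_i = d_i (x_i - xbar(t_i))
              - sum_{t_k in (entry_i, exit_i]} w_i / S(t_k) (x_i - xbar(t_k))
    """
    n, p = X.shape
    w = np.exp(X @ beta)
    ev = np.flatnonzero(event == 1)
    order = np.argsort(exit_[ev], kind="stable")
    ev = ev[order]
    times = exit_[ev]
    d = times.size
    s0 = np.empty(d)
    xbar = np.empty((d, p))
    for k, t in enumerate(times):
        at_risk = (entry < t) & (exit_ >= t)
        wr = w[at_risk]
        s0[k] = wr.sum()
        xbar[k] = wr @ X[at_risk] / s0[k]
    # cumulative sums over event times for the at-risk correction term
    inv_s0 = 1.0 / s0
    cum_a = np.concatenate([[0.0], np.cumsum(inv_s0)])
    cum_b = np.vstack([np.zeros(p), np.cumsum(xbar * inv_s0[:, None], axis=0)])
    lo = np.searchsorted(times, entry, side="right")
    hi = np.searchsorted(times, exit_, side="right")
    a = cum_a[hi] - cum_a[lo]
    b = cum_b[hi] - cum_b[lo]
    resid = -w[:, None] * (X * a[:, None] - b)
    # event contribution: x_i - xbar at the subject's own event time
    pos = np.searchsorted(times, exit_[ev], side="left")
    resid[ev] += X[ev] - xbar[pos]
    return resid


def _cluster_robust_se(X: np.ndarray, beta: np.ndarray, entry: np.ndarray,
                       exit_: np.ndarray, event: np.ndarray,
                       clusters: np.ndarray, naive_cov: np.ndarray
                       ) -> np.ndarray:
    """Cluster-grouped sandwich variance: I^-1 (sum_g U_g U_g') I^-1."""
    resid = _score_residuals(X, beta, entry, exit_, event)
    df = pd.DataFrame(resid)
    df["_g"] = clusters
    u = df.groupby("_g").sum().to_numpy()
    meat = u.T @ u
    cov = naive_cov @ meat @ naive_cov
    return np.sqrt(np.diag(cov))


def _prepare(table: pd.DataFrame, cols: Sequence[str], duration_col: str,
             entry_col: str, event_col: str) -> tuple[pd.DataFrame, int]:
    need = list(dict.fromkeys(cols))
    df = table[need].dropna()
    if (df[duration_col] < df[entry_col]).any():
        raise ValueError("rows with exit age below entry age")
    zero = df[duration_col] == df[entry_col]
    n_dropped = int(zero.sum())
    if n_dropped:
        logger.info("dropping %d rows with zero follow-up (exit == entry)",
                    n_dropped)
        df = df.loc[~zero]
    return df, n_dropped


def fit_cox(
    table: pd.DataFrame,
    terms: Sequence[str],
    duration_col: str = "age_exit",
    entry_col: str = "age_baseline",
    event_col: str = "death",
    cluster_col: str | None = "family_id",
    dm_term: str | None = "dm",
    sd_dm: float | None = None,
    compute_naive_se: bool = True,
) -> CoxFit:
    """Left-truncated Cox fit with Efron ties and sandwich variance.

    ``terms`` are numeric covariate columns (factors must already be dummy
    coded). Rows with ``exit == entry`` (zero follow-up) are dropped with a
    logged count. When ``dm_term`` is among the terms, the fit also reports
    the hazard ratio per SD of that column — ``sd_dm`` defaults to its
    sample SD over the fitted rows.
    """
    terms = list(terms)
    aux = [duration_col, entry_col, event_col] + ([cluster_col] if cluster_col else [])
    df, n_dropped = _prepare(table, terms + aux, duration_col, entry_col, event_col)
    n_events = int(df[event_col].sum())
    if n_events < 2:
        raise ValueError(f"need >= 2 events, got {n_events}")
    for t in terms:
        if df[t].nunique() < 2:
            raise ValueError(f"constant covariate {t!r}")

    cph = CoxPHFitter()
    cph.fit(df[terms + [duration_col, entry_col, event_col]],
            duration_col=duration_col, event_col=event_col,
            entry_col=entry_col)
    coef = cph.params_.copy()
    naive = cph.standard_errors_.copy()
    if cluster_col is not None:
        # lifelines does not propagate delayed entry into its robust
        # variance; build the cluster-grouped sandwich from score
        # residuals on the left-truncated risk sets instead
        se_vals = _cluster_robust_se(
            df[terms].to_numpy(dtype=float), coef.to_numpy(dtype=float),
            df[entry_col].to_numpy(dtype=float),
            df[duration_col].to_numpy(dtype=float),
            df[event_col].to_numpy(dtype=int),
            df[cluster_col].to_numpy(),
            cph.variance_matrix_.to_numpy())
        se = pd.Series(se_vals, index=coef.index)
    else:
        se = naive.copy()
    if not compute_naive_se and cluster_col is not None:
        naive = None
    z = coef / se
    p = pd.Series(2 * stats.norm.sf(np.abs(z)), index=coef.index)

    fit = CoxFit(terms=terms, coefficients=coef, robust_se=se, naive_se=naive,
                 p=p, loglik=float(cph.log_likelihood_), n=len(df),
                 n_events=n_events, n_dropped=n_dropped,
                 _data=df,
                 _cols={"duration": duration_col, "entry": entry_col,
                        "event": event_col})
    if dm_term is not None and dm_term in terms:
        s = float(df[dm_term].std(ddof=1)) if sd_dm is None else float(sd_dm)
        b, e = float(coef[dm_term]), float(se[dm_term])
        fit.sd_dm = s
        fit.hr_per_sd = (float(np.exp(b * s)),
                         float(np.exp((b - Z95 * e) * s)),
                         float(np.exp((b + Z95 * e) * s)))
    fit.hazard_ratios = fit.summary_frame()
    return fit


def fit_cox_quartile(
    table: pd.DataFrame,
    quartile_col: str = "dm_quartile",
    covariates: Sequence[str] = (),
    **kwargs,
) -> CoxFit:
    """Cox model with the score as a categorical quartile variable.

    Builds Q2/Q3/Q4 indicator terms (Q1 is the reference category) and
    fits alongside the other covariates. Each quartile must contain at
    least one event.
    """
    df = table.dropna(subset=[quartile_col]).copy()
    labels = ["Q1", "Q2", "Q3", "Q4"]
    counts = df[quartile_col].value_counts()
    event_col = kwargs.get("event_col", "death")
    for q in labels:
        if counts.get(q, 0) == 0:
            raise ValueError(f"empty quartile {q}")
        if df.loc[df[quartile_col] == q, event_col].sum() < 1:
            raise ValueError(f"no events in quartile {q}")
    ind_cols = []
    for q in labels[1:]:
        col = f"{quartile_col}_{q}"
        df[col] = (df[quartile_col] == q).astype(float)
        ind_cols.append(col)
    kwargs.setdefault("dm_term", None)
    return fit_cox(df, ind_cols + list(covariates), **kwargs)


def test_proportional_hazards(fit: CoxFit) -> pd.Series:
    """Scaled-Schoenfeld score test of proportional hazards, per term.

    Correlates the scaled Schoenfeld residual of each term with the event
    age (identity time transform), honouring delayed-entry risk sets.
    Returns a p-value per term; small p flags a time-varying effect.
    """
    df = fit._data
    if df is None:
        raise ValueError("fit does not carry its training data")
    X = df[fit.terms].to_numpy(dtype=float)
    beta = fit.coefficients.to_numpy(dtype=float)
    entry = df[fit._cols["entry"]].to_numpy(dtype=float)
    exit_ = df[fit._cols["duration"]].to_numpy(dtype=float)
    event = df[fit._cols["event"]].to_numpy(dtype=int).astype(bool)
    d = int(event.sum())
    if d < 2:
        raise ValueError("need >= 2 events for the PH test")

    eta = np.exp(X @ beta)
    ev_idx = np.flatnonzero(event)
    order = np.argsort(exit_[ev_idx], kind="stable")
    ev_idx = ev_idx[order]
    times = exit_[ev_idx]
    p = X.shape[1]
    resid = np.empty((d, p))
    info = np.zeros((p, p))  # total partial-likelihood information
    for k, (i, t) in enumerate(zip(ev_idx, times)):
        at_risk = (entry < t) & (exit_ >= t)
        w = eta[at_risk]
        xr = X[at_risk]
        sw = w.sum()
        xbar = w @ xr / sw
        resid[k] = X[i] - xbar
        dev = xr - xbar
        info += (dev * w[:, None]).T @ dev / sw
    iinv = np.linalg.inv(info)
    sstar = d * resid @ iinv  # scaled residuals (constant offset irrelevant)
    g = times - times.mean()
    gg = float(g @ g)
    num = g @ sstar
    denom = d * np.diag(iinv) * gg
    chi2 = num**2 / denom
    return pd.Series(stats.chi2.sf(chi2, df=1), index=fit.terms, name="ph_p")


def exclude_early_deaths(
    table: pd.DataFrame,
    years: float,
    duration_col: str = "age_exit",
    entry_col: str = "age_baseline",
    event_col: str = "death",
) -> pd.DataFrame:
    """Drop subjects who died within ``years`` of baseline (a pure row
    filter used to guard against reverse causation from terminal decline)."""
    early = (table[event_col] == 1) & \
        (table[duration_col] - table[entry_col] <= years)
    return table.loc[~early]


def km_conditional(
    table: pd.DataFrame,
    conditioning_age: float = 80.0,
    group_col: str | None = None,
    duration_col: str = "age_exit",
    entry_col: str = "age_baseline",
    event_col: str = "death",
) -> dict[object, pd.DataFrame]:
    """Kaplan-Meier survival conditional on being alive at a given age.

    Subjects enter each risk set at ``max(entry age, conditioning age)``;
    subjects whose exit age does not exceed the conditioning age are
    excluded. The 95% confidence band is built on the Nelson-Aalen
    cumulative hazard: ``exp(-exp(log H +/- 1.96 * SE(log H)))``, which
    keeps the bounds inside [0, 1]; bounds are additionally clipped to
    bracket the point estimate.

    Returns per-group long-format frames with columns
    ``age, estimate, lower, upper, n_risk``.
    """
    groups = [(None, table.index)] if group_col is None else \
        list(table.groupby(group_col, observed=True, sort=True).groups.items())
    out: dict[object, pd.DataFrame] = {}
    for key, idx in groups:
        sub = table.loc[idx]
        sub = sub.loc[sub[duration_col] > conditioning_age]
        if sub.empty:
            raise ValueError(
                f"group {key!r}: nobody under observation beyond age "
                f"{conditioning_age}")
        entry = np.maximum(sub[entry_col].to_numpy(dtype=float),
                           conditioning_age)
        kmf = KaplanMeierFitter()
        kmf.fit(sub[duration_col], sub[event_col], entry=entry)
        et = kmf.event_table
        ev = et[et["observed"] > 0]
        ages = ev.index.to_numpy(dtype=float)
        n_risk = ev["at_risk"].to_numpy(dtype=float)
        d_obs = ev["observed"].to_numpy(dtype=float)
        surv = kmf.survival_function_.loc[ages].iloc[:, 0].to_numpy()
        # Nelson-Aalen cumulative hazard and its (Poisson-type) variance
        h = np.cumsum(d_obs / n_risk)
        var_h = np.cumsum(d_obs / n_risk**2)
        se_log_h = np.sqrt(var_h) / h
        lower = np.exp(-np.exp(np.log(h) + Z95 * se_log_h))
        upper = np.exp(-np.exp(np.log(h) - Z95 * se_log_h))
        lower = np.minimum(lower, surv)
        upper = np.maximum(upper, surv)
        grid = pd.DataFrame({
            "age": np.concatenate([[conditioning_age], ages]),
            "estimate": np.concatenate([[1.0], surv]),
            "lower": np.concatenate([[1.0], lower]),
            "upper": np.concatenate([[1.0], upper]),
            "n_risk": np.concatenate([[float(len(sub))], n_risk]),
        })
        out[key if key is not None else "all"] = grid
    return out
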