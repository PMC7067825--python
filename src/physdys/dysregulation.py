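"""Sex-stratified reference model and the Mahalanobis dysregulation score.

The composite dysregulation score of a subject is the Mahalanobis distance

    D_M = sqrt((x - mu)' Sigma^{-1} (x - mu))

of the subject's (Box-Cox transformed, standardised) biomarker vector ``x``
from the centroid ``mu`` of a *reference population* — by default, subjects
younger than 60 years at baseline — with ``Sigma`` the reference sample
covariance. Centroid and covariance are always computed separately for
females and males (optionally further stratified by country/field-center
group), and every subject is scored against the model of their own stratum.

D_M is itself Box-Cox transformed and standardised before entering
regression models; a pass-through mode keeps the raw distance for
sensitivity analysis. Additional helpers implement the biomarker-subset
sensitivity rules (age-correlation thresholds, pairwise decorrelation at
|r| > 0.8, and positive/negative age-correlation splits) and quartile
assignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from . import preprocess

__all__ = [
    "ReferenceModel",
    "ScoreSet",
    "select_reference",
    "fit_reference",
    "compute_dm",
    "transform_dm",
    "assign_quartiles",
    "select_biomarker_subset",
]

PREVALENT_FLAGS = ("prevalent_cancer", "prevalent_cvd",
                   "prevalent_diabetes", "prevalent_ad")


class SingularCovarianceError(np.linalg.LinAlgError):
    pass


@dataclass
class _Stratum:
    centroid: np.ndarray
    covariance: np.ndarray
    n_ref: int
    cho_factor: tuple = None  # cached Cholesky of covariance
    condition_number: float = np.nan


@dataclass
class ReferenceModel:
    """Per-stratum reference moments plus provenance metadata.

    Strata are keyed by sex code (0 female / 1 male) or, under country
    stratification, by ``(sex, country_group)``.
    """

    biomarker_names: list[str]
    strata: dict = field(default_factory=dict)
    age_cutoff: float = 60.0
    healthy_only: bool = False
    exclude_spouses: bool = False
    stratification: str = "pooled"  # or "by_country"

    def to_json(self) -> str:
        d = {
            "biomarker_names": self.biomarker_names,
            "age_cutoff": self.age_cutoff,
            "healthy_only": self.healthy_only,
            "exclude_spouses": self.exclude_spouses,
            "stratification": self.stratification,
            "strata": {
                repr(k): {
                    "centroid": s.centroid.tolist(),
                    "covariance": s.covariance.tolist(),
                    "n_ref": s.n_ref,
                    "condition_number": s.condition_number,
                }
                for k, s in self.strata.items()
            },
        }
        return json.dumps(d, indent=2)


def select_reference(
    table: pd.DataFrame,
    biomarkers: Sequence[str],
    age_cutoff: float = 60.0,
    healthy_only: bool = False,
    exclude_spouses: bool = False,
) -> pd.DataFrame:
    """Rows defining the reference population.

    Keeps complete-case rows (for the chosen panel) with baseline age
    strictly below ``age_cutoff``; optionally drops subjects with any
    prevalent disease (cancer, CVD, diabetes, AD/dementia) and/or spouses.
    """
    mask = table["age_baseline"] < age_cutoff
    mask &= table[list(biomarkers)].notna().all(axis=1)
    if healthy_only:
        flags = [f for f in PREVALENT_FLAGS if f in table.columns]
        if flags:
            mask &= (table[flags] == 0).all(axis=1)
    if exclude_spouses and "spouse" in table.columns:
        mask &= table["spouse"] != 1
    return table.loc[mask]


def _stratum_keys(rows: pd.DataFrame, stratification: str) -> pd.Series:
    if stratification == "pooled":
        return rows["sex"]
    if stratification == "by_country":
        country = np.where(rows["field_center"] == "Denmark", "Denmark", "US")
        return pd.Series(list(zip(rows["sex"], country)), index=rows.index)
    raise ValueError(f"unknown stratification {stratification!r}")


def fit_reference(
    rows: pd.DataFrame,
    biomarkers: Sequence[str],
    stratification: str = "pooled",
    age_cutoff: float = 60.0,
    healthy_only: bool = False,
    exclude_spouses: bool = False,
) -> ReferenceModel:
    """Per-sex (and optionally per-country) centroid and covariance.

    Covariance uses the n-1 denominator. Raises
    :class:`SingularCovarianceError` naming the most collinear biomarker
    pair if the covariance cannot be factorised, and ``ValueError`` when a
    stratum has no more subjects than biomarkers.
    """
    biomarkers = list(biomarkers)
    p = len(biomarkers)
    model = ReferenceModel(biomarker_names=biomarkers, age_cutoff=age_cutoff,
                           healthy_only=healthy_only,
                           exclude_spouses=exclude_spouses,
                           stratification=stratification)
    keys = _stratum_keys(rows, stratification)
    for key, idx in rows.groupby(keys, sort=False).groups.items():
        x = rows.loc[idx, biomarkers].to_numpy(dtype=float)
        n = x.shape[0]
        if n <= p:
            raise ValueError(
                f"reference stratum {key!r} has n={n} <= p={p}; too small "
                "to estimate an invertible covariance")
        centroid = x.mean(axis=0)
        cov = np.cov(x, rowvar=False, ddof=1).reshape(p, p)
        try:
            cf = linalg.cho_factor(cov, lower=True)
        except linalg.LinAlgError as err:
            corr = np.corrcoef(x, rowvar=False)
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
            raise SingularCovarianceError(
                f"singular covariance in stratum {key!r}; most collinear "
                f"pair: {biomarkers[i]} / {biomarkers[j]} "
                f"(r = {corr[i, j]:.4f})") from err
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals[0] <= 0:
            raise SingularCovarianceError(
                f"covariance in stratum {key!r} is not positive definite "
                f"(min eigenvalue {eigvals[0]:.3g})")
        model.strata[key] = _Stratum(
            centroid=centroid, covariance=cov, n_ref=n, cho_factor=cf,
            condition_number=float(eigvals[-1] / eigvals[0]))
    return model


def compute_dm(table: pd.DataFrame, model: ReferenceModel) -> pd.Series:
    """Mahalanobis distance of each subject from their stratum's centroid.

    Requires a complete transformed biomarker vector per scored row and a
    fitted stratum matching the subject's sex (and country group when the
    model is country-stratified).
    """
    x_all = table[model.biomarker_names].to_numpy(dtype=float)
    if np.isnan(x_all).any():
        bad = table.index[np.isnan(x_all).any(axis=1)]
        raise ValueError(
            f"{len(bad)} rows have missing biomarker values (e.g. index "
            f"{bad[0]}); score complete cases or impute first")
    keys = _stratum_keys(table, model.stratification)
    dm = pd.Series(np.nan, index=table.index, name="dm_raw")
    for key, idx in table.groupby(keys, sort=False).groups.items():
        if key not in model.strata:
            raise KeyError(f"no fitted reference stratum for {key!r}")
        s = model.strata[key]
        dev = table.loc[idx, model.biomarker_names].to_numpy(dtype=float) \
            - s.centroid
        # solve L y = dev'; ||y||^2 = dev' Sigma^-1 dev
        y = linalg.solve_triangular(s.cho_factor[0], dev.T, lower=True)
        dm.loc[idx] = np.sqrt((y**2).sum(axis=0))
    return dm


def transform_dm(dm_raw: pd.Series, mode: str = "boxcox"):
    """Box-Cox transform and standardise the raw distance (or pass it
    through untouched in ``mode="raw"``).

    Returns ``(dm_transformed, TransformSpec or None)``. The transform is
    fitted pooled over all scored subjects; monotone, so ranks and hence
    quartile assignments are unchanged.
    """
    if mode == "raw":
        return dm_raw.copy(), None
    if mode != "boxcox":
        raise ValueError(f"unknown mode {mode!r}")
    spec = preprocess.fit_box_cox(dm_raw, shift_policy="auto", variable="dm")
    out = pd.Series(preprocess.apply_transform(dm_raw, spec),
                    index=dm_raw.index, name="dm_transformed")
    return out, spec


def assign_quartiles(
    values: pd.Series,
    by: pd.Series | None = None,
    defining_mask: pd.Series | None = None,
) -> pd.Series:
    """Quartile labels Q1..Q4 with cut points from the defining sample.

    ``by`` optionally computes cut points separately per group (e.g. sex);
    ``defining_mask`` restricts the cut-point sample (e.g. to subjects who
    survived to 80). Cut points are the 25/50/75th percentiles (linear
    interpolation between order statistics); intervals are half-open
    ``(low, high]`` with ties going to the lower bin.
    """
    labels = pd.Series(pd.NA, index=values.index, dtype="object", name="quartile")
    groups = [(None, values.index)] if by is None \
        else list(values.groupby(by, sort=False).groups.items())
    for _, idx in groups:
        v = values.loc[idx]
        defining = v if defining_mask is None else v.loc[defining_mask.loc[idx]]
        defining = defining.dropna()
        if len(defining) < 8:
            raise ValueError("quartile-defining group has fewer than 8 subjects")
        cuts = np.quantile(defining, [0.25, 0.5, 0.75])
        if cuts[0] == cuts[2]:
            raise ValueError("degenerate quartile cut points (all equal)")
        code = np.searchsorted(cuts, v.to_numpy(dtype=float), side="left")
        labels.loc[idx] = np.array(["Q1", "Q2", "Q3", "Q4"])[code]
    labels[values.isna()] = pd.NA
    return labels


def select_biomarker_subset(
    table: pd.DataFrame,
    biomarkers: Sequence[str],
    rule: str,
    threshold: float = 0.05,
    decorrelate_at: float = 0.8,
    age_col: str = "age_baseline",
) -> list[str]:
    """Sensitivity-analysis panel selection.

    Rules (correlations are Pearson, pairwise-complete, on the scale of the
    supplied columns — conventionally the transformed scale):

    - ``age_corr_threshold``: keep markers with |corr(marker, age)| > threshold
    - ``decorrelate``: repeatedly find the pair with |corr| > ``decorrelate_at``
      and drop the member with the larger mean absolute correlation to the
      other markers (ties to the later one in input order)
    - ``positive_age_corr`` / ``negative_age_corr``: sign split

    The output preserves input order and is never empty (raises otherwise).
    """
    biomarkers = list(biomarkers)
    sub = table[biomarkers + [age_col]].astype(float)
    if rule in ("age_corr_threshold", "positive_age_corr", "negative_age_corr"):
        r = sub.corr(min_periods=2)[age_col].drop(age_col)
        if rule == "age_corr_threshold":
            if not 0 < threshold < 1:
                raise ValueError("threshold must be in (0, 1)")
            keep = [b for b in biomarkers if abs(r[b]) > threshold]
        elif rule == "positive_age_corr":
            keep = [b for b in biomarkers if r[b] > 0]
        else:
            keep = [b for b in biomarkers if r[b] < 0]
    elif rule == "decorrelate":
        keep = list(biomarkers)
        while True:
            c = sub[keep].corr(min_periods=2).to_numpy()
            np.fill_diagonal(c, 0.0)
            if np.nanmax(np.abs(c)) <= decorrelate_at:
                break
            i, j = np.unravel_index(np.nanargmax(np.abs(c)), c.shape)
            mean_abs = np.nanmean(np.abs(c), axis=1)
            drop = j if mean_abs[j] >= mean_abs[i] else i
            keep.pop(drop)
            if len(keep) < 2:
                break
    else:
        raise ValueError(f"unknown rule {rule!r}")
    if not keep:
        raise ValueError(f"rule {rule!r} leaves an empty biomarker panel")
    return keep
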