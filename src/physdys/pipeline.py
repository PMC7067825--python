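"""End-to-end analysis pipeline.

Chains the stages in the order of the study design: complete-case
selection on the biomarker panel -> per-variable Box-Cox + standardisation
-> sex-stratified reference moments (baseline age < cutoff) -> Mahalanobis
dysregulation score, its Box-Cox transform and quartiles -> deficits index
-> left-truncated family-clustered Cox model -> LOOCV logistic ROC/AUC
model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import deficits, dysregulation, preprocess, prediction, survival

__all__ = ["ScoreConfig", "encode_covariates", "BASE_COVARIATES",
           "score_cohort", "run_cox_analysis", "run_auc_analysis"]

#: adjustment covariates shared by the Cox and logistic models
#: (field center enters as three dummies with Denmark as reference)
BASE_COVARIATES = [
    "sex", "fc_Boston", "fc_NewYork", "fc_Pittsburgh",
    "education", "smoking", "med_antidiab", "med_antihyp", "med_lipid",
    "fasting",
]


@dataclass
class ScoreConfig:
    """Knobs of the scoring stage (defaults = main analysis)."""

    biomarkers: list[str] | None = None   # None = all panel columns present
    ref_age_cutoff: float = 60.0
    healthy_only: bool = False
    exclude_spouses: bool = False
    stratification: str = "pooled"        # or "by_country"
    dm_mode: str = "boxcox"               # or "raw"
    quartiles_by_sex: bool = False


def encode_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """Add field-center dummies (Denmark reference) as numeric columns."""
    out = table.copy()
    for level in ("Boston", "NewYork", "Pittsburgh"):
        out[f"fc_{level}"] = (table["field_center"] == level).astype(float)
    return out


def score_cohort(table: pd.DataFrame, config: ScoreConfig | None = None):
    """Complete-case filter, transform, reference fit and scoring.

    Returns ``(scored, model, specs)``: the complete-case table with added
    columns ``dm_raw``, ``dm`` (transformed score), ``dm_quartile`` and
    ``di``, the fitted :class:`~physdys.dysregulation.ReferenceModel`, and
    the per-biomarker transform specs.
    """
    config = config or ScoreConfig()
    biomarkers = config.biomarkers
    if biomarkers is None:
        from .cohort import default_biomarker_defs
        panel = [b.name for b in default_biomarker_defs()]
        biomarkers = [b for b in panel if b in table.columns]
    if not biomarkers:
        raise ValueError("no biomarker columns found")

    cc = table.loc[table[biomarkers].notna().all(axis=1)].copy()
    specs = preprocess.fit_panel(cc, biomarkers)
    cc = preprocess.apply_panel(cc, specs)

    ref_rows = dysregulation.select_reference(
        cc, biomarkers, age_cutoff=config.ref_age_cutoff,
        healthy_only=config.healthy_only,
        exclude_spouses=config.exclude_spouses)
    model = dysregulation.fit_reference(
        ref_rows, biomarkers, stratification=config.stratification,
        age_cutoff=config.ref_age_cutoff, healthy_only=config.healthy_only,
        exclude_spouses=config.exclude_spouses)

    cc["dm_raw"] = dysregulation.compute_dm(cc, model)
    cc["dm"], dm_spec = dysregulation.transform_dm(cc["dm_raw"],
                                                   mode=config.dm_mode)
    by = cc["sex"] if config.quartiles_by_sex else None
    cc["dm_quartile"] = dysregulation.assign_quartiles(cc["dm"], by=by)

    items = deficits.deficit_columns(cc)
    if items:
        cc["di"] = deficits.compute_di(cc, items)
    return cc, model, specs


def run_cox_analysis(
    scored: pd.DataFrame,
    terms: Sequence[str] = ("dm", "di"),
    extra_covariates: Sequence[str] | None = None,
    **kwargs,
) -> survival.CoxFit:
    """Cox model of follow-up mortality on the score(s) plus adjustments."""
    df = encode_covariates(scored)
    cov = list(extra_covariates) if extra_covariates is not None \
        else [c for c in BASE_COVARIATES if c in df.columns]
    return survival.fit_cox(df, list(terms) + cov, **kwargs)


def run_auc_analysis(
    scored: pd.DataFrame,
    variants: Sequence[str] = ("none", "di", "dm", "dm_di"),
    outcome_col: str = "death",
) -> dict:
    """LOOCV AUC for each model variant and DeLong dAUC vs the reference.

    The logistic models adjust for the base covariates plus baseline age;
    the ``none`` variant is the reference for every comparison.
    """
    df = encode_covariates(scored)
    base = [c for c in BASE_COVARIATES if c in df.columns] + ["age_baseline"]
    need = set(base) | {outcome_col}
    for v in variants:
        need |= set(prediction.VARIANTS[v])
    df = df.dropna(subset=sorted(need))
    scores = {v: prediction.loocv_scores(df, list(prediction.VARIANTS[v]) + base,
                                         outcome_col=outcome_col)
              for v in variants}
    y = df[outcome_col]
    out = {"n": len(df), "n_events": int(y.sum()), "scores": scores,
           "auc": {v: prediction.roc_auc(s, y) for v, s in scores.items()}}
    if "none" in scores:
        out["comparisons"] = {
            v: prediction.compare_auc(scores[v], scores["none"], y)
            for v in scores if v != "none"}
    return out
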