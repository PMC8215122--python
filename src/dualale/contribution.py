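"""Dual-disorder quantification: who drives each cluster, and does anything
predict a study's contribution?

For every significant cluster the two condition mean maps are summed over
the cluster's voxels and expressed as complementary percentages of the
joint sum — the "intensity ratio". A cluster driven entirely by one
condition shows ~100/0. Each study also receives a scalar contribution
score: its likelihood mass over all significant-cluster voxels divided by
its condition's study count, so that within a condition the scores sum to
that condition's mean-map mass over the clusters. The scores are the
response in ordinary least-squares meta-regression on study-level
covariates (total sample size, disease duration in years, HbA1c %), each
covariate alone and all three jointly; studies missing a covariate are
dropped per model, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ale_maps import LikelihoodMap
from .inference import ClusterResult
from .study_io import StudyRecord

__all__ = [
    "cluster_contribution",
    "annotate_contributions",
    "study_contribution_scores",
    "covariate_frame",
    "ModelFit",
    "MetaRegressionResult",
    "meta_regress",
    "META_COVARIATES",
]

META_COVARIATES = ("study_size", "duration_years", "hba1c_pct")


def cluster_contribution(
    cluster: ClusterResult,
    mean_a: LikelihoodMap,
    mean_b: LikelihoodMap,
) -> tuple[float, float]:
    """Percentage of the cluster's joint intensity owed to each condition.

    pct_A = 100 · Σ_{v∈cluster} M_A(v) / Σ_{v∈cluster} (M_A(v) + M_B(v)),
    pct_B = 100 − pct_A. Raises if the joint intensity is zero over the
    whole cluster (an inconsistent upstream state: such voxels could never
    have been significant).
    """
    idx = tuple(cluster.voxels.T)
    sum_a = float(mean_a.values[idx].sum())
    sum_b = float(mean_b.values[idx].sum())
    total = sum_a + sum_b
    if total <= 0.0:
        raise ValueError(
            f"cluster {cluster.cluster_id}: joint intensity is zero over the "
            "cluster — inconsistent upstream state"
        )
    pct_a = 100.0 * sum_a / total
    return pct_a, 100.0 - pct_a


def annotate_contributions(
    clusters: Sequence[ClusterResult],
    mean_maps: Mapping[str, LikelihoodMap],
) -> list[ClusterResult]:
    """Attach per-condition contribution percentages to each cluster.

    ``mean_maps`` maps the two condition labels to their mean maps.
    """
    if len(mean_maps) != 2:
        raise ValueError("need exactly two condition mean maps")
    (lab_a, map_a), (lab_b, map_b) = mean_maps.items()
    out = []
    for c in clusters:
        pct_a, pct_b = cluster_contribution(c, map_a, map_b)
        out.append(c.with_contributions({lab_a: pct_a, lab_b: pct_b}))
    return out


def study_contribution_scores(
    study_maps: Sequence[tuple[StudyRecord, LikelihoodMap]],
    clusters: Sequence[ClusterResult],
    group_sizes: Mapping[str, int] | None = None,
) -> dict[str, float]:
    """Per-study contribution score over all significant-cluster voxels.

    score_s = Σ_{v ∈ clusters} L_s(v) / n_group(s), where n_group(s) is the
    number of studies in s's condition (so within a condition the scores sum
    to the condition mean map's mass over the clusters). No clusters, or an
    empty-map study, yield score 0.
    """
    if group_sizes is None:
        group_sizes = {}
        for study, _ in study_maps:
            group_sizes[study.condition] = group_sizes.get(study.condition, 0) + 1
    if not clusters:
        return {study.study_id: 0.0 for study, _ in study_maps}
    all_vox = np.vstack([c.voxels for c in clusters])
    idx = tuple(all_vox.T)
    scores: dict[str, float] = {}
    for study, lmap in study_maps:
        n_group = group_sizes[study.condition]
        scores[study.study_id] = float(lmap.values[idx].sum()) / n_group
    return scores


def covariate_frame(records: Sequence[StudyRecord]) -> pd.DataFrame:
    """Study-level covariates for meta-regression, indexed by study_id.

    study_size is the total number of included participants
    (patients + controls); missing covariates are NaN.
    """
    rows = {
        r.study_id: {
            "study_size": float(r.n_patients + r.n_controls),
            "duration_years": np.nan if r.duration_mean is None else r.duration_mean,
            "hba1c_pct": np.nan if r.hba1c_mean is None else r.hba1c_mean,
        }
        for r in records
    }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass(frozen=True)
class ModelFit:
    """One fitted OLS model (coefficients exclude/include the intercept as
    named in ``params``)."""

    params: Mapping[str, float]
    bse: Mapping[str, float]
    tvalues: Mapping[str, float]
    pvalues: Mapping[str, float]
    n_used: int
    n_dropped: int
    r_squared: float


@dataclass(frozen=True)
class MetaRegressionResult:
    """Per-covariate simple regressions plus the combined model."""

    models: Mapping[str, ModelFit]


def _fit_ols(y: pd.Series, X: pd.DataFrame) -> ModelFit:
    n_total = len(y)
    keep = y.notna() & X.notna().all(axis=1)
    yk, Xk = y[keep], X[keep]
    n_used = int(keep.sum())
    n_preds = X.shape[1]
    if n_used < n_preds + 2:
        raise ValueError(
            f"need at least {n_preds + 2} complete studies, have {n_used}"
        )
    for col in Xk.columns:
        if float(np.var(Xk[col])) == 0.0:
            raise ValueError(f"covariate {col!r} has zero variance")
    design = sm.add_constant(Xk, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError(
            f"rank-deficient design over covariates {list(Xk.columns)}"
        )
    fit = sm.OLS(yk, design).fit()
    return ModelFit(
        params=dict(fit.params),
        bse=dict(fit.bse),
        tvalues=dict(fit.tvalues),
        pvalues=dict(fit.pvalues),
        n_used=n_used,
        n_dropped=n_total - n_used,
        r_squared=float(fit.rsquared),
    )


def meta_regress(
    scores: Mapping[str, float],
    covariates: pd.DataFrame,
    covariate_names: Sequence[str] = META_COVARIATES,
) -> MetaRegressionResult:
    """OLS of contribution score on study covariates.

    Fits one simple regression per covariate (with intercept) and one
    combined model on all covariates; the combined model uses only studies
    complete on all of them. Raises for zero-variance covariates or
    rank-deficient designs, naming the culprit.
    """
    ids = [sid for sid in covariates.index if sid in scores]
    y = pd.Series({sid: scores[sid] for sid in ids}, name="score")
    X = covariates.loc[ids, list(covariate_names)]
    models: dict[str, ModelFit] = {}
    for name in covariate_names:
        models[name] = _fit_ols(y, X[[name]])
    models["combined"] = _fit_ols(y, X)
    return MetaRegressionResult(models=models)
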