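"""End-to-end study runner: QC -> harmonise -> score -> statistics.

Glues the modules together the way the analysis scripts and the CLI use
them: sequencing QC on the genotype matrix, harmonisation to the risk
model's counted-allele convention, per-sample scoring, cohort summaries,
the seven planned comparisons against healthy controls, and the ROC of
non-monogenic versus monogenic disease.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import cohort_analysis as ca
from .genotype_io import GenotypeMatrix, apply_sequencing_qc, harmonise_to_model
from .risk_model import RiskModel, score_matrix
from .synthetic_data import StudyBundle

AFFECTED_GROUPS = ("SSNS", "MCD", "SRNS_primary", "SRNS_delayed", "FSGS")
PLANNED_GROUPS = AFFECTED_GROUPS + ("monogenic", "MN")
CONTROL_GROUP = "healthy"
NON_MONOGENIC = ("SSNS", "MCD", "SRNS", "FSGS")


@dataclass
class StudyResult:
    scores: pd.DataFrame  # sample_id, group, cohort, subtype, score, n_loci_used
    summaries: list[ca.CohortSummary]
    omnibus: ca.ComparisonResult
    planned: list[ca.ComparisonResult]
    roc: ca.RocResult


def group_labels(cohorts: pd.DataFrame) -> pd.Series:
    """Analysis group per sample: cohort, with SRNS split by subtype."""
    sub = cohorts["subtype"].fillna("").astype(str)
    return cohorts["cohort"].str.cat(sub.where(sub == "", "_" + sub), na_rep="")


def score_study(
    matrix: GenotypeMatrix,
    model: RiskModel,
    cohorts: pd.DataFrame,
    missing_policy: str = "strict",
    run_qc: bool = True,
    ambiguous_policy: str = "reject",
) -> pd.DataFrame:
    """QC, harmonise and score every sample; returns the scores table."""
    if run_qc:
        matrix, _ = apply_sequencing_qc(matrix)
    counted, _ = harmonise_to_model(matrix, model, ambiguous_policy=ambiguous_policy)
    scores = score_matrix(model, counted, matrix.sample_ids, missing_policy)
    meta = cohorts.set_index("sample_id")
    scores["cohort"] = scores["sample_id"].map(meta["cohort"])
    scores["subtype"] = scores["sample_id"].map(meta["subtype"]).fillna("")
    scores["group"] = group_labels(scores)
    return scores


def analyse_study(
    scores: pd.DataFrame,
    alpha: float = 0.05,
    ci_method: str = "delong",
    seed: int | None = None,
) -> StudyResult:
    """Cohort summaries, omnibus and planned rank tests, and the ROC."""
    group_map = dict(zip(scores["sample_id"], scores["group"]))
    order = [g for g in PLANNED_GROUPS + (CONTROL_GROUP,) if g in set(group_map.values())]
    summaries = ca.summarise_cohorts(scores, group_map, order=order)
    groups = {
        g: scores.loc[scores["group"] == g, "score"].to_numpy() for g in order
    }
    omnibus = ca.kruskal_wallis(groups, alpha=alpha)
    planned = ca.planned_comparisons(
        scores,
        group_map,
        control_label=CONTROL_GROUP,
        comparison_labels=[g for g in PLANNED_GROUPS if g in groups],
        alpha=alpha,
    )
    pos = scores.loc[scores["cohort"].isin(NON_MONOGENIC), "score"].to_numpy()
    neg = scores.loc[scores["cohort"] == "monogenic", "score"].to_numpy()
    roc = ca.roc_analysis(pos, neg, ci_method=ci_method, seed=seed)
    return StudyResult(
        scores=scores, summaries=summaries, omnibus=omnibus, planned=planned, roc=roc
    )


def run_bundle(
    bundle: StudyBundle,
    missing_policy: str = "strict",
    ci_method: str = "delong",
) -> StudyResult:
    scores = score_study(
        bundle.matrix, bundle.model, bundle.cohorts, missing_policy=missing_policy
    )
    return analyse_study(scores, seed=bundle.seed)
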