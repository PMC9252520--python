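"""End-to-end orchestration: patient profile -> ranked drug recommendations.

Composes the pipeline stages (variant genes -> subtype assignment ->
subgroup -> controls -> differential expression -> signature -> reversal
scoring) and provides the subgroup->sRGES closure that the permutation-null
validation re-runs on random subgroups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import pandas as pd

from .io import ExpressionMatrix, PerturbationLibrary, align_genes
from .reversal import DEFAULT_MIN_OVERLAP, fit_reward_model, score_library, \
    srges_table
from .signature import DiseaseSignature, EmptySignatureError, build_signature, \
    differential_expression
from .subtyping import DEFAULT_SUBGROUP_SIZE, SubgroupResult, SubtypeResult, \
    select_controls, select_subgroup, subtype_similarity

logger = logging.getLogger(__name__)


@dataclass
class Recommendation:
    """Outputs of one full patient run."""

    subgroup: SubgroupResult
    signature: DiseaseSignature
    srges: pd.DataFrame  # drug, srges, n_treatments; ascending srges


def subgroup_to_srges(
    cohort: ExpressionMatrix,
    normals: ExpressionMatrix,
    library: PerturbationLibrary,
    genes: list[str],
    n_controls: int | None = None,
    fdr_max: float = 0.05,
    lfc_min: float = 1.0,
    cap: int = 100,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> Callable[[list[str]], Mapping[str, float] | None]:
    """Closure mapping a subgroup sample list to a per-drug sRGES dict.

    Returns ``None`` for subgroups whose differential expression yields an
    empty signature side — the degenerate-replicate convention the
    permutation null scores as r = 0.
    """

    def run(subgroup_ids: list[str]) -> Mapping[str, float] | None:
        sub = cohort.select_samples(subgroup_ids)
        controls = select_controls(sub.to_log2(), normals.to_log2(),
                                   n_controls or len(subgroup_ids), genes)
        case, control = align_genes(sub, normals.select_samples(controls))
        de = differential_expression(case, control)
        try:
            sig = build_signature(de, fdr_max=fdr_max, lfc_min=lfc_min, cap=cap)
        except EmptySignatureError as exc:
            logger.info("subgroup %s: %s", subgroup_ids, exc)
            return None
        records = score_library(sig, library, min_overlap)
        if not records:
            return None
        table = srges_table(records, fit_reward_model(records))
        return dict(zip(table["drug"], table["srges"]))

    return run


def recommend(
    patient: pd.Series,
    cohort: ExpressionMatrix,
    normals: ExpressionMatrix,
    library: PerturbationLibrary,
    subtypes: SubtypeResult,
    genes: list[str],
    n: int = DEFAULT_SUBGROUP_SIZE,
    fdr_max: float = 0.05,
    lfc_min: float = 1.0,
    cap: int = 100,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    patient_id: str = "patient",
) -> Recommendation:
    """Full single-patient run against a pre-computed subtyping result.

    ``patient`` must be on the same scale family as ``cohort`` (raw counts
    or log2); similarity uses Spearman rank correlation so the scale choice
    only needs to be monotone-consistent.
    """
    cohort_log2 = cohort.to_log2()
    # Spearman similarity is monotone-invariant, so counts vs log2 agree
    _, assigned, sample_rho = subtype_similarity(patient.astype(float),
                                                 cohort_log2, subtypes, genes)
    subgroup = select_subgroup(patient_id, sample_rho, subtypes, assigned, n)
    sub = cohort.select_samples(subgroup.subgroup)
    controls = select_controls(sub.to_log2(), normals.to_log2(), n, genes)
    subgroup.controls = controls

    case, control = align_genes(sub, normals.select_samples(controls))
    de = differential_expression(case, control)
    sig = build_signature(
        de, fdr_max=fdr_max, lfc_min=lfc_min, cap=cap,
        provenance={"patient_id": patient_id, "n": n, "purified": False},
    )
    records = score_library(sig, library, min_overlap)
    table = srges_table(records, fit_reward_model(records))
    return Recommendation(subgroup=subgroup, signature=sig, srges=table)
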