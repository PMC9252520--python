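"""Connectivity scoring: KS enrichment -> RGES -> summary sRGES per drug.

Each drug treatment carries a full ranking of the gene universe (rank 1 =
most up-regulated by the drug). Two one-sided Kolmogorov-Smirnov statistics
measure where a tag list sits in that ranking: ``a`` (top enrichment) and
``b`` (bottom enrichment). The signed enrichment of the up- and down-tag
lists combine into the reverse gene expression score (RGES); treatments of
one drug at different dose/time conditions are standardized to the
reference condition (10 uM, 24 h) by additive class offsets (the reward
model) and averaged into a single sRGES. Lower sRGES = stronger reversal of
the disease signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PerturbationLibrary, PerturbationRecord
from .signature import DiseaseSignature

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 5
REFERENCE_DOSE_UM = 10.0
REFERENCE_TIME_H = 24.0


class InsufficientOverlapError(ValueError):
    """A tag list shares too few genes with the perturbation universe."""


@dataclass(frozen=True)
class KSResult:
    """Two one-sided KS statistics and the signed enrichment score."""

    a: float   # positive concordance (set enriched at the top)
    b: float   # negative concordance (set enriched at the bottom)
    es: float  # +a if a > b, -b if b > a, +a on ties
    t: int     # tag-list overlap with the universe
    n: int     # universe size


@dataclass(frozen=True)
class RGESRecord:
    """Signed connectivity of one treatment against a disease signature."""

    drug: str
    cell_line: str
    dose_um: float
    time_h: float
    rges: float
    es_up: float
    es_down: float


@dataclass(frozen=True)
class RewardModel:
    """Additive offsets standardizing non-reference dose/time classes.

    Classes are (dose: low < 10 uM / high >= 10 uM) x (time: short < 24 h /
    long >= 24 h); the reference class (high, long) has offset exactly 0.
    """

    offsets: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        if self.offsets.get(("high", "long"), 0.0) != 0.0:
            raise ValueError("reference class offset must be 0")

    def offset(self, dose_um: float, time_h: float) -> float:
        return self.offsets.get(treatment_class(dose_um, time_h), 0.0)


@dataclass(frozen=True)
class SRGESRecord:
    """Per-drug summary reversal score; lower = stronger reversal."""

    drug: str
    srges: float
    n_treatments: int
    treatments: tuple[RGESRecord, ...]


def treatment_class(dose_um: float, time_h: float) -> tuple[str, str]:
    return ("low" if dose_um < REFERENCE_DOSE_UM else "high",
            "short" if time_h < REFERENCE_TIME_H else "long")


def ks_enrichment(
    gene_set: list[str],
    record: PerturbationRecord,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> KSResult:
    """Two one-sided KS statistics for a tag list in a treatment ranking.

    With V(1) < ... < V(t) the sorted universe ranks of the tag genes and n
    the universe size:

        a = max_j ( j/t - V(j)/n )      (top enrichment)
        b = max_j ( V(j)/n - (j-1)/t )  (bottom enrichment)

    es = +a when a > b, -b when b > a, and +a on an exact tie. Tag genes
    absent from the universe are dropped; fewer than ``min_overlap``
    remaining genes reject the tag list for this record.
    """
    present = [g for g in set(gene_set) if g in record.ranking.index]
    t = len(present)
    if t < min_overlap:
        raise InsufficientOverlapError(
            f"tag list overlaps {t} genes with {record.drug}@{record.cell_line} "
            f"(minimum {min_overlap})"
        )
    n = record.n_genes
    v = np.sort(record.ranking.loc[present].to_numpy(float))
    j = np.arange(1, t + 1, dtype=float)
    a = float(np.max(j / t - v / n))
    b = float(np.max(v / n - (j - 1) / t))
    es = a if a >= b else -b
    return KSResult(a=a, b=b, es=es, t=t, n=n)


def rges_score(
    sig: DiseaseSignature,
    record: PerturbationRecord,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> RGESRecord:
    """Signed connectivity of one treatment against a disease signature.

    When the up- and down-tag enrichments disagree in sign the score is
    es_up - es_down; same-sign enrichment (the drug moves both halves the
    same way) is a non-match and scores 0. Positive RGES = the drug mimics
    the disease; negative = it reverses it.
    """
    es_up = ks_enrichment(sig.up, record, min_overlap).es
    es_down = ks_enrichment(sig.down, record, min_overlap).es
    if np.sign(es_up) == np.sign(es_down):
        rges = 0.0
    else:
        rges = es_up - es_down
    return RGESRecord(
        drug=record.drug, cell_line=record.cell_line,
        dose_um=record.dose_um, time_h=record.time_h,
        rges=float(rges), es_up=float(es_up), es_down=float(es_down),
    )


def score_library(
    sig: DiseaseSignature,
    library: PerturbationLibrary,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> list[RGESRecord]:
    """RGES for every library record; insufficient-overlap records are skipped."""
    out: list[RGESRecord] = []
    skipped = 0
    for record in library.records:
        try:
            out.append(rges_score(sig, record, min_overlap))
        except InsufficientOverlapError as exc:
            skipped += 1
            logger.debug("skipping record: %s", exc)
    if skipped:
        logger.info("skipped %d/%d records for insufficient overlap",
                    skipped, len(library.records))
    return out


def fit_reward_model(records: list[RGESRecord]) -> RewardModel:
    """Estimate per-class additive offsets from drugs measured in both classes.

    For each non-reference (dose, time) class the offset is the mean, over
    drugs having records in both the reference class and that class, of
    (mean reference RGES - mean class RGES). Classes without any paired drug
    keep offset 0, so an all-reference library degrades to plain means.
    """
    by_drug_class: dict[str, dict[tuple[str, str], list[float]]] = {}
    for rec in records:
        cls = treatment_class(rec.dose_um, rec.time_h)
        by_drug_class.setdefault(rec.drug, {}).setdefault(cls, []).append(rec.rges)

    reference = ("high", "long")
    offsets: dict[tuple[str, str], float] = {reference: 0.0}
    for cls in [("low", "long"), ("high", "short"), ("low", "short")]:
        diffs = []
        for classes in by_drug_class.values():
            if reference in classes and cls in classes:
                diffs.append(float(np.mean(classes[reference]))
                             - float(np.mean(classes[cls])))
        offsets[cls] = float(np.mean(diffs)) if diffs else 0.0
    return RewardModel(offsets)


def summarize_srges(records: list[RGESRecord], model: RewardModel) -> SRGESRecord:
    """Unweighted mean of reward-standardized RGES over one drug's treatments."""
    if not records:
        raise ValueError("no treatment records for this drug")
    drugs = {rec.drug for rec in records}
    if len(drugs) != 1:
        raise ValueError(f"records span multiple drugs: {sorted(drugs)}")
    standardized = [rec.rges + model.offset(rec.dose_um, rec.time_h)
                    for rec in records]
    return SRGESRecord(
        drug=records[0].drug,
        srges=float(np.mean(standardized)),
        n_treatments=len(records),
        treatments=tuple(records),
    )


def srges_table(records: list[RGESRecord],
                model: RewardModel | None = None) -> pd.DataFrame:
    """sRGES per drug as a DataFrame sorted ascending (strongest reversal first)."""
    if model is None:
        model = fit_reward_model(records)
    by_drug: dict[str, list[RGESRecord]] = {}
    for rec in records:
        by_drug.setdefault(rec.drug, []).append(rec)
    rows = [summarize_srges(recs, model) for recs in by_drug.values()]
    df = pd.DataFrame(
        {"drug": [r.drug for r in rows],
         "srges": [r.srges for r in rows],
         "n_treatments": [r.n_treatments for r in rows]}
    ).sort_values(["srges", "drug"], kind="mergesort").reset_index(drop=True)
    return df
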