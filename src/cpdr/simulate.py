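"""Synthetic study-condition generator for the whole pipeline.

Emulates, at desk scale, every input the workflow consumes: a tumor cohort
with planted expression subtypes and matched normals, an implanted up/down
disease signature carried by a subset of one subtype (the simulated
patient's "replicates"), optional normal-cell contamination of tumor
profiles, a drug-perturbation library in which a known subset of drugs
reverses the signature with dose/time-dependent strength, dose-response
AUCs linked to reversal strength, and responder labels linked to noisy
per-patient scores. Ground truth is recorded alongside every output so
recovery can be measured exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import COUNTS, DrugSensitivityTable, ExpressionMatrix, \
    PerturbationLibrary, PerturbationRecord

logger = logging.getLogger(__name__)

REFERENCE_CONDITION = (10.0, 24.0)


@dataclass
class ScenarioConfig:
    """All knobs of one synthetic scenario. Counts must be positive.

    The defaults describe the standard scenario: a 3-subtype cohort of 30
    samples per subtype over 2,000 genes, subtype blocks of 400 genes
    shifted by 2 on the log2 scale, biological log-noise SD 0.3 around a
    baseline of ~64 counts, a 100+100 disease signature at log2FC 2
    (4-fold) carried by a sixth of the focal subtype, 20 drugs of which 5
    reverse the signature, and AUCs decreasing with reversal strength.
    """

    seed: int = 0
    # cohort
    n_genes: int = 2000
    k: int = 3
    samples_per_subtype: int = 30
    n_normals: int = 20
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.0
    subtype_shift: float = 2.0
    subtype_block_size: int = 400
    noise_sd: float = 0.3
    # disease signature
    signature_size: int = 100
    signature_effect: float = 2.0
    carrier_fraction: float = 1.0 / 6.0
    # cancer cells get their own baseline program (a seeded permutation of
    # the normal baseline, hence uncorrelated with it across genes); needed
    # for contamination fractions to be identifiable by deconvolution
    distinct_cancer_baseline: bool = False
    # contamination
    alpha_range: tuple[float, float] = (0.0, 0.0)
    mix_noise_sd: float = 0.0
    # perturbation library
    n_drugs: int = 20
    n_reversers: int = 5
    universe_size: int = 1000
    reverser_strength: float = 3.0
    dose_time_grid: tuple[tuple[float, float], ...] = (
        (10.0, 24.0), (1.0, 24.0), (10.0, 6.0), (1.0, 6.0),
    )
    # sensitivity / response
    auc_intercept: float = 0.7
    auc_slope: float = 0.25
    auc_noise_sd: float = 0.05
    n_patients: int = 40
    response_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        counts = [self.n_genes, self.k, self.samples_per_subtype, self.n_normals,
                  self.signature_size, self.n_drugs, self.universe_size,
                  self.n_patients]
        if any(c <= 0 for c in counts):
            raise ValueError("all scenario counts must be positive")
        if self.n_reversers > self.n_drugs:
            raise ValueError("n_reversers must not exceed n_drugs")
        if 2 * self.signature_size + self.k * self.subtype_block_size > self.n_genes:
            raise ValueError("signature and subtype blocks exceed the gene count")
        if 2 * self.signature_size > self.universe_size:
            raise ValueError("signature larger than the perturbation universe")
        if not 0.0 <= self.alpha_range[0] <= self.alpha_range[1] < 1.0:
            raise ValueError("alpha_range must satisfy 0 <= lo <= hi < 1")

    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named randomness stream."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(
            stream + 1)[stream])


@dataclass
class CohortTruth:
    """Everything the generator knows that the pipeline must recover."""

    labels: dict[str, int]            # cohort sample -> planted subtype
    signature_up: list[str]
    signature_down: list[str]
    carriers: list[str]               # focal-subtype samples carrying the signature
    focal_subtype: int
    alphas: dict[str, float]          # planted contamination per tumor sample
    pure_log2: pd.DataFrame           # pre-contamination log2 tumor profiles
    patient: pd.Series                # held-out patient counts (a carrier)
    patient_id: str
    reversers: list[str] = field(default_factory=list)
    reversal_score: dict[str, float] = field(default_factory=dict)


def simulate_cohort(
    cfg: ScenarioConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, CohortTruth]:
    """Generate (tumor cohort counts, normal counts, ground truth).

    Genes get a log-normal baseline; subtype ``j`` shifts its disjoint gene
    block by ``subtype_shift`` relative to the other subtypes (blocks are
    mean-centered across subtypes so normals sit at the cohort average);
    signature genes move by ±``signature_effect`` in carrier tumors of the
    focal subtype; tumors are optionally mixed with the mean normal profile
    at a planted contamination fraction; counts are Poisson around the
    linear-scale mean.
    """
    rng = cfg.rng(0)
    genes = cfg.gene_names()
    n_sig = cfg.signature_size
    sig_up = genes[:n_sig]
    sig_down = genes[n_sig:2 * n_sig]
    block_start = 2 * n_sig
    blocks = [genes[block_start + j * cfg.subtype_block_size:
                    block_start + (j + 1) * cfg.subtype_block_size]
              for j in range(cfg.k)]

    mu = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}

    samples = [f"T{j + 1}-{i + 1:02d}" for j in range(cfg.k)
               for i in range(cfg.samples_per_subtype)]
    labels = {s: j + 1 for j in range(cfg.k)
              for s in samples[j * cfg.samples_per_subtype:
                               (j + 1) * cfg.samples_per_subtype]}

    focal = 1
    focal_samples = [s for s in samples if labels[s] == focal]
    n_carriers = max(1, round(cfg.carrier_fraction * len(focal_samples)))
    carriers = sorted(rng.choice(focal_samples, size=n_carriers, replace=False))

    def subtype_profile(subtype: int) -> np.ndarray:
        prof = mu.copy()
        for j, block in enumerate(blocks):
            idx = [gene_index[g] for g in block]
            if j + 1 == subtype:
                prof[idx] += cfg.subtype_shift * (cfg.k - 1) / cfg.k
            else:
                prof[idx] -= cfg.subtype_shift / cfg.k
        return prof

    up_idx = [gene_index[g] for g in sig_up]
    down_idx = [gene_index[g] for g in sig_down]
    # cancer-cell baseline: normal baseline, or its permutation (uncorrelated)
    cancer_shift = rng.permutation(mu) - mu if cfg.distinct_cancer_baseline else 0.0

    def tumor_log2_mean(sample: str) -> np.ndarray:
        prof = subtype_profile(labels[sample]) + cancer_shift
        if sample in carriers:
            prof = prof.copy()
            prof[up_idx] += cfg.signature_effect
            prof[down_idx] -= cfg.signature_effect
        return prof

    # normals: common baseline plus per-sample noise
    normal_names = [f"N-{i + 1:02d}" for i in range(cfg.n_normals)]
    normal_lin = {}
    for name in normal_names:
        log2_mean = mu + rng.normal(0.0, cfg.noise_sd, cfg.n_genes)
        normal_lin[name] = np.power(2.0, log2_mean)
    normal_lin_mean = np.mean(np.column_stack(list(normal_lin.values())), axis=1)

    alphas: dict[str, float] = {}
    pure_cols: dict[str, np.ndarray] = {}
    tumor_lin: dict[str, np.ndarray] = {}
    lo, hi = cfg.alpha_range
    for sample in samples:
        log2_mean = tumor_log2_mean(sample) + rng.normal(0.0, cfg.noise_sd,
                                                         cfg.n_genes)
        pure = np.power(2.0, log2_mean)
        pure_cols[sample] = np.log2(1.0 + pure)
        alpha = float(rng.uniform(lo, hi)) if hi > 0 else 0.0
        mixed = (1.0 - alpha) * pure + alpha * normal_lin_mean
        if cfg.mix_noise_sd > 0:
            mixed = mixed * np.power(2.0, rng.normal(0.0, cfg.mix_noise_sd,
                                                     cfg.n_genes))
        alphas[sample] = alpha
        tumor_lin[sample] = mixed

    cohort_counts = {s: rng.poisson(tumor_lin[s]).astype(float) for s in samples}
    normal_counts = {n: rng.poisson(normal_lin[n]).astype(float)
                     for n in normal_names}

    # held-out patient: a fresh carrier profile from the focal subtype
    patient_log2 = (subtype_profile(focal) + cancer_shift
                    + rng.normal(0.0, cfg.noise_sd, cfg.n_genes))
    patient_log2[up_idx] += cfg.signature_effect
    patient_log2[down_idx] -= cfg.signature_effect
    patient = pd.Series(rng.poisson(np.power(2.0, patient_log2)).astype(float),
                        index=genes, name="PT1")

    cohort = ExpressionMatrix(pd.DataFrame(cohort_counts, index=genes)[samples],
                              COUNTS)
    normals = ExpressionMatrix(
        pd.DataFrame(normal_counts, index=genes)[normal_names], COUNTS)
    truth = CohortTruth(
        labels=labels,
        signature_up=sig_up,
        signature_down=sig_down,
        carriers=list(carriers),
        focal_subtype=focal,
        alphas=alphas,
        pure_log2=pd.DataFrame(pure_cols, index=genes)[samples],
        patient=patient,
        patient_id="PT1",
    )
    logger.info("simulated cohort: %d tumors (%d carriers), %d normals",
                len(samples), len(carriers), cfg.n_normals)
    return cohort, normals, truth


def condition_scale(dose_um: float, time_h: float) -> float:
    """Reversal-strength multiplier: low dose and short time each halve it."""
    scale = 1.0
    if dose_um < REFERENCE_CONDITION[0]:
        scale *= 0.5
    if time_h < REFERENCE_CONDITION[1]:
        scale *= 0.5
    return scale


def simulate_perturbation_library(
    cfg: ScenarioConfig, truth: CohortTruth
) -> PerturbationLibrary:
    """Drug-perturbation rankings with a known reverser subset.

    Reverser drugs push signature-up genes toward the bottom of their
    ranking and signature-down genes toward the top, with strength
    ``reverser_strength`` at the reference condition (10 uM, 24 h) decayed
    by half per low-dose or short-time class; non-reversers rank genes
    uniformly at random. Every drug has one record per grid condition.
    """
    rng = cfg.rng(1)
    universe = cfg.gene_names()[:cfg.universe_size]
    missing = (set(truth.signature_up) | set(truth.signature_down)) - set(universe)
    if missing:
        raise ValueError("signature genes missing from the perturbation universe")
    up_mask = np.isin(universe, truth.signature_up)
    down_mask = np.isin(universe, truth.signature_down)

    width = len(str(cfg.n_drugs))
    drugs = [f"drug-{i + 1:0{width}d}" for i in range(cfg.n_drugs)]
    reversers = drugs[:cfg.n_reversers]

    records = []
    for drug in drugs:
        for dose, time in cfg.dose_time_grid:
            z = rng.normal(0.0, 1.0, len(universe))
            if drug in reversers:
                s = cfg.reverser_strength * condition_scale(dose, time)
                z = z - s * up_mask + s * down_mask
            # rank 1 = most up-regulated by the treatment
            order = np.argsort(-z, kind="stable")
            ranks = np.empty(len(universe), dtype=int)
            ranks[order] = np.arange(1, len(universe) + 1)
            records.append(PerturbationRecord(
                drug=drug, cell_line="CL-1", dose_um=dose, time_h=time,
                ranking=pd.Series(ranks, index=universe)))
    truth.reversers = reversers
    truth.reversal_score = {d: (-1.0 if d in reversers else 0.0) for d in drugs}
    return PerturbationLibrary(records, universe)


def simulate_cell_lines(
    cfg: ScenarioConfig, truth: CohortTruth, noise_sd: float = 0.3
) -> ExpressionMatrix:
    """One cell line per subtype: the subtype's mean pure profile plus noise.

    The patient-relevant line is the focal subtype's (``CL-1`` for subtype 1).
    """
    rng = cfg.rng(2)
    genes = cfg.gene_names()
    cols = {}
    for j in range(1, cfg.k + 1):
        members = [s for s, lab in truth.labels.items() if lab == j]
        centroid = truth.pure_log2[members].mean(axis=1).to_numpy()
        log2_mean = centroid + rng.normal(0.0, noise_sd, cfg.n_genes)
        cols[f"CL-{j}"] = rng.poisson(
            np.maximum(np.power(2.0, log2_mean) - 1.0, 0.0)).astype(float)
    return ExpressionMatrix(pd.DataFrame(cols, index=genes), COUNTS)


@dataclass
class ResponseData:
    """Per-patient focal-drug scores and linked responder labels."""

    scores: dict[str, float]
    labels: dict[str, str]


def simulate_sensitivity_and_response(
    cfg: ScenarioConfig, truth: CohortTruth, cell_lines: list[str] | None = None
) -> tuple[DrugSensitivityTable, ResponseData]:
    """AUCs monotone in reversal strength, plus noisy responder labels.

    AUC = clip(intercept + slope * reversal_score + noise), reversal_score
    being -1 for reverser drugs and 0 otherwise, so stronger reversers are
    more sensitive (lower AUC). Responder labels come from thresholding each
    simulated patient's standardized score plus Gaussian noise at zero.
    """
    if not truth.reversal_score:
        raise ValueError("run simulate_perturbation_library first")
    rng = cfg.rng(3)
    if cell_lines is None:
        cell_lines = [f"CL-{j}" for j in range(1, cfg.k + 1)]
    rows = []
    for cell in cell_lines:
        for drug, score in truth.reversal_score.items():
            auc = (cfg.auc_intercept + cfg.auc_slope * score
                   + rng.normal(0.0, cfg.auc_noise_sd))
            rows.append((drug, cell, float(np.clip(auc, 0.05, 1.5))))
    sens = DrugSensitivityTable(
        pd.DataFrame(rows, columns=["drug", "cell_line", "auc"]))

    patients = [f"P{i + 1:03d}" for i in range(cfg.n_patients)]
    scores = {p: float(rng.normal(0.0, 1.0)) for p in patients}
    labels = {
        p: ("responder"
            if scores[p] + rng.normal(0.0, cfg.response_noise_sd) < 0.0
            else "non-responder")
        for p in patients
    }
    return sens, ResponseData(scores=scores, labels=labels)
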