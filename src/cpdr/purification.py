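"""Tumor-microenvironment scoring and expression-profile purification.

Bulk tumor profiles mix cancer cells with stromal and immune infiltrate.
Infiltration is quantified per sample by single-sample gene set enrichment
(ssGSEA) of stromal/immune signatures; subgroups whose mean infiltration
exceeds a cohort quantile are flagged for purification. Purification models
each tumor on the linear scale as a non-negative combination of normal
profiles plus a cancer-specific residual, and rescales the residual by the
estimated cancer fraction — a constrained least-squares deconvolution in the
spirit of two-component tumor purity models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize, nnls
from scipy.stats import rankdata

from .io import LOG2, ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

ALPHA_CAP = 0.99  # maximal admissible normal-contamination fraction
DEFAULT_SSGSEA_WEIGHT = 0.25
DEFAULT_INFILTRATION_QUANTILE = 0.75


@dataclass
class TMEScoreMatrix:
    """ssGSEA enrichment scores, one row per gene set, one column per sample."""

    scores: pd.DataFrame
    gene_sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("TME scores must be finite")
        if set(self.scores.index) != set(self.gene_sets):
            raise ValueError("score rows must match the gene sets used")


@dataclass
class PurificationResult:
    """Estimated contamination fractions and purified cancer-cell profiles."""

    alphas: dict[str, float]
    purified: ExpressionMatrix

    def __post_init__(self) -> None:
        for sample, alpha in self.alphas.items():
            if not 0.0 <= alpha <= ALPHA_CAP:
                raise ValueError(f"alpha for {sample} outside [0, {ALPHA_CAP}]")


def ssgsea_score(
    expr: ExpressionMatrix,
    gene_set: list[str],
    alpha_weight: float = DEFAULT_SSGSEA_WEIGHT,
) -> dict[str, float]:
    """Integrated single-sample enrichment score of one gene set per sample.

    Genes are ordered by descending expression within each sample; walking
    down the list, the running sum gains ``rank**alpha_weight`` (normalized
    over the in-set genes; rank n = highest expression) at in-set genes and
    loses ``1/(n - t)`` at out-of-set genes. The score is the sum of the
    running-sum values over all positions (integrated enrichment score), so
    it depends only on within-sample ranks.
    """
    if expr.units != LOG2:
        raise ValueError("ssGSEA expects log2-scale expression")
    genes = expr.genes
    in_set = np.array([g in set(gene_set) for g in genes])
    t = int(in_set.sum())
    n = len(genes)
    if t == 0:
        raise ValueError("gene set shares no genes with the expression matrix")
    if t == n:
        raise ValueError("gene set covers every gene; out-of-set ECDF undefined")
    scores: dict[str, float] = {}
    gene_arr = np.array(genes)
    for sample in expr.samples:
        x = expr.data[sample].to_numpy(float)
        ranks = rankdata(x, method="average")  # highest expression -> rank n
        # deterministic descending order, ties broken by gene symbol
        order = np.lexsort((gene_arr, -x))
        weights = np.where(in_set[order], ranks[order] ** alpha_weight, 0.0)
        inc = weights / weights.sum()
        dec = np.where(in_set[order], 0.0, 1.0 / (n - t))
        running = np.cumsum(inc - dec)
        scores[sample] = float(running.sum())
    return scores


def score_gene_sets(
    expr: ExpressionMatrix,
    collection: GeneSetCollection,
    alpha_weight: float = DEFAULT_SSGSEA_WEIGHT,
) -> TMEScoreMatrix:
    """ssGSEA-score every set of a collection against every sample."""
    rows = {name: ssgsea_score(expr, genes, alpha_weight)
            for name, genes in collection.sets.items()}
    scores = pd.DataFrame(rows).T[expr.samples]
    return TMEScoreMatrix(scores, dict(collection.sets))


def infiltration_flag(
    tme: TMEScoreMatrix,
    subgroup: list[str],
    set_names: list[str],
    q: float = DEFAULT_INFILTRATION_QUANTILE,
) -> tuple[float, bool]:
    """Mean stromal+immune score of a subgroup and a high-infiltration flag.

    The flag is raised when the subgroup mean of the summed named-set scores
    exceeds the ``q`` quantile of the same statistic over all cohort samples.
    """
    if not subgroup:
        raise ValueError("subgroup is empty")
    missing = [s for s in set_names if s not in tme.scores.index]
    if missing:
        raise KeyError(f"gene sets not scored: {missing}")
    totals = tme.scores.loc[set_names].sum(axis=0)
    subgroup_mean = float(totals[subgroup].mean())
    threshold = float(np.quantile(totals.to_numpy(), q))
    return subgroup_mean, subgroup_mean > threshold


def purify_profiles(
    subgroup: ExpressionMatrix,
    normals: ExpressionMatrix,
) -> PurificationResult:
    """Deconvolve each subgroup profile into contamination and cancer parts.

    On the linear scale (2**x - 1) each tumor sample y is modelled as
    y ~= N w + c with w >= 0 (weights over the normal profiles), c >= 0 and
    sum(w) = alpha <= 0.99. The purified cancer profile is
    log2(1 + max(0, (y - N w) / (1 - alpha))).
    """
    if subgroup.units != LOG2 or normals.units != LOG2:
        raise ValueError("purification expects log2-scale matrices")
    if subgroup.genes != normals.genes:
        raise ValueError("subgroup and normals must be gene-aligned")
    N = np.power(2.0, normals.values) - 1.0  # genes x normals, linear scale
    m = N.shape[1]
    design = np.column_stack([N, np.ones(N.shape[0])])
    n_genes = design.shape[0]
    G = design.T @ design / n_genes  # scaled normal equations keep SLSQP well-conditioned

    alphas: dict[str, float] = {}
    purified_cols: dict[str, np.ndarray] = {}
    for sample in subgroup.samples:
        y = np.power(2.0, subgroup.data[sample].to_numpy(float)) - 1.0
        b = design.T @ y / n_genes
        z0, _ = nnls(design, y)
        if z0[:m].sum() > ALPHA_CAP:
            z = _constrained_fit(G, b, z0, m)
        else:
            z = z0
        w = z[:m]
        alpha = float(min(w.sum(), ALPHA_CAP))
        residual = y - N @ w
        cancer = np.maximum(0.0, residual) / (1.0 - alpha)
        alphas[sample] = alpha
        purified_cols[sample] = np.log2(1.0 + cancer)
        logger.debug("purified %s: alpha=%.3f", sample, alpha)

    purified = ExpressionMatrix(
        pd.DataFrame(purified_cols, index=subgroup.genes)[subgroup.samples], LOG2
    )
    return PurificationResult(alphas, purified)


def _constrained_fit(G: np.ndarray, b: np.ndarray, z0: np.ndarray, m: int) -> np.ndarray:
    """Quadratic program: min 1/2 z'Gz - b'z, z >= 0, sum(z[:m]) <= ALPHA_CAP."""

    def objective(z: np.ndarray) -> float:
        return 0.5 * z @ G @ z - b @ z

    def gradient(z: np.ndarray) -> np.ndarray:
        return G @ z - b

    start = z0.copy()
    if start[:m].sum() > ALPHA_CAP:
        start[:m] *= ALPHA_CAP / start[:m].sum()
    result = minimize(
        objective, start, jac=gradient, method="SLSQP",
        bounds=[(0.0, None)] * len(z0),
        constraints=[{"type": "ineq",
                      "fun": lambda z: ALPHA_CAP - z[:m].sum(),
                      "jac": lambda z: np.concatenate([-np.ones(m),
                                                       np.zeros(len(z) - m)])}],
        options={"maxiter": 200, "ftol": 1e-12},
    )
    z = np.maximum(result.x, 0.0)
    if z[:m].sum() > ALPHA_CAP:
        z[:m] *= ALPHA_CAP / z[:m].sum()
    return z
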