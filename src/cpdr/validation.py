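"""In-silico validation of drug predictions against sensitivity and response data.

Three checks mirror how reversal predictions are judged: (a) the Pearson
correlation between per-drug sRGES and dose-response AUC on the
patient-matched cell line (reversal should track sensitivity), (b) a Welch
t-test of sRGES between effective and ineffective drugs on that line, and
(c) a permutation null that re-draws the patient's subgroup at random and
recomputes the correlation, with a one-sample t-test of the null against
the observed value. A fourth check scores responder/non-responder patient
labels against per-patient sRGES by t-test and ROC AUC.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import DrugSensitivityTable, ExpressionMatrix
from .subtyping import select_variant_genes, _spearman

logger = logging.getLogger(__name__)

DEFAULT_N_VARIANT_GENES = 1500
DEFAULT_N_PERM = 100
EFFICACY_SD_FACTOR = 0.5


@dataclass
class EfficacyLabels:
    """Effective/ineffective drug labels on one cell line.

    A drug is effective when its AUC is at least ``EFFICACY_SD_FACTOR``
    sample standard deviations below the mean AUC of that cell line
    (inclusive threshold).
    """

    labels: dict[str, bool]  # drug -> effective?
    mean: float
    sd: float

    @property
    def threshold(self) -> float:
        return self.mean - EFFICACY_SD_FACTOR * self.sd


@dataclass
class ValidationReport:
    """All in-silico validation outputs for one patient."""

    cell_line: str
    cell_line_rho: float
    pearson_r: float
    pearson_p: float
    t_statistic: float | None
    t_p: float | None
    null_correlations: list[float] = field(default_factory=list)
    null_t_p: float | None = None
    drugs_used: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(
                {
                    "cell_line": self.cell_line,
                    "cell_line_rho": self.cell_line_rho,
                    "pearson_r": self.pearson_r,
                    "pearson_p": self.pearson_p,
                    "t_statistic": self.t_statistic,
                    "t_p": self.t_p,
                    "null_correlations": self.null_correlations,
                    "null_t_p": self.null_t_p,
                    "drugs_used": self.drugs_used,
                },
                handle, indent=1,
            )


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the constant-vector convention r = 0 (p = 1)."""
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant vector in Pearson correlation; returning r=0")
        return 0.0, 1.0
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def match_cell_line(
    patient: pd.Series,
    cell_lines: ExpressionMatrix,
    n_genes: int = DEFAULT_N_VARIANT_GENES,
) -> tuple[str, float]:
    """The cell line most Spearman-correlated with the patient.

    Variant genes are selected by variance across the cell-line panel (at
    most ``n_genes``); ties in rho break to the lexicographically smallest
    cell line id.
    """
    if not cell_lines.samples:
        raise ValueError("cell-line matrix is empty")
    panel = cell_lines.to_log2()
    genes = select_variant_genes(panel, min(n_genes, len(panel.genes)))
    shared = [g for g in genes if g in patient.index]
    if len(shared) < 2:
        raise ValueError("fewer than 2 genes shared between patient and panel")
    pvec = patient.loc[shared].to_numpy(float)
    rhos = {cl: _spearman(pvec, panel.data.loc[shared, cl].to_numpy(float))
            for cl in panel.samples}
    best = min(rhos, key=lambda cl: (-round(rhos[cl], 12), cl))
    return best, rhos[best]


def classify_drug_efficacy(
    sens: DrugSensitivityTable, cell_line: str
) -> EfficacyLabels:
    """Label each drug on a cell line effective iff AUC <= mean - 0.5*SD."""
    aucs = sens.aucs_for(cell_line)
    if len(aucs) < 3:
        raise ValueError(
            f"cell line {cell_line!r} has {len(aucs)} drugs measured; need >=3"
        )
    mean = float(aucs.mean())
    sd = float(aucs.std(ddof=1))
    threshold = mean - EFFICACY_SD_FACTOR * sd
    labels = {drug: bool(auc <= threshold) for drug, auc in aucs.items()}
    return EfficacyLabels(labels=labels, mean=mean, sd=sd)


def validate_correlation(
    srges: Mapping[str, float],
    sens: DrugSensitivityTable,
    cell_line: str,
) -> tuple[float, float, float | None, float | None, list[str]]:
    """Pearson r (sRGES vs AUC) and Welch t of sRGES by efficacy label.

    Returns (r, p, t_statistic, t_p, drugs_used); the t-test entries are
    ``None`` when only one efficacy class is present among the shared drugs.
    """
    aucs = sens.aucs_for(cell_line)
    drugs = sorted(set(srges) & set(aucs.index))
    if len(drugs) < 3:
        raise ValueError(
            f"only {len(drugs)} drugs shared between sRGES list and "
            f"sensitivity data on {cell_line!r}; need >=3"
        )
    s = np.array([srges[d] for d in drugs], dtype=float)
    a = aucs.loc[drugs].to_numpy(float)
    r, p = _pearson(s, a)

    labels = classify_drug_efficacy(sens, cell_line).labels
    eff = np.array([srges[d] for d in drugs if labels.get(d)])
    ineff = np.array([srges[d] for d in drugs if not labels.get(d)])
    if len(eff) and len(ineff):
        t_stat, t_p = stats.ttest_ind(eff, ineff, equal_var=False)
        t_stat, t_p = float(t_stat), float(t_p)
    else:
        logger.warning("single efficacy class on %s; t-test not applicable",
                       cell_line)
        t_stat = t_p = None
    return r, p, t_stat, t_p, drugs


def permutation_null(
    subtype_samples: Sequence[str],
    subgroup_size: int,
    pipeline: Callable[[list[str]], Mapping[str, float] | None],
    sens: DrugSensitivityTable,
    cell_line: str,
    observed_r: float,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> tuple[list[float], float]:
    """Null distribution of r under random patient-subgroup assignment.

    Each replicate draws a uniformly random subgroup of ``subgroup_size``
    from the assigned subtype, pushes it through ``pipeline`` (subgroup ids
    -> per-drug sRGES mapping, or None when no signature can be built) and
    correlates the result with the cell line's AUCs. Degenerate replicates
    (no signature, constant scores) contribute r = 0. Returns the null
    correlations and the one-sample t-test p of the null against
    ``observed_r``.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    if subgroup_size >= len(subtype_samples):
        raise ValueError("subtype must be larger than the subgroup")
    rng = np.random.default_rng(seed)
    aucs = sens.aucs_for(cell_line)
    null: list[float] = []
    for i in range(n_perm):
        draw = sorted(rng.choice(len(subtype_samples), size=subgroup_size,
                                 replace=False))
        subgroup = [subtype_samples[j] for j in draw]
        scores = pipeline(subgroup)
        if not scores:
            null.append(0.0)
            continue
        drugs = sorted(set(scores) & set(aucs.index))
        if len(drugs) < 3:
            null.append(0.0)
            continue
        r, _ = _pearson(np.array([scores[d] for d in drugs], dtype=float),
                        aucs.loc[drugs].to_numpy(float))
        null.append(r)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t_p = stats.ttest_1samp(null, popmean=observed_r).pvalue
    t_p = float(t_p) if np.isfinite(t_p) else 1.0
    return null, t_p


def responder_auc(
    scores: Mapping[str, float],
    labels: Mapping[str, str],
) -> tuple[float, float]:
    """Welch t-test p and ROC AUC of per-patient sRGES against response labels.

    ``labels`` maps patient id to ``"responder"``/``"non-responder"``. Lower
    sRGES counts as more responder-like; the AUC is the Mann-Whitney
    probability that a responder scores below a non-responder (ties count
    half).
    """
    resp = np.array([scores[p] for p, lab in labels.items()
                     if lab == "responder" and p in scores], dtype=float)
    non = np.array([scores[p] for p, lab in labels.items()
                    if lab == "non-responder" and p in scores], dtype=float)
    if len(resp) == 0 or len(non) == 0:
        raise ValueError("both responder and non-responder classes must be non-empty")
    _, t_p = stats.ttest_ind(resp, non, equal_var=False)
    # U counts pairs with non-responder > responder (+ half the ties)
    u = stats.mannwhitneyu(non, resp, alternative="two-sided").statistic
    auc = float(u) / (len(resp) * len(non))
    return float(t_p), auc
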