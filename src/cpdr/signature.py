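"""Individual disease signature from subgroup-vs-control differential expression.

The built-in method is a Welch t-test per gene on log2(CPM + 1), with
Benjamini-Hochberg FDR control. The signature splits the significant genes
into an up-regulated and a down-regulated list, ordered by effect size — the
two tag lists the connectivity scoring reverses. The DE step is pluggable:
any callable producing the same table columns can stand in for the default.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import COUNTS, LOG2, ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_FDR_MAX = 0.05
DEFAULT_LFC_MIN = 1.0
DEFAULT_CAP = 100


class EmptySignatureError(ValueError):
    """No gene passed the signature thresholds on one side."""


@dataclass
class DiseaseSignature:
    """Ordered up- and down-regulated gene lists with per-gene log2FC."""

    up: list[str]
    down: list[str]
    log2_fc: dict[str, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("up and down gene lists must be disjoint")
        if not self.up or not self.down:
            raise EmptySignatureError("both signature sides must be non-empty")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump({"up": self.up, "down": self.down,
                       "log2_fc": self.log2_fc, "provenance": self.provenance},
                      handle, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "DiseaseSignature":
        with open(path) as handle:
            d = json.load(handle)
        return cls(d["up"], d["down"], d["log2_fc"], d.get("provenance", {}))

    def to_gene_sets(self, name: str = "signature") -> GeneSetCollection:
        """Two-set GMT-ready representation (name_up / name_down)."""
        return GeneSetCollection(
            sets={f"{name}_up": list(self.up), f"{name}_down": list(self.down)},
            descriptions={f"{name}_up": "up-regulated disease genes",
                          f"{name}_down": "down-regulated disease genes"},
        )


def _log_cpm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Counts -> CPM -> log2(CPM + 1); log2 input passes through."""
    if matrix.units == LOG2:
        return matrix.data
    totals = matrix.data.sum(axis=0)
    cpm = matrix.data.div(totals, axis=1) * 1e6
    return np.log2(cpm + 1.0)


def differential_expression(
    case: ExpressionMatrix, control: ExpressionMatrix
) -> pd.DataFrame:
    """Per-gene Welch t-test of case vs control on the log2 scale.

    Returns a DataFrame indexed by gene with columns ``log2_fc`` (case mean
    minus control mean), ``p_value``, ``fdr`` (Benjamini-Hochberg) and
    ``mean_expr``. Counts are normalized to log2(CPM + 1) first; genes with
    all-zero counts on both sides are dropped (count logged).
    """
    if case.genes != control.genes:
        raise ValueError("case and control must be gene-aligned")
    if case.units != control.units:
        raise ValueError("case and control must share units")
    if len(case.samples) < 2 or len(control.samples) < 2:
        raise ValueError("differential expression needs >=2 samples per side")

    if case.units == COUNTS:
        zero = (case.data.sum(axis=1) == 0) & (control.data.sum(axis=1) == 0)
        if zero.any():
            logger.info("dropping %d all-zero gene rows", int(zero.sum()))
            case = ExpressionMatrix(case.data.loc[~zero], COUNTS)
            control = ExpressionMatrix(control.data.loc[~zero], COUNTS)

    a = _log_cpm(case).to_numpy(float)
    b = _log_cpm(control).to_numpy(float)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        result = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(result.pvalue, dtype=float)
    # zero-variance genes: identical groups are null, separated groups certain
    p = np.where(np.isfinite(p), p, np.where(np.abs(lfc) > 0, 0.0, 1.0))
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2_fc": lfc,
            "p_value": p,
            "fdr": fdr,
            "mean_expr": np.concatenate([a, b], axis=1).mean(axis=1),
        },
        index=case.genes,
    )


def build_signature(
    de: pd.DataFrame,
    fdr_max: float = DEFAULT_FDR_MAX,
    lfc_min: float = DEFAULT_LFC_MIN,
    cap: int = DEFAULT_CAP,
    provenance: dict | None = None,
) -> DiseaseSignature:
    """Split a DE table into capped up/down signature gene lists.

    Genes pass with FDR < ``fdr_max`` and |log2FC| >= ``lfc_min``; each side
    keeps at most ``cap`` genes, the largest |log2FC| first (ties by gene
    symbol). Raises :class:`EmptySignatureError` when either side is empty,
    with advice to relax the thresholds.
    """
    if de.empty:
        raise ValueError("differential expression table is empty")
    passing = de[de["fdr"] < fdr_max]
    up = passing[passing["log2_fc"] >= lfc_min]
    down = passing[passing["log2_fc"] <= -lfc_min]

    def top(side: pd.DataFrame) -> list[str]:
        ordered = sorted(side.index, key=lambda g: (-abs(side.at[g, "log2_fc"]), g))
        return ordered[:cap]

    up_genes, down_genes = top(up), top(down)
    if not up_genes or not down_genes:
        raise EmptySignatureError(
            f"signature empty on the {'up' if not up_genes else 'down'} side; "
            f"relax fdr_max (now {fdr_max}) or lfc_min (now {lfc_min})"
        )
    lfc = {g: float(de.at[g, "log2_fc"]) for g in up_genes + down_genes}
    return DiseaseSignature(up_genes, down_genes, lfc, provenance or {})
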