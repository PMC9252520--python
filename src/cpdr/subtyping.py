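"""Cancer subtype recognition and patient subgroup/control selection.

The cohort is clustered by consensus non-negative matrix factorization on its
most variant genes; the number of subtypes is chosen by the cophenetic
correlation of the consensus matrix, with the average silhouette width as the
tie-breaker. The input patient is assigned to the subtype with the largest
median Spearman correlation, and its subgroup is the top-N most correlated
subtype samples — the "biological replicates" used for differential
expression. Controls are the normal samples best matched to the subgroup.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.decomposition import NMF
from sklearn.metrics import silhouette_score

from .io import LOG2, ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_N_VARIANT_GENES = 1500
DEFAULT_SUBGROUP_SIZE = 5  # middle of the supported replicate sizes {3, 5, 10}


@dataclass
class SubtypeResult:
    """Consensus-NMF subtyping of a cohort."""

    labels: dict[str, int]              # sample id -> subtype id (1-based)
    k: int                              # chosen number of subtypes
    metrics: dict[int, dict[str, float]]  # per k: cophenetic, silhouette
    consensus: pd.DataFrame             # sample x sample co-clustering frequency (chosen k)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        c = self.consensus.to_numpy()
        if not np.allclose(c, c.T):
            raise ValueError("consensus matrix must be symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("consensus diagonal must be 1")
        if c.min() < -1e-12 or c.max() > 1 + 1e-12:
            raise ValueError("consensus entries must lie in [0, 1]")
        if set(self.labels) != set(self.consensus.index):
            raise ValueError("labels must cover all cohort samples")

    def samples_in(self, subtype: int) -> list[str]:
        return [s for s, lab in self.labels.items() if lab == subtype]

    def to_json_dict(self) -> dict:
        return {
            "labels": self.labels,
            "k": self.k,
            "metrics": {str(k): m for k, m in self.metrics.items()},
            "samples": list(self.consensus.index),
            "consensus": self.consensus.to_numpy().tolist(),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SubtypeResult":
        samples = d["samples"]
        return cls(
            labels={s: int(v) for s, v in d["labels"].items()},
            k=int(d["k"]),
            metrics={int(k): m for k, m in d["metrics"].items()},
            consensus=pd.DataFrame(d["consensus"], index=samples, columns=samples),
        )


@dataclass
class SubgroupResult:
    """Patient subgroup (top-N correlated subtype samples) and matched controls."""

    patient_id: str
    subtype: int
    subgroup: list[str]
    controls: list[str] = field(default_factory=list)
    similarity: dict[str, float] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "subtype": self.subtype,
            "subgroup": self.subgroup,
            "controls": self.controls,
            "similarity": self.similarity,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SubgroupResult":
        return cls(d["patient_id"], int(d["subtype"]), list(d["subgroup"]),
                   list(d["controls"]), dict(d["similarity"]))


def select_variant_genes(expr: ExpressionMatrix, n: int) -> list[str]:
    """The ``n`` genes with the largest sample variance, most variant first.

    Ties are broken by gene symbol, lexicographically, so the selection is
    deterministic. Requires log2-scale input.
    """
    if expr.units != LOG2:
        raise ValueError("variant-gene selection expects log2-scale expression")
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(expr.genes):
        raise ValueError(f"requested {n} genes but matrix has {len(expr.genes)}")
    variances = expr.data.var(axis=1, ddof=1)
    order = sorted(expr.genes, key=lambda g: (-variances[g], g))
    return order[:n]


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with the constant-vector convention rho = 0."""
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant vector in Spearman correlation; returning 0")
        return 0.0
    rho = spearmanr(x, y).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def consensus_subtype(
    expr: ExpressionMatrix,
    genes: list[str],
    k_range: range = range(2, 7),
    n_runs: int = 30,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> SubtypeResult:
    """Consensus NMF clustering of cohort samples over ``genes``.

    For each candidate k, ``n_runs`` multiplicative-update Frobenius NMF
    factorizations from random non-negative initializations each assign every
    sample to its argmax metagene; the fraction of runs in which two samples
    co-cluster forms the consensus matrix. Final labels come from
    average-linkage hierarchical clustering of 1 - consensus. The chosen k
    maximizes the cophenetic correlation, ties broken by average silhouette
    width, then by the smaller k.
    """
    if min(k_range) < 2:
        raise ValueError("k_range minimum must be >= 2")
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if expr.units != LOG2:
        raise ValueError("consensus subtyping expects log2-scale expression")

    sub = expr.select_genes(genes)
    X = sub.values.astype(float)
    # shift each gene to be non-negative before factorization
    X = X - X.min(axis=1, keepdims=True)
    samples = sub.samples
    n_samples = len(samples)
    rng = np.random.default_rng(seed)

    metrics: dict[int, dict[str, float]] = {}
    consensus_by_k: dict[int, np.ndarray] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_range:
        co = np.zeros((n_samples, n_samples))
        for _ in range(n_runs):
            run_seed = int(rng.integers(0, 2**31 - 1))
            model = NMF(n_components=k, init="random", solver="mu",
                        beta_loss="frobenius", max_iter=max_iter, tol=tol,
                        random_state=run_seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X)
            assign = np.argmax(model.components_, axis=0)  # per-sample metagene
            co += (assign[:, None] == assign[None, :]).astype(float)
        consensus = co / n_runs
        np.fill_diagonal(consensus, 1.0)
        consensus = (consensus + consensus.T) / 2.0

        dist = 1.0 - consensus
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
        Z = linkage(condensed, method="average")
        labels = fcluster(Z, t=k, criterion="maxclust")
        coph = _cophenetic_correlation(Z, condensed)
        sil = _safe_silhouette(dist, labels)
        metrics[k] = {"cophenetic": coph, "silhouette": sil}
        consensus_by_k[k] = consensus
        labels_by_k[k] = labels
        logger.info("k=%d cophenetic=%.4f silhouette=%.4f", k, coph, sil)

    best_k = min(
        k_range,
        key=lambda k: (-round(metrics[k]["cophenetic"], 9),
                       -round(metrics[k]["silhouette"], 9), k),
    )
    labels = _relabel_by_first_appearance(labels_by_k[best_k])
    consensus_df = pd.DataFrame(consensus_by_k[best_k], index=samples, columns=samples)
    return SubtypeResult(
        labels={s: int(lab) for s, lab in zip(samples, labels)},
        k=best_k,
        metrics=metrics,
        consensus=consensus_df,
    )


def _cophenetic_correlation(Z: np.ndarray, condensed: np.ndarray) -> float:
    if np.allclose(condensed, condensed[0] if condensed.size else 0.0):
        return 0.0  # degenerate: constant distances carry no hierarchy signal
    coph, _ = cophenet(Z, condensed)
    return float(coph) if np.isfinite(coph) else 0.0


def _safe_silhouette(dist: np.ndarray, labels: np.ndarray) -> float:
    if len(np.unique(labels)) < 2 or len(np.unique(labels)) >= len(labels):
        return -1.0
    try:
        return float(silhouette_score(dist, labels, metric="precomputed"))
    except ValueError:
        return -1.0


def _relabel_by_first_appearance(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster labels 1, 2, ... in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def subtype_similarity(
    patient: pd.Series,
    cohort: ExpressionMatrix,
    result: SubtypeResult,
    genes: list[str],
) -> tuple[dict[int, float], int, dict[str, float]]:
    """Median Spearman similarity of the patient to each subtype.

    Returns (per-subtype similarity, assigned subtype, per-sample rho). The
    assigned subtype maximizes the median rho; ties go to the smallest
    subtype id.
    """
    shared = [g for g in genes if g in patient.index and g in set(cohort.genes)]
    if len(shared) < 2:
        raise ValueError("fewer than 2 genes shared between patient and cohort")
    pvec = patient.loc[shared].to_numpy(float)
    sample_rho: dict[str, float] = {}
    cohort_sub = cohort.data.loc[shared]
    for sample in cohort.samples:
        sample_rho[sample] = _spearman(pvec, cohort_sub[sample].to_numpy(float))
    per_subtype: dict[int, float] = {}
    for subtype in sorted(set(result.labels.values())):
        members = result.samples_in(subtype)
        per_subtype[subtype] = float(np.median([sample_rho[s] for s in members]))
    assigned = min(per_subtype, key=lambda s: (-per_subtype[s], s))
    return per_subtype, assigned, sample_rho


def select_subgroup(
    patient_id: str,
    sample_rho: dict[str, float],
    result: SubtypeResult,
    subtype: int,
    n: int = DEFAULT_SUBGROUP_SIZE,
) -> SubgroupResult:
    """Top-``n`` subtype samples by Spearman rho to the patient."""
    members = result.samples_in(subtype)
    if n > len(members):
        raise ValueError(f"subgroup size {n} exceeds subtype size {len(members)}")
    ordered = sorted(members, key=lambda s: (-sample_rho[s], s))
    subgroup = ordered[:n]
    return SubgroupResult(
        patient_id=patient_id,
        subtype=subtype,
        subgroup=subgroup,
        similarity={s: sample_rho[s] for s in members},
    )


def select_controls(
    subgroup_expr: ExpressionMatrix,
    normal_pool: ExpressionMatrix,
    n: int,
    genes: list[str],
) -> list[str]:
    """The ``n`` normal samples with the largest median Spearman rho to the subgroup.

    A correlation-based stand-in for matched-control selection: controls are
    the normals whose expression over ``genes`` best tracks the subgroup
    members. Ties break by sample id.
    """
    if n > len(normal_pool.samples):
        raise ValueError(f"requested {n} controls but pool has "
                         f"{len(normal_pool.samples)} samples")
    shared = [g for g in genes
              if g in set(subgroup_expr.genes) and g in set(normal_pool.genes)]
    if len(shared) < 2:
        raise ValueError("fewer than 2 genes shared with the normal pool")
    sub = subgroup_expr.data.loc[shared]
    pool = normal_pool.data.loc[shared]
    medians: dict[str, float] = {}
    for normal in normal_pool.samples:
        nvec = pool[normal].to_numpy(float)
        rhos = [_spearman(nvec, sub[s].to_numpy(float)) for s in subgroup_expr.samples]
        medians[normal] = float(np.median(rhos))
    ordered = sorted(normal_pool.samples, key=lambda s: (-medians[s], s))
    return ordered[:n]
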