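"""Readers/writers for the formats the pipeline touches, plus gene alignment.

Expression matrices travel as TSV/CSV with genes in rows and one header row
of sample identifiers; gene sets as GMT; drug sensitivity as a three-column
CSV (drug, cell_line, auc); perturbation libraries as long-form TSV or HDF5.
Gene identifiers are plain, case-sensitive symbols throughout — no
identifier translation is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COUNTS = "counts"
LOG2 = "log2"
_UNITS = (COUNTS, LOG2)


class FormatError(ValueError):
    """A file violated its declared format."""


@dataclass
class ExpressionMatrix:
    """Gene x sample numeric expression matrix with a units tag.

    ``data`` is a DataFrame with gene symbols as the index and sample
    identifiers as columns; ``units`` is ``"counts"`` (non-negative raw
    counts) or ``"log2"`` (log2-scale values).
    """

    data: pd.DataFrame
    units: str

    def __post_init__(self) -> None:
        if self.units not in _UNITS:
            raise ValueError(f"units must be one of {_UNITS}, got {self.units!r}")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("expression matrix is empty")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            raise ValueError("expression values must be finite")
        if self.units == COUNTS and (values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def to_log2(self) -> "ExpressionMatrix":
        """Return a log2-scale copy; counts are transformed as log2(x + 1)."""
        if self.units == LOG2:
            return ExpressionMatrix(self.data.copy(), LOG2)
        return ExpressionMatrix(np.log2(self.data + 1.0), LOG2)

    def select_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(genes)], self.units)

    def select_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data[list(samples)], self.units)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. stromal/immune signatures) with descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


@dataclass
class DrugSensitivityTable:
    """Dose-response AUC per (drug, cell line), aggregated to unique pairs."""

    data: pd.DataFrame  # columns: drug, cell_line, auc

    def __post_init__(self) -> None:
        required = {"drug", "cell_line", "auc"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"sensitivity table needs columns {sorted(required)}")
        if self.data.duplicated(["drug", "cell_line"]).any():
            raise ValueError("(drug, cell line) pairs must be unique after aggregation")
        auc = self.data["auc"].to_numpy(float)
        if not np.isfinite(auc).all():
            raise ValueError("AUC values must be finite")
        if (auc < 0).any():
            raise ValueError("AUC values must be non-negative")

    def aucs_for(self, cell_line: str) -> pd.Series:
        """AUC per drug on one cell line, indexed by drug id."""
        sub = self.data[self.data["cell_line"] == cell_line]
        return sub.set_index("drug")["auc"].sort_index()


@dataclass
class PerturbationRecord:
    """One drug treatment with a full-ranked gene signature.

    ``ranking`` maps every gene of the library universe to a rank in 1..n,
    rank 1 being the gene most up-regulated by the treatment.
    """

    drug: str
    cell_line: str
    dose_um: float
    time_h: float
    ranking: pd.Series  # index: gene symbols, values: ranks 1..n

    def __post_init__(self) -> None:
        if self.dose_um <= 0:
            raise ValueError("dose must be positive")
        if self.time_h <= 0:
            raise ValueError("time must be positive")
        n = len(self.ranking)
        ranks = np.sort(self.ranking.to_numpy())
        if n == 0 or not np.array_equal(ranks, np.arange(1, n + 1)):
            raise ValueError(
                f"ranking of {self.drug}@{self.cell_line} is not a permutation of 1..{n}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.ranking)


@dataclass
class PerturbationLibrary:
    """Collection of PerturbationRecord sharing one gene universe."""

    records: list[PerturbationRecord]
    universe: list[str]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        if len(uni) != len(self.universe):
            raise ValueError("gene universe contains duplicates")
        for rec in self.records:
            if set(rec.ranking.index) != uni:
                raise ValueError(
                    f"record {rec.drug}@{rec.cell_line} does not cover the gene universe"
                )

    @property
    def drugs(self) -> list[str]:
        return sorted({rec.drug for rec in self.records})


# ---------------------------------------------------------------------------
# expression matrices


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression_matrix(path: str | Path, units: str) -> ExpressionMatrix:
    """Read a genes-in-rows TSV/CSV expression table.

    Duplicate gene rows are collapsed by summation for counts (counts are
    additive) and by the mean for log2 values. Any non-numeric cell raises a
    :class:`FormatError` naming the offending gene/sample coordinate.
    """
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str,
                      keep_default_na=False)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise FormatError(f"{path}: empty expression matrix")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        gene = bad.index[bad.any(axis=1)][0]
        sample = bad.columns[bad.loc[gene]][0]
        raise FormatError(
            f"{path}: non-numeric value {raw.loc[gene, sample]!r} "
            f"at gene {gene!r}, sample {sample!r}"
        )
    # exact float() conversion round-trips repr()-formatted values bit-for-bit
    numeric = pd.DataFrame(raw.to_numpy(dtype=np.float64),
                           index=raw.index, columns=raw.columns)
    numeric.index = numeric.index.astype(str)
    if numeric.index.has_duplicates:
        n_dup = int(numeric.index.duplicated().sum())
        agg = "sum" if units == COUNTS else "mean"
        logger.info("collapsing %d duplicate gene rows by %s", n_dup, agg)
        grouped = numeric.groupby(level=0, sort=False)
        numeric = grouped.sum() if units == COUNTS else grouped.mean()
    return ExpressionMatrix(numeric, units)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix so that :func:`read_expression_matrix` round-trips it."""
    df = matrix.data.copy()
    df.index.name = "gene"
    # repr() keeps full float precision through the text round-trip
    df.to_csv(path, sep=_sep_for(path), float_format=lambda x: repr(float(x)))


def align_genes(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their shared genes, in identical order.

    The order of ``a`` is kept for the shared genes; disjoint gene sets are
    an error.
    """
    shared = [g for g in a.genes if g in set(b.genes)]
    if not shared:
        raise ValueError("no shared genes between the two matrices")
    return a.select_genes(shared), b.select_genes(shared)


def batch_center(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Per-gene batch mean-centering on the log2 scale.

    Each matrix is treated as one batch: its per-gene mean is replaced by the
    pooled per-gene grand mean (all samples of both batches). Equivalent to a
    batch-only linear batch-effect removal. Inputs must be gene-aligned and
    log2-scale.
    """
    if a.units != LOG2 or b.units != LOG2:
        raise ValueError("batch centering requires log2-scale matrices")
    if a.genes != b.genes:
        raise ValueError("matrices must be gene-aligned (run align_genes first)")
    pooled = pd.concat([a.data, b.data], axis=1)
    grand = pooled.mean(axis=1)
    a_centered = a.data.sub(a.data.mean(axis=1), axis=0).add(grand, axis=0)
    b_centered = b.data.sub(b.data.mean(axis=1), axis=0).add(grand, axis=0)
    return ExpressionMatrix(a_centered, LOG2), ExpressionMatrix(b_centered, LOG2)


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name<TAB>description<TAB>gene1<TAB>gene2..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            handle.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# drug sensitivity


def read_drug_sensitivity(path: str | Path) -> DrugSensitivityTable:
    """Read a drug,cell_line,auc CSV; repeated pairs aggregate by median AUC."""
    df = pd.read_csv(path, dtype={"drug": str, "cell_line": str})
    required = {"drug", "cell_line", "auc"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: needs columns {sorted(required)}")
    if (df["auc"].to_numpy(float) < 0).any():
        raise FormatError(f"{path}: negative AUC values")
    agg = (
        df.groupby(["drug", "cell_line"], as_index=False, sort=True)["auc"].median()
    )
    return DrugSensitivityTable(agg)


def write_drug_sensitivity(table: DrugSensitivityTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# perturbation libraries

_LIB_COLUMNS = ["drug", "cell_line", "dose_um", "time_h", "gene", "rank"]


def read_perturbation_library(path: str | Path) -> PerturbationLibrary:
    """Read a perturbation library from long-form TSV or HDF5 (by extension)."""
    if str(path).endswith((".h5", ".hdf5")):
        return _read_library_hdf5(path)
    df = pd.read_csv(path, sep="\t",
                     dtype={"drug": str, "cell_line": str, "gene": str})
    missing = [c for c in _LIB_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records = []
    universe: list[str] | None = None
    keys = ["drug", "cell_line", "dose_um", "time_h"]
    for (drug, cell, dose, time), grp in df.groupby(keys, sort=True):
        ranking = pd.Series(grp["rank"].to_numpy(int), index=grp["gene"].to_numpy())
        records.append(PerturbationRecord(drug, cell, float(dose), float(time),
                                          ranking.sort_index()))
        if universe is None:
            universe = sorted(ranking.index)
    if universe is None:
        raise FormatError(f"{path}: empty perturbation library")
    return PerturbationLibrary(records, universe)


def write_perturbation_library(lib: PerturbationLibrary, path: str | Path) -> None:
    if str(path).endswith((".h5", ".hdf5")):
        _write_library_hdf5(lib, path)
        return
    rows = []
    for rec in lib.records:
        for gene, rank in rec.ranking.items():
            rows.append((rec.drug, rec.cell_line, rec.dose_um, rec.time_h,
                         gene, int(rank)))
    pd.DataFrame(rows, columns=_LIB_COLUMNS).to_csv(path, sep="\t", index=False)


def _write_library_hdf5(lib: PerturbationLibrary, path: str | Path) -> None:
    genes = list(lib.universe)
    ranks = np.array([rec.ranking.loc[genes].to_numpy() for rec in lib.records],
                     dtype=np.int32)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("ranks", data=ranks)
        h5.create_dataset("genes", data=np.array(genes, dtype="S"))
        h5.create_dataset("drug", data=np.array([r.drug for r in lib.records], dtype="S"))
        h5.create_dataset("cell_line",
                          data=np.array([r.cell_line for r in lib.records], dtype="S"))
        h5.create_dataset("dose_um", data=[r.dose_um for r in lib.records])
        h5.create_dataset("time_h", data=[r.time_h for r in lib.records])


def _read_library_hdf5(path: str | Path) -> PerturbationLibrary:
    with h5py.File(path, "r") as h5:
        genes = [g.decode() for g in h5["genes"][()]]
        ranks = h5["ranks"][()]
        drugs = [d.decode() for d in h5["drug"][()]]
        cells = [c.decode() for c in h5["cell_line"][()]]
        doses = h5["dose_um"][()]
        times = h5["time_h"][()]
    records = [
        PerturbationRecord(drugs[i], cells[i], float(doses[i]), float(times[i]),
                           pd.Series(ranks[i].astype(np.int64), index=genes))
        for i in range(len(drugs))
    ]
    return PerturbationLibrary(records, sorted(genes))
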