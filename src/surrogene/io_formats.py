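"""Readers, writers and validated domain containers.

Every downstream stage consumes only the three containers defined here:

* :class:`ExpressionMatrix` — a genes × samples numeric matrix carrying a
  ``value_space`` flag so that log transformation is applied exactly once.
* :class:`GeneSet` / :class:`GeneSetCollection` — named gene lists, read from
  GMT (the MSigDB interchange format: one tab-separated set per line).
* :class:`ClinicalTable` — per-patient cohort, tumor type, overall survival,
  RECIST category and response duration.

Gene identifiers are matched case-sensitively and exactly; alias mapping is a
data-preparation concern and is out of scope here.  Missing expression values
are rejected: rank-based enrichment scores are undefined for missing data, so
the caller must impute or filter first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "ClinicalTable",
    "ParseError",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "RECIST_CODES",
]

RECIST_CODES = ("CR", "PR", "SD", "PD", "NA")


class ParseError(ValueError):
    """Malformed input file (bad header, non-numeric cell, short GMT line...)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes × samples expression matrix.

    Parameters
    ----------
    gene_ids, sample_ids
        Unique identifiers for rows and columns.
    values
        ``(n_genes, n_samples)`` float array; must be finite, and non-negative
        when ``value_space == "linear"`` (FPKM-like units).
    value_space
        ``"linear"`` for FPKM-scale values, ``"log"`` for already-log values.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    value_space: str = "linear"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.value_space not in ("linear", "log"):
            raise ValueError(f"value_space must be 'linear' or 'log', got {self.value_space!r}")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (impute or filter first)")
        if self.value_space == "linear" and np.any(self.values < 0):
            raise ValueError("linear-space (FPKM) values must be non-negative")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_row(self, gene_id: str) -> np.ndarray:
        """Expression vector (over samples) for one gene."""
        return self.values[self._gene_index[gene_id]]

    def gene_indices(self, genes: Iterable[str]) -> np.ndarray:
        """Row indices of the given genes, silently dropping unmeasured ones."""
        return np.array([self._gene_index[g] for g in genes if g in self._gene_index], dtype=int)

    def log2p1(self) -> "ExpressionMatrix":
        """Return a log-space copy: log2(x + 1) if linear, identity if already log."""
        if self.value_space == "log":
            return self
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            values=np.log2(self.values + 1.0),
            value_space="log",
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (pathway, signature or marker panel)."""

    name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(str(g) for g in self.genes))

    def __len__(self) -> int:
        return len(self.genes)


class GeneSetCollection:
    """Ordered collection of uniquely named gene sets."""

    def __init__(self, sets: Iterable[GeneSet] = ()):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.name in self._sets:
                raise ValueError(f"duplicate gene set name {s.name!r}")
            self._sets[s.name] = s

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    @property
    def names(self) -> list[str]:
        return list(self._sets)


@dataclass
class ClinicalTable:
    """Per-patient clinical annotations as a validated DataFrame wrapper.

    Columns: ``patient_id, cohort_id, tumor_type, os_months, event, recist,
    response_duration_months``.  ``event`` is 1 for death, 0 for censoring;
    ``recist`` is one of CR/PR/SD/PD/NA; the response duration may be NaN.
    """

    frame: pd.DataFrame = field(repr=False)

    REQUIRED = (
        "patient_id",
        "cohort_id",
        "tumor_type",
        "os_months",
        "event",
        "recist",
        "response_duration_months",
    )

    def __post_init__(self) -> None:
        df = self.frame.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"clinical table missing required columns: {missing}")
        df["patient_id"] = df["patient_id"].astype(str)
        if df["patient_id"].duplicated().any():
            dups = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
            raise ValueError(f"duplicate patient_id values: {dups}")
        df["os_months"] = pd.to_numeric(df["os_months"])
        if not np.all(np.isfinite(df["os_months"])):
            raise ValueError("os_months must be finite")
        if (df["os_months"] < 0).any():
            bad = df.loc[df["os_months"] < 0, "patient_id"].tolist()
            raise ValueError(f"negative os_months for patients {bad}")
        df["event"] = pd.to_numeric(df["event"]).astype(int)
        if not df["event"].isin([0, 1]).all():
            raise ValueError("event must be 0 (censored) or 1 (death)")
        df["recist"] = df["recist"].fillna("NA").astype(str)
        bad = sorted(set(df["recist"]) - set(RECIST_CODES))
        if bad:
            raise ValueError(f"unknown RECIST codes {bad}; allowed: {RECIST_CODES}")
        df["response_duration_months"] = pd.to_numeric(df["response_duration_months"])
        neg = df["response_duration_months"] < 0
        if neg.any():
            raise ValueError("response_duration_months must be non-negative")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def patient_ids(self) -> list[str]:
        return self.frame["patient_id"].tolist()

    def strata(self, column: str = "tumor_type") -> dict[str, str]:
        """Mapping patient_id -> stratum label (tumor type by default)."""
        return dict(zip(self.frame["patient_id"], self.frame[column].astype(str)))


# ---------------------------------------------------------------------------
# expression I/O
# ---------------------------------------------------------------------------


def _collapse_duplicate_genes(df: pd.DataFrame, how: str) -> pd.DataFrame:
    dup = df.index.duplicated(keep=False)
    if dup.any():
        names = sorted(set(df.index[dup]))
        logger.warning(
            "collapsing %d duplicated gene ids by %s: %s%s",
            len(names), how, names[:5], "..." if len(names) > 5 else "",
        )
        grouped = df.groupby(level=0, sort=False)
        df = grouped.max() if how == "max" else grouped.mean()
    return df


def read_expression(
    path: str | Path,
    value_space: str = "linear",
    collapse: str = "max",
) -> ExpressionMatrix:
    """Read a genes × samples expression matrix.

    Accepts a delimited text table (genes in rows, header row of sample IDs;
    TSV or CSV sniffed from the extension) or a MatrixMarket triplet: a
    ``.mtx`` file with ``<stem>.genes.tsv`` / ``<stem>.samples.tsv`` sidecars
    listing row and column identifiers, one per line.

    Duplicate gene rows are collapsed (``collapse='max'`` by default, ``'mean'``
    available) with a logged warning.  Non-numeric cells and duplicate sample
    IDs raise :class:`ParseError` naming the offending coordinate.
    """
    path = Path(path)
    if collapse not in ("max", "mean"):
        raise ValueError("collapse must be 'max' or 'mean'")
    if path.suffix == ".mtx":
        from scipy.io import mmread

        genes_path = path.with_suffix(".genes.tsv")
        samples_path = path.with_suffix(".samples.tsv")
        for sidecar in (genes_path, samples_path):
            if not sidecar.exists():
                raise ParseError(f"missing MTX sidecar file {sidecar}")
        mat = np.asarray(mmread(path).todense() if hasattr(mmread(path), "todense") else mmread(path))
        mat = np.asarray(mat, dtype=float)
        genes = genes_path.read_text().split()
        samples = samples_path.read_text().split()
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        dup = [s for s in set(header) if header.count(s) > 1]
        if dup:
            raise ParseError(f"duplicate sample IDs in header of {path}: {sorted(dup)}")
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # malformed header / ragged rows
            raise ParseError(f"cannot parse expression table {path}: {exc}") from exc
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad.argmax()]
                raise ParseError(
                    f"non-numeric cell at gene {gene!r}, sample {col!r} in {path}"
                )
            df[col] = coerced
        if df.isna().any().any():
            cell = np.argwhere(df.isna().to_numpy())[0]
            raise ParseError(
                f"missing value at gene {df.index[cell[0]]!r}, "
                f"sample {df.columns[cell[1]]!r} in {path}"
            )
    df.index = df.index.astype(str)
    df = _collapse_duplicate_genes(df, collapse)
    return ExpressionMatrix(
        gene_ids=list(df.index),
        sample_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        value_space=value_space,
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix as TSV (genes in rows)."""
    expr.to_frame().to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets from a GMT file (``name TAB description TAB gene...``).

    Within-set duplicate genes are dropped with a warning; a line with fewer
    than three fields raises :class:`ParseError` with its line number.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if len(set(genes)) != len(genes):
                logger.warning(
                    "%s:%d: gene set %r contains duplicate genes; deduplicating",
                    path, lineno, name,
                )
            sets.append(GeneSet(name=name, description=desc, genes=frozenset(genes)))
    return GeneSetCollection(sets)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


# ---------------------------------------------------------------------------
# clinical I/O
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS: Mapping[str, str] = {c: c for c in ClinicalTable.REQUIRED}


def read_clinical(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> ClinicalTable:
    """Read a clinical table from a delimited file.

    ``column_map`` maps the canonical column names (see
    :attr:`ClinicalTable.REQUIRED`) to the names used in the file; identity by
    default.  Missing RECIST entries are coded ``NA``; a missing response
    duration becomes NaN.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep)
    colmap = dict(_DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)
    out = {}
    for canonical, actual in colmap.items():
        if actual not in raw.columns:
            if canonical == "response_duration_months":
                out[canonical] = np.nan
                continue
            raise ParseError(f"{path}: missing required column {actual!r} ({canonical})")
        out[canonical] = raw[actual]
    return ClinicalTable(pd.DataFrame(out))


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)
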