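"""Data containers and delimited-text I/O for the two molecular modalities.

Matrices are stored dense, samples in rows.  DNA methylation holds beta
values (per-CpG methylation fractions in [0, 1], NaN marking a missing
measurement); gene expression holds either raw read counts or
log2-transformed GeTMM-normalized values, tracked by a ``state`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pandas.errors


class MatrixParseError(ValueError):
    """A delimited matrix file could not be tokenized."""


class MatrixValidationError(ValueError):
    """A parsed matrix violates a container invariant."""


def _check_unique(ids, what: str) -> list:
    ids = [str(i) for i in ids]
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise MatrixValidationError(f"duplicate {what} ids: {dups[:5]}")
    return ids


@dataclass
class MethylationMatrix:
    """Samples x CpGs matrix of beta values in [0, 1] (NaN = missing)."""

    sample_ids: list
    cpg_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.cpg_ids = _check_unique(self.cpg_ids, "CpG")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.cpg_ids)):
            raise MatrixValidationError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.cpg_ids)} CpGs"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.values < 0) | (self.values > 1)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise MatrixValidationError(
                f"beta value {self.values[r, c]} outside [0, 1] at "
                f"sample {self.sample_ids[r]!r}, CpG {self.cpg_ids[c]!r}"
            )

    @property
    def feature_ids(self) -> list:
        return self.cpg_ids

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.cpg_ids)

    def subset_samples(self, ids) -> "MethylationMatrix":
        idx = [self.sample_ids.index(i) for i in ids]
        return MethylationMatrix(list(ids), list(self.cpg_ids), self.values[idx])


RAW_COUNTS = "raw_counts"
LOG2_GETMM = "log2_getmm"


@dataclass
class ExpressionMatrix:
    """Samples x genes matrix: raw counts, or log2 GeTMM after normalization."""

    sample_ids: list
    gene_ids: list
    values: np.ndarray
    state: str = RAW_COUNTS

    def __post_init__(self):
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise MatrixValidationError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if self.state not in (RAW_COUNTS, LOG2_GETMM):
            raise MatrixValidationError(f"unknown state {self.state!r}")
        if not np.isfinite(self.values).all():
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise MatrixValidationError(
                f"non-finite value at sample {self.sample_ids[r]!r}, "
                f"gene {self.gene_ids[c]!r}"
            )
        if (self.values < 0).any():
            r, c = np.argwhere(self.values < 0)[0]
            raise MatrixValidationError(
                f"negative value {self.values[r, c]} at sample "
                f"{self.sample_ids[r]!r}, gene {self.gene_ids[c]!r}"
            )
        if self.state == RAW_COUNTS and np.any(self.values % 1 != 0):
            r, c = np.argwhere(self.values % 1 != 0)[0]
            raise MatrixValidationError(
                f"non-integer count {self.values[r, c]} at sample "
                f"{self.sample_ids[r]!r}, gene {self.gene_ids[c]!r}"
            )

    @property
    def feature_ids(self) -> list:
        return self.gene_ids

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def subset_samples(self, ids) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(i) for i in ids]
        return ExpressionMatrix(list(ids), list(self.gene_ids), self.values[idx], self.state)


ANNOTATION_COLUMNS = ("gene_id", "chromosome", "length_bp", "biotype", "symbol")


@dataclass
class GeneAnnotation:
    """Per-gene annotation: chromosome, length in bp, biotype, symbol."""

    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise MatrixValidationError(f"annotation missing columns: {missing}")
        self.table = self.table.loc[:, list(ANNOTATION_COLUMNS)].copy()
        self.table["gene_id"] = self.table["gene_id"].astype(str)
        if self.table["gene_id"].duplicated().any():
            raise MatrixValidationError("duplicate gene_id rows in annotation")
        self.table["length_bp"] = self.table["length_bp"].astype(int)
        if (self.table["length_bp"] < 1).any():
            bad = self.table.loc[self.table["length_bp"] < 1, "gene_id"].tolist()
            raise MatrixValidationError(f"non-positive gene length for: {bad[:5]}")
        self.table = self.table.set_index("gene_id", drop=False)

    def require(self, gene_ids) -> pd.DataFrame:
        """Return annotation rows for *gene_ids*; error on unannotated ids."""
        missing = [g for g in gene_ids if g not in self.table.index]
        if missing:
            raise MatrixValidationError(f"unannotated gene ids: {missing[:10]}")
        return self.table.loc[list(gene_ids)]

    @classmethod
    def read_tsv(cls, path) -> "GeneAnnotation":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class LabeledCohort:
    """Mapping sample id -> subtype label (or B_OTHER / CONTROL)."""

    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = {str(k): str(v) for k, v in self.labels.items()}

    @property
    def sample_ids(self) -> list:
        return list(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, sample_id: str) -> str:
        return self.labels[sample_id]

    def subset(self, ids) -> "LabeledCohort":
        return LabeledCohort({i: self.labels[i] for i in ids})

    def counts(self) -> pd.Series:
        return pd.Series(self.labels, dtype=object).value_counts().sort_index()

    @classmethod
    def read_tsv(cls, path) -> "LabeledCohort":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))

    def write_tsv(self, path) -> None:
        pd.DataFrame(
            {"sample_id": list(self.labels), "label": list(self.labels.values())}
        ).to_csv(path, sep="\t", index=False)


def _read_table(path):
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    try:
        # round_trip parsing keeps serialized float64 values bit-exact
        return pd.read_csv(
            path, sep=sep, index_col=0, float_precision="round_trip"
        )
    except pandas.errors.ParserError as exc:
        raise MatrixParseError(f"{path}: {exc}") from exc


def load_matrix(path, modality: str, *, sample_ids=None, orientation: str = "auto"):
    """Load a delimited matrix file as a validated modality matrix.

    Parameters
    ----------
    path : str or Path
        Tab- or comma-delimited text with one header row and row ids in
        the first column.
    modality : {"dnam", "gex"}
        Selects the container (and its invariants).
    sample_ids : iterable of str, optional
        Known sample ids; when given, orientation is auto-detected by id
        overlap with rows vs columns.  Without it, features are assumed
        to be in rows (samples in columns).
    orientation : {"auto", "samples_in_rows", "features_in_rows"}
        Force an orientation instead of detecting it.
    """
    if modality not in ("dnam", "gex"):
        raise ValueError(f"modality must be 'dnam' or 'gex', got {modality!r}")
    df = _read_table(path)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    if orientation == "auto":
        if sample_ids is not None:
            known = set(map(str, sample_ids))
            in_rows = len(known.intersection(df.index))
            in_cols = len(known.intersection(df.columns))
            orientation = "samples_in_rows" if in_rows >= in_cols else "features_in_rows"
        else:
            orientation = "features_in_rows"
    if orientation == "features_in_rows":
        df = df.T
    elif orientation != "samples_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    values = df.to_numpy(dtype=float)
    if modality == "dnam":
        return MethylationMatrix(list(df.index), list(df.columns), values)
    return ExpressionMatrix(list(df.index), list(df.columns), values, RAW_COUNTS)


def write_matrix(matrix, path, *, orientation: str = "features_in_rows", sep: str = "\t") -> None:
    """Write a modality matrix as delimited text (features in rows by default)."""
    df = matrix.to_frame()
    if orientation == "features_in_rows":
        df = df.T
    elif orientation != "samples_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    # %.17g round-trips float64 exactly
    df.to_csv(path, sep=sep, float_format="%.17g")


__all__ = [
    "MethylationMatrix",
    "ExpressionMatrix",
    "GeneAnnotation",
    "LabeledCohort",
    "MatrixParseError",
    "MatrixValidationError",
    "RAW_COUNTS",
    "LOG2_GETMM",
    "load_matrix",
    "write_matrix",
    "replace",
]
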