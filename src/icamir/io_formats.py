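"""Readers, writers and preprocessing for the external formats the pipeline
touches: tab-separated expression matrices, sample-design tables, FASTA
(RNA/DNA), GMT gene-set collections, and flat result tables with JSON
provenance sidecars.

Expression values are assumed to be on the log2 scale throughout (as produced
by standard array summarization); "ratios" are therefore differences.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTUN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ConfigurationError(ValueError):
    """Raised when inputs are structurally valid but inconsistent with the
    requested operation (e.g. no control samples flagged)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A features x samples grid of log2-scale values with unique ids.

    ``row_ids`` index genes (or miRNAs), ``col_ids`` index samples.
    """

    row_ids: list
    col_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.row_ids = list(self.row_ids)
        self.col_ids = list(self.col_ids)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.row_ids)) != len(self.row_ids):
            raise FormatError("duplicate row identifiers")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise FormatError("duplicate column identifiers")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise FormatError(
                f"value grid shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.col_ids)} columns"
            )

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def n_cols(self) -> int:
        return len(self.col_ids)

    def row(self, row_id) -> np.ndarray:
        return self.values[self.row_ids.index(row_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def subset_rows(self, row_ids: Iterable) -> "ExpressionMatrix":
        ids = list(row_ids)
        pos = {r: i for i, r in enumerate(self.row_ids)}
        idx = [pos[r] for r in ids]
        return ExpressionMatrix(ids, self.col_ids, self.values[idx])

    def reorder_cols(self, col_ids: Iterable) -> "ExpressionMatrix":
        ids = list(col_ids)
        pos = {c: i for i, c in enumerate(self.col_ids)}
        missing = [c for c in ids if c not in pos]
        if missing:
            raise ConfigurationError(f"sample columns not present: {missing}")
        idx = [pos[c] for c in ids]
        return ExpressionMatrix(self.row_ids, ids, self.values[:, idx])


_RESERVED_DESIGN_COLS = ("sample_id", "replicate", "is_control")


@dataclass
class SampleDesign:
    """Per-sample factor assignments, replicate labels and control flags.

    The cross-classification of all factor columns defines the one-way ANOVA
    grouping used for component ranking and miRNA selection.
    """

    table: pd.DataFrame
    factor_names: list = field(default_factory=list)

    def __post_init__(self):
        if "sample_id" not in self.table.columns:
            raise FormatError("design table requires a 'sample_id' column")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample id in design: {dup!r}")
        if not self.factor_names:
            self.factor_names = [
                c for c in self.table.columns if c not in _RESERVED_DESIGN_COLS
            ]
        if "is_control" not in self.table.columns:
            self.table = self.table.assign(is_control=False)
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list:
        return list(self.table["sample_id"])

    def control_samples(self) -> list:
        mask = self.table["is_control"].astype(bool)
        return list(self.table.loc[mask, "sample_id"])

    def noncontrol_samples(self) -> list:
        mask = ~self.table["is_control"].astype(bool)
        return list(self.table.loc[mask, "sample_id"])

    def group_labels(self, sample_ids: Iterable, factors: Iterable | None = None) -> list:
        """Cross-classification label (all factors joined) per sample id."""
        factors = list(factors) if factors is not None else self.factor_names
        lookup = self.table.set_index("sample_id")
        missing = [s for s in sample_ids if s not in lookup.index]
        if missing:
            raise ConfigurationError(f"samples missing from design: {missing}")
        labels = []
        for s in sample_ids:
            row = lookup.loc[s]
            labels.append("|".join(str(row[f]) for f in factors))
        return labels

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    @classmethod
    def read(cls, path) -> "SampleDesign":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        if "is_control" in df.columns:
            df["is_control"] = df["is_control"].map(_parse_bool)
        return cls(df)


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("1", "true", "yes", "y"):
        return True
    if s in ("0", "false", "no", "n", ""):
        return False
    raise FormatError(f"cannot parse boolean flag: {x!r}")


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways) with descriptions."""

    sets: dict  # name -> (description, set of gene ids)

    def __post_init__(self):
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def names(self) -> list:
        return list(self.sets)

    def genes(self, name) -> set:
        return self.sets[name][1]

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_expression_table(path, rows_are_features: bool = True) -> ExpressionMatrix:
    """Parse a tab-separated expression matrix.

    Expects a header row of sample ids and a first column of feature ids.
    Duplicate ids, empty cells and non-numeric cells are format errors that
    name the offending row/column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate feature id {dup!r} in {path}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"duplicate sample id {dup!r} in {path}")
    # validate with to_numeric (locates bad cells), convert with astype
    # (Python float parsing round-trips full precision; to_numeric does not)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raw = df.iat[r, c]
        what = "empty cell" if raw is None or (isinstance(raw, float) and np.isnan(raw)) else f"non-numeric value {raw!r}"
        raise FormatError(
            f"{what} at row {df.index[r]!r}, column {df.columns[c]!r} in {path}"
        )
    mat = ExpressionMatrix(list(df.index), list(df.columns), df.astype(float).to_numpy())
    if not rows_are_features:
        mat = ExpressionMatrix(mat.col_ids, mat.row_ids, mat.values.T)
    return mat


def format_float(value) -> str:
    """Full round-trip precision float formatting for TSV output."""
    return repr(float(value))


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    # repr round-trips float64 exactly; pandas' default formatting does not
    matrix.to_frame().to_csv(path, sep="\t", index_label="id", float_format=format_float)


def read_fasta(path, alphabet: str = "rna") -> dict:
    """Read FASTA into an ordered ``{id: sequence}`` mapping.

    Ids are the first whitespace-delimited header token; sequences are
    uppercased and U/T transliterated to the requested alphabet.
    """
    if alphabet not in ("rna", "dna"):
        raise ValueError(f"alphabet must be 'rna' or 'dna', got {alphabet!r}")
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for record {rec.id!r} in {path}")
        extra = set(seq) - _VALID_BASES
        if extra:
            raise FormatError(
                f"invalid characters {sorted(extra)} in record {rec.id!r} of {path}"
            )
        if alphabet == "rna":
            seq = seq.replace("T", "U")
        else:
            seq = seq.replace("U", "T")
        if rec.id in records:
            raise FormatError(f"duplicate record id {rec.id!r} in {path}")
        records[rec.id] = seq
    return records


def write_fasta(records: Mapping, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: ``name TAB description TAB gene TAB gene ...``."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: expected >= 3 fields, got {len(fields)}")
            name, desc = fields[0], fields[1]
            genes = {g for g in fields[2:] if g}
            if name in sets:
                raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = (desc, genes)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in collection.sets.items():
            fh.write("\t".join([name, desc] + sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def compute_log_ratios(raw: ExpressionMatrix, design: SampleDesign) -> ExpressionMatrix:
    """Subtract the mean of the flagged control columns from each row.

    Input values are already log2, so the log-ratio is a difference. Control
    columns are dropped from the output.
    """
    controls = [c for c in design.control_samples() if c in raw.col_ids]
    if not controls:
        raise ConfigurationError("no control samples flagged in the design")
    noncontrols = [c for c in raw.col_ids if c not in set(controls)]
    pos = {c: i for i, c in enumerate(raw.col_ids)}
    ctrl_idx = [pos[c] for c in controls]
    keep_idx = [pos[c] for c in noncontrols]
    ctrl_mean = raw.values[:, ctrl_idx].mean(axis=1, keepdims=True)
    return ExpressionMatrix(raw.row_ids, noncontrols, raw.values[:, keep_idx] - ctrl_mean)


def median_normalize(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Shift each column so its median is 0 (log scale)."""
    if raw.n_rows < 1:
        raise ConfigurationError("cannot median-normalize an empty matrix")
    med = np.median(raw.values, axis=0, keepdims=True)
    return ExpressionMatrix(raw.row_ids, raw.col_ids, raw.values - med)


def drop_missing_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Drop rows containing any missing value; the count is logged."""
    mask = ~np.isnan(matrix.values).any(axis=1)
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("dropped %d rows with missing values", n_dropped)
    ids = [r for r, keep in zip(matrix.row_ids, mask) if keep]
    return ExpressionMatrix(ids, matrix.col_ids, matrix.values[mask])


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_results(results: pd.DataFrame, path, metadata: Mapping | None = None) -> None:
    """Write a flat result table as TSV plus a JSON provenance sidecar.

    Floats are serialized at full round-trip precision so a read-back
    reproduces values bit-identically.
    """
    path = Path(path)
    results.to_csv(path, sep="\t", index=False, float_format=format_float)
    sidecar = path.with_name(path.name + ".meta.json")
    meta = dict(metadata or {})
    meta.setdefault("columns", list(results.columns))
    meta.setdefault("n_rows", int(len(results)))
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
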