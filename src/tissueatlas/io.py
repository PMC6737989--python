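"""Readers and writers for the pipeline's on-disk formats.

Count matrices travel as TSV (feature IDs in the first column, sample
names in the header), genomic annotation as GTF, sequences as FASTA.
GTF is 1-based inclusive on disk; every internal interval is 0-based
half-open.  Result tables are written with fixed 6-decimal floats,
except correlation columns which keep 7 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

__all__ = [
    "FeatureAnnotation",
    "SequenceSet",
    "read_count_matrix",
    "write_count_matrix",
    "read_annotation",
    "write_annotation",
    "read_fasta",
    "write_fasta",
    "write_result_table",
]

_VALID_STRANDS = frozenset("+-")


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a features x samples abundance matrix from TSV.

    The first column holds feature IDs, the header row sample names.
    Raises ``ValueError`` on duplicated feature IDs or sample names and
    on any negative or non-numeric cell, naming the offender.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns.name = None
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature IDs in {path}: {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample names in {path}: {dupes}")
    if df.empty:
        return pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {df.iat[r, c]!r} at feature "
            f"{df.index[r]!r}, sample {df.columns[c]!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at feature {df.index[r]!r}, sample "
            f"{df.columns[c]!r} in {path}"
        )
    if (numeric.to_numpy() < 0).any():
        r, c = np.argwhere(numeric.to_numpy() < 0)[0]
        raise ValueError(
            f"negative value {numeric.iat[r, c]} at feature "
            f"{numeric.index[r]!r}, sample {numeric.columns[c]!r} in {path}"
        )
    return numeric.astype(float)


def write_count_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a matrix as TSV; integral values are written without decimals."""
    out = matrix.copy()
    arr = out.to_numpy()
    if arr.size and np.allclose(arr, np.round(arr)):
        out = out.astype(np.int64)
    out.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# genomic annotation
# ---------------------------------------------------------------------------

@dataclass
class FeatureAnnotation:
    """Genomic interval records for genes and miRNA loci.

    ``records`` has one row per locus with columns ``name``, ``chrom``,
    ``start``, ``end`` (0-based half-open), ``strand``, ``feature_type``.
    A miRNA name may own several loci (genomic copies); ``copy_count``
    reports how many.
    """

    records: pd.DataFrame
    copy_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.copy_counts:
            self.copy_counts = self.records["name"].value_counts().to_dict()

    def of_type(self, feature_type: str) -> pd.DataFrame:
        return self.records[self.records["feature_type"] == feature_type]

    def copy_count(self, name: str) -> int:
        return self.copy_counts.get(name, 0)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureAnnotation):
            return NotImplemented
        a = self.records.sort_values(list(self.records.columns)).reset_index(drop=True)
        b = other.records.sort_values(list(other.records.columns)).reset_index(drop=True)
        return a.equals(b)


def read_annotation(path: str | Path, feature_types: Sequence[str] = ("gene", "miRNA")) -> FeatureAnnotation:
    """Parse a GTF file into a :class:`FeatureAnnotation`.

    Only rows whose feature type is in ``feature_types`` are kept.  The
    locus name is the ``gene_id`` attribute.  Coordinates are converted
    from GTF's 1-based inclusive convention to 0-based half-open.
    Malformed lines raise ``ValueError`` with their line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            ftype = fields[2]
            if ftype not in feature_types:
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise ValueError(
                    f"{path}:{lineno}: end ({end1}) < start ({start1})"
                )
            strand = fields[6]
            if strand not in _VALID_STRANDS:
                raise ValueError(
                    f"{path}:{lineno}: unknown strand symbol {strand!r} (expected + or -)"
                )
            feat = feature_from_line(line)
            try:
                name = feat.attributes["gene_id"][0]
            except (KeyError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute") from exc
            rows.append((name, fields[0], start1 - 1, end1, strand, ftype))
    records = pd.DataFrame(
        rows, columns=["name", "chrom", "start", "end", "strand", "feature_type"]
    )
    return FeatureAnnotation(records)


def write_annotation(annotation: FeatureAnnotation, path: str | Path, source: str = "tissueatlas") -> None:
    """Serialize annotation back to GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for rec in annotation.records.itertuples(index=False):
            fh.write(
                f"{rec.chrom}\t{source}\t{rec.feature_type}\t{rec.start + 1}\t{rec.end}"
                f"\t.\t{rec.strand}\t.\tgene_id \"{rec.name}\";\n"
            )


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

_RNA_ALPHABET = frozenset("ACGU")


@dataclass
class SequenceSet:
    """Named nucleotide sequences over the uppercase RNA alphabet (T -> U)."""

    sequences: dict[str, str]

    @staticmethod
    def normalize(seq: str, name: str = "?") -> str:
        s = seq.upper().replace("T", "U")
        bad = set(s) - _RNA_ALPHABET
        if bad:
            pos = next(i for i, ch in enumerate(s) if ch in bad)
            raise ValueError(
                f"sequence {name!r}: non-nucleotide symbol {s[pos]!r} at position {pos}"
            )
        return s

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "SequenceSet":
        return cls({name: cls.normalize(seq, name) for name, seq in pairs})

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __len__(self) -> int:
        return len(self.sequences)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SequenceSet):
            return NotImplemented
        return self.sequences == other.sequences


def read_fasta(path: str | Path) -> SequenceSet:
    pairs = ((rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta"))
    return SequenceSet.from_pairs(pairs)


def write_fasta(seqs: SequenceSet | Mapping[str, str], path: str | Path) -> None:
    mapping = seqs.sequences if isinstance(seqs, SequenceSet) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in mapping.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_result_table(
    df: pd.DataFrame,
    path: str | Path,
    correlation_cols: Sequence[str] = (),
    index: bool = False,
) -> None:
    """Write a result table as TSV with fixed decimal formatting.

    Floats get 6 decimals; columns listed in ``correlation_cols`` get 7
    (the precision correlations are conventionally reported at).
    """
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            nd = 7 if col in correlation_cols else 6
            out[col] = out[col].map(
                lambda v, nd=nd: "" if pd.isna(v) else f"{v:.{nd}f}"
            )
    out.to_csv(path, sep="\t", index=index)
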