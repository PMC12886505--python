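"""File formats and core containers for the dsRNA risk-assessment pipeline.

Everything downstream operates on the containers defined here: nucleotide
sequences (the insecticidal dsRNA trigger and transcriptome unigenes, one
record per gene), a gene x sample count matrix with treatment/control
labels, a per-gene differential-expression table, and named gene sets
(KEGG pathways or GO terms in GMT form).

Conventions
-----------
* Sequences are uppercased on read, ``U`` is mapped to ``T``, and any
  character outside ``{A, C, G, T, N}`` is rejected.  ``N`` bases are kept
  but never participate in exact matching downstream.
* Counts must be non-negative integers.  Estimated counts (e.g. RSEM
  expected counts) must be rounded by the caller before import.
* All tables are TSV with a header row, UTF-8, ``.`` decimal separator.
* Files ending in ``.gz`` are read/written gzip-compressed transparently.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "CountMatrix",
    "DiffExprTable",
    "GeneSetCollection",
    "SIGNIFICANT",
    "FOLD_ONLY",
    "UNCHANGED",
    "read_fasta",
    "write_fasta",
    "read_counts",
    "write_counts",
    "read_de_table",
    "write_de_table",
    "read_gene_sets",
    "write_gene_sets",
]

VALID_BASES = frozenset("ACGTN")

#: change-class labels used throughout the pipeline
SIGNIFICANT = "significant_deg"
FOLD_ONLY = "fold_only"
UNCHANGED = "unchanged"
CHANGE_CLASSES = (SIGNIFICANT, FOLD_ONLY, UNCHANGED)


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8" if "t" in mode else None)
    return open(path, mode, encoding="utf-8")


def normalize_sequence(seq: str, context: str = "sequence") -> str:
    """Uppercase, map U->T and validate the alphabet of a nucleotide string."""
    norm = seq.upper().replace("U", "T")
    bad = set(norm) - VALID_BASES
    if bad:
        raise ValueError(
            f"invalid character(s) {sorted(bad)} in {context}; allowed: A,C,G,T,N"
        )
    return norm


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide sequence (dsRNA trigger or transcript)."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id must be a non-empty token, got {self.id!r}")
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"invalid character(s) {sorted(bad)} in sequence {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of validated :class:`SequenceRecord`.

    Sequences are normalized (uppercase, U->T); duplicate ids and empty or
    invalid sequences raise ``ValueError``.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
            seen.add(rec.id)
            seq = normalize_sequence(str(rec.seq), context=f"record {rec.id!r}")
            if not seq:
                raise ValueError(f"empty sequence for record {rec.id!r} in {path}")
            records.append(SequenceRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with _open_text(path, "wt") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


def sequence_index(records: Iterable[SequenceRecord]) -> dict[str, SequenceRecord]:
    """Id -> record mapping, enforcing unique ids."""
    index: dict[str, SequenceRecord] = {}
    for rec in records:
        if rec.id in index:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        index[rec.id] = rec
    return index


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Non-negative integer gene x sample table with group labels.

    ``counts`` is a pandas DataFrame indexed by gene id with sample-id
    columns; ``groups`` maps every sample id to a group label such as
    ``"treatment"`` / ``"control"``.
    """

    counts: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self):
        df = self.counts
        if df.shape[0] < 1 or df.shape[1] < 2:
            raise ValueError(
                f"count matrix needs >=1 gene and >=2 samples, got {df.shape}"
            )
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r} in count matrix")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r} in count matrix")
        arr = df.to_numpy()
        if (arr < 0).any():
            gi, sj = divmod(int((arr < 0).argmax()), arr.shape[1])
            raise ValueError(
                f"negative count {arr[gi, sj]} at gene {df.index[gi]!r}, "
                f"sample {df.columns[sj]!r}"
            )
        missing = [s for s in df.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.counts = df.astype("int64")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.sample_ids:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]


def read_counts(path, group_map: Mapping[str, str]) -> CountMatrix:
    """Read a TSV count table (first column gene ids, header row sample ids).

    Non-integer or negative entries raise with the offending gene/sample.
    """
    df = pd.read_csv(_open_text(path), sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    for gi, sj in zip(*numeric.isna().to_numpy().nonzero()):
        raise ValueError(
            f"non-numeric count {df.iloc[gi, sj]!r} at gene {df.index[gi]!r}, "
            f"sample {df.columns[sj]!r}"
        )
    frac = (numeric % 1) != 0
    for gi, sj in zip(*frac.to_numpy().nonzero()):
        raise ValueError(
            f"non-integer count {df.iloc[gi, sj]!r} at gene {df.index[gi]!r}, "
            f"sample {df.columns[sj]!r}"
        )
    return CountMatrix(numeric.astype("int64"), dict(group_map))


def write_counts(matrix: CountMatrix, path) -> None:
    with _open_text(path, "wt") as out:
        matrix.counts.to_csv(out, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# differential-expression table
# ---------------------------------------------------------------------------


@dataclass
class DiffExprTable:
    """Per-gene differential-expression results.

    Columns: ``base_mean`` (mean normalized count), ``log2fc`` (treatment
    over control), ``pvalue``, ``fdr`` (Benjamini-Hochberg), and
    ``change_class`` in {significant_deg, fold_only, unchanged}.
    """

    table: pd.DataFrame

    REQUIRED = ("base_mean", "log2fc", "pvalue", "fdr")

    def __post_init__(self):
        df = self.table
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"DE table missing column {col!r}")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r} in DE table")
        for col in ("pvalue", "fdr"):
            vals = df[col].to_numpy(dtype=float)
            bad = (vals < 0) | (vals > 1)
            if bad.any():
                gene = df.index[int(bad.argmax())]
                raise ValueError(
                    f"{col} outside [0,1] for gene {gene!r}: {vals[bad.argmax()]}"
                )
        if "change_class" not in df.columns:
            self.table = self.classify().table

    def classify(
        self,
        lfc_thresh: float = 1.0,
        fdr_thresh: float = 0.05,
        boundary: str = "strict",
    ) -> "DiffExprTable":
        """Recompute ``change_class`` from thresholds.

        strict (default): significant iff |log2fc| > lfc_thresh AND
        fdr < fdr_thresh.  inclusive: >= / <=.  Genes that are not
        significant are ``fold_only`` when |log2fc| >= lfc_thresh and
        ``unchanged`` when |log2fc| < lfc_thresh.
        """
        if boundary not in ("strict", "inclusive"):
            raise ValueError(f"boundary must be strict|inclusive, got {boundary!r}")
        df = self.table.copy()
        lfc = df["log2fc"].to_numpy(dtype=float)
        fdr = df["fdr"].to_numpy(dtype=float)
        if boundary == "strict":
            sig = (abs(lfc) > lfc_thresh) & (fdr < fdr_thresh)
        else:
            sig = (abs(lfc) >= lfc_thresh) & (fdr <= fdr_thresh)
        fold = ~sig & (abs(lfc) >= lfc_thresh)
        cls = pd.Series(UNCHANGED, index=df.index, dtype=object)
        cls[fold] = FOLD_ONLY
        cls[sig] = SIGNIFICANT
        df["change_class"] = cls
        return DiffExprTable(df)

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def degs(self) -> list[str]:
        """Gene ids classified as significant DEGs."""
        return list(self.table.index[self.table["change_class"] == SIGNIFICANT])

    def direction(self) -> pd.Series:
        """Per-gene 'up'/'down'/'unchanged' (direction only for DEGs)."""
        up = (self.table["change_class"] == SIGNIFICANT) & (self.table["log2fc"] > 0)
        down = (self.table["change_class"] == SIGNIFICANT) & (self.table["log2fc"] < 0)
        out = pd.Series("unchanged", index=self.table.index, dtype=object)
        out[up] = "up"
        out[down] = "down"
        return out


def read_de_table(path) -> DiffExprTable:
    """Read a precomputed DE table (columns gene, log2fc, pvalue, fdr).

    ``base_mean`` is optional; ``change_class`` is always recomputed from
    the default thresholds, never trusted from the file.
    """
    df = pd.read_csv(_open_text(path), sep="\t")
    if "gene" not in df.columns:
        raise ValueError("DE table missing column 'gene'")
    for col in ("log2fc", "pvalue", "fdr"):
        if col not in df.columns:
            raise ValueError(f"DE table missing column {col!r}")
    df["gene"] = df["gene"].astype(str)
    df = df.set_index("gene")
    if "base_mean" not in df.columns:
        df["base_mean"] = float("nan")
    df = df[["base_mean", "log2fc", "pvalue", "fdr"]]
    return DiffExprTable(df).classify()


def write_de_table(table: DiffExprTable, path) -> None:
    with _open_text(path, "wt") as out:
        table.table.to_csv(out, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways / GO terms) with an optional universe."""

    sets: dict[str, set[str]]
    universe: set[str] | None = None

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return out


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file (name, description, members...); members deduplicated."""
    sets: dict[str, set[str]] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            members = {m for m in fields[2:] if m}
            if not members:
                raise ValueError(f"GMT line {lineno}: set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path, description: str = "na") -> None:
    with _open_text(path, "wt") as out:
        for name in collection.names():
            members = sorted(collection.sets[name])
            out.write("\t".join([name, description, *members]) + "\n")
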