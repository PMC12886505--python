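"""Contiguous-match off-target scanning of a transcriptome against a dsRNA.

A dsRNA trigger is diced into siRNAs from both strands, so a transcript is
a potential off-target if it shares a sufficiently long contiguous exact
match with either strand of the trigger.  This module computes, for every
transcript, the longest contiguous exact match with the dsRNA (sense and
antisense), bins genes by match length for the report table, and
correlates match length with expression change.

``N`` bases never participate in matches: any window containing ``N`` is
excluded from the longest-common-substring search.

The search binary-searches the match length, testing feasibility of a
candidate length L by intersecting the L-mer sets of transcript and
trigger.  Feasibility is monotone (a common substring of length L implies
one of length L-1), so the search is exact; correctness is anchored to a
quadratic dynamic-programming oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._tables import EMPTY_CELL, count_pct, pct_string, pct_value
from .io_formats import (
    SIGNIFICANT,
    DiffExprTable,
    SequenceRecord,
    normalize_sequence,
)

__all__ = [
    "MatchResult",
    "reverse_complement",
    "longest_contiguous_match",
    "scan_transcriptome",
    "bin_by_match_length",
    "summary_from_counts",
    "match_results_frame",
    "match_fold_change_correlation",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MIN_REPORT_LEN = 7  # shortest contiguous match reported in the study's table


def reverse_complement(sequence: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    seq = normalize_sequence(sequence)
    return seq.translate(_COMPLEMENT)[::-1]


def _kmer_set(seq: str, k: int) -> set[str]:
    """All k-mers of seq that are free of N."""
    return {
        seq[i : i + k]
        for i in range(len(seq) - k + 1)
        if "N" not in seq[i : i + k]
    }


def _has_match(query: str, subject_kmers: set[str], k: int) -> bool:
    return any(
        query[i : i + k] in subject_kmers for i in range(len(query) - k + 1)
    )


class _SubjectIndex:
    """Per-length k-mer sets of a subject sequence, built lazily and cached.

    Reused across transcripts so the dsRNA is only indexed O(log L) times.
    """

    def __init__(self, sequence: str):
        self.sequence = sequence
        self._cache: dict[int, set[str]] = {}

    def kmers(self, k: int) -> set[str]:
        if k not in self._cache:
            self._cache[k] = _kmer_set(self.sequence, k)
        return self._cache[k]

    def longest_match(self, query: str) -> int:
        """Length of the longest common N-free substring with ``query``."""
        hi = min(len(query), len(self.sequence))
        lo = 0  # invariant: a common substring of length lo exists (or lo==0)
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if _has_match(query, self.kmers(mid), mid):
                lo = mid
            else:
                hi = mid - 1
        return lo

    def positions(self, query: str, length: int) -> list[tuple[int, int]]:
        """All (query_start, subject_start) of common substrings of ``length``."""
        if length <= 0:
            return []
        index: dict[str, list[int]] = {}
        for j in range(len(self.sequence) - length + 1):
            w = self.sequence[j : j + length]
            if "N" not in w:
                index.setdefault(w, []).append(j)
        out: list[tuple[int, int]] = []
        for i in range(len(query) - length + 1):
            w = query[i : i + length]
            for j in index.get(w, ()):
                out.append((i, j))
        return out


def longest_contiguous_match(query: str, subject: str) -> tuple[int, list[tuple[int, int]]]:
    """Longest common substring over {A,C,G,T} of two sequences.

    Returns ``(length, positions)`` with every occurrence of the maximal
    match as ``(query_start, subject_start)`` pairs (0-based).  Windows
    containing N are excluded.  Length 0 means no common base.
    """
    query = normalize_sequence(query, "query")
    subject = normalize_sequence(subject, "subject")
    if not query or not subject:
        raise ValueError("both sequences must be non-empty")
    idx = _SubjectIndex(subject)
    length = idx.longest_match(query)
    return length, idx.positions(query, length)


@dataclass
class MatchResult:
    """Per-gene maximal contiguous match with the dsRNA trigger.

    ``positions`` lists every occurrence attaining ``max_match`` as
    ``(transcript_start, trigger_start, strand)``; trigger coordinates are
    on the scanned strand (the reverse complement of the dsRNA for
    antisense hits), 0-based half-open.
    """

    gene_id: str
    max_match_sense: int
    max_match_antisense: int
    positions: list[tuple[int, int, str]] = field(default_factory=list)
    below_threshold: bool = False

    @property
    def max_match(self) -> int:
        return max(self.max_match_sense, self.max_match_antisense)


def scan_transcriptome(
    dsrna: SequenceRecord,
    transcripts: list[SequenceRecord],
    min_report_len: int = MIN_REPORT_LEN,
    strands: str = "both",
) -> list[MatchResult]:
    """Longest contiguous match of every transcript with the dsRNA.

    Both trigger strands are scanned by default (a dsRNA yields siRNAs
    from both); ``strands="sense"`` restricts to the given sequence.
    Results shorter than ``min_report_len`` are flagged
    ``below_threshold`` but retained.
    """
    if strands not in ("both", "sense"):
        raise ValueError(f"strands must be both|sense, got {strands!r}")
    if not transcripts:
        raise ValueError("empty transcriptome")
    if len(dsrna.sequence) < min_report_len:
        raise ValueError(
            f"dsRNA length {len(dsrna)} shorter than min_report_len {min_report_len}"
        )
    sense_idx = _SubjectIndex(dsrna.sequence)
    anti_idx = _SubjectIndex(reverse_complement(dsrna.sequence))
    results: list[MatchResult] = []
    for tr in transcripts:
        s_len = sense_idx.longest_match(tr.sequence)
        a_len = anti_idx.longest_match(tr.sequence) if strands == "both" else 0
        best = max(s_len, a_len)
        positions: list[tuple[int, int, str]] = []
        if best > 0:
            if s_len == best:
                positions += [
                    (i, j, "sense") for i, j in sense_idx.positions(tr.sequence, best)
                ]
            if strands == "both" and a_len == best:
                positions += [
                    (i, j, "antisense")
                    for i, j in anti_idx.positions(tr.sequence, best)
                ]
        results.append(
            MatchResult(
                gene_id=tr.id,
                max_match_sense=s_len,
                max_match_antisense=a_len,
                positions=positions,
                below_threshold=best < min_report_len,
            )
        )
    return results


def match_results_frame(results: list[MatchResult]) -> pd.DataFrame:
    """Tabular view: gene, sense, antisense, max, n_positions."""
    return pd.DataFrame(
        {
            "gene": [r.gene_id for r in results],
            "max_match_sense": [r.max_match_sense for r in results],
            "max_match_antisense": [r.max_match_antisense for r in results],
            "max_match": [r.max_match for r in results],
            "n_positions": [len(r.positions) for r in results],
        }
    ).set_index("gene")


# ---------------------------------------------------------------------------
# match-length report table
# ---------------------------------------------------------------------------


def _directions(de_table: DiffExprTable | None) -> pd.Series:
    if de_table is None:
        return pd.Series(dtype=object)
    return de_table.direction()


def bin_by_match_length(
    results: list[MatchResult],
    de_table: DiffExprTable | None,
    min_len: int = MIN_REPORT_LEN,
    max_bin: int = 15,
    legacy_percent: bool = False,
) -> pd.DataFrame:
    """Bin genes by longest-match length and count expression directions.

    Bins are exclusive per-gene values ``min_len .. max_bin-1`` plus a
    final ``>=max_bin`` bin, so bin totals partition the genes with
    ``max_match >= min_len``.  Genes absent from the DE table (filtered
    upstream) count as unchanged; their number is in
    ``frame.attrs["n_missing_from_de"]``.
    """
    direction = _directions(de_table)
    counts: dict[int, list[int]] = {
        k: [0, 0, 0] for k in range(min_len, max_bin + 1)
    }  # bin -> [up, down, unchanged]
    n_missing = 0
    for r in results:
        if r.max_match < min_len:
            continue
        k = min(r.max_match, max_bin)
        if r.gene_id in direction.index:
            d = direction[r.gene_id]
        else:
            d = "unchanged"
            n_missing += 1
        counts[k][{"up": 0, "down": 1, "unchanged": 2}[d]] += 1
    bin_counts = {
        k: (sum(v), v[0], v[1], v[2]) for k, v in counts.items()
    }
    frame = summary_from_counts(bin_counts, legacy_percent=legacy_percent)
    frame.attrs["n_missing_from_de"] = n_missing
    return frame


def summary_from_counts(
    bin_counts: dict[int, tuple[int, int, int, int]],
    legacy_percent: bool = False,
) -> pd.DataFrame:
    """Build the match-length report table from per-bin counts.

    ``bin_counts`` maps bin label -> (total, n_up, n_down, n_unchanged);
    the summarizer recomputes all percentages (round half-up, 2 decimals)
    and renders 'count (pct%)' cells.  Empty bins render percentages as
    an en-dash.
    """
    rows = []
    for k in sorted(bin_counts):
        total, up, down, unchanged = bin_counts[k]
        if up + down + unchanged != total:
            raise ValueError(
                f"bin {k}: up+down+unchanged = {up + down + unchanged} != total {total}"
            )
        if total == 0:
            rows.append(
                {
                    "bin": k,
                    "total_genes": 0,
                    "n_up": 0,
                    "n_down": 0,
                    "n_unchanged": 0,
                    "pct_up": float("nan"),
                    "pct_down": float("nan"),
                    "pct_unchanged": float("nan"),
                    "up_cell": EMPTY_CELL,
                    "down_cell": EMPTY_CELL,
                    "unchanged_cell": EMPTY_CELL,
                }
            )
            continue
        rows.append(
            {
                "bin": k,
                "total_genes": total,
                "n_up": up,
                "n_down": down,
                "n_unchanged": unchanged,
                "pct_up": pct_value(up, total),
                "pct_down": pct_value(down, total),
                "pct_unchanged": pct_value(unchanged, total),
                "up_cell": count_pct(up, total, legacy=legacy_percent),
                "down_cell": count_pct(down, total, legacy=legacy_percent),
                "unchanged_cell": count_pct(unchanged, total, legacy=legacy_percent),
            }
        )
    return pd.DataFrame(rows).set_index("bin")


# ---------------------------------------------------------------------------
# match length vs fold change
# ---------------------------------------------------------------------------

#: point classes of the match-vs-fold-change figure (inclusive boundaries)
RED = "red"  # |log2fc| >= 1 and FDR <= 0.05
BLUE = "blue"  # |log2fc| >= 1 and FDR > 0.05
GRAY = "gray"  # |log2fc| < 1


def _color_class(log2fc: float, fdr: float) -> str:
    if abs(log2fc) < 1:
        return GRAY
    return RED if fdr <= 0.05 else BLUE


def match_fold_change_correlation(
    results: list[MatchResult],
    de_table: DiffExprTable,
    min_len: int = MIN_REPORT_LEN,
) -> tuple[pd.DataFrame, float, float]:
    """Spearman correlation of match length vs |log2 fold change|.

    Returns ``(per_gene_table, rho, p)`` over genes with
    ``max_match >= min_len`` present in the DE table.  A constant input
    vector makes rho undefined by ties; it is reported as 0.0 with p 1.0
    and ``table.attrs["constant_input"] = True``.
    """
    de = de_table.table
    rows = []
    n_dropped = 0
    for r in results:
        if r.max_match < min_len:
            continue
        if r.gene_id not in de.index:
            n_dropped += 1
            continue
        lfc = float(de.loc[r.gene_id, "log2fc"])
        fdr = float(de.loc[r.gene_id, "fdr"])
        rows.append(
            {
                "gene": r.gene_id,
                "max_match": r.max_match,
                "log2fc": lfc,
                "abs_log2fc": abs(lfc),
                "color_class": _color_class(lfc, fdr),
            }
        )
    if len(rows) < 3:
        raise ValueError(
            f"need >=3 genes with max_match >= {min_len} in the DE table, got {len(rows)}"
        )
    frame = pd.DataFrame(rows).set_index("gene")
    frame.attrs["n_missing_from_de"] = n_dropped
    x = frame["max_match"].to_numpy(dtype=float)
    y = frame["abs_log2fc"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        frame.attrs["constant_input"] = True
        return frame, 0.0, 1.0
    frame.attrs["constant_input"] = False
    rho, p = stats.spearmanr(x, y)
    return frame, float(rho), float(p)
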