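"""Three-class attribution of DEGs: target homologs, pathway proximity, matches.

After differential expression, each DEG is attributed to (possibly
several) candidate causes of an off-target response:

1. homologs of the dsRNA target gene, found by local alignment with a
   BLASTN-like scoring scheme (+2/-3, affine gaps 5/2) and a
   Karlin-Altschul E-value threshold (default 1e-10);
2. proximity of the gene's KEGG pathways to the target: level-1 pathways
   contain a seed gene (target homolog or best match), level-(k+1)
   pathways share at least one gene with a level-k pathway
   ("interaction" is operationalized as shared-gene overlap, since only
   flat gene sets are ingested);
3. contiguous sequence matches with the dsRNA itself (from the scan
   module).

The local-alignment engine is an affine-gap Smith-Waterman (Gotoh) DP; a
gap of length k costs ``gap_open + k * gap_extend``.  N scores as a
mismatch against everything, including another N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from ._tables import count_pct, pct_value
from .io_formats import DiffExprTable, GeneSetCollection, SequenceRecord
from .offtarget_scan import MatchResult, reverse_complement

__all__ = [
    "LocalAlignment",
    "HomologHit",
    "PathwayLevelAssignment",
    "smith_waterman",
    "evalue_from_score",
    "find_homologs",
    "assign_pathway_levels",
    "summarize_levels",
    "level_summary_from_counts",
    "classify_degs",
]

#: ungapped Karlin-Altschul constants for the +2/-3 scheme
KA_K = 0.41
KA_LAMBDA = 0.625

_NEG = -(2**40)

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=False)
def _sw_best(q, s, match, mismatch, gap_open, gap_extend):
    """Best local-alignment score and its end cell (first in row-major order)."""
    n, m = q.shape[0], s.shape[0]
    h_prev = np.zeros(m + 1, np.int64)
    f_prev = np.full(m + 1, _NEG, np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        h_cur = np.zeros(m + 1, np.int64)
        f_cur = np.empty(m + 1, np.int64)
        f_cur[0] = _NEG
        e = _NEG
        qi = q[i - 1]
        for j in range(1, m + 1):
            e_open = h_cur[j - 1] - gap_open
            if e_open > e:
                e = e_open
            e -= gap_extend
            f = f_prev[j]
            f_open = h_prev[j] - gap_open
            if f_open > f:
                f = f_open
            f -= gap_extend
            f_cur[j] = f
            sub = match if (qi == s[j - 1] and qi < 4) else mismatch
            h = h_prev[j - 1] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            h_cur[j] = h
            if h > best:
                best = h
                bi = i
                bj = j
        h_prev = h_cur
        f_prev = f_cur
    return best, bi, bj


@njit(cache=False)
def _sw_matrices(q, s, match, mismatch, gap_open, gap_extend):
    """Full H/E/F matrices for traceback (small inputs only)."""
    n, m = q.shape[0], s.shape[0]
    H = np.zeros((n + 1, m + 1), np.int64)
    E = np.full((n + 1, m + 1), _NEG, np.int64)
    F = np.full((n + 1, m + 1), _NEG, np.int64)
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = E[i, j - 1]
            e_open = H[i, j - 1] - gap_open
            if e_open > e:
                e = e_open
            E[i, j] = e - gap_extend
            f = F[i - 1, j]
            f_open = H[i - 1, j] - gap_open
            if f_open > f:
                f = f_open
            F[i, j] = f - gap_extend
            sub = match if (qi == s[j - 1] and qi < 4) else mismatch
            h = H[i - 1, j - 1] + sub
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
    return H, E, F


@dataclass(frozen=True)
class LocalAlignment:
    """A best local alignment: score and 0-based half-open spans."""

    score: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int

    @property
    def query_span(self) -> tuple[int, int]:
        return (self.query_start, self.query_end)

    @property
    def subject_span(self) -> tuple[int, int]:
        return (self.subject_start, self.subject_end)


def _traceback(q, s, H, E, F, i, j, match, mismatch, gap_extend):
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            sub = match if (q[i - 1] == s[j - 1] and q[i - 1] < 4) else mismatch
            if H[i, j] == H[i - 1, j - 1] + sub:
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            if E[i, j] == E[i, j - 1] - gap_extend:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:
            if F[i, j] == F[i - 1, j] - gap_extend:
                i -= 1
            else:
                i -= 1
                state = "H"
    return i, j


def smith_waterman(
    query: str,
    subject: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = 5,
    gap_extend: int = 2,
) -> LocalAlignment:
    """Optimal affine-gap local alignment (gap of length k costs open + k*extend).

    Ties between equally scoring alignments are broken by the lowest
    (query_start, subject_start, query_end, subject_end).  A best score of
    0 yields an empty alignment with spans (0, 0).
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    q = _encode(query)
    s = _encode(subject)
    H, E, F = _sw_matrices(q, s, match, mismatch, gap_open, gap_extend)
    best = int(H.max())
    if best == 0:
        return LocalAlignment(0, 0, 0, 0, 0)
    cells = np.argwhere(H == best)
    candidates = []
    for bi, bj in cells:
        si, sj = _traceback(q, s, H, E, F, int(bi), int(bj), match, mismatch, gap_extend)
        candidates.append((si, sj, int(bi), int(bj)))
    si, sj, bi, bj = min(candidates)
    return LocalAlignment(best, si, bi, sj, bj)


def sw_score(
    query: str,
    subject: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = 5,
    gap_extend: int = 2,
) -> int:
    """Score-only Smith-Waterman (linear memory, fast path for scanning)."""
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    best, _, _ = _sw_best(_encode(query), _encode(subject), match, mismatch, gap_open, gap_extend)
    return int(best)


def evalue_from_score(
    score: float,
    query_len: int,
    db_len: int,
    K: float = KA_K,
    lambda_nat: float = KA_LAMBDA,
) -> float:
    """Karlin-Altschul E-value: E = K * m * n * exp(-lambda * S)."""
    if query_len <= 0 or db_len <= 0:
        raise ValueError("lengths must be positive")
    return float(K * query_len * db_len * np.exp(-lambda_nat * score))


def bit_score(score: float, K: float = KA_K, lambda_nat: float = KA_LAMBDA) -> float:
    """Normalized bit score: (lambda*S - ln K) / ln 2."""
    return float((lambda_nat * score - np.log(K)) / np.log(2.0))


@dataclass(frozen=True)
class HomologHit:
    """Best local-alignment hit of the target gene against one transcript."""

    gene_id: str
    score: int
    alignment_score: float  # bit score
    evalue: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]  # on the transcript's forward strand
    strand: str  # sense | antisense


def find_homologs(
    target: SequenceRecord,
    transcriptome: list[SequenceRecord],
    evalue_thresh: float = 1e-10,
    K: float = KA_K,
    lambda_nat: float = KA_LAMBDA,
) -> list[HomologHit]:
    """Homologs of the target gene in a transcriptome by local alignment.

    Both transcript strands are searched; one best hit per transcript;
    hits with E-value below ``evalue_thresh`` are returned sorted by
    E-value ascending (ties by gene id).  The E-value threshold, not the
    alignment engine, is the contract.
    """
    if not transcriptome:
        raise ValueError("empty transcriptome")
    db_len = sum(len(t) for t in transcriptome)
    q = _encode(target.sequence)
    hits: list[HomologHit] = []
    for tr in transcriptome:
        fwd = tr.sequence
        rev = reverse_complement(fwd)
        score_f, _, _ = _sw_best(q, _encode(fwd), 2, -3, 5, 2)
        score_r, _, _ = _sw_best(q, _encode(rev), 2, -3, 5, 2)
        score = int(max(score_f, score_r))
        ev = evalue_from_score(score, len(target), db_len, K, lambda_nat)
        if ev >= evalue_thresh:
            continue
        strand = "sense" if score_f >= score_r else "antisense"
        aln = smith_waterman(target.sequence, fwd if strand == "sense" else rev)
        sub_span = aln.subject_span
        if strand == "antisense":  # map back onto the forward strand
            sub_span = (len(fwd) - aln.subject_end, len(fwd) - aln.subject_start)
        hits.append(
            HomologHit(
                gene_id=tr.id,
                score=score,
                alignment_score=bit_score(score, K, lambda_nat),
                evalue=ev,
                query_span=aln.query_span,
                subject_span=sub_span,
                strand=strand,
            )
        )
    hits.sort(key=lambda h: (h.evalue, h.gene_id))
    return hits


# ---------------------------------------------------------------------------
# pathway proximity levels
# ---------------------------------------------------------------------------


@dataclass
class PathwayLevelAssignment:
    """Proximity levels of pathways and genes to the seed genes.

    ``pathway_levels`` maps assigned pathways to 1..max_level (unassigned
    pathways are absent, i.e. level 'none').  ``gene_levels`` maps each
    non-seed gene of an assigned pathway to the minimum level over its
    pathways; seed genes are recorded separately (they are the cause of
    the classification, not part of its effect counts).
    """

    pathway_levels: dict[str, int]
    gene_levels: dict[str, int]
    seed_genes: set[str]

    def genes_at(self, level: int) -> list[str]:
        return sorted(g for g, l in self.gene_levels.items() if l == level)


def assign_pathway_levels(
    gene_sets: GeneSetCollection,
    seed_genes,
    max_level: int = 3,
    min_overlap: int = 1,
) -> PathwayLevelAssignment:
    """Breadth-first pathway levels from seed-containing gene sets.

    Level-1 pathways contain at least one seed gene; level-(k+1) pathways
    are unassigned pathways sharing >= ``min_overlap`` genes with some
    level-k pathway.  Deterministic: pathways are visited in sorted-name
    order, and results are order-invariant by construction.
    """
    seeds = set(seed_genes)
    if not seeds:
        raise ValueError("seed_genes must be non-empty")
    levels: dict[str, int] = {}
    frontier = sorted(n for n, members in gene_sets.sets.items() if members & seeds)
    if not frontier:
        warnings.warn("no pathway contains a seed gene; empty assignment")
        return PathwayLevelAssignment({}, {}, seeds)
    for name in frontier:
        levels[name] = 1
    k = 1
    while frontier and k < max_level:
        frontier_genes: set[str] = set()
        nxt = []
        for name in sorted(set(gene_sets.sets) - set(levels)):
            members = gene_sets.sets[name]
            if any(
                len(members & gene_sets.sets[f]) >= min_overlap for f in frontier
            ):
                nxt.append(name)
        for name in nxt:
            levels[name] = k + 1
        frontier = nxt
        k += 1
    gene_levels: dict[str, int] = {}
    for name, level in levels.items():
        for g in gene_sets.sets[name]:
            if g in seeds:
                continue
            if g not in gene_levels or level < gene_levels[g]:
                gene_levels[g] = level
    return PathwayLevelAssignment(levels, gene_levels, seeds)


def summarize_levels(
    assignment: PathwayLevelAssignment,
    de_table: DiffExprTable | None,
    max_level: int = 3,
    legacy_percent: bool = False,
) -> pd.DataFrame:
    """Per-level counts of up/down/unchanged genes plus a Total row.

    Each gene is counted once, at its minimum level; direction comes from
    the DE table's change class and log2FC sign (genes absent from the DE
    table count as unchanged).
    """
    direction = (
        de_table.direction() if de_table is not None else pd.Series(dtype=object)
    )
    counts: dict[int | str, tuple[int, int, int, int]] = {}
    tot = [0, 0, 0]
    for level in range(1, max_level + 1):
        genes = assignment.genes_at(level)
        tally = [0, 0, 0]
        for g in genes:
            d = direction[g] if g in direction.index else "unchanged"
            tally[{"up": 0, "down": 1, "unchanged": 2}[d]] += 1
        counts[level] = (len(genes), tally[0], tally[1], tally[2])
        for i in range(3):
            tot[i] += tally[i]
    counts["Total"] = (sum(tot), tot[0], tot[1], tot[2])
    return level_summary_from_counts(counts, legacy_percent=legacy_percent)


def level_summary_from_counts(
    level_counts: dict,
    legacy_percent: bool = False,
) -> pd.DataFrame:
    """Build the pathway-level report table from per-level counts.

    ``level_counts`` maps level label -> (total, n_up, n_down,
    n_unchanged); if no "Total" key is present a Total row summing the
    numeric levels is added.  Percentages are recomputed (round half-up,
    2 decimals).
    """
    counts = dict(level_counts)
    if "Total" not in counts:
        sums = [0, 0, 0, 0]
        for v in counts.values():
            for i in range(4):
                sums[i] += v[i]
        counts["Total"] = tuple(sums)
    rows = []
    for label, (total, up, down, unchanged) in counts.items():
        if up + down + unchanged != total:
            raise ValueError(
                f"level {label}: up+down+unchanged = {up + down + unchanged} "
                f"!= total {total}"
            )
        name = f"Level {label}" if isinstance(label, int) else str(label)
        if total == 0:
            rows.append(
                {
                    "level": name,
                    "total_genes": 0,
                    "n_up": 0,
                    "n_down": 0,
                    "n_unchanged": 0,
                    "pct_up": float("nan"),
                    "pct_down": float("nan"),
                    "pct_unchanged": float("nan"),
                    "up_cell": "0 (0.00%)",
                    "down_cell": "0 (0.00%)",
                    "unchanged_cell": "0 (0.00%)",
                }
            )
            continue
        rows.append(
            {
                "level": name,
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
    return pd.DataFrame(rows).set_index("level")


# ---------------------------------------------------------------------------
# three-class DEG attribution
# ---------------------------------------------------------------------------


def classify_degs(
    deg_genes,
    homolog_hits: list[HomologHit],
    assignment: PathwayLevelAssignment | None,
    match_results: list[MatchResult],
    min_match: int = 7,
) -> tuple[pd.DataFrame, dict]:
    """Label each DEG with its (possibly empty) set of attribution classes.

    Classes are non-exclusive: ``homolog_of_target``, ``pathway_level_k``
    and ``continuous_match_k`` (k = the gene's longest match, if >=
    ``min_match``).  DEGs with no label land in the ``unattributed``
    bucket.  Returns the per-DEG table and a summary dict with per-class
    and per-combination counts.
    """
    homolog_ids = {h.gene_id for h in homolog_hits}
    gene_levels = assignment.gene_levels if assignment is not None else {}
    match_by_gene = {r.gene_id: r.max_match for r in match_results}
    rows = []
    combo_counts: dict[str, int] = {}
    class_counts = {"homolog_of_target": 0, "pathway_level": 0, "continuous_match": 0, "unattributed": 0}
    for g in deg_genes:
        labels = []
        if g in homolog_ids:
            labels.append("homolog_of_target")
            class_counts["homolog_of_target"] += 1
        level = gene_levels.get(g)
        if level is not None:
            labels.append(f"pathway_level_{level}")
            class_counts["pathway_level"] += 1
        mm = match_by_gene.get(g, 0)
        if mm >= min_match:
            labels.append(f"continuous_match_{mm}")
            class_counts["continuous_match"] += 1
        key = ";".join(labels) if labels else "unattributed"
        if not labels:
            class_counts["unattributed"] += 1
        combo_counts[key] = combo_counts.get(key, 0) + 1
        rows.append(
            {
                "gene": g,
                "is_homolog": g in homolog_ids,
                "pathway_level": level if level is not None else 0,
                "max_match": mm,
                "labels": key,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["gene", "is_homolog", "pathway_level", "max_match", "labels"]
    ).set_index("gene")
    summary = {"classes": class_counts, "combinations": combo_counts, "n_degs": len(frame)}
    return frame, summary
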