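"""Seeded synthetic datasets with recorded ground truth for every stage.

Generates the artifacts the pipeline consumes — a dsRNA trigger, a
transcriptome with planted contiguous matches and planted target
homologs, a negative-binomial count matrix with planted log2 fold
changes, and a pathway collection with a controlled overlap graph — so
off-target scanning, DE calling, homolog search, pathway levelling and
enrichment can all be tested against known truth without any downloads.

Guarantees (enforced, not merely expected):

* every planted contiguous match is recovered at exactly its planted
  length, and every unplanted, non-homolog transcript has a longest
  match below the reporting threshold.  Chance matches are removed by
  verify-and-repair: offending match windows are located, one base
  inside each window is resampled, and the final transcript is verified
  by an independent quadratic-DP longest-common-substring oracle
  (:func:`longest_common_substring_dp`), which also serves as the test
  oracle for the scanner;
* the emitted pathway collection reproduces the configured proximity
  level of every pathway under the pipeline's own breadth-first
  assignment (self-validated before emission);
* one integer seed fixes every emitted artifact byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .classification import assign_pathway_levels
from .io_formats import CountMatrix, GeneSetCollection, SequenceRecord
from .offtarget_scan import _SubjectIndex, reverse_complement

__all__ = [
    "PathwaySpec",
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "longest_common_substring_dp",
    "oracle_max_match",
    "generate_dsrna",
    "generate_transcriptome",
    "generate_homologs",
    "generate_counts",
    "generate_pathways",
    "simulate_dataset",
]

_BASES = np.array(list("ACGT"))

_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


@njit(cache=False)
def _lcs_dp(a, b):
    """Quadratic DP longest-common-substring length; code 4 (N) matches nothing."""
    n, m = a.shape[0], b.shape[0]
    prev = np.zeros(m, np.int32)
    best = 0
    for i in range(n):
        cur = np.zeros(m, np.int32)
        ai = a[i]
        if ai < 4:
            for j in range(m):
                if b[j] == ai:
                    if j > 0:
                        cur[j] = prev[j - 1] + 1
                    else:
                        cur[j] = 1
                    if cur[j] > best:
                        best = cur[j]
        prev = cur
    return best


def longest_common_substring_dp(a: str, b: str) -> int:
    """Brute-force DP oracle for the longest common N-free substring length."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ea = _ENC[np.frombuffer(a.upper().encode("ascii"), dtype=np.uint8)]
    eb = _ENC[np.frombuffer(b.upper().encode("ascii"), dtype=np.uint8)]
    return int(_lcs_dp(ea, eb))


def oracle_max_match(transcript: str, dsrna: str) -> int:
    """DP-oracle longest contiguous match over both dsRNA strands."""
    return max(
        longest_common_substring_dp(transcript, dsrna),
        longest_common_substring_dp(transcript, reverse_complement(dsrna)),
    )


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PathwaySpec:
    """Overlap structure of the synthetic pathway collection.

    ``edges`` are undirected pathway-index pairs that will share exactly
    one bridge gene; pathways are otherwise disjoint.  ``seed_pathways``
    receive the seed genes (the planted target homologs), making them
    proximity level 1.  ``None`` edges default to a chain 0-1-2-...
    """

    n_pathways: int = 12
    size_range: tuple[int, int] = (8, 20)
    edges: tuple[tuple[int, int], ...] | None = None
    seed_pathways: tuple[int, ...] = (0,)

    def resolved_edges(self) -> tuple[tuple[int, int], ...]:
        if self.edges is not None:
            return self.edges
        return tuple((i, i + 1) for i in range(self.n_pathways - 1))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped defaults: a 403 bp trigger, 3 vs 3 replicates, ~30k genes.

    ``planted_matches`` is a list of ``(gene_index, match_length, strand)``
    with strand "sense" or "antisense"; ``planted_homologs`` a list of
    ``(gene_index, percent_identity)`` with identity in (0.5, 1].
    """

    seed: int = 0
    n_genes: int = 30_000
    transcript_length_range: tuple[int, int] = (300, 1500)
    gc_content: float = 0.42
    dsrna_length: int = 403
    planted_matches: tuple[tuple[int, int, str], ...] = ()
    planted_homologs: tuple[tuple[int, float], ...] = ()
    de_fraction: float = 0.01
    de_log2fc_magnitude: float = 2.0
    nb_dispersion: float = 0.05
    mean_depth: float = 1_000_000.0
    n_replicates_per_group: int = 3
    depth_factors: tuple[float, ...] | None = None
    min_match_len: int = 7
    pathway_spec: PathwaySpec = field(default_factory=PathwaySpec)

    def __post_init__(self):
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if not 0 <= self.de_fraction < 1:
            raise ValueError("de_fraction must be in [0, 1)")
        seen = set()
        for idx, length, strand in self.planted_matches:
            if not (self.min_match_len <= length <= self.dsrna_length):
                raise ValueError(
                    f"planted match length {length} outside "
                    f"[{self.min_match_len}, {self.dsrna_length}]"
                )
            if strand not in ("sense", "antisense"):
                raise ValueError(f"invalid strand {strand!r}")
            if not 0 <= idx < self.n_genes:
                raise ValueError(f"planted match gene index {idx} out of range")
            if idx in seen:
                raise ValueError(f"gene index {idx} planted twice")
            seen.add(idx)
        for idx, ident in self.planted_homologs:
            if not 0.5 < ident <= 1.0:
                raise ValueError(f"homolog identity {ident} outside (0.5, 1]")
            if not 0 <= idx < self.n_genes:
                raise ValueError(f"homolog gene index {idx} out of range")
            if idx in seen:
                raise ValueError(f"gene index {idx} planted twice")
            seen.add(idx)


@dataclass
class GroundTruth:
    """Recorded truth for every emitted artifact, keyed by gene id."""

    genes: pd.DataFrame
    seed_genes: set[str] = field(default_factory=set)
    pathway_levels: dict[str, int | None] = field(default_factory=dict)
    pathway_members: dict[str, set[str]] = field(default_factory=dict)

    def planted_match_genes(self) -> pd.DataFrame:
        return self.genes[self.genes["planted_match"]]

    def homolog_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["is_homolog"]])

    def de_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["is_de"]])


@dataclass
class SyntheticDataset:
    dsrna: SequenceRecord
    transcripts: list[SequenceRecord]
    truth: GroundTruth
    counts: CountMatrix | None = None
    gene_sets: GeneSetCollection | None = None


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def generate_dsrna(config: SimulationConfig) -> SequenceRecord:
    rng = _rng(config, 0)
    return SequenceRecord("dsRNA", _random_seq(rng, config.dsrna_length, config.gc_content))


# ---------------------------------------------------------------------------
# transcriptome with planted matches and homologs
# ---------------------------------------------------------------------------


def generate_homologs(
    target: SequenceRecord,
    identities,
    rng: np.random.Generator,
) -> list[tuple[str, float]]:
    """Mutated copies of the target at the given identities.

    Point substitutions at uniformly chosen distinct positions; returns
    ``(sequence, realized_identity)`` per requested identity.
    """
    out = []
    L = len(target.sequence)
    for ident in identities:
        if not 0.5 < ident <= 1.0:
            raise ValueError(f"identity {ident} outside (0.5, 1]")
        n_sub = int(round(L * (1.0 - ident)))
        seq = list(target.sequence)
        for pos in rng.choice(L, size=n_sub, replace=False):
            old = seq[pos]
            choices = [b for b in "ACGT" if b != old]
            seq[pos] = choices[rng.integers(3)]
        out.append(("".join(seq), 1.0 - n_sub / L))
    return out


def _mutate(seq: list[str], pos: int, rng: np.random.Generator) -> None:
    old = seq[pos]
    choices = [b for b in "ACGT" if b != old]
    seq[pos] = choices[rng.integers(3)]


def _strip_chance_matches(
    seq: list[str],
    forbidden_kmers: set[str],
    k: int,
    rng: np.random.Generator,
    keep_span: tuple[int, int] | None = None,
    max_pass: int = 60,
) -> None:
    """Resample one base inside every k-mer window matching the trigger.

    ``keep_span`` protects a planted region from mutation; windows fully
    inside it are expected matches and skipped.
    """
    for _ in range(max_pass):
        text = "".join(seq)
        bad = []
        for i in range(len(text) - k + 1):
            if keep_span and i >= keep_span[0] and i + k <= keep_span[1]:
                continue
            if text[i : i + k] in forbidden_kmers:
                bad.append(i)
        if not bad:
            return
        last = -(10**9)
        for i in bad:
            if last >= i:  # window already broken by the previous mutation
                continue
            lo, hi = i, i + k
            if keep_span:
                # never mutate inside the planted region
                allowed = [p for p in range(lo, hi) if not keep_span[0] <= p < keep_span[1]]
            else:
                allowed = list(range(lo, hi))
            # random position: a fixed one can cycle when every variant of
            # the window is itself a trigger k-mer
            pos = allowed[int(rng.integers(len(allowed)))]
            _mutate(seq, pos, rng)
            last = pos
    raise RuntimeError("chance-match repair did not converge")


def _repair_planted(
    seq: list[str],
    planted_span: tuple[int, int],
    planted_len: int,
    sense_idx: _SubjectIndex,
    anti_idx: _SubjectIndex,
    rng: np.random.Generator,
    max_iter: int = 200,
) -> None:
    """Mutate around the planted window until the gene's max match is exact."""
    for _ in range(max_iter):
        text = "".join(seq)
        s_len = sense_idx.longest_match(text)
        a_len = anti_idx.longest_match(text)
        best = max(s_len, a_len)
        if best < planted_len:
            raise RuntimeError("planted match destroyed during repair")
        if best == planted_len:
            return
        idx = sense_idx if s_len >= a_len else anti_idx
        t_start, _ = idx.positions(text, best)[0]
        window = range(t_start, t_start + best)
        allowed = [p for p in window if not planted_span[0] <= p < planted_span[1]]
        _mutate(seq, allowed[int(rng.integers(len(allowed)))], rng)
    raise RuntimeError("planted-match repair did not converge")


def generate_transcriptome(
    config: SimulationConfig,
) -> tuple[SequenceRecord, list[SequenceRecord], GroundTruth]:
    """Trigger + transcriptome with planted matches/homologs and verified truth.

    Planted matches are inserted by copying trigger-strand substrings at
    random positions; planted homologs replace whole transcripts with
    mutated copies of the trigger.  After repair, the DP oracle verifies
    that every planted gene's max match equals its planted length and
    every other (non-homolog) gene's max match is below the reporting
    threshold.
    """
    dsrna = generate_dsrna(config)
    rng = _rng(config, 1)
    k = config.min_match_len
    ds, rc_ds = dsrna.sequence, reverse_complement(dsrna.sequence)
    sense_idx, anti_idx = _SubjectIndex(ds), _SubjectIndex(rc_ds)
    forbidden = sense_idx.kmers(k) | anti_idx.kmers(k)

    planted = {idx: (length, strand) for idx, length, strand in config.planted_matches}
    homolog = dict(config.planted_homologs)

    lo, hi = config.transcript_length_range
    n_digits = len(str(max(config.n_genes - 1, 1)))
    records: list[SequenceRecord] = []
    rows = []
    for g in range(config.n_genes):
        gene_id = f"g{g:0{n_digits}d}"
        if g in homolog:
            seq, realized = generate_homologs(dsrna, [homolog[g]], rng)[0]
            records.append(SequenceRecord(gene_id, seq))
            rows.append(
                dict(
                    gene=gene_id,
                    true_max_match=oracle_max_match(seq, ds),
                    match_strand="",
                    planted_match=False,
                    is_homolog=True,
                    target_identity=realized,
                )
            )
            continue
        length = int(rng.integers(lo, hi + 1))
        seq = list(_random_seq(rng, length, config.gc_content))
        if g in planted:
            p_len, strand = planted[g]
            if p_len > length:
                raise ValueError(
                    f"planted length {p_len} exceeds transcript length {length}"
                )
            src = ds if strand == "sense" else rc_ds
            a = int(rng.integers(0, len(src) - p_len + 1))
            pos = int(rng.integers(0, length - p_len + 1))
            seq[pos : pos + p_len] = list(src[a : a + p_len])
            span = (pos, pos + p_len)
            _strip_chance_matches(seq, forbidden, k, rng, keep_span=span)
            _repair_planted(seq, span, p_len, sense_idx, anti_idx, rng)
            text = "".join(seq)
            verified = oracle_max_match(text, ds)
            if verified != p_len:
                raise RuntimeError(
                    f"oracle verification failed for {gene_id}: "
                    f"max match {verified} != planted {p_len}"
                )
            records.append(SequenceRecord(gene_id, text))
            rows.append(
                dict(
                    gene=gene_id,
                    true_max_match=p_len,
                    match_strand=strand,
                    planted_match=True,
                    is_homolog=False,
                    target_identity=float("nan"),
                )
            )
        else:
            _strip_chance_matches(seq, forbidden, k, rng)
            text = "".join(seq)
            verified = oracle_max_match(text, ds)
            if verified >= k:
                raise RuntimeError(
                    f"oracle verification failed for {gene_id}: "
                    f"chance match of length {verified} survived repair"
                )
            records.append(SequenceRecord(gene_id, text))
            rows.append(
                dict(
                    gene=gene_id,
                    true_max_match=verified,
                    match_strand="",
                    planted_match=False,
                    is_homolog=False,
                    target_identity=float("nan"),
                )
            )

    genes = pd.DataFrame(rows).set_index("gene")
    genes["true_log2fc"] = 0.0
    genes["is_de"] = False
    truth = GroundTruth(genes=genes)
    homolog_ids = truth.homolog_genes()
    # seed genes anchor pathway level 1: the planted homologs, or the first
    # gene as a stand-in for the target's best transcriptome match
    truth.seed_genes = set(homolog_ids) if homolog_ids else {records[0].id}
    return dsrna, records, truth


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def blank_truth(config: SimulationConfig) -> GroundTruth:
    """Sequence-free ground truth (gene ids only), for counts-only studies."""
    n_digits = len(str(max(config.n_genes - 1, 1)))
    idx = pd.Index([f"g{g:0{n_digits}d}" for g in range(config.n_genes)], name="gene")
    genes = pd.DataFrame(
        {
            "true_max_match": 0,
            "match_strand": "",
            "planted_match": False,
            "is_homolog": False,
            "target_identity": float("nan"),
            "true_log2fc": 0.0,
            "is_de": False,
        },
        index=idx,
    )
    return GroundTruth(genes=genes, seed_genes={idx[0]})


def generate_counts(truth: GroundTruth, config: SimulationConfig) -> CountMatrix:
    """NB counts with log-normal baseline means and planted fold changes.

    Gene means are log-normal, scaled so each sample's expected depth is
    ``mean_depth`` (times its depth factor); treatment means of DE genes
    are multiplied by ``2**true_log2fc``.  Updates ``truth`` in place
    with the planted fold changes.
    """
    rng = _rng(config, 2)
    n = len(truth.genes)
    raw = rng.lognormal(mean=0.0, sigma=1.5, size=n)
    mu = raw / raw.sum() * config.mean_depth

    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc = np.zeros(n)
    lfc[de_idx] = signs * config.de_log2fc_magnitude
    truth.genes["true_log2fc"] = lfc
    truth.genes["is_de"] = lfc != 0.0

    n_rep = config.n_replicates_per_group
    samples = [f"treatment_{i + 1}" for i in range(n_rep)] + [
        f"control_{i + 1}" for i in range(n_rep)
    ]
    depth = (
        np.asarray(config.depth_factors, dtype=float)
        if config.depth_factors is not None
        else np.ones(2 * n_rep)
    )
    if depth.shape[0] != 2 * n_rep:
        raise ValueError("depth_factors must have one entry per sample")

    alpha = config.nb_dispersion
    cols = {}
    for j, s in enumerate(samples):
        m = mu * depth[j]
        if s.startswith("treatment"):
            m = m * 2.0**lfc
        if alpha < 1e-8:
            cols[s] = rng.poisson(m)
        else:
            size = 1.0 / alpha
            p = size / (size + m)
            cols[s] = rng.negative_binomial(size, p)
    df = pd.DataFrame(cols, index=truth.genes.index)
    groups = {s: ("treatment" if s.startswith("treatment") else "control") for s in samples}
    return CountMatrix(df, groups)


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------


def _expected_levels(spec: PathwaySpec, max_level: int = 3) -> dict[int, int | None]:
    """BFS distance (+1) of every pathway index from the seed pathways."""
    adj: dict[int, set[int]] = {i: set() for i in range(spec.n_pathways)}
    for i, j in spec.resolved_edges():
        if not (0 <= i < spec.n_pathways and 0 <= j < spec.n_pathways) or i == j:
            raise ValueError(f"invalid overlap edge ({i}, {j})")
        adj[i].add(j)
        adj[j].add(i)
    level: dict[int, int | None] = {i: None for i in range(spec.n_pathways)}
    frontier = [i for i in spec.seed_pathways]
    for i in frontier:
        if not 0 <= i < spec.n_pathways:
            raise ValueError(f"seed pathway index {i} out of range")
        level[i] = 1
    d = 1
    while frontier and d < max_level:
        nxt = []
        for i in frontier:
            for j in sorted(adj[i]):
                if level[j] is None:
                    level[j] = d + 1
                    nxt.append(j)
        frontier = nxt
        d += 1
    return level


def generate_pathways(
    truth: GroundTruth,
    config: SimulationConfig,
    max_level: int = 3,
) -> GeneSetCollection:
    """Gene sets whose overlap graph realizes the configured proximity levels.

    Pathways draw disjoint member genes from the transcriptome; each
    configured edge adds a single shared bridge gene; seed pathways also
    contain the seed genes.  The emitted collection is self-validated:
    the pipeline's breadth-first level assignment must reproduce the
    configured level of every pathway, else the spec is impossible.
    """
    spec = config.pathway_spec
    rng = _rng(config, 3)
    expected = _expected_levels(spec, max_level=max_level)

    pool = [g for g in truth.genes.index if g not in truth.seed_genes]
    pool = list(np.array(pool)[rng.permutation(len(pool))])
    sizes = rng.integers(spec.size_range[0], spec.size_range[1] + 1, size=spec.n_pathways)
    need = int(sizes.sum()) + len(spec.resolved_edges())
    if need > len(pool):
        raise ValueError(
            f"pathway spec needs {need} distinct genes but only {len(pool)} available"
        )
    names = [f"P{i:02d}" for i in range(spec.n_pathways)]
    sets: dict[str, set[str]] = {}
    cursor = 0
    for i, name in enumerate(names):
        sets[name] = set(pool[cursor : cursor + int(sizes[i])])
        cursor += int(sizes[i])
    for i, j in spec.resolved_edges():
        bridge = pool[cursor]
        cursor += 1
        sets[names[i]].add(bridge)
        sets[names[j]].add(bridge)
    for i in spec.seed_pathways:
        sets[names[i]] |= truth.seed_genes

    collection = GeneSetCollection(sets)
    if spec.seed_pathways:
        assignment = assign_pathway_levels(
            collection, truth.seed_genes, max_level=max_level
        )
        got = {names[i]: assignment.pathway_levels.get(names[i]) for i in range(spec.n_pathways)}
    else:
        got = {names[i]: None for i in range(spec.n_pathways)}
    want = {names[i]: expected[i] for i in range(spec.n_pathways)}
    if got != want:
        raise ValueError(
            f"impossible overlap spec: configured levels {want} but the "
            f"breadth-first assignment yields {got}"
        )
    truth.pathway_levels = want
    truth.pathway_members = {n: set(m) for n, m in sets.items()}
    return collection


def simulate_dataset(config: SimulationConfig, with_pathways: bool = True) -> SyntheticDataset:
    """Full seeded dataset: trigger, transcriptome, truth, counts, pathways."""
    dsrna, transcripts, truth = generate_transcriptome(config)
    counts = generate_counts(truth, config)
    gene_sets = generate_pathways(truth, config) if with_pathways else None
    return SyntheticDataset(dsrna, transcripts, truth, counts, gene_sets)
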