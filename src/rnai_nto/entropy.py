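"""Shannon transcriptomic entropy as a transcriptome-homeostasis metric.

A sample's transcriptome is summarized as the Shannon entropy of its
relative transcript abundances, H = -sum p_i log2 p_i (bits by default).
A perturbation that concentrates expression on few genes lowers H; a
treatment that leaves H unchanged relative to controls is evidence that
transcriptome homeostasis is preserved even if individual genes moved.

Entropy is computed on size-factor-normalized relative abundances of raw
counts; because p_i is scale-free per sample, the per-sample entropy is
invariant to sequencing depth, and the treatment/control comparison is
invariant to the logarithm base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de_analysis import median_of_ratios
from .io_formats import CountMatrix

__all__ = [
    "relative_abundance",
    "shannon_entropy",
    "sample_entropies",
    "compare_group_entropy",
    "EntropyResult",
]


def relative_abundance(counts_column, size_factor: float = 1.0) -> np.ndarray:
    """Normalized counts rescaled to a probability vector (sums to 1)."""
    x = np.asarray(counts_column, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if size_factor <= 0:
        raise ValueError("size factor must be positive")
    x = x / size_factor
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero column has no abundance distribution")
    return x / total


def shannon_entropy(p, base: float = 2.0) -> float:
    """H = -sum_{p_i > 0} p_i log p_i, with 0 log 0 = 0 (default: bits)."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1, got {p.sum()}")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(base))


def sample_entropies(counts: CountMatrix, base: float = 2.0) -> pd.DataFrame:
    """Per-sample entropy H and effective gene count base**H."""
    sf = median_of_ratios(counts)
    rows = []
    for s in counts.sample_ids:
        p = relative_abundance(counts.counts[s].to_numpy(), sf[s])
        h = shannon_entropy(p, base=base)
        rows.append(
            {
                "sample": s,
                "group": counts.groups[s],
                "H": h,
                "effective_gene_count": float(base**h),
            }
        )
    return pd.DataFrame(rows).set_index("sample")


@dataclass
class EntropyResult:
    """Per-sample entropies, group means +- SE, and the group comparison."""

    per_sample: pd.DataFrame
    group_stats: pd.DataFrame  # index group: mean, se, n
    t_statistic: float
    pvalue: float
    zero_variance: bool = False


def compare_group_entropy(counts: CountMatrix, base: float = 2.0) -> EntropyResult:
    """Two-sided Student's t-test of per-sample entropies between two groups.

    Requires exactly two groups with >=2 replicates each.  When both
    groups have zero variance (e.g. identical columns) the comparison is
    degenerate: t = 0, p = 1, flagged ``zero_variance``.
    """
    labels = counts.group_labels
    if len(labels) != 2:
        raise ValueError(f"expected exactly two groups, got {labels}")
    per_sample = sample_entropies(counts, base=base)
    groups = {g: per_sample.loc[per_sample["group"] == g, "H"].to_numpy() for g in labels}
    for g, h in groups.items():
        if len(h) < 2:
            raise ValueError(f"group {g!r} needs >=2 replicates, got {len(h)}")
    stats_rows = []
    for g in labels:
        h = groups[g]
        stats_rows.append(
            {
                "group": g,
                "mean": float(h.mean()),
                "se": float(h.std(ddof=1) / np.sqrt(len(h))),
                "n": len(h),
            }
        )
    group_stats = pd.DataFrame(stats_rows).set_index("group")
    a, b = groups[labels[0]], groups[labels[1]]
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return EntropyResult(per_sample, group_stats, 0.0, 1.0, zero_variance=True)
        return EntropyResult(
            per_sample, group_stats, float("inf"), 0.0, zero_variance=True
        )
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return EntropyResult(per_sample, group_stats, float(t), float(p))
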