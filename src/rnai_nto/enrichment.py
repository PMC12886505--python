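"""Hypergeometric over-representation test for gene sets.

For each pathway / GO term, the probability of drawing at least the
observed number of DEGs when sampling the DEG list from the gene
universe without replacement: upper-tail P(X >= k) for
X ~ Hypergeometric(N, K, n), where N is the universe size, K the set
size within the universe, n the number of DEGs, and k the DEGs in the
set.  Benjamini-Hochberg correction is applied across tested sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .de_analysis import bh_fdr
from .io_formats import GeneSetCollection

__all__ = ["hypergeom_pvalue", "enrich"]

logger = logging.getLogger(__name__)


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k), X ~ Hypergeometric(N, K, n).

    k: observed DEGs in the set; K: universe genes in the set; n: number
    of DEGs drawn; N: universe size.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K,n <= N; got k={k}, K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}, N={N}")
    # survival function at k-1 gives P(X >= k)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    deg_genes,
    universe,
    gene_sets: GeneSetCollection,
    min_set_size: int = 3,
) -> pd.DataFrame:
    """Over-representation of DEGs in each gene set, BH-corrected.

    Sets are intersected with the universe first; sets smaller than
    ``min_set_size`` after intersection are skipped (logged).  DEGs must
    be a subset of the universe.  Rows are sorted by p-value.
    """
    degs = set(deg_genes)
    uni = set(universe)
    outside = sorted(degs - uni)
    if outside:
        raise ValueError(
            f"{len(outside)} DEG(s) outside the universe, e.g. {outside[:10]}"
        )
    N = len(uni)
    n = len(degs)
    rows = []
    for name in gene_sets.names():
        members = gene_sets.sets[name] & uni
        if len(members) < min_set_size:
            logger.info("skipping set %r: %d genes in universe < %d",
                        name, len(members), min_set_size)
            continue
        K = len(members)
        k = len(members & degs)
        p = hypergeom_pvalue(k, K, n, N)
        fold = (k / n) / (K / N) if n > 0 else float("nan")
        rows.append(
            {
                "set_name": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "fold_enrichment": fold,
                "pvalue": p,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["set_name", "k", "K", "n", "N", "fold_enrichment", "pvalue"]
    )
    if len(frame):
        frame["fdr"] = bh_fdr(frame["pvalue"].to_numpy())
        frame = frame.sort_values(["pvalue", "set_name"], kind="mergesort")
    else:
        frame["fdr"] = np.array([], dtype=float)
    return frame.set_index("set_name")
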