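"""Hypergeometric over-representation of candidate genes in gene families.

For a universe of N genes, a family covering K of them, and a candidate
list of n genes overlapping the family in k, the enrichment p-value is the
hypergeometric upper tail P(X >= k).  Families are ranked by -log10 of
their Benjamini-Hochberg q-value.

The default universe is the set of genes carrying at least one variant
surviving the population-frequency stage (the exome-tested genes),
intersected with the genes that have family/set annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError, VariantKey
from .association import bh_fdr

__all__ = ["EnrichmentResult", "hypergeometric_upper_tail", "enrich", "enrich_by_feature"]

#: q-values are clipped here before taking -log10, to keep ranks finite.
NEG_LOG10_FLOOR = 1e-300


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    set_name: str
    k: int          # candidate genes in the set
    K: int          # set size within the universe
    n: int          # candidate list size
    N: int          # universe size
    p: float
    q: float
    neg_log10_q: float
    genes: tuple[str, ...]


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed in log space."""
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"hypergeometric bounds violated: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    candidate_genes,
    set_map: dict[str, set[str]],
    universe_genes,
    alpha: float = 0.05,
    set_names: dict[str, str] | None = None,
    include_empty: bool = False,
) -> list[EnrichmentResult]:
    """Test each gene set for over-representation among the candidates.

    Sets are intersected with the universe before K is computed; sets with
    no universe member or no candidate overlap are skipped unless
    ``include_empty``.  BH correction runs over all tested sets; results
    are sorted by -log10(q) descending, then overlap k descending, then
    set id.
    """
    universe = set(universe_genes)
    if not universe:
        raise ValidationError("empty universe")
    candidates = set(candidate_genes)
    strays = candidates - universe
    if strays:
        raise ValidationError(f"candidates outside the universe: {sorted(strays)}")
    set_names = set_names or {}

    N, n = len(universe), len(candidates)
    tested = []
    for set_id in sorted(set_map):
        members = set_map[set_id] & universe
        K = len(members)
        overlap = sorted(members & candidates)
        k = len(overlap)
        if K == 0 or (k == 0 and not include_empty):
            continue
        p = hypergeometric_upper_tail(k, K, n, N)
        tested.append((set_id, k, K, overlap, p))
    if not tested:
        return []

    qs = bh_fdr([t[4] for t in tested])
    results = [
        EnrichmentResult(
            set_id=set_id,
            set_name=set_names.get(set_id, set_id),
            k=k, K=K, n=n, N=N,
            p=p,
            q=float(q),
            neg_log10_q=float(-np.log10(max(q, NEG_LOG10_FLOOR))),
            genes=tuple(overlap),
        )
        for (set_id, k, K, overlap, p), q in zip(tested, qs)
    ]
    results.sort(key=lambda r: (-r.neg_log10_q, -r.k, r.set_id))
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    cols = ["set_id", "name", "k", "K", "n", "N", "p", "q", "neg_log10_q", "genes"]
    rows = [
        {
            "set_id": r.set_id, "name": r.set_name, "k": r.k, "K": r.K,
            "n": r.n, "N": r.N, "p": r.p, "q": r.q,
            "neg_log10_q": r.neg_log10_q, "genes": ",".join(r.genes),
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=cols)


def enrich_by_feature(
    feature_variant_sets: dict[str, set[VariantKey]],
    gene_of: dict[VariantKey, str],
    set_map: dict[str, set[str]],
    universe_genes,
    alpha: float = 0.05,
    set_names: dict[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Run enrichment per clinical feature's significant-variant gene list.

    Each feature's variant set is mapped to genes (restricted to the
    universe) and passed through :func:`enrich`; output tables carry
    -log10(p) and the gene ratio k/n for dot-plot style reporting.
    """
    out: dict[str, pd.DataFrame] = {}
    universe = set(universe_genes)
    for feature, keys in feature_variant_sets.items():
        genes = {gene_of[k] for k in keys if k in gene_of} & universe
        if not genes:
            out[feature] = enrichment_frame([])
            out[feature]["neg_log10_p"] = []
            out[feature]["gene_ratio"] = []
            continue
        results = enrich(genes, set_map, universe, alpha, set_names)
        frame = enrichment_frame(results)
        frame["neg_log10_p"] = -np.log10(np.maximum(frame["p"], NEG_LOG10_FLOOR))
        frame["gene_ratio"] = frame["k"] / frame["n"]
        out[feature] = frame
    return out
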