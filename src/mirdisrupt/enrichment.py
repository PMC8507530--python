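"""Target networks and enrichment statistics.

Three pieces: (1) a bipartite miRNA->target network built from an
experimentally-validated interaction table, keeping the top-N edges by
evidence strength then support count; (2) hypergeometric
over-representation of a query gene list in GMT gene sets with BH
adjustment; (3) preranked GSEA — the weighted Kolmogorov-Smirnov running
sum with gene-label permutation p-values, applied to a fold-change
ranking with an exclusive (min, max) set-size window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .core_io import AnalysisConfig, GeneSet, InteractionEdge
from .differential import benjamini_hochberg

__all__ = [
    "EnrichmentResult",
    "GseaResult",
    "build_target_network",
    "overrepresentation",
    "gsea_preranked",
    "enrichment_score",
]


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    query_size: int
    set_size: int
    universe_size: int
    p_value: float
    fdr: float = np.nan
    gene_ratio: float = 0.0  # overlap / query_size


@dataclass
class GseaResult:
    set_name: str
    es: float
    p_perm: float
    leading_edge: list[str] = field(default_factory=list)


def build_target_network(
    demirs: Sequence[str],
    interactions: Sequence[InteractionEdge],
    top_n: int = 100,
) -> nx.Graph:
    """Bipartite miRNA-target network from the top-ranked interactions.

    Edges are restricted to the query miRNAs, ranked by evidence level
    (strong before weak) then support count descending, ties broken
    lexicographically by (mirna, gene), and truncated to top_n.
    """
    query = set(demirs)
    edges = [e for e in interactions if e.mirna_id in query]
    edges.sort(key=lambda e: (e.evidence != "strong", -e.support,
                              e.mirna_id, e.target_gene))
    edges = edges[:top_n]
    g = nx.Graph()
    for m in demirs:
        g.add_node(m, bipartite="mirna")
    for e in edges:
        g.add_node(e.mirna_id, bipartite="mirna")
        g.add_node(e.target_gene, bipartite="gene")
        g.add_edge(e.mirna_id, e.target_gene,
                   evidence=e.evidence, support=e.support)
    if not edges:
        import warnings
        warnings.warn("no interactions for any query miRNA; network is empty")
    return g


def overrepresentation(
    query_genes: set[str] | Sequence[str],
    gene_sets: Sequence[GeneSet],
    universe: set[str] | Sequence[str],
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail over-representation per gene set.

    p = P(X >= overlap) with X ~ Hypergeom(universe_size, set_size,
    query_size); sets are intersected with the universe first and the
    query must be a subset of the universe.  FDR is BH across sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query_genes)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    results: list[EnrichmentResult] = []
    for gs in gene_sets:
        members = set(gs.members) & universe
        overlap = len(query & members)
        # upper tail P(X >= k) = sf(k - 1)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe),
                                     len(members), len(query)))
        results.append(EnrichmentResult(
            set_name=gs.name,
            overlap=overlap,
            query_size=len(query),
            set_size=len(members),
            universe_size=len(universe),
            p_value=min(p, 1.0),
            gene_ratio=overlap / len(query) if query else 0.0,
        ))
    fdrs = benjamini_hochberg([r.p_value for r in results])
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
    return results


def enrichment_score(
    ranked_genes: Sequence[str],
    scores: Sequence[float],
    members: set[str],
    weight: float = 1.0,
) -> tuple[float, int]:
    """Weighted KS running-sum enrichment score of one gene set.

    Walking the ranking, hits increment by |score|^weight (normalised to
    sum 1 over hits) and misses decrement by 1/(N - k).  ES is the
    running sum's maximum deviation from zero (signed); returns
    (ES, index of the extreme position).
    """
    n = len(ranked_genes)
    hit = np.fromiter((g in members for g in ranked_genes), bool, n)
    k = int(hit.sum())
    if k == 0 or k == n:
        raise ValueError("gene set must hit a strict subset of the ranking")
    w = np.abs(np.asarray(scores, float)) ** weight
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit scores zero -> uniform increments
        hit_w = hit.astype(float)
        total = float(k)
    running = np.cumsum(hit_w / total - (~hit) / (n - k))
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), idx


def gsea_preranked(
    ranking: Mapping[str, float],
    gene_sets: Sequence[GeneSet],
    cfg: AnalysisConfig | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> list[GseaResult]:
    """Preranked GSEA over a feature -> score mapping.

    Features are sorted by score descending (ties broken by name for
    determinism).  Sets are filtered to sizes strictly inside
    (cfg.gsea_min_set, cfg.gsea_max_set) after intersection with the
    ranking.  p_perm draws random same-size gene sets from the ranking
    (gene-label permutation — the only scheme available preranked) and
    applies the (# as-or-more-extreme on the matching sign + 1)/(n + 1)
    convention.  leading_edge is the member run up to the ES extremum.
    """
    cfg = cfg or AnalysisConfig()
    if len(set(ranking)) != len(ranking):
        raise ValueError("duplicate features in ranking")
    items = sorted(ranking.items(), key=lambda kv: (-kv[1], kv[0]))
    genes = [g for g, _ in items]
    scores = np.array([s for _, s in items], float)
    gene_set_index = set(genes)
    rng = np.random.default_rng(seed)

    out: list[GseaResult] = []
    for gs in gene_sets:
        members = set(gs.members) & gene_set_index
        if not (cfg.gsea_min_set < len(members) < cfg.gsea_max_set):
            continue
        es, idx = enrichment_score(genes, scores, members, weight)
        k = len(members)
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm = set(rng.choice(len(genes), size=k, replace=False))
            pm = {genes[i] for i in perm}
            null[b], _ = enrichment_score(genes, scores, pm, weight)
        if es >= 0:
            p = (int((null >= es).sum()) + 1) / (n_perm + 1)
        else:
            p = (int((null <= es).sum()) + 1) / (n_perm + 1)
        if es >= 0:
            leading = [g for g in genes[: idx + 1] if g in members]
        else:
            leading = [g for g in genes[idx:] if g in members]
        out.append(GseaResult(set_name=gs.name, es=es, p_perm=float(p),
                              leading_edge=leading))
    if not out:
        import warnings
        warnings.warn("all gene sets filtered out by the size window")
    return out
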