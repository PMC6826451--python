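"""Cluster-function association statistics.

Two complementary views of whether a compositional IGS cluster carries
biological signal:

* Interaction-network statistics -- genes behind the cluster's IGSs are
  mapped onto an interaction graph (score table thresholded at 700,
  strictly, edges unweighted); the size N_LCC and internal edge count
  N_link of the largest connected component are compared with a null
  obtained by drawing the same number of IGSs at random (operon structure
  preserved: IGSs are drawn, then expanded to all their genes), with mean,
  sample sd and z-score over the resamples.
* Category enrichment -- per functional category, an exact two-sided
  binomial test of the cluster's category count against the genomic
  background proportion, with Benjamini-Hochberg adjusted p-values
  reported alongside the raw ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

DEFAULT_SCORE_THRESHOLD = 700


@dataclass(frozen=True)
class NetworkStats:
    n_igs: int
    n_genes: int
    n_lcc: int
    n_link: int
    null_mean_lcc: float
    null_sd_lcc: float
    null_mean_link: float
    null_sd_link: float
    z_lcc: Optional[float]
    z_link: Optional[float]
    degenerate_null: bool = False  # sd = 0: z undefined


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Three-column TSV: gene1, gene2, integer channel score in [0, 1000]."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["gene1", "gene2", "score"], dtype=str, comment="#")
    if len(df) and tuple(df.iloc[0])[:2] == ("gene1", "gene2"):
        df = df.iloc[1:]
    df["score"] = df["score"].astype(int)
    if ((df["score"] < 0) | (df["score"] > 1000)).any():
        raise ValueError("scores must lie in [0, 1000]")
    return df.reset_index(drop=True)


def build_network(scores: pd.DataFrame,
                  threshold: int = DEFAULT_SCORE_THRESHOLD,
                  strict: bool = True) -> nx.Graph:
    """Unweighted graph of associations whose score overtakes the
    threshold (strictly by default; ``strict=False`` keeps ties)."""
    g = nx.Graph()
    keep = scores["score"] > threshold if strict else scores["score"] >= threshold
    for row in scores[keep].itertuples(index=False):
        if row.gene1 != row.gene2:
            g.add_edge(row.gene1, row.gene2)
    return g


def lcc_stats(graph: nx.Graph, gene_subset: Sequence[str]) -> tuple[int, int]:
    """(node count, internal edge count) of the largest connected component
    of the subgraph induced on ``gene_subset``.

    Genes absent from the graph count as isolated nodes.  Ties on size
    break by more internal edges, then by lexicographically smallest
    member.  An edgeless induced graph yields (1, 0).
    """
    subset = list(dict.fromkeys(gene_subset))
    if not subset:
        raise ValueError("empty gene subset")
    present = [g for g in subset if g in graph]
    sub = graph.subgraph(present).copy()
    sub.add_nodes_from(g for g in subset if g not in graph)
    best = None
    for comp in nx.connected_components(sub):
        edges = sub.subgraph(comp).number_of_edges()
        key = (len(comp), edges, tuple(sorted(comp)))
        if best is None or (key[0], key[1]) > (best[0], best[1]) or (
                (key[0], key[1]) == (best[0], best[1]) and key[2] < best[2]):
            best = key
    assert best is not None
    return best[0], best[1]


def resampling_null(
    graph: nx.Graph,
    igs_to_genes: Mapping[str, Sequence[str]],
    cluster_igs: Sequence[str],
    n_resamples: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> NetworkStats:
    """Observed LCC statistics for a cluster of IGSs against a resampling
    null of equal-size random IGS draws.

    Each resample draws ``len(cluster_igs)`` IGS ids uniformly without
    replacement from the whole set and expands them to their genes, so
    operon structure is preserved per draw.  The sample sd uses divisor
    n - 1; a zero sd flags the z-score as undefined.
    """
    rng = np.random.default_rng() if rng is None else rng
    all_igs = list(igs_to_genes)
    size = len(cluster_igs)
    if size == 0 or size > len(all_igs):
        raise ValueError("cluster size must be in [1, total IGS count]")
    genes = [g for igs in cluster_igs for g in igs_to_genes[igs]]
    obs_lcc, obs_link = lcc_stats(graph, genes)
    null = np.empty((n_resamples, 2))
    for r in range(n_resamples):
        draw = rng.choice(len(all_igs), size=size, replace=False)
        sample_genes = [g for i in draw for g in igs_to_genes[all_igs[i]]]
        null[r] = lcc_stats(graph, sample_genes)
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1) if n_resamples > 1 else np.zeros(2)
    degenerate = bool(np.any(sd == 0))
    z = [None if sd[i] == 0 else float(((obs_lcc, obs_link)[i] - mean[i]) / sd[i])
         for i in range(2)]
    return NetworkStats(
        n_igs=size, n_genes=len(set(genes)),
        n_lcc=obs_lcc, n_link=obs_link,
        null_mean_lcc=float(mean[0]), null_sd_lcc=float(sd[0]),
        null_mean_link=float(mean[1]), null_sd_link=float(sd[1]),
        z_lcc=z[0], z_link=z[1], degenerate_null=degenerate,
    )


def two_sided_binomial_p(k: int, n: int, p: float) -> float:
    """Exact two-sided binomial p-value as min(1, 2 * min(tails))."""
    lower = binom.cdf(k, n, p)
    upper = binom.sf(k - 1, n, p)
    return float(min(1.0, 2.0 * min(lower, upper)))


def binomial_enrichment(
    cluster_counts: Mapping[str, int],
    background_counts: Mapping[str, int],
) -> pd.DataFrame:
    """Exact binomial over/under-representation of functional categories.

    For each category, k successes out of n (the cluster's annotated
    total) are tested against the background proportion p.  Raw p-values
    are the primary output; Benjamini-Hochberg adjusted values are
    reported alongside.
    """
    bg_total = sum(background_counts.values())
    if bg_total == 0:
        raise ValueError("empty background")
    n = sum(cluster_counts.values())
    rows = []
    for cat in sorted(background_counts):
        if n == 0:
            continue
        k = int(cluster_counts.get(cat, 0))
        p = background_counts[cat] / bg_total
        if p == 0 or p == 1:
            continue
        rows.append({
            "category": cat,
            "cluster_count": k,
            "cluster_total": n,
            "background_proportion": p,
            "p_value": two_sided_binomial_p(k, n, p),
            "direction": "over" if k / n >= p else "under",
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def read_category_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV gene_id -> category."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["gene_id", "category"], dtype=str, comment="#")
    if len(df) and tuple(df.iloc[0]) == ("gene_id", "category"):
        df = df.iloc[1:]
    return dict(zip(df["gene_id"], df["category"]))


def category_counts(genes: Sequence[str],
                    gene_to_category: Mapping[str, str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for g in genes:
        cat = gene_to_category.get(g)
        if cat is not None:
            out[cat] = out.get(cat, 0) + 1
    return out
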