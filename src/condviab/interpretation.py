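"""Interpretation of attribution matrices.

Covers the downstream analyses: filtering to a control compound set (CCS),
K-means / Leiden clustering of attribution vectors with adjusted mutual
information against mechanism-of-action (MOA) labels, per-gene differential
attribution analysis (Wilcoxon rank-sum + Benjamini-Hochberg), and
protein-interaction network statistics for pooled target sets (subgraph
density against Monte-Carlo nulls, hypergeometric edge enrichment, and
generic gene-set enrichment over GMT files).
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_mutual_info_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "rank_sum_test", "bh_adjust", "build_ccs", "kmeans_ami",
    "compare_ami_baselines", "target_attribution_test", "leiden_clusters",
    "differential_attribution", "cluster_target_profile",
    "subgraph_connectivity", "connectivity_null", "interaction_enrichment",
    "geneset_enrichment", "load_ppi", "load_gmt", "DaaResult",
]


# ---------------------------------------------------------------------------
# Statistical kernels

def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Uses the exact Mann-Whitney U distribution for small tie-free groups and
    the tie-corrected normal approximation otherwise (scipy's 'auto' rule).
    """
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=np.float64)
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Control compound set and clustering

def build_ccs(meta: pd.DataFrame, moa_map: dict[str, str],
              n_cell_lines: int | None = None):
    """Filter attribution rows to MOA classes with >= 2 compounds
    attributed in *all* cell lines.

    ``meta`` needs cell_line_id and compound_id columns; ``moa_map`` maps
    compound_id -> MOA class.  Returns ``(row_mask, labels)`` where labels
    is a Series of MOA classes over the retained rows.
    """
    cells = sorted(meta["cell_line_id"].unique())
    if n_cell_lines is None:
        n_cell_lines = len(cells)
    complete = {
        comp for comp, grp in meta.groupby("compound_id")
        if grp["cell_line_id"].nunique() == n_cell_lines
    }
    by_class: dict[str, set] = {}
    for comp in complete:
        cls = moa_map.get(comp)
        if cls is not None:
            by_class.setdefault(cls, set()).add(comp)
    kept_classes = {cls for cls, comps in by_class.items() if len(comps) >= 2}
    if not kept_classes:
        raise ValueError("no MOA class survives the control-compound-set "
                         "filter (>= 2 compounds in all cell lines)")
    kept_compounds = {c for cls in kept_classes for c in by_class[cls]}
    mask = meta["compound_id"].isin(kept_compounds).to_numpy()
    labels = meta.loc[mask, "compound_id"].map(moa_map)
    return mask, labels


def kmeans_ami(vectors, true_labels, k: int | None = None,
               n_trials: int = 5, seed: int = 0) -> list[float]:
    """AMI between K-means clusters of the rows and the true labels, over
    ``n_trials`` independently seeded trials.

    k defaults to the number of distinct true labels.  AMI uses the
    expected-mutual-information chance correction, so an uninformative
    clustering scores ~0 and a label-identical one scores 1.
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    true_labels = np.asarray(true_labels)
    if k is None:
        k = len(set(true_labels.tolist()))
    if k < 2 or vectors.shape[0] < k:
        raise ValueError("need k >= 2 and at least k rows")
    out = []
    for t in range(n_trials):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed + t)
        pred = km.fit_predict(vectors)
        out.append(float(adjusted_mutual_info_score(true_labels, pred)))
    return out


def compare_ami_baselines(sources: dict[str, np.ndarray], labels,
                          k: int | None = None, n_trials: int = 5,
                          seed: int = 0):
    """AMI distributions for several row-aligned feature sources (trained
    attributions, fingerprints, control-model attributions, ...) plus
    pairwise two-sided Wilcoxon rank-sum tests between them."""
    labels = np.asarray(labels)
    amis = {}
    for name, vec in sources.items():
        vec = np.asarray(vec, dtype=np.float64)
        if vec.shape[0] != len(labels):
            raise ValueError(f"source {name!r} is not row-aligned to labels")
        amis[name] = kmeans_ami(vec, labels, k=k, n_trials=n_trials, seed=seed)
    names = list(sources)
    tests = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            tests[(a, b)] = rank_sum_test(amis[a], amis[b])
    return amis, tests


# ---------------------------------------------------------------------------
# Target-level attribution statistics

def target_attribution_test(values: pd.DataFrame, labels,
                            class_targets: dict[str, list[str]]) -> pd.DataFrame:
    """Per MOA class, per nominal target: rank-sum test of the target
    gene's attribution in-class vs out-of-class, BH-adjusted across all
    tests.  Also reports the mean attribution difference so each class's
    strongest target can be selected."""
    labels = np.asarray(labels)
    rows = []
    for cls, targets in class_targets.items():
        in_mask = labels == cls
        if in_mask.sum() == 0 or (~in_mask).sum() == 0:
            continue
        for gene in targets:
            if gene not in values.columns:
                rows.append((cls, gene, np.nan, np.nan, False))
                continue
            col = values[gene].to_numpy(dtype=np.float64)
            p = rank_sum_test(col[in_mask], col[~in_mask])
            eff = float(col[in_mask].mean() - col[~in_mask].mean())
            rows.append((cls, gene, eff, p, True))
    df = pd.DataFrame(rows, columns=["moa_class", "target", "effect",
                                     "p", "testable"])
    df["q"] = np.nan
    ok = df["testable"].to_numpy()
    if ok.any():
        df.loc[ok, "q"] = bh_adjust(df.loc[ok, "p"].to_numpy())
    return df


def leiden_clusters(vectors, resolution: float = 1.0, k_neighbors: int = 15,
                    seed: int = 0) -> np.ndarray:
    """Leiden community detection on a cosine-similarity kNN graph of the
    rows; deterministic given the seed."""
    X = np.asarray(vectors, dtype=np.float64)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need >= 2 rows")
    k = min(k_neighbors, n - 1)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    U = X / norms
    sim = U @ U.T
    np.fill_diagonal(sim, -np.inf)
    edges, weights = [], []
    for i in range(n):
        for j in np.argpartition(-sim[i], k)[:k]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            edges.append((a, b))
            weights.append(max(float(sim[a, b]), 1e-9))
    uniq = {}
    for e, w in zip(edges, weights):
        uniq[e] = w
    graph = ig.Graph(n=n, edges=list(uniq), edge_attrs={"weight":
                                                        list(uniq.values())})
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=seed)
    return np.asarray(part.membership)


@dataclass
class DaaResult:
    """Differential attribution analysis output for one cluster."""
    table: pd.DataFrame          # gene, statistic effect, p, q — ranked
    top10: list[str]

    @property
    def genes(self):
        return self.table["gene"].tolist()


def differential_attribution(values: pd.DataFrame, cluster_labels,
                             cluster_ids) -> DaaResult:
    """Per-gene rank-sum test of attributions inside a cluster (or a merge
    of clusters) against all remaining rows, BH-adjusted across genes.

    The output is ranked by q then descending absolute mean difference;
    ``top10`` is the head of that ranking.
    """
    cluster_labels = np.asarray(cluster_labels)
    if np.isscalar(cluster_ids):
        cluster_ids = [cluster_ids]
    mask = np.isin(cluster_labels, np.asarray(cluster_ids))
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("cluster and complement each need >= 2 rows")
    M = values.to_numpy(dtype=np.float64)
    pvals, effects = [], []
    for j in range(M.shape[1]):
        pvals.append(rank_sum_test(M[mask, j], M[~mask, j]))
        effects.append(float(M[mask, j].mean() - M[~mask, j].mean()))
    q = bh_adjust(pvals)
    df = pd.DataFrame({"gene": values.columns, "effect": effects,
                       "p": pvals, "q": q})
    df = df.sort_values(["q", "effect"],
                        key=lambda s: s if s.name == "q" else -s.abs(),
                        kind="mergesort").reset_index(drop=True)
    return DaaResult(table=df, top10=df["gene"].head(10).tolist())


def cluster_target_profile(cluster_compounds, moa_map: dict[str, str],
                           class_targets: dict[str, list[str]],
                           seed: int = 0) -> set[str]:
    """Pooled target set for one attribution cluster: one nominal target
    chosen uniformly at random per MOA class present (avoids
    over-connectivity from same-pathway co-targets); classes without
    annotated targets are skipped with a warning."""
    import warnings
    rng = np.random.default_rng(seed)
    classes = sorted({moa_map[c] for c in cluster_compounds if c in moa_map})
    chosen = set()
    for cls in classes:
        targets = sorted(class_targets.get(cls, []))
        if not targets:
            warnings.warn(f"MOA class {cls!r} has no annotated targets",
                          stacklevel=2)
            continue
        chosen.add(targets[int(rng.integers(len(targets)))])
    return chosen


# ---------------------------------------------------------------------------
# Protein-interaction network statistics

def load_ppi(path, score_floor: float = 0.7) -> nx.Graph:
    """TSV edge list (node_a, node_b, combined_score).  Scores on a 0-1000
    scale are auto-detected and rescaled to 0-1; edges at or below
    ``score_floor`` are dropped, as are self-loops."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns[:3])
    scores = df[cols[2]].to_numpy(dtype=np.float64)
    if scores.max() > 1.0:
        scores = scores / 1000.0
    graph = nx.Graph()
    for (a, b), s in zip(df[cols[:2]].itertuples(index=False), scores):
        if a == b or s <= score_floor:
            continue
        graph.add_edge(str(a), str(b), weight=float(s))
    return graph


def subgraph_connectivity(graph: nx.Graph, nodes) -> float:
    """Induced-subgraph edge density: edges among the node set over
    n(n-1)/2.  Nodes absent from the graph count with degree 0; sets of
    size < 2 score 0."""
    nodes = set(nodes)
    n = len(nodes)
    if n < 2:
        return 0.0
    present = [v for v in nodes if v in graph]
    edges = sum(1 for u in present for v in graph.adj[u] if v in nodes) // 2
    return float(edges / (n * (n - 1) / 2))


def induced_edge_count(graph: nx.Graph, nodes) -> int:
    present = [v for v in set(nodes) if v in graph]
    return int(nx.induced_subgraph(graph, present).number_of_edges())


def connectivity_null(graph: nx.Graph, node_set, pool, n_draws: int = 1000,
                      seed: int = 0):
    """Monte-Carlo null for subgraph density: ``n_draws`` same-size sets
    drawn from ``pool`` without replacement, with the +1-smoothed empirical
    one-sided p-value P(null >= observed)."""
    node_set = set(node_set)
    pool = sorted(set(pool))
    if len(pool) < len(node_set):
        raise ValueError("candidate pool smaller than the query set")
    rng = np.random.default_rng(seed)
    observed = subgraph_connectivity(graph, node_set)
    null = np.empty(n_draws)
    pool_arr = np.asarray(pool, dtype=object)
    for i in range(n_draws):
        draw = rng.choice(pool_arr, size=len(node_set), replace=False)
        null[i] = subgraph_connectivity(graph, draw)
    p = (1 + int(np.sum(null >= observed))) / (n_draws + 1)
    return {"observed": observed, "null": null, "p": float(p)}


def interaction_enrichment(graph: nx.Graph, nodes, background_size: int
                           ) -> float:
    """Upper-tail hypergeometric probability of the observed induced edge
    count: draw |pairs(nodes)| pairs from the background pair universe in
    which the graph's edges are the successes."""
    nodes = set(nodes)
    n = len(nodes)
    if n < 2:
        raise ValueError("need >= 2 nodes")
    if background_size < n:
        raise ValueError("background smaller than the query set")
    universe = background_size * (background_size - 1) // 2
    successes = graph.number_of_edges()
    if successes > universe:
        raise ValueError("graph has more edges than the background pair "
                         "universe allows")
    draws = n * (n - 1) // 2
    observed = induced_edge_count(graph, nodes)
    return float(stats.hypergeom.sf(observed - 1, universe, successes, draws))


def load_gmt(path) -> dict[str, set]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def geneset_enrichment(query_genes, genesets: dict[str, set] | str,
                       background) -> pd.DataFrame:
    """One-sided hypergeometric overlap enrichment of a query gene list
    against each gene set, BH-adjusted across sets."""
    if isinstance(genesets, str):
        genesets = load_gmt(genesets)
    background = set(background)
    query = set(query_genes) & background
    if not query:
        raise ValueError("empty query after background intersection")
    N, n = len(background), len(query)
    rows = []
    for name, genes in genesets.items():
        K = len(genes & background)
        k = len(genes & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, K, k, p))
    df = pd.DataFrame(rows, columns=["gene_set", "set_size", "overlap", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values("p", kind="mergesort").reset_index(drop=True)
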