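"""Interaction-network enrichment and ranked candidate expansion.

Deconvoluted hits are placed on a supplied gene-gene interaction edge list
(a STRING-style export; the database itself is never fetched).  Enrichment
of a gene set is measured by the edge count of its induced subgraph against
a permutation null of equal-size gene sets drawn uniformly from the
background universe:

    p = (1 + #{null >= observed}) / (1 + R)

for R permutations.  An analytic mode fits a normal tail to the permutation
null so that p-values far below 1/R (such as the 1e-8 background-noise
threshold used for expansion) can be resolved; it is the package's own
approximation, with no claim of equivalence to any database's score.

The expansion procedure adds ranked candidate genes in groups (default ten,
by ranked z-score) and stops before the first group whose inclusion pushes
the cumulative enrichment p past the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


# --------------------------------------------------------------------------
# graph construction
# --------------------------------------------------------------------------


def read_edge_list(path) -> pd.DataFrame:
    """Read a 3-column TSV edge list (gene_a, gene_b, score); header optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("edge list needs at least two columns")
    first = df.iloc[0]
    if str(first[0]).lower() in ("gene_a", "protein1", "node1", "source"):
        df = df.iloc[1:].reset_index(drop=True)
    df = df.iloc[:, :3] if df.shape[1] >= 3 else df.assign(score="1")
    df.columns = ["gene_a", "gene_b", "score"]
    df["score"] = pd.to_numeric(df["score"], errors="coerce").fillna(1.0)
    return df


def build_network(
    edges: pd.DataFrame | Iterable[tuple],
    universe: Sequence[str] | None = None,
    score_floor: float | None = None,
) -> nx.Graph:
    """Undirected scored graph from an edge table; dedup, no self-loops.

    ``universe`` (default: all genes touched by an edge) becomes the
    background gene set for permutation nulls, stored on the graph.
    """
    if isinstance(edges, pd.DataFrame):
        rows = edges[["gene_a", "gene_b", "score"]].itertuples(index=False)
    else:
        rows = ((a, b, s) for a, b, s in edges)
    g = nx.Graph()
    for a, b, score in rows:
        if a == b:
            continue
        if score_floor is not None and float(score) < score_floor:
            continue
        if g.has_edge(a, b):
            g[a][b]["score"] = max(g[a][b]["score"], float(score))
        else:
            g.add_edge(a, b, score=float(score))
    if universe is not None:
        g.add_nodes_from(universe)
        g.graph["universe"] = tuple(sorted(set(universe)))
    else:
        g.graph["universe"] = tuple(sorted(g.nodes))
    return g


def build_subnetwork(genes: Sequence[str], graph: nx.Graph) -> nx.Graph:
    """Induced subgraph on ``genes``; symbols absent from the graph are logged."""
    if len(genes) == 0:
        raise ValueError("gene set must be nonempty")
    present = [g for g in genes if g in graph]
    missing = sorted(set(genes) - set(present))
    sub = graph.subgraph(present).copy()
    sub.add_nodes_from(present)
    sub.graph["unmatched"] = tuple(missing)
    return sub


def induced_edge_count(graph: nx.Graph, genes: Sequence[str]) -> int:
    node_set = set(genes)
    return sum(1 for a, b in graph.edges if a in node_set and b in node_set)


def largest_component_stats(graph: nx.Graph) -> tuple[int, int]:
    """(nodes, edges) of the largest connected component.

    Ties on node count break by edge count, then by lexicographically
    smallest member node.  Empty graph -> (0, 0).
    """
    if graph.number_of_nodes() == 0:
        return (0, 0)
    comps = [
        (len(c), graph.subgraph(c).number_of_edges(), min(c))
        for c in nx.connected_components(graph)
    ]
    comps.sort(key=lambda t: (-t[0], -t[1], t[2]))
    return comps[0][0], comps[0][1]


# --------------------------------------------------------------------------
# enrichment
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentResult:
    pvalue: float
    observed_edges: int
    null_mean: float
    null_sd: float
    n_permutations: int
    mode: str
    null_model: str = "permutation"


@dataclass(frozen=True)
class EnrichmentConfig:
    """Parameters of the expansion procedure; the seed is mandatory."""

    seed: int
    group_size: int = 10
    threshold: float = 1e-8
    n_permutations: int = 10_000
    mode: str = "analytic"  # needed to resolve p below 1/R
    scope: str = "cumulative"  # or "marginal": test each group's contribution
    score_floor: float | None = None
    null_model: str = "permutation"  # or "rewiring" (degree-preserving)

    def __post_init__(self) -> None:
        if self.group_size < 1:
            raise ValueError("group size must be >= 1")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")


def _null_edge_counts(
    graph: nx.Graph,
    universe: Sequence[str],
    k: int,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Edge counts of R uniform k-subsets of the universe (vectorized)."""
    nodes = list(universe)
    n = len(nodes)
    index = {g: i for i, g in enumerate(nodes)}
    adj = np.zeros((n, n), dtype=bool)
    for a, b in graph.edges:
        ia, ib = index.get(a), index.get(b)
        if ia is not None and ib is not None:
            adj[ia, ib] = adj[ib, ia] = True
    counts = np.empty(n_permutations, dtype=np.int64)
    pairs = list(combinations(range(k), 2))
    pi = np.array([p[0] for p in pairs])
    pj = np.array([p[1] for p in pairs])
    chunk = max(1, min(n_permutations, 20_000_000 // max(1, n)))
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        keys = rng.random((m, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        counts[done : done + m] = adj[idx[:, pi], idx[:, pj]].sum(axis=1)
        done += m
    return counts


def _rewired_edge_counts(
    graph: nx.Graph,
    selected: Sequence[str],
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null via degree-preserving double-edge swaps of the whole graph."""
    counts = np.empty(n_permutations, dtype=np.int64)
    n_swaps = max(1, 2 * graph.number_of_edges())
    for i in range(n_permutations):
        g = graph.copy()
        try:
            nx.double_edge_swap(
                g, nswap=n_swaps, max_tries=20 * n_swaps, seed=int(rng.integers(2**31))
            )
        except nx.NetworkXError:
            pass
        counts[i] = induced_edge_count(g, selected)
    return counts


def enrichment_pvalue(
    selected: Sequence[str],
    graph: nx.Graph,
    universe: Sequence[str] | None = None,
    n_permutations: int = 10_000,
    seed: int = 0,
    mode: str = "permutation",
    null_model: str = "permutation",
) -> EnrichmentResult:
    """Enrichment p of the induced edge count of ``selected`` genes.

    Permutation mode: ``p = (1 + #{null >= observed}) / (1 + R)`` over R
    equal-size gene sets drawn uniformly from the universe (or, with
    ``null_model='rewiring'``, over degree-preserving rewirings of the
    graph).  Analytic mode fits a normal tail (continuity-corrected) to the
    same null sample, resolving p-values below 1/R; the result is floored at
    1e-300 so it stays in (0, 1].
    """
    selected = sorted(set(selected))
    universe = list(universe if universe is not None else graph.graph.get("universe", graph.nodes))
    if not set(selected) <= set(universe):
        raise ValueError("selected genes must lie within the universe")
    if len(universe) < 2 * len(selected):
        raise ValueError("universe must be at least twice the selected set")
    observed = induced_edge_count(graph, selected)
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xE27])
    if null_model == "rewiring":
        null = _rewired_edge_counts(graph, selected, n_permutations, rng)
    else:
        null = _null_edge_counts(graph, universe, len(selected), n_permutations, rng)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if len(null) > 1 else 0.0

    if observed == 0:
        p = 1.0
    elif mode == "analytic":
        if null_sd == 0:
            p = 1.0 if observed <= null_mean else 1e-300
        else:
            p = float(stats.norm.sf(observed - 0.5, loc=null_mean, scale=null_sd))
            p = max(p, 1e-300)
    else:
        p = (1 + int(np.sum(null >= observed))) / (1 + n_permutations)
    return EnrichmentResult(
        pvalue=min(p, 1.0),
        observed_edges=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        n_permutations=n_permutations,
        mode=mode,
        null_model=null_model,
    )


def enrichment_pvalue_exact(
    selected: Sequence[str], graph: nx.Graph, universe: Sequence[str]
) -> float:
    """Exact enumeration over all equal-size subsets (small universes only)."""
    observed = induced_edge_count(graph, selected)
    if observed == 0:
        return 1.0
    k = len(set(selected))
    universe = sorted(set(universe))
    total = 0
    at_least = 0
    for subset in combinations(universe, k):
        total += 1
        if induced_edge_count(graph, subset) >= observed:
            at_least += 1
    return at_least / total


# --------------------------------------------------------------------------
# ranked expansion
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpansionResult:
    final_genes: tuple[str, ...]
    n_added: int
    trace: pd.DataFrame  # one row per evaluated set (core first)


def iterative_expansion(
    core: Sequence[str],
    candidates: Sequence[str],
    graph: nx.Graph,
    config: EnrichmentConfig,
    universe: Sequence[str] | None = None,
) -> ExpansionResult:
    """Grow the core set by ranked candidate groups under an enrichment gate.

    Candidates (already ranked, disjoint from the core) are appended in
    groups of ``config.group_size``; after each addition the enrichment p of
    the cumulative set (or of the group's marginal edge contribution, with
    ``scope='marginal'``) is computed.  Expansion stops before the first
    group whose inclusion makes p exceed the threshold; the last compliant
    set and the full trace are returned.  Reproducible for a fixed seed.
    """
    core = list(dict.fromkeys(core))
    candidates = [c for c in dict.fromkeys(candidates) if c not in set(core)]
    universe = list(
        universe if universe is not None else graph.graph.get("universe", graph.nodes)
    )

    def _p(genes: Sequence[str], prev_edges: int, step: int) -> EnrichmentResult:
        res = enrichment_pvalue(
            genes,
            graph,
            universe=universe,
            n_permutations=config.n_permutations,
            seed=config.seed + step,
            mode=config.mode,
            null_model=config.null_model,
        )
        if config.scope == "marginal" and step > 0:
            # p of the marginal edge gain against the same-size null gain
            marginal = res.observed_edges - prev_edges
            if res.null_sd == 0:
                p = 1.0 if marginal <= 0 else 1e-300
            else:
                p = float(
                    stats.norm.sf(marginal - 0.5, loc=0.0, scale=res.null_sd)
                )
            res = EnrichmentResult(
                max(min(p, 1.0), 1e-300),
                res.observed_edges,
                res.null_mean,
                res.null_sd,
                res.n_permutations,
                res.mode,
                res.null_model,
            )
        return res

    rows = []
    current = list(core)
    res = _p(current, 0, 0)
    rows.append(
        {
            "step": 0,
            "n_genes": len(current),
            "added": "",
            "observed_edges": res.observed_edges,
            "pvalue": res.pvalue,
            "accepted": True,
        }
    )
    prev_edges = res.observed_edges
    n_added = 0
    step = 0
    for start in range(0, len(candidates), config.group_size):
        group = candidates[start : start + config.group_size]
        step += 1
        trial = current + group
        res = _p(trial, prev_edges, step)
        accepted = res.pvalue <= config.threshold
        rows.append(
            {
                "step": step,
                "n_genes": len(trial),
                "added": ";".join(group),
                "observed_edges": res.observed_edges,
                "pvalue": res.pvalue,
                "accepted": accepted,
            }
        )
        if not accepted:
            break
        current = trial
        n_added += len(group)
        prev_edges = res.observed_edges
    trace = pd.DataFrame(rows)
    return ExpansionResult(tuple(current), n_added, trace)
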