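"""Compositional sparse association networks with stability selection.

Counts are compositional: only relative abundances are observed, so raw
correlations are spurious.  The approach here follows the
neighborhood-selection flavour of sparse inverse-covariance estimation for
microbiome data: counts are centered-log-ratio (CLR) transformed, each
species' CLR profile is regressed on all others with an L1 penalty, and the
union ("or" rule) of nonzero coefficients defines the graph.  The penalty
is chosen by StARS — the Stability Approach to Regularization Selection —
which subsamples the data and picks the densest graph whose edge-selection
instability stays below a threshold (default 0.05).

Multi-study consensus: per-study networks are merged by keeping edges that
appear with the same sign in at least ``consensus_min_support`` studies
(default 2), mirroring a "2 of 3 data sets" rule.  Edge endpoints are then
annotated with cobamide biosynthesis categories to count producer/salvager/
nonproducer edge classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

from .genome_classification import CobamideAnnotation


@dataclass(frozen=True)
class NetworkParams:
    pseudocount: float = 1.0
    n_lambda: int = 20
    lambda_min_ratio: float = 0.01
    stars_subsamples: int = 50
    stars_instability_threshold: float = 0.05
    symmetrization: str = "or"  # or | and
    seed: int = 0
    min_mean_abundance: float = 0.00015
    min_prevalence: float = 0.55
    consensus_min_support: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.lambda_min_ratio < 1):
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        if self.symmetrization not in ("or", "and"):
            raise ValueError("symmetrization must be 'or' or 'and'")


def stars_subsample_size(n: int) -> int:
    """StARS subsample size: min(floor(10*sqrt(n)), floor(0.8*n))."""
    return min(int(np.floor(10 * np.sqrt(n))), int(np.floor(0.8 * n)))


@dataclass
class AssociationNetwork:
    """Signed species graph: edges (a, b, sign, weight) with a < b."""

    edges: pd.DataFrame  # columns: species_a, species_b, sign, weight
    node_attrs: pd.DataFrame | None = None  # indexed by species

    def __post_init__(self) -> None:
        required = ["species_a", "species_b", "sign", "weight"]
        missing = [c for c in required if c not in self.edges.columns]
        if missing:
            raise ValueError(f"edge table missing columns {missing}")
        if (self.edges["species_a"] >= self.edges["species_b"]).any():
            raise ValueError("edges must be canonically ordered (a < b)")
        pairs = list(zip(self.edges["species_a"], self.edges["species_b"]))
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate edges")

    @property
    def nodes(self) -> set[str]:
        if self.node_attrs is not None:
            return set(self.node_attrs.index)
        return set(self.edges["species_a"]) | set(self.edges["species_b"])

    def edge_set(self) -> dict[tuple[str, str], int]:
        return {
            (a, b): int(s)
            for a, b, s in zip(
                self.edges["species_a"], self.edges["species_b"], self.edges["sign"]
            )
        }

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.species_a, row.species_b,
                       sign=int(row.sign), weight=float(row.weight))
        if self.node_attrs is not None:
            for col in self.node_attrs.columns:
                nx.set_node_attributes(g, self.node_attrs[col].to_dict(), col)
        return g


def filter_species(
    matrices: Sequence[pd.DataFrame],
    params: NetworkParams | None = None,
) -> list[str]:
    """Roster of species passing abundance/prevalence cutoffs, pooled.

    A species is kept when its mean relative abundance across the pooled
    samples exceeds ``min_mean_abundance`` and it is detected (count > 0)
    in at least ``min_prevalence`` of pooled samples.
    """
    params = params or NetworkParams()
    if not matrices:
        raise ValueError("no count matrices supplied")
    pooled = pd.concat(matrices, axis=0)
    if pooled.empty:
        raise ValueError("pooled sample set is empty")
    rel = pooled.div(pooled.sum(axis=1), axis=0)
    mean_ab = rel.mean(axis=0)
    prevalence = (pooled > 0).mean(axis=0)
    keep = (mean_ab > params.min_mean_abundance) & (
        prevalence >= params.min_prevalence
    )
    return [s for s in pooled.columns if keep[s]]


def clr_transform(counts: np.ndarray | pd.DataFrame, pseudocount: float = 1.0) -> np.ndarray:
    """Centered log-ratio transform, per sample (row)."""
    x = np.asarray(counts, dtype=float) + pseudocount
    if (x <= 0).any():
        raise ValueError("nonpositive entries after pseudocount; "
                         "all-zero rows need pseudocount > 0")
    p = x / x.sum(axis=1, keepdims=True)
    logp = np.log(p)
    return logp - logp.mean(axis=1, keepdims=True)


def _lambda_path(z: np.ndarray, params: NetworkParams) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max down, shared across nodes.

    lambda_max is the largest |off-diagonal| entry of the empirical
    covariance of the standardized CLR columns, which zeroes every
    neighborhood regression.
    """
    n = z.shape[0]
    s = (z.T @ z) / n
    off = np.abs(s - np.diag(np.diag(s)))
    lam_max = off.max()
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * params.lambda_min_ratio, params.n_lambda)


def _standardize(clr: np.ndarray) -> np.ndarray:
    z = clr - clr.mean(axis=0)
    sd = z.std(axis=0)
    sd[sd == 0] = 1.0
    return z / sd


def neighborhood_path(
    clr: np.ndarray, params: NetworkParams | None = None,
    lambdas: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-node lasso regressions along a shared penalty path.

    Each node's standardized CLR column is regressed on all others via
    coordinate descent (objective (1/2n)||y - Xb||^2 + lambda*||b||_1,
    tolerance 1e-6).  Returns ``(lambdas, adjacency, coefs)`` where
    ``adjacency[k]`` is the symmetrized 0/1 matrix at ``lambdas[k]`` and
    ``coefs[k][i, j]`` is node i's coefficient on node j.
    """
    params = params or NetworkParams()
    z = _standardize(np.asarray(clr, dtype=float))
    n, p = z.shape
    if n < 10 or p < 3:
        raise ValueError("need at least 10 samples and 3 species")
    if lambdas is None:
        lambdas = _lambda_path(z, params)
    nl = len(lambdas)
    coefs = np.zeros((nl, p, p))
    others = np.arange(p)
    for j in range(p):
        idx = others[others != j]
        X, y = z[:, idx], z[:, j]
        # sklearn's coordinate descent solves the same (1/2n) objective
        _, path_coefs, _ = lasso_path(
            X, y, alphas=lambdas, tol=1e-6, max_iter=10_000
        )
        # lasso_path returns coefficients for alphas in decreasing order
        order = np.argsort(lambdas)[::-1]
        inverse = np.argsort(order)
        coefs[:, j, idx] = path_coefs.T[inverse]
    directed = coefs != 0
    if params.symmetrization == "or":
        adjacency = directed | directed.transpose(0, 2, 1)
    else:
        adjacency = directed & directed.transpose(0, 2, 1)
    for k in range(nl):
        np.fill_diagonal(adjacency[k], False)
    return np.asarray(lambdas), adjacency, coefs


@dataclass
class StarsResult:
    lambda_opt: float
    lambda_index: int
    lambdas: np.ndarray
    instability: np.ndarray             # raw, per lambda
    monotonized_instability: np.ndarray
    stability: np.ndarray               # per-edge selection frequency at lambda_opt
    adjacency: np.ndarray               # full-data adjacency at lambda_opt
    coefs: np.ndarray                   # full-data directed coefficients at lambda_opt


def stars_select(
    clr: np.ndarray, params: NetworkParams | None = None
) -> StarsResult:
    """Choose the penalty by StARS and refit the network on the full data.

    Draws ``stars_subsamples`` subsamples without replacement of size
    min(floor(10*sqrt(n)), floor(0.8*n)); per edge and penalty the selection
    frequency xi is recorded; per-penalty instability is the mean of
    2*xi*(1 - xi) over all node pairs.  The selected penalty is the smallest
    (densest graph) whose monotonized instability (cumulative max from the
    sparse end) stays at or below the threshold; if none qualifies, the
    sparsest penalty is returned with a warning.
    """
    params = params or NetworkParams()
    z = np.asarray(clr, dtype=float)
    n, p = z.shape
    rng = np.random.default_rng(params.seed)
    lambdas = _lambda_path(_standardize(z), params)
    b = stars_subsample_size(n)
    freq = np.zeros((len(lambdas), p, p))
    for _ in range(params.stars_subsamples):
        idx = rng.choice(n, size=b, replace=False)
        _, adj, _ = neighborhood_path(z[idx], params, lambdas=lambdas)
        freq += adj
    freq /= params.stars_subsamples
    iu = np.triu_indices(p, k=1)
    xi = freq[:, iu[0], iu[1]]
    instability = (2 * xi * (1 - xi)).mean(axis=1)
    # lambdas run dense->... no: index 0 is lambda_max (sparsest graph)
    monotonized = np.maximum.accumulate(instability)
    ok = np.flatnonzero(monotonized <= params.stars_instability_threshold)
    if ok.size:
        k = int(ok.max())  # smallest qualifying lambda = densest graph
    else:
        warnings.warn("no penalty met the StARS instability threshold; "
                      "returning the sparsest penalty", stacklevel=2)
        k = 0
    _, adj_full, coef_full = neighborhood_path(z, params, lambdas=lambdas)
    return StarsResult(
        lambda_opt=float(lambdas[k]),
        lambda_index=k,
        lambdas=np.asarray(lambdas),
        instability=instability,
        monotonized_instability=monotonized,
        stability=freq[k],
        adjacency=adj_full[k],
        coefs=coef_full[k],
    )


def network_from_fit(
    adjacency: np.ndarray,
    coefs: np.ndarray,
    species: Sequence[str],
    node_attrs: pd.DataFrame | None = None,
) -> AssociationNetwork:
    """Build a signed network from a neighborhood-selection fit.

    Edge sign and weight come from the symmetrized mean of the two directed
    coefficients; pairs whose symmetrized mean is exactly zero are dropped.
    """
    species = list(species)
    sym = (coefs + coefs.T) / 2.0
    rows = []
    p = len(species)
    for i in range(p):
        for j in range(i + 1, p):
            if not adjacency[i, j]:
                continue
            w = sym[i, j]
            if w == 0:
                continue
            a, b = sorted((species[i], species[j]))
            rows.append((a, b, 1 if w > 0 else -1, float(w)))
    df = pd.DataFrame(rows, columns=["species_a", "species_b", "sign", "weight"])
    return AssociationNetwork(df, node_attrs)


def infer_network(
    counts: pd.DataFrame,
    params: NetworkParams | None = None,
    node_attrs: pd.DataFrame | None = None,
) -> tuple[AssociationNetwork, StarsResult]:
    """CLR-transform counts, run StARS-selected neighborhood selection."""
    params = params or NetworkParams()
    clr = clr_transform(counts.to_numpy(), params.pseudocount)
    res = stars_select(clr, params)
    net = network_from_fit(res.adjacency, res.coefs, list(counts.columns), node_attrs)
    return net, res


def consensus_merge(
    networks: Sequence[AssociationNetwork],
    params: NetworkParams | None = None,
) -> AssociationNetwork:
    """Merge per-study networks into a sign-consistent consensus.

    An edge is kept iff it appears with the same sign in at least
    ``consensus_min_support`` input networks; its weight is the mean of the
    contributing weights.  Nodes are the endpoints of kept edges (isolated
    nodes are dropped).
    """
    params = params or NetworkParams()
    if len(networks) < 1:
        raise ValueError("need at least one network")
    support: dict[tuple[str, str, int], list[float]] = {}
    for net in networks:
        for row in net.edges.itertuples(index=False):
            key = (row.species_a, row.species_b, int(row.sign))
            support.setdefault(key, []).append(float(row.weight))
    rows = []
    for (a, b, sign), weights in support.items():
        if len(weights) >= params.consensus_min_support:
            rows.append((a, b, sign, float(np.mean(weights)), len(weights)))
    df = pd.DataFrame(
        rows, columns=["species_a", "species_b", "sign", "weight", "support"]
    ).sort_values(["species_a", "species_b"], ignore_index=True)
    return AssociationNetwork(df)


@dataclass
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    degree: dict[str, int]
    density: float
    transitivity: float
    modularity: float
    partition: list[set[str]]
    phylum_assortativity: float | None


def _greedy_modularity(g: nx.Graph) -> tuple[float, list[set[str]]]:
    """Greedy agglomerative modularity maximization, deterministic.

    Starts from singleton communities and repeatedly merges the connected
    pair of communities with the largest modularity gain, breaking ties by
    the lexicographically smallest (min-node, min-node) pair; stops when no
    merge improves modularity.
    """
    communities: list[set[str]] = [{v} for v in sorted(g.nodes)]
    q = nx.algorithms.community.modularity(g, communities)
    while len(communities) > 1:
        best = None
        for i in range(len(communities)):
            for j in range(i + 1, len(communities)):
                # only merging connected communities can increase Q
                if not any(
                    g.has_edge(u, v) for u in communities[i] for v in communities[j]
                ):
                    continue
                merged = (
                    communities[:i]
                    + communities[i + 1 : j]
                    + communities[j + 1 :]
                    + [communities[i] | communities[j]]
                )
                dq = nx.algorithms.community.modularity(g, merged) - q
                key = (min(communities[i]), min(communities[j]))
                if best is None or dq > best[0] + 1e-12 or (
                    abs(dq - best[0]) <= 1e-12 and key < best[1]
                ):
                    best = (dq, key, merged)
        if best is None or best[0] <= 1e-12:
            break
        q += best[0]
        communities = best[2]
    return q, communities


def network_metrics(net: AssociationNetwork) -> NetworkMetrics:
    """Topology summary: degree, density, transitivity, modularity,
    phylum assortativity (requires a ``phylum`` node attribute)."""
    g = net.to_graph()
    if g.number_of_nodes() < 2:
        raise ValueError("network needs at least 2 nodes")
    q, partition = _greedy_modularity(g)
    assort = None
    phyla = nx.get_node_attributes(g, "phylum")
    if phyla and len(phyla) == g.number_of_nodes():
        assort = float(nx.attribute_assortativity_coefficient(g, "phylum"))
    return NetworkMetrics(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        degree=dict(g.degree()),
        density=float(nx.density(g)),
        transitivity=float(nx.transitivity(g)),
        modularity=float(q),
        partition=partition,
        phylum_assortativity=assort,
    )


_CATEGORY_CODE = {"producer": "P", "salvager": "S", "nonproducer": "NP"}
EDGE_CATEGORIES = ("P-P", "P-S", "P-NP", "S-S", "S-NP", "NP-NP")


@dataclass
class EdgeCategoryReport:
    counts: dict[str, int]
    percentages: dict[str, float]
    producer_dependent_count: int
    producer_dependent_pct: float
    n_edges: int


def categorize_edges(
    net: AssociationNetwork,
    annotations: Mapping[str, CobamideAnnotation],
) -> EdgeCategoryReport:
    """Count edges by unordered biosynthesis-category pair.

    Also reports the share of edges joining a producer to a
    cobamide-dependent nonproducer or salvager (the putative sharing edges).
    """
    for node in net.nodes:
        if node not in annotations:
            raise KeyError(f"node {node!r} lacks a cobamide annotation")
    counts = {c: 0 for c in EDGE_CATEGORIES}
    sharing = 0
    for row in net.edges.itertuples(index=False):
        ann_a, ann_b = annotations[row.species_a], annotations[row.species_b]
        ca, cb = _CATEGORY_CODE[ann_a.category], _CATEGORY_CODE[ann_b.category]
        order = {"P": 0, "S": 1, "NP": 2}
        pair = tuple(sorted((ca, cb), key=order.get))
        counts[f"{pair[0]}-{pair[1]}"] += 1
        for prod, other in ((ann_a, ann_b), (ann_b, ann_a)):
            if (
                prod.category == "producer"
                and other.category in ("nonproducer", "salvager")
                and other.dependent
            ):
                sharing += 1
                break
    n = len(net.edges)
    if n == 0:
        raise ValueError("network has no edges")
    pct = {c: 100.0 * counts[c] / n for c in EDGE_CATEGORIES}
    return EdgeCategoryReport(
        counts=counts,
        percentages=pct,
        producer_dependent_count=sharing,
        producer_dependent_pct=100.0 * sharing / n,
        n_edges=n,
    )
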