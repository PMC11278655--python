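"""Thresholded Spearman co-occurrence networks and their analysis.

Networks are built per pooled treatment pair: OTUs pass a prevalence
filter, all-pairs Spearman correlations are screened at p < 0.01 and
|rho| > 0.6 (strict, no multiplicity correction on edge p-values), and the
surviving correlations become signed weighted edges.  Downstream analyses:
topology summaries (degree, clustering, greedy-modularity modules,
edge-sign fractions), natural-connectivity robustness under random node
removal, Zi-Pi keystone-role classification at the 2.5 / 0.62 thresholds,
Jaccard node/edge dissimilarity between networks, and per-module
taxonomic summaries.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .io_tables import CountTable, SampleMetadata, TaxonomyMap, _as_graph

logger = logging.getLogger(__name__)

R_THRESHOLD = 0.6
P_THRESHOLD = 0.01

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


# ---------------------------------------------------------------------------
# filtering and correlation screening
# ---------------------------------------------------------------------------

def prevalence_filter(
    table: CountTable,
    min_prevalence: float = 0.5,
    min_mean_relabund: float = 0.0,
) -> CountTable:
    """Keep OTUs present in >= ``min_prevalence`` of samples and with mean
    relative abundance >= ``min_mean_relabund``."""
    if not (0 <= min_prevalence <= 1 and 0 <= min_mean_relabund <= 1):
        raise ValueError("filter thresholds must lie in [0, 1]")
    rel = table.relative_abundance()
    prevalence = (table.data > 0).mean(axis=0)
    mean_rel = rel.mean(axis=0)
    keep = (prevalence >= min_prevalence) & (mean_rel >= min_mean_relabund)
    if not keep.any():
        raise ValueError("prevalence filter removed every OTU")
    logger.info(
        "prevalence filter kept %d / %d OTUs", int(keep.sum()), table.data.shape[1]
    )
    return CountTable(table.data.loc[:, keep].copy())


@dataclasses.dataclass
class CorrelationScreen:
    """All-pairs Spearman rho and p matrices plus the edge thresholds."""

    otu_ids: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame
    r_threshold: float = R_THRESHOLD
    p_threshold: float = P_THRESHOLD
    undefined_otus: list[str] = dataclasses.field(default_factory=list)


def correlation_screen(
    table: CountTable,
    r_threshold: float = R_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    use_relative: bool = True,
) -> CorrelationScreen:
    """All-pairs Spearman correlation of OTU abundances across samples.

    p-values come from the two-sided t-approximation.  OTUs with constant
    abundance have undefined correlations; their rows/columns are NaN and
    they are excluded from edge formation.
    """
    if table.data.shape[0] < 5:
        raise ValueError("need at least 5 pooled samples for the screen")
    x = table.relative_abundance() if use_relative else table.data.astype(float)
    arr = x.to_numpy()
    constant = np.ptp(arr, axis=0) == 0
    undefined = [o for o, c in zip(table.otu_ids, constant) if c]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns emit spearmanr warnings
        rho, p = stats.spearmanr(arr, axis=0)
    if np.ndim(rho) == 0:  # spearmanr collapses the 2-column case to scalars
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    rho = np.asarray(rho, dtype=float)
    p = np.asarray(p, dtype=float)
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)  # diagonal convention
    if undefined:
        mask = np.asarray(constant)
        rho[mask, :] = np.nan
        rho[:, mask] = np.nan
        p[mask, :] = np.nan
        p[:, mask] = np.nan
        logger.warning("%d constant OTU(s) excluded from screening", len(undefined))
    ids = table.otu_ids
    return CorrelationScreen(
        otu_ids=ids,
        rho=pd.DataFrame(rho, index=ids, columns=ids),
        p=pd.DataFrame(p, index=ids, columns=ids),
        r_threshold=r_threshold,
        p_threshold=p_threshold,
        undefined_otus=undefined,
    )


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CooccurrenceNetwork:
    """Undirected signed-weighted co-occurrence graph over OTU nodes."""

    graph: nx.Graph
    r_threshold: float
    p_threshold: float
    label: str = ""

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}


def build_network(
    screen: CorrelationScreen,
    table: CountTable | None = None,
    tax: TaxonomyMap | None = None,
    label: str = "",
) -> CooccurrenceNetwork:
    """Form edges where p < p_threshold and |rho| > r_threshold (strict).

    Edge weight is the signed rho; isolated nodes are dropped.  Node
    attributes carry phylum (if a taxonomy is given) and total abundance
    (if the source table is given).
    """
    rho = screen.rho.to_numpy()
    p = screen.p.to_numpy()
    ids = screen.otu_ids
    g = nx.Graph()
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            r_ij, p_ij = rho[i, j], p[i, j]
            if np.isnan(r_ij) or np.isnan(p_ij):
                continue
            if p_ij < screen.p_threshold and abs(r_ij) > screen.r_threshold:
                g.add_edge(
                    ids[i], ids[j],
                    weight=float(r_ij),
                    sign="+" if r_ij > 0 else "-",
                )
    if g.number_of_edges() == 0:
        logger.warning("network %r has zero edges", label)
    for node in g.nodes:
        if tax is not None:
            g.nodes[node]["phylum"] = tax.rank_of(node, "phylum")
        if table is not None and node in table.data.columns:
            g.nodes[node]["total_abundance"] = int(table.data[node].sum())
    return CooccurrenceNetwork(g, screen.r_threshold, screen.p_threshold, label)


def paired_networks(
    table: CountTable,
    meta: SampleMetadata,
    pairs: Sequence[tuple[str, str]],
    tax: TaxonomyMap | None = None,
    min_prevalence: float = 0.5,
    min_mean_relabund: float = 0.0,
    r_threshold: float = R_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    use_relative: bool = True,
) -> list[CooccurrenceNetwork]:
    """One network per treatment pair: pool the two treatments' samples,
    prevalence-filter, screen, threshold."""
    nets = []
    for k, (a, b) in enumerate(pairs):
        if a == b:
            raise ValueError(f"treatment pair must name two distinct labels, got ({a}, {b})")
        samples = meta.samples_of(a, b)
        pooled = table.subset_samples(samples)
        filtered = prevalence_filter(pooled, min_prevalence, min_mean_relabund)
        screen = correlation_screen(
            filtered, r_threshold=r_threshold, p_threshold=p_threshold,
            use_relative=use_relative,
        )
        label = f"Network {k + 1}: {a}+{b}"
        nets.append(build_network(screen, table=filtered, tax=tax, label=label))
    return nets


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class NetworkTopology:
    n_nodes: int
    n_edges: int
    average_degree: float
    average_weighted_degree: float
    average_clustering_coefficient: float
    modularity: float
    n_modules: int
    positive_edge_fraction: float
    negative_edge_fraction: float

    def as_series(self) -> pd.Series:
        return pd.Series(dataclasses.asdict(self))


def _canonical_graph(graph: nx.Graph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(sorted(graph.nodes))
    g.add_edges_from(sorted((min(u, v), max(u, v)) for u, v in graph.edges))
    return g


def detect_modules(net: CooccurrenceNetwork | nx.Graph) -> dict[str, int]:
    """Greedy modularity-maximising partition of the unweighted graph.

    The graph is canonicalised (sorted node/edge order) first so the
    partition is reproducible; module ids are assigned by decreasing module
    size, ties broken by smallest member label.
    """
    graph = _as_graph(net)
    g = _canonical_graph(graph)
    if g.number_of_nodes() == 0:
        return {}
    if g.number_of_edges() == 0:
        comms = [{n} for n in g.nodes]
    else:
        comms = [set(c) for c in nx.community.greedy_modularity_communities(g)]
    comms.sort(key=lambda c: (-len(c), min(c)))
    return {node: k for k, c in enumerate(comms) for node in c}


def topology(
    net: CooccurrenceNetwork, partition: dict[str, int] | None = None
) -> tuple[NetworkTopology, dict[str, int]]:
    """Topological summary plus the module partition it was computed on."""
    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise ValueError("network has no nodes")
    if partition is None:
        partition = detect_modules(net)
    avg_degree = 2.0 * e / n
    awd = float(
        np.mean([sum(abs(d["weight"]) for _, _, d in g.edges(u, data=True)) for u in g.nodes])
    )
    clustering = float(np.mean(list(nx.clustering(g).values()))) if n else 0.0
    comms: dict[int, set[str]] = {}
    for node, mod in partition.items():
        comms.setdefault(mod, set()).add(node)
    communities = list(comms.values())
    q = nx.community.modularity(g, communities) if e > 0 else 0.0
    signs = [d.get("sign", "+" if d.get("weight", 1) > 0 else "-") for _, _, d in g.edges(data=True)]
    pos = signs.count("+") / e if e else 0.0
    neg = signs.count("-") / e if e else 0.0
    topo = NetworkTopology(
        n_nodes=n,
        n_edges=e,
        average_degree=avg_degree,
        average_weighted_degree=awd,
        average_clustering_coefficient=clustering,
        modularity=float(q),
        n_modules=len(communities),
        positive_edge_fraction=pos,
        negative_edge_fraction=neg,
    )
    return topo, partition


# ---------------------------------------------------------------------------
# stability: natural connectivity and node-removal robustness
# ---------------------------------------------------------------------------

def natural_connectivity(net: CooccurrenceNetwork | nx.Graph) -> float:
    """Natural connectivity ln( mean_i exp(lambda_i) ) of the unweighted
    adjacency spectrum, computed overflow-safely via log-sum-exp."""
    graph = _as_graph(net)
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("natural connectivity needs at least one node")
    a = nx.to_numpy_array(graph, weight=None)
    evals = np.linalg.eigvalsh(a)
    return float(logsumexp(evals) - np.log(n))


def _average_degree(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    return 2.0 * graph.number_of_edges() / n if n else 0.0


@dataclasses.dataclass
class RobustnessCurve:
    curve: pd.DataFrame  # fraction, nc_mean, nc_sd, degree_mean, degree_sd
    n_replicates: int
    seed: int | None


def robustness(
    net: CooccurrenceNetwork | nx.Graph,
    fractions: Iterable[float] = tuple(np.round(np.arange(0.05, 0.51, 0.05), 2)),
    n_replicates: int = 100,
    seed: int | None = 0,
) -> RobustnessCurve:
    """Stability under random node removal.

    For each removal fraction f, ``floor(f * N)`` nodes are deleted
    uniformly at random; natural connectivity and average degree of the
    induced remainder are recorded (0 for an empty remainder) and
    aggregated over replicates.  Fractions removing zero nodes return the
    intact values with sd 0.
    """
    graph = _as_graph(net)
    fractions = list(fractions)
    if any(f >= 1 or f < 0 for f in fractions):
        raise ValueError("removal fractions must lie in [0, 1)")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    nodes = sorted(graph.nodes)
    n = len(nodes)
    rng = np.random.default_rng(seed)
    nc0, deg0 = natural_connectivity(graph), _average_degree(graph)
    rows = []
    for f in fractions:
        m = int(np.floor(f * n))
        if m == 0:
            rows.append({"fraction": f, "nc_mean": nc0, "nc_sd": 0.0,
                         "degree_mean": deg0, "degree_sd": 0.0})
            continue
        ncs, degs = [], []
        for _ in range(n_replicates):
            removed = set(rng.choice(n, size=m, replace=False).tolist())
            keep = [nodes[i] for i in range(n) if i not in removed]
            sub = graph.subgraph(keep)
            if sub.number_of_nodes() == 0:
                ncs.append(0.0)
                degs.append(0.0)
            else:
                ncs.append(natural_connectivity(sub))
                degs.append(_average_degree(sub))
        rows.append({
            "fraction": f,
            "nc_mean": float(np.mean(ncs)), "nc_sd": float(np.std(ncs, ddof=0)),
            "degree_mean": float(np.mean(degs)), "degree_sd": float(np.std(degs, ddof=0)),
        })
    return RobustnessCurve(pd.DataFrame(rows), n_replicates, seed)


# ---------------------------------------------------------------------------
# Zi-Pi keystone roles
# ---------------------------------------------------------------------------

ROLE_PERIPHERAL = "peripheral"
ROLE_CONNECTOR = "connector"
ROLE_MODULE_HUB = "module hub"
ROLE_NETWORK_HUB = "network hub"


def classify_role(zi: float, pi: float) -> str:
    if zi > ZI_THRESHOLD:
        return ROLE_NETWORK_HUB if pi > PI_THRESHOLD else ROLE_MODULE_HUB
    return ROLE_CONNECTOR if pi > PI_THRESHOLD else ROLE_PERIPHERAL


def zipi(net: CooccurrenceNetwork | nx.Graph, partition: dict[str, int]) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi standardises a node's within-module degree against its module's
    mean and *population* standard deviation (Zi = 0 for degenerate
    modules with sd 0 or fewer than two members).  Pi = 1 - sum_t
    (k_it / k_i)^2 over modules t (Pi = 0 for isolated nodes).  Roles use
    the 2.5 / 0.62 thresholds.
    """
    graph = _as_graph(net)
    missing = [v for v in graph.nodes if v not in partition]
    if missing:
        raise KeyError(f"node(s) absent from partition: {sorted(missing)[:5]}")
    modules: dict[int, list[str]] = {}
    for v in graph.nodes:
        modules.setdefault(partition[v], []).append(v)

    within = {
        v: sum(1 for u in graph.neighbors(v) if partition[u] == partition[v])
        for v in graph.nodes
    }
    rows = []
    for mod, members in modules.items():
        ks = np.array([within[v] for v in members], dtype=float)
        mu = ks.mean()
        sd = ks.std(ddof=0)
        for v in members:
            k_total = graph.degree(v)
            zi_v = 0.0 if (sd == 0 or len(members) < 2) else (within[v] - mu) / sd
            if k_total == 0:
                pi_v = 0.0
            else:
                per_mod: dict[int, int] = {}
                for u in graph.neighbors(v):
                    per_mod[partition[u]] = per_mod.get(partition[u], 0) + 1
                pi_v = 1.0 - sum((c / k_total) ** 2 for c in per_mod.values())
            rows.append({
                "otu_id": v, "module_id": mod, "degree": int(k_total),
                "zi": float(zi_v), "pi": float(pi_v),
                "role": classify_role(zi_v, pi_v),
            })
    out = pd.DataFrame(rows).sort_values("otu_id").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# network comparison and module summaries
# ---------------------------------------------------------------------------

def network_dissimilarity(
    net_a: CooccurrenceNetwork | nx.Graph, net_b: CooccurrenceNetwork | nx.Graph
) -> tuple[float, float]:
    """Jaccard dissimilarity of node sets and of (unordered, unweighted)
    edge sets: 1 - |intersection| / |union|; (0, 0) for identical graphs
    and defined as 0 when both sets are empty."""
    ga = _as_graph(net_a)
    gb = _as_graph(net_b)
    va, vb = set(ga.nodes), set(gb.nodes)
    ea = {frozenset((u, v)) for u, v in ga.edges}
    eb = {frozenset((u, v)) for u, v in gb.edges}
    node_d = 1.0 - len(va & vb) / len(va | vb) if (va | vb) else 0.0
    edge_d = 1.0 - len(ea & eb) / len(ea | eb) if (ea | eb) else 0.0
    return node_d, edge_d


def module_summary(
    net: CooccurrenceNetwork | nx.Graph,
    partition: dict[str, int],
    tax: TaxonomyMap | None = None,
    top_n: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-module size and phylum richness plus the between-module edge
    count matrix; the ``top_flag`` column marks the ``top_n`` largest
    modules."""
    graph = _as_graph(net)
    modules: dict[int, list[str]] = {}
    for v in graph.nodes:
        modules.setdefault(partition[v], []).append(v)
    rows = []
    for mod, members in sorted(modules.items()):
        if tax is not None:
            phyla = {tax.rank_of(v, "phylum") or "Unclassified" for v in members}
            richness = len(phyla)
        else:
            richness = np.nan
        rows.append({"module_id": mod, "size": len(members), "phylum_richness": richness})
    summary = pd.DataFrame(rows).sort_values(
        ["size", "module_id"], ascending=[False, True]
    ).reset_index(drop=True)
    summary["top_flag"] = [i < top_n for i in range(len(summary))]

    mods = sorted(modules)
    inter = pd.DataFrame(0, index=mods, columns=mods, dtype=int)
    for u, v in graph.edges:
        mu, mv = partition[u], partition[v]
        if mu != mv:
            inter.loc[mu, mv] += 1
            inter.loc[mv, mu] += 1
    return summary, inter
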