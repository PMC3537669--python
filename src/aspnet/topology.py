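"""Sub-network topology statistics against degree-preserving random networks.

Three statistics summarise how modular a block's gene set is inside the
integrated interactome:

* characteristic path length — mean shortest-path distance (in edges, on the
  undirected simple view of the *full* network) over unordered gene pairs of
  the set; disconnected pairs are excluded and their fraction reported;
* density — 2E / (N(N-1)) of the induced subgraph (typed parallel edges
  counted once);
* in-degree ratio — edges with both endpoints in the set divided by edges
  with exactly one endpoint in the set.

The null model is Maslov–Sneppen degree-preserving randomization: repeated
double-edge swaps within each interaction type (directed types preserve in-
and out-degrees) until every edge has been rewired ``swaps_per_edge`` times
on average; 1,000 null networks by default yield a Z-score and an empirical
p-value per statistic.  A same-size gene-resampling null is also available.

Sub-network overlap is measured by the Component Share Ratio (CSR): the
Jaccard index of two blocks' gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.stats import mannwhitneyu

from .containers import DIRECTED_TYPES, INTERACTION_TYPES, Interactome, SubNetwork

__all__ = [
    "characteristic_path_length",
    "subnetwork_density",
    "in_degree_ratio",
    "maslov_sneppen_randomize",
    "topology_null_test",
    "TopologyStats",
    "csr",
    "csr_group_contrast",
]


class RandomizationWarning(UserWarning):
    pass


def characteristic_path_length(
    network: Interactome | nx.Graph, gene_set: Iterable[str]
) -> tuple[float, float]:
    """Mean shortest-path distance between gene pairs of the set, measured
    in the full network's undirected simple view.

    Returns (mean length, fraction of pairs excluded as disconnected or
    absent).  Raises if every pair is disconnected.
    """
    g = network.undirected_view() if isinstance(network, Interactome) else network
    genes = sorted(set(gene_set))
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    present = [x for x in genes if x in g]
    n_pairs_total = len(genes) * (len(genes) - 1) // 2
    dists = []
    for i, src in enumerate(present):
        lengths = nx.single_source_shortest_path_length(g, src)
        for dst in present[i + 1 :]:
            if dst in lengths:
                dists.append(lengths[dst])
    if not dists:
        raise ValueError("all gene pairs disconnected; path length undefined")
    excluded = 1.0 - len(dists) / n_pairs_total
    return float(np.mean(dists)), excluded


def subnetwork_density(subnetwork: SubNetwork | tuple) -> float:
    """2E / (N(N-1)) on the undirected simple view of a sub-network."""
    if isinstance(subnetwork, SubNetwork):
        genes = subnetwork.genes
        pairs = {
            tuple(sorted((a, b)))
            for a, b, _ in subnetwork.edges.itertuples(index=False, name=None)
        }
    else:
        genes, pairs = subnetwork
    n = len(genes)
    if n < 2:
        raise ValueError("density undefined for fewer than 2 genes")
    return 2.0 * len(pairs) / (n * (n - 1))


def in_degree_ratio(
    network: Interactome | nx.Graph, gene_set: Iterable[str]
) -> float:
    """Within-edge count / boundary-edge count (undirected simple view).

    Returns ``inf`` when no boundary edge exists (isolated module, flagged
    maximum).
    """
    g = network.undirected_view() if isinstance(network, Interactome) else network
    gs = set(gene_set)
    if not gs:
        raise ValueError("empty gene set")
    within = boundary = 0
    for a, b in g.edges():
        ina, inb = a in gs, b in gs
        if ina and inb:
            within += 1
        elif ina or inb:
            boundary += 1
    if boundary == 0:
        warnings.warn("no boundary edges; in-degree ratio infinite", RandomizationWarning)
        return float("inf")
    return within / boundary


def maslov_sneppen_randomize(
    network: Interactome, swaps_per_edge: int = 100, seed: int | None = 0
) -> Interactome:
    """Degree-preserving randomization by repeated double-edge swaps.

    Each interaction type is rewired independently (so per-type degree
    sequences are preserved exactly; PDI/KPI preserve in- and out-degrees).
    Swaps creating self-loops or duplicate edges are rejected and retried;
    a type with fewer than two edges is returned unchanged with a warning.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, str]] = []
    for itype in INTERACTION_TYPES:
        sub = network.edges_of_type(itype)
        if len(sub) == 0:
            continue
        if len(sub) < 2:
            warnings.warn(
                f"type {itype} has <2 edges; left unchanged", RandomizationWarning
            )
            rows.extend(sub.itertuples(index=False, name=None))
            continue
        nswap = swaps_per_edge * len(sub)
        swap_seed = int(rng.integers(2**31 - 1))
        if itype in DIRECTED_TYPES:
            g: nx.Graph = nx.DiGraph()
            g.add_edges_from(sub[["gene_a", "gene_b"]].itertuples(index=False, name=None))
            try:
                nx.directed_edge_swap(g, nswap=nswap, max_tries=100 * nswap + 100,
                                      seed=swap_seed)
            except nx.NetworkXException as exc:  # tiny or rigid graph
                warnings.warn(f"{itype} randomization incomplete: {exc}",
                              RandomizationWarning)
            rows.extend((a, b, itype) for a, b in g.edges())
        else:
            g = nx.Graph()
            g.add_edges_from(sub[["gene_a", "gene_b"]].itertuples(index=False, name=None))
            try:
                nx.double_edge_swap(g, nswap=nswap, max_tries=100 * nswap + 100,
                                    seed=swap_seed)
            except nx.NetworkXException as exc:
                warnings.warn(f"{itype} randomization incomplete: {exc}",
                              RandomizationWarning)
            rows.extend((a, b, itype) for a, b in g.edges())
    return Interactome(rows)


@dataclass
class TopologyStats:
    """Observed statistics of one sub-network with null-ensemble context."""

    owner: str
    observed: dict[str, float]
    null_mean: dict[str, float] = field(default_factory=dict)
    null_sd: dict[str, float] = field(default_factory=dict)
    z_scores: dict[str, float] = field(default_factory=dict)
    p_empirical: dict[str, float] = field(default_factory=dict)
    excluded_pair_fraction: float = 0.0


_STATS = ("char_path_length", "density", "in_degree_ratio")
#: direction of enrichment per statistic: path length is expected *shorter*
_LOWER_IS_ENRICHED = {"char_path_length": True, "density": False, "in_degree_ratio": False}


def _stats_for(network: Interactome, g_und: nx.Graph, gene_set: frozenset[str]):
    cpl, excl = characteristic_path_length(g_und, gene_set)
    present = gene_set & set(g_und.nodes)
    pairs = {
        tuple(sorted((a, b)))
        for a, b in g_und.edges()
        if a in present and b in present
    }
    dens = subnetwork_density((present, pairs))
    with warnings.catch_warnings():
        # infinite ratios in an ensemble draw are summarised, not warned
        warnings.simplefilter("ignore", RandomizationWarning)
        ratio = in_degree_ratio(g_und, present)
    return {"char_path_length": cpl, "density": dens, "in_degree_ratio": ratio}, excl


def topology_null_test(
    network: Interactome,
    subnetworks: Mapping[str, SubNetwork],
    n_random: int = 1000,
    swaps_per_edge: int = 100,
    seed: int | None = 0,
    null: str = "edge_swap",
) -> dict[str, TopologyStats]:
    """Z-scores and empirical p-values of the three statistics per
    sub-network against ``n_random`` null networks.

    ``null="edge_swap"`` (default) rewires the network and keeps the gene
    sets; ``null="gene_resample"`` keeps the network and redraws same-size
    gene sets from its node set.  For greater-is-enriched statistics
    (density, in-degree ratio) p = #(null >= observed)/n_random; for path
    length (expected shorter) p = #(null <= observed)/n_random.
    """
    if null not in ("edge_swap", "gene_resample"):
        raise ValueError("null must be 'edge_swap' or 'gene_resample'")
    rng = np.random.default_rng(seed)
    g_obs = network.undirected_view()
    nodes = sorted(g_obs.nodes)
    out: dict[str, TopologyStats] = {}
    obs: dict[str, dict[str, float]] = {}
    excl: dict[str, float] = {}
    for owner, sub in subnetworks.items():
        obs[owner], excl[owner] = _stats_for(network, g_obs, sub.genes)
    null_vals: dict[str, dict[str, list[float]]] = {
        o: {s: [] for s in _STATS} for o in subnetworks
    }
    for _ in range(n_random):
        if null == "edge_swap":
            rand_net = maslov_sneppen_randomize(
                network, swaps_per_edge, seed=int(rng.integers(2**31 - 1))
            )
            g_rand = rand_net.undirected_view()
            g_rand.add_nodes_from(nodes)
            for owner, sub in subnetworks.items():
                try:
                    vals, _ = _stats_for(rand_net, g_rand, sub.genes)
                except ValueError:
                    continue
                for s in _STATS:
                    null_vals[owner][s].append(vals[s])
        else:
            for owner, sub in subnetworks.items():
                size = len(sub.genes)
                sample = frozenset(rng.choice(nodes, size=size, replace=False))
                try:
                    vals, _ = _stats_for(network, g_obs, sample)
                except ValueError:
                    continue
                for s in _STATS:
                    null_vals[owner][s].append(vals[s])
    for owner in subnetworks:
        ts = TopologyStats(owner=owner, observed=obs[owner],
                           excluded_pair_fraction=excl[owner])
        for s in _STATS:
            draws = np.array(
                [v for v in null_vals[owner][s] if np.isfinite(v)], dtype=float
            )
            if draws.size == 0:
                ts.null_mean[s] = ts.null_sd[s] = ts.z_scores[s] = np.nan
                ts.p_empirical[s] = np.nan
                continue
            mu, sd = float(draws.mean()), float(draws.std(ddof=1)) if draws.size > 1 else 0.0
            ts.null_mean[s], ts.null_sd[s] = mu, sd
            o = obs[owner][s]
            ts.z_scores[s] = (o - mu) / sd if sd > 0 else np.nan
            if _LOWER_IS_ENRICHED[s]:
                ts.p_empirical[s] = float((draws <= o).sum() / draws.size)
            else:
                ts.p_empirical[s] = float((draws >= o).sum() / draws.size)
        out[owner] = ts
    return out


def csr(genes_i: Iterable[str], genes_j: Iterable[str]) -> float:
    """Component Share Ratio: |intersection| / |union| of two gene sets.

    1 means the two blocks regulate identical network components; 0 means
    disjoint components.
    """
    a, b = set(genes_i), set(genes_j)
    if not a or not b:
        raise ValueError("CSR undefined for an empty gene set")
    return len(a & b) / len(a | b)


def csr_group_contrast(
    csr_same_chrom: Sequence[float],
    csr_diff_chrom: Sequence[float],
    log_transform: bool = True,
    method: str = "auto",
) -> float:
    """Two-sided Wilcoxon rank-sum p comparing CSR values of block pairs on
    the same chromosome vs different chromosomes.

    CSR values are log-transformed first (rank-based test, so this only
    affects presentation; zeros are clipped to a tiny positive value).
    """
    x = np.asarray(csr_same_chrom, dtype=float)
    y = np.asarray(csr_diff_chrom, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    if log_transform:
        eps = 1e-12
        x, y = np.log(np.clip(x, eps, None)), np.log(np.clip(y, eps, None))
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
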