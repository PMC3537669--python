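"""Core data containers shared by all pipeline stages.

The pipeline operates on four kinds of objects: a genotype matrix over a
haploid biallelic segregant panel, an expression matrix over the same strains
(plus parental replicate measurements), a typed molecular interactome, and
the record types produced by the statistical stages (eQTL hits, perturbation
records, enrichment rows, sub-networks).

Conventions
-----------
* Genotypes are coded 0 (parent A allele) / 1 (parent B allele); the panel is
  haploid so no heterozygote code exists.  Missing calls are ``NaN``.
* Genomic coordinates are 1-based inclusive base pairs.
* Interaction types: ``PPI`` and ``EEI`` are undirected (endpoints are stored
  in lexicographic order), ``PDI`` (regulator -> target) and ``KPI``
  (kinase -> substrate) are directed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "INTERACTION_TYPES",
    "DIRECTED_TYPES",
    "UNDIRECTED_TYPES",
    "GenotypeMatrix",
    "Interactome",
    "HeritabilityRecord",
    "EqtlHit",
    "PerturbationRecord",
    "LDBlock",
    "SubNetwork",
    "EnrichmentRecord",
    "canonical_edge",
]

INTERACTION_TYPES = ("PPI", "PDI", "KPI", "EEI")
DIRECTED_TYPES = frozenset({"PDI", "KPI"})
UNDIRECTED_TYPES = frozenset({"PPI", "EEI"})


class FormatError(ValueError):
    """Raised when an input table violates the documented format contract."""


def canonical_edge(gene_a: str, gene_b: str, itype: str) -> tuple[str, str, str]:
    """Return the canonical key of a typed edge.

    Undirected types are stored with lexicographically ordered endpoints so
    that (a, b) and (b, a) denote the same interaction; directed types keep
    their orientation.
    """
    if itype in UNDIRECTED_TYPES and gene_b < gene_a:
        gene_a, gene_b = gene_b, gene_a
    return (gene_a, gene_b, itype)


@dataclass
class GenotypeMatrix:
    """Biallelic marker calls with genomic positions.

    Parameters
    ----------
    calls
        markers x strains data frame of {0, 1, NaN} values; index = marker
        ids, columns = strain ids.
    marker_map
        One row per marker (same index as ``calls``) with columns
        ``chromosome`` and ``position`` (1-based bp).  Markers must be sorted
        by position within each chromosome.
    """

    calls: pd.DataFrame
    marker_map: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.calls.index.equals(self.marker_map.index):
            raise FormatError("calls and marker_map must share the same marker index")
        vals = self.calls.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise FormatError(
                f"non-biallelic genotype code at marker "
                f"{self.calls.index[bad[0]]!r}, strain {self.calls.columns[bad[1]]!r}"
            )
        if self.calls.index.has_duplicates:
            dup = self.calls.index[self.calls.index.duplicated()][0]
            raise FormatError(f"duplicate marker id {dup!r}")
        for chrom, grp in self.marker_map.groupby("chromosome", sort=False):
            pos = grp["position"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise FormatError(
                    f"marker positions not strictly increasing on chromosome {chrom!r}"
                )

    @property
    def markers(self) -> pd.Index:
        return self.calls.index

    @property
    def strains(self) -> pd.Index:
        return self.calls.columns

    def chromosome_of(self, marker: str) -> str:
        return self.marker_map.at[marker, "chromosome"]

    def position_of(self, marker: str) -> int:
        return int(self.marker_map.at[marker, "position"])


class Interactome:
    """Typed multi-layer interaction network over gene identifiers.

    Stores one edge list per interaction type; within a type duplicate edges
    are collapsed (undirected edges after canonicalization).  The same gene
    pair may be linked by edges of several types (typed multigraph).
    """

    def __init__(self, edges: pd.DataFrame | Iterable[tuple[str, str, str]]):
        if not isinstance(edges, pd.DataFrame):
            edges = pd.DataFrame(list(edges), columns=["gene_a", "gene_b", "itype"])
        edges = edges.loc[:, ["gene_a", "gene_b", "itype"]].astype(str)
        unknown = set(edges["itype"]) - set(INTERACTION_TYPES)
        if unknown:
            raise FormatError(f"unknown interaction type(s): {sorted(unknown)}")
        canon = [
            canonical_edge(a, b, t)
            for a, b, t in edges.itertuples(index=False, name=None)
        ]
        df = pd.DataFrame(canon, columns=["gene_a", "gene_b", "itype"])
        self.n_duplicates_collapsed = int(df.duplicated().sum())
        df = df.drop_duplicates(ignore_index=True)
        df = df[df["gene_a"] != df["gene_b"]].reset_index(drop=True)
        self.edges = df

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.edges["gene_a"]) | frozenset(self.edges["gene_b"])

    @property
    def edge_keys(self) -> frozenset[tuple[str, str, str]]:
        return frozenset(self.edges.itertuples(index=False, name=None))

    def __len__(self) -> int:
        return len(self.edges)

    def edges_of_type(self, itype: str) -> pd.DataFrame:
        return self.edges[self.edges["itype"] == itype]

    def undirected_view(self) -> nx.Graph:
        """Simple undirected graph: parallel typed edges collapse to one."""
        g = nx.Graph()
        g.add_nodes_from(self.genes)
        g.add_edges_from(
            (a, b) for a, b, _ in self.edges.itertuples(index=False, name=None)
        )
        return g

    def induced_edges(self, gene_set: Iterable[str]) -> pd.DataFrame:
        """All typed edges with both endpoints in ``gene_set``."""
        gs = set(gene_set)
        mask = self.edges["gene_a"].isin(gs) & self.edges["gene_b"].isin(gs)
        return self.edges[mask].reset_index(drop=True)

    def adjacency(self) -> dict[str, set[str]]:
        """Undirected simple adjacency over all types."""
        adj: dict[str, set[str]] = {g: set() for g in self.genes}
        for a, b, _ in self.edges.itertuples(index=False, name=None):
            adj[a].add(b)
            adj[b].add(a)
        return adj


@dataclass
class HeritabilityRecord:
    trait: str
    h2: float
    sigma2_seg: float
    sigma2_parent_pooled: float
    p_perm: float
    passes_fdr: bool = False
    defined: bool = True


@dataclass(frozen=True)
class EqtlHit:
    marker: str
    trait: str
    t_stat: float
    p_perm: float
    q: float
    cis: str = "unknown"  # {"cis", "trans", "unknown"}


@dataclass(frozen=True)
class PerturbationRecord:
    """One (eQTL, interaction) relationship.

    ``kind`` is ``"ASCP"`` (the marker is an eQTL of both endpoints) or
    ``"ASDP"`` (the two allele groups differ significantly in the Pearson
    correlation of the endpoints' expression; ``dys`` = \\|r0 - r1\\|).
    ASCP records leave r0/r1/dys/p/q as NaN.
    """

    marker: str
    gene_a: str
    gene_b: str
    itype: str
    kind: str
    r0: float = float("nan")
    r1: float = float("nan")
    dys: float = float("nan")
    p_perm: float = float("nan")
    q: float = float("nan")

    @property
    def edge(self) -> tuple[str, str, str]:
        return (self.gene_a, self.gene_b, self.itype)


@dataclass
class LDBlock:
    id: str
    chromosome: str
    markers: list[str]
    span_bp: tuple[int, int]

    def __contains__(self, marker: str) -> bool:
        return marker in self.markers


@dataclass
class SubNetwork:
    """Gene set plus induced typed edges for an LD block or a compound."""

    owner: str
    genes: frozenset[str]
    edges: pd.DataFrame
    perturbing_records: list[PerturbationRecord] = field(default_factory=list)

    @property
    def edge_keys(self) -> frozenset[tuple[str, str, str]]:
        return frozenset(self.edges.itertuples(index=False, name=None))

    def n_components(self) -> int:
        g = nx.Graph()
        g.add_nodes_from(self.genes)
        g.add_edges_from(
            (a, b) for a, b, _ in self.edges.itertuples(index=False, name=None)
        )
        return nx.number_connected_components(g)


@dataclass
class EnrichmentRecord:
    """Hypergeometric enrichment row: x of k sub-network genes hit a set of
    m known members against a background of m + n genes."""

    set_name: str
    x: int
    k: int
    m: int
    n: int
    p: float
    q: float = float("nan")
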