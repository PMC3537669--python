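"""Allele-specific perturbation of molecular interactions.

Two models connect an eQTL to a change of state of an interaction:

* **ASCP** (allele-specific co-perturbation): the marker is a significant
  eQTL of *both* endpoint genes of an edge — the locus synchronously
  regulates the interacting pair.
* **ASDP** (allele-specific dys-perturbation): splitting the strains by the
  marker's allele, the Pearson correlation of the two endpoints' expression
  differs between the groups.  The statistic is Dys = |r0 - r1|, and its
  significance comes from randomly reassigning strains to two groups of the
  original sizes (1,000 times by default); the p-value is the frequency of
  null Dys values *strictly greater* than the observed one.  BH controls the
  FDR across all tested (marker, edge) pairs.

The CPN and DPN are the unions of all ASCP and ASDP edges respectively.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .containers import EqtlHit, Interactome, PerturbationRecord, canonical_edge
from .qtl import benjamini_hochberg

__all__ = [
    "detect_ascp",
    "dys_statistic",
    "detect_asdp",
    "build_perturbed_network",
    "MIN_GROUP_SIZE",
]

logger = logging.getLogger(__name__)

#: smallest allele group for which a Pearson correlation is estimated
MIN_GROUP_SIZE = 3


def detect_ascp(
    eqtl_hits: Iterable[EqtlHit], interactome: Interactome
) -> list[PerturbationRecord]:
    """One ASCP record per (marker, edge) where the marker is an eQTL of
    both edge endpoints.

    ``eqtl_hits`` is assumed already thresholded by the caller.  The result
    is deterministic and sorted by (marker, edge key).
    """
    targets: dict[str, set[str]] = {}
    for h in eqtl_hits:
        targets.setdefault(h.marker, set()).add(h.trait)
    records = []
    edges = list(interactome.edges.itertuples(index=False, name=None))
    for marker in sorted(targets):
        tg = targets[marker]
        for a, b, t in edges:
            if a in tg and b in tg:
                records.append(PerturbationRecord(marker, a, b, t, "ASCP"))
    return records


def dys_statistic(
    expr_a: Sequence[float],
    expr_b: Sequence[float],
    genotype_vector: Sequence[float],
) -> tuple[float, float, float]:
    """(r0, r1, Dys) for one gene pair at one marker.

    r0 and r1 are the Pearson correlations of the two genes' expression in
    the allele-0 and allele-1 strain groups; Dys = |r0 - r1|.  Raises if a
    group is smaller than :data:`MIN_GROUP_SIZE` or has zero variance in
    either gene.
    """
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    g = np.asarray(genotype_vector, dtype=float)
    rs = []
    for allele in (0.0, 1.0):
        idx = np.flatnonzero(g == allele)
        if idx.size < MIN_GROUP_SIZE:
            raise ValueError(f"allele-{int(allele)} group smaller than {MIN_GROUP_SIZE}")
        xa, xb = a[idx], b[idx]
        if np.std(xa) == 0.0 or np.std(xb) == 0.0:
            raise ValueError(f"zero variance in allele-{int(allele)} group")
        rs.append(float(np.corrcoef(xa, xb)[0, 1]))
    r0, r1 = rs
    return r0, r1, abs(r0 - r1)


def _group_correlations(
    A: np.ndarray, B: np.ndarray, idx: np.ndarray
) -> np.ndarray:
    """Pearson r of each row-pair (A[i], B[i]) restricted to columns idx."""
    X = A[:, idx]
    Y = B[:, idx]
    X = X - X.mean(axis=1, keepdims=True)
    Y = Y - Y.mean(axis=1, keepdims=True)
    num = (X * Y).sum(axis=1)
    den = np.sqrt((X**2).sum(axis=1) * (Y**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / den


def detect_asdp(
    expression: pd.DataFrame,
    genotypes,
    eqtl_hits: Iterable[EqtlHit],
    interactome: Interactome,
    n_perm: int = 1000,
    fdr_level: float = 0.05,
    seed: int | None = 0,
    candidate_mode: str = "eqtl",
    return_all: bool = False,
) -> list[PerturbationRecord]:
    """Permutation test of Dys over candidate (marker, edge) pairs.

    Candidates (default ``"eqtl"`` mode) are pairs where the marker is a
    significant eQTL of at least one edge endpoint; ``"all"`` scans every
    marker x edge combination (quadratic).  For each candidate the strains
    are randomly reassigned to two groups of the original allele-group sizes
    ``n_perm`` times; p = #(Dys* > Dys_obs) / n_perm (strict inequality).
    Records with BH q < ``fdr_level`` are returned (every tested record,
    significant or not, with ``return_all=True``).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if candidate_mode not in ("eqtl", "all"):
        raise ValueError("candidate_mode must be 'eqtl' or 'all'")
    common = expression.columns.intersection(genotypes.strains)
    expr = expression.loc[:, common]
    gene_row = {g: i for i, g in enumerate(expr.index)}
    E = expr.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    targets: dict[str, set[str]] = {}
    for h in eqtl_hits:
        targets.setdefault(h.marker, set()).add(h.trait)
    edges = [
        (a, b, t)
        for a, b, t in interactome.edges.itertuples(index=False, name=None)
        if a in gene_row and b in gene_row
    ]
    if candidate_mode == "eqtl":
        candidates: dict[str, list[tuple[str, str, str]]] = {}
        for marker, tg in targets.items():
            cand = [e for e in edges if e[0] in tg or e[1] in tg]
            if cand:
                candidates[marker] = cand
    else:
        candidates = {m: list(edges) for m in genotypes.markers}

    results = []
    n = len(common)
    for marker in sorted(candidates):
        gvec = genotypes.calls.loc[marker, common].to_numpy(dtype=float)
        idx0 = np.flatnonzero(gvec == 0.0)
        idx1 = np.flatnonzero(gvec == 1.0)
        if idx0.size < MIN_GROUP_SIZE or idx1.size < MIN_GROUP_SIZE:
            logger.info("marker %s skipped: allele group too small", marker)
            continue
        pairs = candidates[marker]
        ra = np.array([gene_row[a] for a, _b, _t in pairs])
        rb = np.array([gene_row[b] for _a, b, _t in pairs])
        A, B = E[ra], E[rb]
        r0 = _group_correlations(A, B, idx0)
        r1 = _group_correlations(A, B, idx1)
        dys_obs = np.abs(r0 - r1)
        valid = np.isfinite(dys_obs)
        if not valid.any():
            continue
        exceed = np.zeros(len(pairs))
        order = np.arange(n)
        for _ in range(n_perm):
            perm = rng.permutation(order)
            p0, p1 = perm[: idx0.size], perm[idx0.size :]
            d = np.abs(
                _group_correlations(A, B, p0) - _group_correlations(A, B, p1)
            )
            exceed += (d > dys_obs) & np.isfinite(d)
        p = exceed / n_perm
        for i, (a, b, t) in enumerate(pairs):
            if not valid[i]:
                logger.info(
                    "pair (%s, %s-%s) skipped: degenerate correlation", marker, a, b
                )
                continue
            results.append(
                (marker, a, b, t, float(r0[i]), float(r1[i]), float(dys_obs[i]), float(p[i]))
            )
    if not results:
        return []
    pvals = np.array([r[-1] for r in results])
    qvals = benjamini_hochberg(pvals)
    records = [
        PerturbationRecord(m, a, b, t, "ASDP", r0, r1, dys, p, float(q))
        for (m, a, b, t, r0, r1, dys, p), q in zip(results, qvals)
        if return_all or q < fdr_level
    ]
    return records


def build_perturbed_network(
    records: Iterable[PerturbationRecord], kind: str
) -> tuple[Interactome, dict]:
    """Union of the edges of all records of ``kind`` ("ASCP" -> CPN,
    "ASDP" -> DPN), with summary statistics.

    Returns the perturbed network and a dict with ``n_nodes``, ``n_edges``,
    ``largest_component_fraction`` and ``degree_sequence``.
    """
    edges = sorted(
        {r.edge for r in records if r.kind == kind}
    )
    net = Interactome(edges)
    g = net.undirected_view()
    if g.number_of_nodes() == 0:
        stats = {
            "n_nodes": 0,
            "n_edges": 0,
            "largest_component_fraction": 0.0,
            "degree_sequence": [],
        }
    else:
        comp = max(nx.connected_components(g), key=len)
        stats = {
            "n_nodes": g.number_of_nodes(),
            "n_edges": len(net),
            "largest_component_fraction": len(comp) / g.number_of_nodes(),
            "degree_sequence": sorted((d for _, d in g.degree()), reverse=True),
        }
    return net, stats
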