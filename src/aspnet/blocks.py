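"""LD blocks, block x interaction association, and sub-network extraction.

Adjacent markers in a cross travel together through meiosis, so eQTLs
cluster into haplotype blocks that act as one allele-context unit.  Blocks
here are found with a contiguous-r^2 rule suited to a haploid biallelic
panel: a block grows along the chromosome while the next marker's minimum
pairwise r^2 against every marker already in the block stays at or above a
threshold.  An externally computed marker -> block assignment can be
supplied instead, overriding the built-in rule.

A block's allele-specific sub-network is the induced subgraph of the
integrated interactome on the endpoint genes of the interactions perturbed
by the block's eQTLs; by construction it contains every perturbed edge.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, Interactome, LDBlock, PerturbationRecord, SubNetwork

__all__ = [
    "find_ld_blocks",
    "blocks_from_assignment",
    "block_of_marker",
    "block_association_matrix",
    "extract_subnetwork",
    "assemble_block_subnetworks",
]

logger = logging.getLogger(__name__)


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    obs = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[obs], b[obs]
    if a.size < 2 or a.std() == 0.0 or b.std() == 0.0:
        return np.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def find_ld_blocks(
    genotypes: GenotypeMatrix,
    r2_threshold: float = 0.8,
    min_markers: int = 1,
) -> list[LDBlock]:
    """Partition markers into contiguous LD blocks (B1, B2, ...).

    Greedy extension within each chromosome: the next marker joins the
    current block iff its minimum pairwise r^2 with *all* markers already in
    the block is >= ``r2_threshold``.  Every marker belongs to exactly one
    block; blocks shorter than ``min_markers`` are still returned (the
    filter is applied by association-stage callers).
    """
    arr = genotypes.calls.to_numpy(dtype=float)
    markers = genotypes.markers.to_numpy()
    mmap = genotypes.marker_map
    blocks: list[LDBlock] = []
    bid = 0
    for chrom, grp in mmap.groupby("chromosome", sort=False):
        idxs = [genotypes.markers.get_loc(m) for m in grp.index]
        current: list[int] = []
        for i in idxs:
            if current:
                r2min = min(_pairwise_r2(arr[i], arr[j]) for j in current)
                joins = np.isfinite(r2min) and r2min >= r2_threshold
            else:
                joins = False
            if current and joins:
                current.append(i)
            else:
                if current:
                    bid += 1
                    blocks.append(_make_block(bid, chrom, current, markers, mmap))
                current = [i]
        if current:
            bid += 1
            blocks.append(_make_block(bid, chrom, current, markers, mmap))
    return [b for b in blocks if len(b.markers) >= min_markers]


def _make_block(bid, chrom, idxs, markers, mmap) -> LDBlock:
    ms = [markers[i] for i in idxs]
    pos = [int(mmap.at[m, "position"]) for m in ms]
    return LDBlock(id=f"B{bid}", chromosome=chrom, markers=ms, span_bp=(min(pos), max(pos)))


def blocks_from_assignment(
    genotypes: GenotypeMatrix, assignment: Mapping[str, str]
) -> list[LDBlock]:
    """Build blocks from an external marker -> block-label table.

    Markers sharing a label must be contiguous on one chromosome; labels are
    kept as given.
    """
    mmap = genotypes.marker_map
    order: list[str] = []
    members: dict[str, list[str]] = {}
    for m in genotypes.markers:
        lbl = assignment.get(m)
        if lbl is None:
            continue
        if lbl not in members:
            members[lbl] = []
            order.append(lbl)
        members[lbl].append(m)
    blocks = []
    for lbl in order:
        ms = members[lbl]
        chroms = {mmap.at[m, "chromosome"] for m in ms}
        if len(chroms) != 1:
            raise ValueError(f"block {lbl!r} spans multiple chromosomes")
        pos = [int(mmap.at[m, "position"]) for m in ms]
        blocks.append(LDBlock(lbl, chroms.pop(), ms, (min(pos), max(pos))))
    return blocks


def block_of_marker(blocks: Iterable[LDBlock]) -> dict[str, str]:
    """marker id -> block id lookup."""
    out: dict[str, str] = {}
    for b in blocks:
        for m in b.markers:
            out[m] = b.id
    return out


def block_association_matrix(
    blocks: list[LDBlock],
    records: Iterable[PerturbationRecord],
    min_edges: int = 3,
) -> pd.DataFrame:
    """Binary block x interaction matrix.

    Cell (block, edge) is 1 iff some record's marker lies in the block and
    perturbs that edge.  Blocks perturbing fewer than ``min_edges`` distinct
    edges are dropped.  Rows are ordered by block id as given; columns by
    edge key (sorted) — both stable under record reordering.
    """
    lookup = block_of_marker(blocks)
    cells: set[tuple[str, tuple[str, str, str]]] = set()
    for r in records:
        bid = lookup.get(r.marker)
        if bid is None:
            logger.info("record marker %s lies in no block; skipped", r.marker)
            continue
        cells.add((bid, r.edge))
    edge_cols = sorted({e for _, e in cells})
    row_ids = [b.id for b in blocks]
    mat = pd.DataFrame(
        0,
        index=pd.Index(row_ids, name="block"),
        columns=pd.Index(["|".join(e) for e in edge_cols], name="interaction"),
        dtype=int,
    )
    for bid, e in cells:
        mat.at[bid, "|".join(e)] = 1
    keep = mat.sum(axis=1) >= min_edges
    return mat.loc[keep]


def extract_subnetwork(
    interactome: Interactome, gene_set: Iterable[str], owner: str = ""
) -> SubNetwork:
    """Induced subgraph of the integrated network on ``gene_set``.

    All typed edges with both endpoints in the set are included; genes not
    present in the interactome are logged and dropped.
    """
    gs = set(gene_set)
    known = interactome.genes
    missing = gs - known
    if missing:
        logger.info("%d gene(s) not in interactome dropped: %s",
                    len(missing), sorted(missing)[:5])
    gs &= known
    return SubNetwork(owner=owner, genes=frozenset(gs),
                      edges=interactome.induced_edges(gs))


def assemble_block_subnetworks(
    blocks: list[LDBlock],
    records: Iterable[PerturbationRecord],
    interactome: Interactome,
    min_edges: int = 3,
) -> dict[str, SubNetwork]:
    """Per block: gene set = endpoints of its perturbed edges; sub-network =
    induced subgraph on that set.  Blocks with fewer than ``min_edges``
    distinct perturbed edges are omitted."""
    lookup = block_of_marker(blocks)
    per_block: dict[str, list[PerturbationRecord]] = {}
    for r in records:
        bid = lookup.get(r.marker)
        if bid is None:
            logger.info("record marker %s lies in no block; skipped", r.marker)
            continue
        per_block.setdefault(bid, []).append(r)
    out: dict[str, SubNetwork] = {}
    for b in blocks:
        recs = per_block.get(b.id, [])
        edges = {r.edge for r in recs}
        if len(edges) < min_edges:
            continue
        genes = {g for e in edges for g in (e[0], e[1])}
        sub = extract_subnetwork(interactome, genes, owner=b.id)
        sub.perturbing_records = sorted(
            recs, key=lambda r: (r.marker, r.edge)
        )
        out[b.id] = sub
    return out
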