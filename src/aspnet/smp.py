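"""Small-molecule response QTLs and per-compound perturbed sub-networks.

Each compound's growth-yield trait is measured under several conditions
(time point x concentration); every compound x condition is mapped as an
independent trait with the same permutation machinery as eQTL mapping, hits
are kept at |t| strictly greater than a threshold (3.28 by default, the
FDR < 0.05 operating point of the study design), and markers are unioned
across a compound's conditions.

A compound's sub-network collects the perturbed interactions (ASCP/ASDP
records) of eQTLs lying in any LD block that contains one of the compound's
QTL markers — bridging drug loci to network perturbations at block
resolution — and induces the subgraph on those edges' endpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from .blocks import block_of_marker, extract_subnetwork
from .containers import (
    EqtlHit,
    GenotypeMatrix,
    Interactome,
    LDBlock,
    PerturbationRecord,
    SubNetwork,
)
from .qtl import map_qtls

__all__ = [
    "SmpQtlSet",
    "map_smp_qtls",
    "smp_subnetworks",
    "association_matrices",
    "cluster_order",
]

logger = logging.getLogger(__name__)


@dataclass
class SmpQtlSet:
    """QTL markers of one compound, unioned across its conditions."""

    compound: str
    qtl_markers: set[str] = field(default_factory=set)
    per_condition_hits: dict[str, list[EqtlHit]] = field(default_factory=dict)


def map_smp_qtls(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    t_threshold: float = 3.28,
    n_perm: int = 1000,
    fdr_level: float = 0.05,
    seed: int | None = 0,
) -> dict[str, SmpQtlSet]:
    """Map every compound x condition trait; union markers per compound.

    ``phenotypes``: (compound, condition) MultiIndex x strain columns.
    Hits must pass both the permutation FDR and |t| > ``t_threshold``
    (strict).  Compounds whose values are entirely missing are skipped with
    a warning.
    """
    if not isinstance(phenotypes.index, pd.MultiIndex):
        raise ValueError("phenotypes must have a (compound, condition) MultiIndex")
    out: dict[str, SmpQtlSet] = {}
    for compound, grp in phenotypes.groupby(level="compound", sort=True):
        vals = grp.droplevel("compound")
        if vals.isna().all().all():
            logger.warning("compound %s has no observed values; skipped", compound)
            continue
        traits = vals  # one trait per condition
        hits = map_qtls(
            genotypes, traits, n_perm=n_perm, fdr_level=fdr_level, seed=seed
        )
        qs = SmpQtlSet(compound=compound)
        for h in hits:
            if abs(h.t_stat) > t_threshold:
                qs.per_condition_hits.setdefault(h.trait, []).append(h)
                qs.qtl_markers.add(h.marker)
        out[compound] = qs
    return out


def smp_subnetworks(
    smp_qtls: Mapping[str, SmpQtlSet],
    blocks: list[LDBlock],
    perturbation_records: Iterable[PerturbationRecord],
    interactome: Interactome,
    bridging: str = "block",
) -> dict[str, SubNetwork]:
    """Per-compound perturbed sub-network.

    ``bridging="block"`` (default): a compound recruits every perturbation
    record whose eQTL marker lies in an LD block containing one of the
    compound's QTL markers.  ``bridging="marker"`` requires the record's
    marker to *be* one of the compound's QTL markers.  Compounds with no
    recruitable records get an empty sub-network (logged).
    """
    if bridging not in ("block", "marker"):
        raise ValueError("bridging must be 'block' or 'marker'")
    lookup = block_of_marker(blocks)
    records = list(perturbation_records)
    out: dict[str, SubNetwork] = {}
    for compound in sorted(smp_qtls):
        qs = smp_qtls[compound]
        if bridging == "block":
            qtl_blocks = {lookup[m] for m in qs.qtl_markers if m in lookup}
            recs = [r for r in records if lookup.get(r.marker) in qtl_blocks]
        else:
            recs = [r for r in records if r.marker in qs.qtl_markers]
        if not recs:
            logger.info("compound %s: no perturbed interactions recruited", compound)
            out[compound] = SubNetwork(compound, frozenset(), interactome.edges.iloc[0:0])
            continue
        genes = {g for r in recs for g in (r.gene_a, r.gene_b)}
        sub = extract_subnetwork(interactome, genes, owner=compound)
        sub.perturbing_records = sorted(recs, key=lambda r: (r.marker, r.edge))
        out[compound] = sub
    return out


def association_matrices(
    smp_qtls: Mapping[str, SmpQtlSet],
    blocks: list[LDBlock],
    enrichments: Mapping[str, Iterable] | None = None,
    q_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary compound x block and compound x functional-class matrices.

    Block matrix: cell = 1 iff at least one of the compound's QTL markers
    lies in the block.  Function matrix: cell = 1 iff the compound's
    sub-network is enriched (q < ``q_threshold``) in the class;
    ``enrichments`` maps compound -> EnrichmentRecord list.  Row/column
    order is sorted and independent of input order; use
    :func:`cluster_order` for a clustering-based presentation order.
    """
    lookup = block_of_marker(blocks)
    compounds = sorted(smp_qtls)
    block_ids = [b.id for b in blocks]
    bm = pd.DataFrame(0, index=pd.Index(compounds, name="compound"),
                      columns=pd.Index(block_ids, name="block"), dtype=int)
    for c in compounds:
        for m in smp_qtls[c].qtl_markers:
            bid = lookup.get(m)
            if bid is not None:
                bm.at[c, bid] = 1
    if enrichments:
        classes = sorted({r.set_name for recs in enrichments.values() for r in recs})
        fm = pd.DataFrame(0, index=pd.Index(sorted(enrichments), name="compound"),
                          columns=pd.Index(classes, name="functional_class"), dtype=int)
        for c, recs in enrichments.items():
            for r in recs:
                if np.isfinite(r.q) and r.q < q_threshold:
                    fm.at[c, r.set_name] = 1
    else:
        fm = pd.DataFrame(index=pd.Index(compounds, name="compound"))
    return bm, fm


def cluster_order(matrix: pd.DataFrame) -> pd.DataFrame:
    """Reorder rows and columns by average-linkage hierarchical clustering
    on Jaccard distance (presentation only; values untouched)."""
    out = matrix
    for axis in (0, 1):
        data = out.to_numpy(dtype=bool) if axis == 0 else out.to_numpy(dtype=bool).T
        if data.shape[0] < 3:
            continue
        d = pdist(data, metric="jaccard")
        d = np.nan_to_num(d, nan=1.0)
        order = leaves_list(average(d))
        out = out.iloc[order] if axis == 0 else out.iloc[:, order]
    return out
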