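"""Hypergeometric enrichment of gene sets in perturbed sub-networks.

The test asks whether a sub-network of k genes contains surprisingly many
members (x) of a known set (m members against a background of m + n genes).
The tail convention is strict: p = P(X > x) = 1 - F(x; m, n, k), i.e. the
observed count itself is *excluded* from the tail (so x = m or x = k gives
p = 0 exactly).  The conventional inclusive tail P(X >= x) is available via
``inclusive=True``.  BH q-values are computed across the sets tested
together.

Candidate drug targets are predicted from connectivity: a gene not in any
known target set that is linked through perturbed (ASCP/ASDP) edges to at
least ``min_links`` distinct known targets inside compound sub-networks.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import EnrichmentRecord, SubNetwork
from .qtl import benjamini_hochberg

__all__ = [
    "hypergeom_upper_tail",
    "enrich_sets",
    "predict_candidate_targets",
]


def hypergeom_upper_tail(
    x: int, m: int, n: int, k: int, inclusive: bool = False
) -> float:
    """P(X > x) for X ~ Hypergeometric(m successes, n failures, k draws).

    ``inclusive=True`` gives the conventional P(X >= x) instead.  Validates
    0 <= x <= min(m, k) and k <= m + n.
    """
    for name, v in (("x", x), ("m", m), ("n", n), ("k", k)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if x > min(m, k):
        raise ValueError(f"x={x} exceeds min(m, k)={min(m, k)}")
    if k > m + n:
        raise ValueError(f"k={k} draws exceed background size {m + n}")
    if inclusive:
        return float(hypergeom.sf(x - 1, m + n, m, k))
    return float(hypergeom.sf(x, m + n, m, k))


def enrich_sets(
    subnetwork_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    background_genes: Iterable[str],
    inclusive: bool = False,
) -> list[EnrichmentRecord]:
    """Test every gene set for over-representation in the sub-network.

    Per set: m = |set ∩ background|, n = |background| - m,
    k = |sub-network genes|, x = |set ∩ sub-network genes|.  BH q-values are
    computed across the tested sets; records are returned sorted by p.
    """
    background = set(background_genes)
    if not background:
        raise ValueError("background gene set is empty")
    sub = set(subnetwork_genes) & background
    k = len(sub)
    records = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & background
        m = len(members)
        n = len(background) - m
        x = len(members & sub)
        p = hypergeom_upper_tail(x, m, n, k, inclusive=inclusive)
        records.append(EnrichmentRecord(name, x=x, k=k, m=m, n=n, p=p))
    if records:
        q = benjamini_hochberg([r.p for r in records])
        for r, qv in zip(records, q):
            r.q = float(qv)
    records.sort(key=lambda r: (r.p, r.set_name))
    return records


def predict_candidate_targets(
    smp_subnetworks: Mapping[str, SubNetwork],
    known_target_sets: Mapping[str, Iterable[str]],
    min_links: int = 3,
) -> pd.DataFrame:
    """Candidate drug targets by connectivity to known targets.

    For each gene that is not itself a known target, count the *distinct*
    known target genes it touches through perturbed (ASCP/ASDP) edges inside
    the compound sub-networks, pooled across compounds.  Genes with count >=
    ``min_links`` are returned with their per-compound link breakdown.
    """
    known_by_compound = {c: set(g) for c, g in known_target_sets.items()}
    all_known = set().union(*known_by_compound.values()) if known_by_compound else set()
    links: dict[str, set[str]] = {}
    breakdown: dict[str, dict[str, set[str]]] = {}
    for compound, sub in smp_subnetworks.items():
        known = known_by_compound.get(compound, all_known)
        for r in sub.perturbing_records:
            for gene, partner in ((r.gene_a, r.gene_b), (r.gene_b, r.gene_a)):
                if gene in all_known or partner not in known:
                    continue
                links.setdefault(gene, set()).add(partner)
                breakdown.setdefault(gene, {}).setdefault(compound, set()).add(partner)
    rows = []
    for gene in sorted(links):
        targets = links[gene]
        if len(targets) < min_links:
            continue
        per_drug = ";".join(
            f"{c}:{len(ts)}" for c, ts in sorted(breakdown[gene].items())
        )
        rows.append((gene, len(targets), ",".join(sorted(targets)), per_drug))
    return pd.DataFrame(
        rows, columns=["gene", "n_known_targets", "linked_targets", "per_compound"]
    )
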