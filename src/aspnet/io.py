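"""Readers and writers for the pipeline's plain-text formats.

All tables are TSV (tab-separated, LF or CRLF) with a header row:

* genotypes: ``marker  chromosome  position  <strain...>`` with values in
  {0, 1, NA};
* expression / phenotypes: identifier column(s) then strain columns;
* gene positions: ``gene  chromosome  start  end`` (1-based inclusive bp);
* interactome: ``gene_a  gene_b  itype`` with itype in {PPI, PDI, KPI, EEI};
* gene sets: GMT (name, description, then member genes);
* perturbation records / eQTL hits / block tables: flat TSVs with stable
  column order;
* ground truth: JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import (
    EqtlHit,
    FormatError,
    GenotypeMatrix,
    Interactome,
    LDBlock,
    PerturbationRecord,
)
from .simulate import ExpressionData, GroundTruth

__all__ = [
    "read_genotypes", "write_genotypes",
    "read_expression", "write_expression",
    "read_gene_positions", "write_gene_positions",
    "read_phenotypes", "write_phenotypes",
    "read_interactome", "write_interactome",
    "read_gmt", "write_gmt",
    "read_ground_truth", "write_ground_truth",
    "write_records", "read_records",
    "write_hits", "read_hits",
    "write_blocks", "read_block_assignment",
]


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chromosome": str})
    for col in ("marker", "chromosome", "position"):
        if col not in df.columns:
            raise FormatError(f"genotype file missing column {col!r}")
    df = df.set_index("marker")
    mmap = df[["chromosome", "position"]]
    calls = df.drop(columns=["chromosome", "position"])
    vals = calls.apply(pd.to_numeric, errors="coerce")
    # anything that failed numeric parsing but was not NA is a bad code
    bad_parse = vals.isna() & calls.notna() & (calls.astype(str) != "NA")
    bad_code = vals.notna() & ~vals.isin([0, 1])
    bad = bad_parse | bad_code
    if bad.any().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-biallelic genotype value {calls.iat[i, j]!r} at marker "
            f"{calls.index[i]!r}, strain {calls.columns[j]!r}"
        )
    return GenotypeMatrix(vals, mmap)


def write_genotypes(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = genotypes.marker_map.join(genotypes.calls)
    out = df.reset_index().rename(columns={"index": "marker"})
    out.columns = ["marker"] + list(df.columns)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    if "gene" not in df.columns:
        raise FormatError("expression file missing 'gene' column")
    df = df.set_index("gene")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate gene id {dup!r}")
    return df.apply(pd.to_numeric, errors="raise")


def write_expression(values: pd.DataFrame, path: str | Path) -> None:
    values.rename_axis("gene").to_csv(path, sep="\t", na_rep="NA")


def read_gene_positions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chromosome": str})
    need = {"gene", "chromosome", "start", "end"}
    if not need.issubset(df.columns):
        raise FormatError(f"gene position file needs columns {sorted(need)}")
    return df.set_index("gene")


def write_gene_positions(positions: pd.DataFrame, path: str | Path) -> None:
    positions.rename_axis("gene").to_csv(path, sep="\t")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"compound": str, "condition": str})
    if "compound" not in df.columns or "condition" not in df.columns:
        raise FormatError("phenotype file needs 'compound' and 'condition' columns")
    return df.set_index(["compound", "condition"]).apply(pd.to_numeric, errors="raise")


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.to_csv(path, sep="\t", na_rep="NA")


def read_interactome(path: str | Path) -> Interactome:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = ["gene_a", "gene_b", "itype"]
    if not set(need).issubset(df.columns):
        raise FormatError(f"interactome file needs columns {need}")
    return Interactome(df[need])


def write_interactome(interactome: Interactome, path: str | Path) -> None:
    interactome.edges.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\r\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"GMT line has fewer than 3 fields: {line[:60]!r}")
        sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "na") -> None:
    lines = [
        "\t".join([name, description] + sorted(set(genes)))
        for name, genes in sorted(gene_sets.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "planted_eqtls": sorted([m, g, e] for m, g, e in truth.planted_eqtls),
        "planted_ascp": sorted([m, list(e)] for m, e in truth.planted_ascp),
        "planted_asdp": sorted(
            [m, list(e), r0, r1] for m, e, r0, r1 in truth.planted_asdp
        ),
        "planted_smp_qtls": sorted([m, c] for m, c in truth.planted_smp_qtls),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        planted_eqtls={(m, g, float(e)) for m, g, e in d["planted_eqtls"]},
        planted_ascp={(m, tuple(e)) for m, e in d["planted_ascp"]},
        planted_asdp={
            (m, tuple(e), float(r0), float(r1))
            for m, e, r0, r1 in d["planted_asdp"]
        },
        planted_smp_qtls={(m, c) for m, c in d["planted_smp_qtls"]},
    )


_REC_COLS = ["marker", "gene_a", "gene_b", "itype", "kind", "r0", "r1", "dys",
             "p_perm", "q"]


def write_records(records: Iterable[PerturbationRecord], path: str | Path) -> None:
    rows = [
        (r.marker, r.gene_a, r.gene_b, r.itype, r.kind, r.r0, r.r1, r.dys,
         r.p_perm, r.q)
        for r in records
    ]
    pd.DataFrame(rows, columns=_REC_COLS).to_csv(path, sep="\t", index=False,
                                                 na_rep="NA")


def read_records(path: str | Path) -> list[PerturbationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"marker": str})
    return [
        PerturbationRecord(r.marker, r.gene_a, r.gene_b, r.itype, r.kind,
                           float(r.r0), float(r.r1), float(r.dys),
                           float(r.p_perm), float(r.q))
        for r in df.itertuples(index=False)
    ]


_HIT_COLS = ["marker", "trait", "t_stat", "p_perm", "q", "cis"]


def write_hits(hits: Iterable[EqtlHit], path: str | Path) -> None:
    rows = [(h.marker, h.trait, h.t_stat, h.p_perm, h.q, h.cis) for h in hits]
    pd.DataFrame(rows, columns=_HIT_COLS).to_csv(path, sep="\t", index=False)


def read_hits(path: str | Path) -> list[EqtlHit]:
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "trait": str, "cis": str})
    return [
        EqtlHit(h.marker, h.trait, float(h.t_stat), float(h.p_perm), float(h.q),
                h.cis)
        for h in df.itertuples(index=False)
    ]


def write_blocks(blocks: Iterable[LDBlock], path: str | Path) -> None:
    rows = [
        (b.id, b.chromosome, b.markers[0], b.markers[-1], len(b.markers),
         b.span_bp[0], b.span_bp[1])
        for b in blocks
    ]
    pd.DataFrame(
        rows,
        columns=["block", "chromosome", "first_marker", "last_marker",
                 "n_markers", "span_start", "span_end"],
    ).to_csv(path, sep="\t", index=False)


def read_block_assignment(path: str | Path) -> dict[str, str]:
    """marker -> block label table (external block caller override)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"marker", "block"}.issubset(df.columns):
        raise FormatError("block assignment file needs 'marker' and 'block' columns")
    return dict(zip(df["marker"], df["block"]))
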