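"""End-to-end pipeline: impute -> heritability filter -> marker merge ->
eQTL mapping -> perturbation detection -> blocks -> topology -> SMP mapping
-> enrichment, with a reproducibility manifest per run."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import blocks as blocks_mod
from . import enrichment as enrich_mod
from . import io as io_mod
from . import perturbation as pert_mod
from . import qtl as qtl_mod
from . import smp as smp_mod
from . import topology as topo_mod

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """File paths, thresholds, permutation counts and mode flags for a run.

    Every stochastic stage draws from ``seed``; reruns with the same config
    and seed produce identical outputs and manifests.
    """

    genotypes: str = ""
    expression: str = ""
    expression_parents: str = ""  # optional; enables the heritability filter
    gene_positions: str = ""
    interactome: str = ""
    phenotypes: str = ""  # optional; enables the SMP stages
    target_sets: str = ""  # GMT of known drug targets per compound
    block_assignment: str = ""  # optional external marker->block table
    out_dir: str = "run"

    fdr_level: float = 0.05
    t_threshold: float = 3.28
    r2_threshold: float = 0.8
    min_edges: int = 3
    min_links: int = 3
    cis_window_bp: int = 10_000
    knn_k: int = 15
    h2_fdr_level: float = 0.05

    n_perm_h2: int = 200
    n_perm_eqtl: int = 200
    n_perm_asdp: int = 1000
    n_random_networks: int = 200
    swaps_per_edge: int = 10

    seed: int = 0
    tail_convention: str = "strict"  # enrichment: strict P(X>x) vs inclusive
    null_pooling: str = "trait"
    bridging: str = "block"
    run_topology: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _preflight(config: RunConfig) -> None:
    required = ["genotypes", "expression", "interactome"]
    optional = ["expression_parents", "gene_positions", "phenotypes",
                "target_sets", "block_assignment"]
    for name in required:
        p = getattr(config, name)
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"required input {name!r} missing: {p!r}")
    for name in optional:
        p = getattr(config, name)
        if p and not Path(p).exists():
            raise FileNotFoundError(f"configured input {name!r} missing: {p!r}")


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in dependency order; returns the run directory.

    A stage failure halts the run with the stage name; outputs of completed
    stages are preserved in the run directory.
    """
    _preflight(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages_done: list[str] = []
    rng = np.random.default_rng(config.seed)
    seeds = {name: int(rng.integers(2**31 - 1)) for name in
             ("h2", "eqtl", "asdp", "topology", "smp")}

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            stages_done.append(name)
            logger.info("stage %s complete", name)
            return result
        return deco

    @stage("read_inputs")
    def _inputs():
        genotypes = io_mod.read_genotypes(config.genotypes)
        expression = io_mod.read_expression(config.expression)
        interactome = io_mod.read_interactome(config.interactome)
        gene_pos = (io_mod.read_gene_positions(config.gene_positions)
                    if config.gene_positions else None)
        parents = (io_mod.read_expression(config.expression_parents)
                   if config.expression_parents else None)
        phenotypes = (io_mod.read_phenotypes(config.phenotypes)
                      if config.phenotypes else None)
        targets = io_mod.read_gmt(config.target_sets) if config.target_sets else {}
        return genotypes, expression, interactome, gene_pos, parents, phenotypes, targets

    genotypes, expression, interactome, gene_pos, parents, phenotypes, targets = _inputs

    @stage("impute")
    def expression_imputed():
        imp = qtl_mod.knn_impute_expression(expression, k=config.knn_k)
        io_mod.write_expression(imp, out / "expression_imputed.tsv")
        return imp

    @stage("heritability_filter")
    def kept_expression():
        if parents is None:
            return expression_imputed
        groups = sorted({c.split("_")[0] for c in parents.columns})
        rows = []
        for gene in expression_imputed.index:
            by_parent = {
                g: parents.loc[gene, [c for c in parents.columns
                                      if c.startswith(g + "_")]].to_numpy()
                for g in groups
            }
            rec = qtl_mod.estimate_heritability(
                expression_imputed.loc[gene].to_numpy(), by_parent,
                n_perm=config.n_perm_h2, seed=seeds["h2"],
            )
            rec.trait = gene
            rows.append(rec)
        ps = [r.p_perm if r.defined else 1.0 for r in rows]
        qs = qtl_mod.benjamini_hochberg(ps)
        keep = []
        tab = []
        for r, q in zip(rows, qs):
            r.passes_fdr = bool(q < config.h2_fdr_level) and r.defined
            if r.passes_fdr:
                keep.append(r.trait)
            tab.append((r.trait, r.h2, r.sigma2_seg, r.sigma2_parent_pooled,
                        r.p_perm, q, r.passes_fdr))
        pd.DataFrame(tab, columns=["trait", "h2", "sigma2_seg",
                                   "sigma2_parent_pooled", "p_perm", "q",
                                   "passes_fdr"]).to_csv(
            out / "heritability.tsv", sep="\t", index=False)
        return expression_imputed.loc[keep] if keep else expression_imputed

    @stage("merge_markers")
    def merged():
        mg, merge_map = qtl_mod.merge_identical_markers(genotypes)
        pd.DataFrame(
            [(rep, m) for rep, ms in merge_map.items() for m in ms],
            columns=["representative", "marker"],
        ).to_csv(out / "marker_merge_map.tsv", sep="\t", index=False)
        return mg

    @stage("map_eqtl")
    def eqtl_hits():
        hits = qtl_mod.map_qtls(
            merged, kept_expression, n_perm=config.n_perm_eqtl,
            fdr_level=config.fdr_level, seed=seeds["eqtl"],
            null_pooling=config.null_pooling,
        )
        if gene_pos is not None:
            hits = qtl_mod.classify_cis_trans(
                hits, merged.marker_map, gene_pos, window_bp=config.cis_window_bp
            )
        io_mod.write_hits(hits, out / "eqtl_hits.tsv")
        return hits

    @stage("perturbation")
    def records():
        ascp = pert_mod.detect_ascp(eqtl_hits, interactome)
        asdp = pert_mod.detect_asdp(
            kept_expression, merged, eqtl_hits, interactome,
            n_perm=config.n_perm_asdp, fdr_level=config.fdr_level,
            seed=seeds["asdp"],
        )
        io_mod.write_records(ascp + asdp, out / "perturbation_records.tsv")
        for kind, name in (("ASCP", "cpn"), ("ASDP", "dpn")):
            net, stats = pert_mod.build_perturbed_network(ascp + asdp, kind)
            io_mod.write_interactome(net, out / f"{name}_edges.tsv")
            (out / f"{name}_stats.json").write_text(json.dumps(
                {k: v for k, v in stats.items() if k != "degree_sequence"}))
        return ascp + asdp

    @stage("blocks")
    def block_results():
        if config.block_assignment:
            assign = io_mod.read_block_assignment(config.block_assignment)
            blks = blocks_mod.blocks_from_assignment(merged, assign)
        else:
            blks = blocks_mod.find_ld_blocks(merged, r2_threshold=config.r2_threshold)
        io_mod.write_blocks(blks, out / "blocks.tsv")
        assoc = blocks_mod.block_association_matrix(blks, records,
                                                    min_edges=config.min_edges)
        assoc.to_csv(out / "block_association_matrix.tsv", sep="\t")
        subs = blocks_mod.assemble_block_subnetworks(
            blks, records, interactome, min_edges=config.min_edges)
        for bid, sub in subs.items():
            sub.edges.to_csv(out / f"subnetwork_{bid}.tsv", sep="\t", index=False)
        return blks, subs

    blks, block_subs = block_results

    @stage("topology")
    def topo():
        if not config.run_topology:
            return {}
        if block_subs:
            stats = topo_mod.topology_null_test(
                interactome, block_subs, n_random=config.n_random_networks,
                swaps_per_edge=config.swaps_per_edge, seed=seeds["topology"],
            )
        else:
            stats = {}
        rows = []
        for owner, ts in sorted(stats.items()):
            for s in ("char_path_length", "density", "in_degree_ratio"):
                rows.append((owner, s, ts.observed[s], ts.null_mean[s],
                             ts.null_sd[s], ts.z_scores[s], ts.p_empirical[s]))
        pd.DataFrame(rows, columns=["block", "statistic", "observed",
                                    "null_mean", "null_sd", "z", "p"]).to_csv(
            out / "topology_stats.tsv", sep="\t", index=False)
        return stats

    @stage("smp")
    def smp_results():
        if phenotypes is None:
            return None
        qtls = smp_mod.map_smp_qtls(
            merged, phenotypes, t_threshold=config.t_threshold,
            n_perm=config.n_perm_eqtl, fdr_level=config.fdr_level,
            seed=seeds["smp"],
        )
        subs = smp_mod.smp_subnetworks(qtls, blks, records, interactome,
                                       bridging=config.bridging)
        background = sorted(interactome.genes)
        enrichments = {}
        rows = []
        for compound, sub in subs.items():
            if not sub.genes or compound not in targets:
                continue
            recs = enrich_mod.enrich_sets(
                sub.genes, {compound: targets[compound]}, background,
                inclusive=(config.tail_convention == "inclusive"),
            )
            enrichments[compound] = recs
            for r in recs:
                rows.append((compound, r.m, r.k, r.x, r.n, r.p, r.q))
        pd.DataFrame(rows, columns=["compound", "m", "k", "x", "n", "p", "q"]
                     ).to_csv(out / "smp_enrichment.tsv", sep="\t", index=False)
        cand = enrich_mod.predict_candidate_targets(subs, targets,
                                                    min_links=config.min_links)
        cand.to_csv(out / "candidate_targets.tsv", sep="\t", index=False)
        bm, fm = smp_mod.association_matrices(qtls, blks, enrichments)
        bm.to_csv(out / "block_smp_matrix.tsv", sep="\t")
        fm.to_csv(out / "function_smp_matrix.tsv", sep="\t")
        return qtls

    manifest = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": stages_done,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
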