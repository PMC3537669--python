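"""Synthetic segregant panels with planted, recoverable network perturbations.

The generator emulates the structure of a two-parent haploid yeast cross that
has been genotyped, expression-profiled, and screened against a compound
panel:

* genotypes: per chromosome, each strain's allele sequence is a two-state
  Markov chain (switch probability = ``recomb_prob`` between adjacent
  markers), which produces linkage disequilibrium decaying with distance;
* expression: an additive model, planted eQTL effects (in units of the
  residual SD) plus Gaussian noise, with parental replicate measurements
  generated from the two parental genotypes;
* allele-conditioned co-expression: for planted dys-perturbed (ASDP) gene
  pairs, a latent factor shared by the two genes' noise terms is injected
  with a different loading in each allele group, so the within-group Pearson
  correlations hit prescribed targets r0 and r1;
* interactome: a typed, heavy-tailed (degree-biased attachment) network over
  the simulated genes;
* compound response: growth-yield traits driven by planted QTL alleles, with
  known drug-target gene sets biased into the perturbed network
  neighbourhoods.

Every operation is deterministic under a fixed seed, and all planted signals
are returned in a :class:`GroundTruth` object so downstream stages can be
scored for recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, Interactome, canonical_edge

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ExpressionData",
    "simulate_cross",
    "simulate_interactome",
    "plant_perturbations",
    "simulate_expression",
    "simulate_smp_phenotypes",
    "simulate_dataset",
]


class ConfigurationError(ValueError):
    pass


class IntegrityError(ValueError):
    """A planted signal references an entity absent from the dataset."""


def _default_markers_per_chrom() -> list[int]:
    # 2,956 markers spread over 16 chromosomes, matching the cross panel.
    return [185] * 12 + [184] * 4


def _default_edge_counts() -> dict[str, int]:
    # Layer sizes of the integrated yeast interactome this generator emulates.
    return {"PPI": 25301, "PDI": 12681, "KPI": 28785, "EEI": 3486}


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic cross.

    Defaults reproduce the panel the analysis was designed for: 112 haploid
    segregants over 2,956 markers on 16 chromosomes, a 6,064-gene typed
    interactome, and compound-response phenotypes.  Tests use smaller,
    explicitly scaled configurations.
    """

    n_strains: int = 112
    n_chromosomes: int = 16
    n_markers_per_chrom: list[int] = field(default_factory=_default_markers_per_chrom)
    marker_spacing_bp: int = 4000
    recomb_prob: float = 0.02
    n_genes: int = 6064
    edge_counts_by_type: dict[str, int] = field(default_factory=_default_edge_counts)
    n_planted_eqtls: int = 200
    n_planted_ascp: int = 30
    n_planted_asdp: int = 30
    effect_size: float = 2.0  # standardized mean shift, units of residual SD
    noise_sd: float = 1.0
    n_parent_reps: int = 4
    dys_delta: float = 0.9  # target |r0 - r1| for planted ASDP pairs
    seed: int = 0

    def validate(self) -> None:
        if self.n_strains <= 0 or self.n_genes <= 0 or self.n_chromosomes <= 0:
            raise ConfigurationError("counts must be positive")
        if len(self.n_markers_per_chrom) != self.n_chromosomes:
            raise ConfigurationError(
                "n_markers_per_chrom must list one count per chromosome"
            )
        if any(m <= 0 for m in self.n_markers_per_chrom):
            raise ConfigurationError("marker counts must be positive")
        if not 0.0 <= self.recomb_prob <= 1.0:
            raise ConfigurationError("recomb_prob must be in [0, 1]")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be non-negative")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if not 0.0 <= self.dys_delta <= 2.0:
            raise ConfigurationError("dys_delta must be in [0, 2]")
        if self.n_parent_reps < 2:
            raise ConfigurationError("need >=2 parental replicates")


@dataclass
class GroundTruth:
    """Planted signals, for scoring downstream recovery."""

    planted_eqtls: set[tuple[str, str, float]] = field(default_factory=set)
    planted_ascp: set[tuple[str, tuple[str, str, str]]] = field(default_factory=set)
    planted_asdp: set[tuple[str, tuple[str, str, str], float, float]] = field(
        default_factory=set
    )
    planted_smp_qtls: set[tuple[str, str]] = field(default_factory=set)

    def eqtl_pairs(self) -> set[tuple[str, str]]:
        return {(m, g) for m, g, _ in self.planted_eqtls}

    def validate(
        self, genotypes: GenotypeMatrix, interactome: Interactome | None = None
    ) -> None:
        markers = set(genotypes.markers)
        for m, g, _ in self.planted_eqtls:
            if m not in markers:
                raise IntegrityError(f"planted eQTL references unknown marker {m!r}")
        for m, _c in self.planted_smp_qtls:
            if m not in markers:
                raise IntegrityError(f"planted SMP QTL references unknown marker {m!r}")
        if interactome is not None:
            keys = interactome.edge_keys
            for m, e in self.planted_ascp:
                if e not in keys:
                    raise IntegrityError(f"planted ASCP references unknown edge {e}")
            for m, e, _r0, _r1 in self.planted_asdp:
                if e not in keys:
                    raise IntegrityError(f"planted ASDP references unknown edge {e}")


@dataclass
class ExpressionData:
    """Expression values for segregants plus parental replicates.

    ``values``: genes x strains; ``parent_reps``: parent label -> genes x
    replicate data frame; ``gene_positions``: chromosome/start/end per gene
    (1-based, inclusive).
    """

    values: pd.DataFrame
    parent_reps: dict[str, pd.DataFrame]
    gene_positions: pd.DataFrame


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _marker_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1:02d}"
        for j in range(config.n_markers_per_chrom[c]):
            rows.append(
                (f"{chrom}_m{j + 1:04d}", chrom, (j + 1) * config.marker_spacing_bp)
            )
    return pd.DataFrame(rows, columns=["marker", "chromosome", "position"]).set_index(
        "marker"
    )


def simulate_cross(config: SimulationConfig) -> tuple[GenotypeMatrix, GroundTruth]:
    """Simulate segregant genotypes and choose planted eQTL assignments.

    Each strain's alleles along a chromosome follow a two-state Markov chain:
    the first marker is a fair coin, and each subsequent marker switches
    parental origin with probability ``recomb_prob``.  Planted eQTLs are
    (marker, gene, effect) triples drawn uniformly without replacement over
    marker-gene pairs; the expression generator realises them.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_geno, rng_plant = (np.random.default_rng(s) for s in ss.spawn(2))

    mmap = _marker_table(config)
    n = config.n_strains
    blocks = []
    for c in range(config.n_chromosomes):
        m = config.n_markers_per_chrom[c]
        first = rng_geno.integers(0, 2, size=(1, n))
        switches = rng_geno.random(size=(m - 1, n)) < config.recomb_prob
        # cumulative XOR of switch indicators realizes the Markov chain
        states = np.vstack([first, switches.astype(np.int8)])
        blocks.append(np.cumsum(states, axis=0) % 2)
    calls = pd.DataFrame(
        np.vstack(blocks).astype(np.int8),
        index=mmap.index,
        columns=[f"seg{i + 1:03d}" for i in range(n)],
    )
    genotypes = GenotypeMatrix(calls, mmap)

    truth = GroundTruth()
    genes = _gene_ids(config.n_genes)
    n_eqtl = min(config.n_planted_eqtls, config.n_genes)
    target_genes = rng_plant.choice(config.n_genes, size=n_eqtl, replace=False)
    markers = mmap.index.to_numpy()
    chosen_markers = rng_plant.choice(len(markers), size=n_eqtl, replace=True)
    for gi, mi in zip(target_genes, chosen_markers):
        truth.planted_eqtls.add((markers[mi], genes[gi], config.effect_size))
    return genotypes, truth


def simulate_interactome(
    n_genes: int, edge_counts_by_type: dict[str, int], seed: int
) -> Interactome:
    """Typed interactome with a heavy-tailed degree distribution.

    Edges are placed by degree-biased attachment: endpoint sampling
    probability is proportional to (current total degree + 1), shared across
    layers so hub genes are hubs in every type.  PDI and KPI edges are
    directed (first endpoint regulator/kinase); PPI and EEI are undirected.
    Self-loops and within-type duplicates are rejected and resampled.
    """
    max_pairs = n_genes * (n_genes - 1) // 2
    for t, cnt in edge_counts_by_type.items():
        if cnt > max_pairs:
            raise ConfigurationError(
                f"{cnt} {t} edges infeasible for {n_genes} genes"
            )
        if cnt < 0:
            raise ConfigurationError("edge counts must be non-negative")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    degree = np.ones(n_genes, dtype=float)  # +1 smoothing; all genes reachable
    rows: list[tuple[str, str, str]] = []
    for itype in sorted(edge_counts_by_type):
        want = edge_counts_by_type[itype]
        seen: set[tuple[int, int]] = set()
        guard = 0
        while len(seen) < want:
            batch = max(64, 2 * (want - len(seen)))
            p = degree / degree.sum()
            a = rng.choice(n_genes, size=batch, p=p)
            b = rng.choice(n_genes, size=batch, p=p)
            for i, j in zip(a, b):
                if i == j:
                    continue
                key = (int(i), int(j))
                if itype in ("PPI", "EEI") and key[0] > key[1]:
                    key = (key[1], key[0])
                if key in seen:
                    continue
                seen.add(key)
                degree[key[0]] += 1
                degree[key[1]] += 1
                rows.append((genes[key[0]], genes[key[1]], itype))
                if len(seen) == want:
                    break
            guard += 1
            if guard > 10000:
                raise ConfigurationError(f"could not place requested {itype} edges")
    return Interactome(rows)


def plant_perturbations(
    genotypes: GenotypeMatrix,
    truth: GroundTruth,
    interactome: Interactome,
    config: SimulationConfig,
) -> GroundTruth:
    """Choose edges to carry planted ASCP and ASDP signals.

    ASCP: an edge is selected and a marker is made an eQTL of *both*
    endpoints (extra planted eQTLs are appended as needed).  ASDP: an edge
    and marker are selected and target within-group correlations are set to
    r0 = dys_delta, r1 = 0, realised later by the expression generator.
    Returns a new GroundTruth; the input is not mutated.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    edges = list(interactome.edge_keys)
    edges.sort()
    if not edges:
        return truth
    markers = genotypes.markers.to_numpy()
    out = GroundTruth(
        planted_eqtls=set(truth.planted_eqtls),
        planted_ascp=set(truth.planted_ascp),
        planted_asdp=set(truth.planted_asdp),
        planted_smp_qtls=set(truth.planted_smp_qtls),
    )
    used_genes = {g for _, g, _ in out.planted_eqtls}
    picks = rng.choice(
        len(edges),
        size=min(config.n_planted_ascp + config.n_planted_asdp, len(edges)),
        replace=False,
    )
    ascp_edges = picks[: config.n_planted_ascp]
    asdp_edges = picks[config.n_planted_ascp :]
    for ei in ascp_edges:
        a, b, t = edges[ei]
        if a in used_genes or b in used_genes:
            continue  # keep planted effects non-overlapping, analysis stays clean
        m = markers[rng.integers(len(markers))]
        out.planted_eqtls.add((m, a, config.effect_size))
        out.planted_eqtls.add((m, b, config.effect_size))
        out.planted_ascp.add((m, (a, b, t)))
        used_genes.update((a, b))
    for ei in asdp_edges:
        a, b, t = edges[ei]
        if a in used_genes or b in used_genes:
            continue
        m = markers[rng.integers(len(markers))]
        # marker is also a (weak) eQTL of endpoint a so the default ASDP
        # candidate universe (markers that are eQTLs of >=1 endpoint) sees it
        out.planted_eqtls.add((m, a, config.effect_size))
        out.planted_asdp.add((m, (a, b, t), config.dys_delta, 0.0))
        used_genes.update((a, b))
    return out


def _correlated_noise(
    rng: np.random.Generator, n: int, r: float, sd: float
) -> tuple[np.ndarray, np.ndarray]:
    """Two length-n noise vectors with population correlation r, SD ``sd``."""
    z = rng.standard_normal(n)
    ea = rng.standard_normal(n)
    eb = rng.standard_normal(n)
    lam = math.sqrt(abs(r))
    res = math.sqrt(1.0 - abs(r))
    sign = 1.0 if r >= 0 else -1.0
    na = lam * z + res * ea
    nb = sign * lam * z + res * eb
    return sd * na, sd * nb


def simulate_expression(
    genotypes: GenotypeMatrix, truth: GroundTruth, config: SimulationConfig
) -> ExpressionData:
    """Realise the additive expression model with planted signals.

    expression(gene, strain) = sum of planted allele effects + Gaussian
    noise(0, noise_sd).  For planted ASDP pairs the two genes' noise vectors
    share a latent factor within each allele group, with loadings solved from
    the target correlations (r0, r1).  Parental replicates are generated from
    the two parental genotypes (all-0 and all-1).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    genes = _gene_ids(config.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    marker_set = set(genotypes.markers)
    for m, g, _ in truth.planted_eqtls:
        if m not in marker_set or g not in gene_index:
            raise IntegrityError(f"planted eQTL ({m}, {g}) dangles")

    n = len(genotypes.strains)
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))
    # overwrite noise of ASDP pairs with allele-conditioned correlated noise
    for m, (a, b, _t), r0, r1 in sorted(truth.planted_asdp):
        if a not in gene_index or b not in gene_index:
            raise IntegrityError(f"planted ASDP edge ({a}, {b}) dangles")
        gvec = genotypes.calls.loc[m].to_numpy(dtype=float)
        for allele, r in ((0.0, r0), (1.0, r1)):
            idx = np.flatnonzero(gvec == allele)
            na, nb = _correlated_noise(rng, len(idx), r, config.noise_sd)
            noise[gene_index[a], idx] = na
            noise[gene_index[b], idx] = nb

    expr = noise.copy()
    for m, g, eff in sorted(truth.planted_eqtls):
        gvec = genotypes.calls.loc[m].to_numpy(dtype=float)
        expr[gene_index[g]] += eff * config.noise_sd * gvec

    values = pd.DataFrame(expr, index=genes, columns=genotypes.strains)

    parent_reps = {}
    for label, allele in (("A", 0.0), ("B", 1.0)):
        pr = rng.normal(
            0.0, config.noise_sd, size=(config.n_genes, config.n_parent_reps)
        )
        for m, g, eff in sorted(truth.planted_eqtls):
            pr[gene_index[g]] += eff * config.noise_sd * allele
        parent_reps[label] = pd.DataFrame(
            pr,
            index=genes,
            columns=[f"{label}_rep{i + 1}" for i in range(config.n_parent_reps)],
        )

    # genes sit at marker positions round-robin so cis pairs are constructible
    mmap = genotypes.marker_map
    rows = []
    for i, g in enumerate(genes):
        m = mmap.iloc[i % len(mmap)]
        start = int(m["position"])
        rows.append((g, m["chromosome"], start, start + 1499))
    gene_positions = pd.DataFrame(
        rows, columns=["gene", "chromosome", "start", "end"]
    ).set_index("gene")
    return ExpressionData(values, parent_reps, gene_positions)


def simulate_smp_phenotypes(
    genotypes: GenotypeMatrix,
    truth: GroundTruth,
    n_compounds: int = 100,
    conditions_per_compound: int = 3,
    seed: int = 0,
    effect_size: float = 1.5,
    noise_sd: float = 1.0,
    interactome: Interactome | None = None,
    targets_per_compound: int = 10,
) -> tuple[pd.DataFrame, dict[str, set[str]], GroundTruth]:
    """Growth-yield traits per compound x condition, plus known-target sets.

    Each compound gets one planted QTL marker whose allele shifts every
    condition's trait by ``effect_size`` (in noise-SD units).  When an
    interactome is supplied, each compound's known drug-target gene set is
    biased toward the network neighbourhood of the genes its QTL marker
    perturbs (planted eQTL targets of that marker and their interactors),
    emulating targets living inside the perturbed sub-network.
    """
    rng = np.random.default_rng(seed)
    markers = genotypes.markers.to_numpy()
    strains = genotypes.strains
    n = len(strains)
    out_truth = GroundTruth(
        planted_eqtls=set(truth.planted_eqtls),
        planted_ascp=set(truth.planted_ascp),
        planted_asdp=set(truth.planted_asdp),
        planted_smp_qtls=set(truth.planted_smp_qtls),
    )
    eqtl_markers = sorted({m for m, _g, _e in truth.planted_eqtls})
    adj = interactome.adjacency() if interactome is not None else None
    all_genes = sorted(interactome.genes) if interactome is not None else []

    rows = []
    index = []
    target_sets: dict[str, set[str]] = {}
    for ci in range(n_compounds):
        compound = f"SMP{ci + 1:03d}"
        if eqtl_markers:
            qtl = eqtl_markers[rng.integers(len(eqtl_markers))]
        else:
            qtl = markers[rng.integers(len(markers))]
        if qtl not in set(markers):
            raise IntegrityError(f"planted SMP QTL marker {qtl!r} dangles")
        out_truth.planted_smp_qtls.add((qtl, compound))
        gvec = genotypes.calls.loc[qtl].to_numpy(dtype=float)
        for k in range(conditions_per_compound):
            cond = f"t{k + 1}c1"
            vals = effect_size * noise_sd * gvec + rng.normal(0, noise_sd, size=n)
            rows.append(vals)
            index.append((compound, cond))
        if adj is not None:
            perturbed = {g for m, g, _e in truth.planted_eqtls if m == qtl}
            hood = set(perturbed)
            for g in perturbed:
                hood |= adj.get(g, set())
            hood = sorted(hood)
            tset: set[str] = set()
            if hood:
                k_in = min(len(hood), max(1, int(0.7 * targets_per_compound)))
                tset |= set(rng.choice(hood, size=k_in, replace=False))
            while len(tset) < targets_per_compound and all_genes:
                tset.add(all_genes[rng.integers(len(all_genes))])
            target_sets[compound] = tset
    phenotypes = pd.DataFrame(
        np.asarray(rows),
        index=pd.MultiIndex.from_tuples(index, names=["compound", "condition"]),
        columns=strains,
    )
    return phenotypes, target_sets, out_truth


def simulate_dataset(config: SimulationConfig, n_compounds: int = 100):
    """End-to-end convenience generator: cross, interactome, planted
    perturbations, expression, and compound phenotypes, all from one seed."""
    genotypes, truth = simulate_cross(config)
    interactome = simulate_interactome(
        config.n_genes, config.edge_counts_by_type, seed=config.seed + 101
    )
    truth = plant_perturbations(genotypes, truth, interactome, config)
    expression = simulate_expression(genotypes, truth, config)
    phenotypes, target_sets, truth = simulate_smp_phenotypes(
        genotypes,
        truth,
        n_compounds=n_compounds,
        seed=config.seed + 202,
        interactome=interactome,
    )
    truth.validate(genotypes, interactome)
    return genotypes, expression, interactome, phenotypes, target_sets, truth
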