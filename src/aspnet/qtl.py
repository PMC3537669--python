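"""Heritability estimation and genome-wide linkage (QTL) mapping.

The mapping model is deliberately simple and matches the design of a haploid
biallelic cross: for every marker the strains split into two allele groups
(0/1) and a trait is tested with the pooled-variance two-sample Student t
statistic.  Significance comes from permutations of the strain labels; by
default the null |t| values are pooled across all markers of a trait
(genome-wide permutation null), and Benjamini-Hochberg is applied across all
marker x trait tests.

Heritability of a trait is H^2 = (sigma^2_seg - sigma^2_parents) /
sigma^2_seg, where sigma^2_parents is the df-weighted pooled within-parent
replicate variance; its significance comes from permuting the combined
segregant + parent values into null groups of the original sizes.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer
from statsmodels.stats.multitest import multipletests

from .containers import EqtlHit, GenotypeMatrix, HeritabilityRecord

__all__ = [
    "merge_identical_markers",
    "estimate_heritability",
    "linkage_t",
    "map_qtls",
    "classify_cis_trans",
    "knn_impute_expression",
    "benjamini_hochberg",
]

#: finite stand-in for an infinite t statistic (zero within-group variance
#: with distinct group means)
T_DEGENERATE = 1e6


class DegenerateGroupWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# marker preprocessing


def merge_identical_markers(
    genotypes: GenotypeMatrix,
) -> tuple[GenotypeMatrix, dict[str, list[str]]]:
    """Collapse maximal runs of adjacent markers with identical genotypes.

    Markers carrying no extra information (identical genotype vectors to
    their neighbour on the same chromosome) are represented by the first
    marker of the run.  Returns the reduced matrix and a map
    representative -> full list of merged marker ids (inverting the merge).
    Non-adjacent duplicates are never merged.
    """
    calls = genotypes.calls
    mmap = genotypes.marker_map
    keep: list[str] = []
    merge_map: dict[str, list[str]] = {}
    arr = calls.to_numpy(dtype=float)
    markers = calls.index.to_numpy()
    chroms = mmap["chromosome"].to_numpy()
    rep = None
    for i in range(len(markers)):
        same = (
            rep is not None
            and chroms[i] == chroms[i - 1]
            and _rows_equal(arr[i], arr[i - 1])
        )
        if same:
            merge_map[rep].append(markers[i])
        else:
            rep = markers[i]
            keep.append(rep)
            merge_map[rep] = [rep]
    merged = GenotypeMatrix(calls.loc[keep], mmap.loc[keep])
    return merged, merge_map


def _rows_equal(a: np.ndarray, b: np.ndarray) -> bool:
    # NaN-aware elementwise equality (two missing calls count as equal)
    both_nan = np.isnan(a) & np.isnan(b)
    return bool(np.all(both_nan | (a == b)))


# ---------------------------------------------------------------------------
# heritability


def estimate_heritability(
    seg_values: Sequence[float],
    parent_values_by_parent: Mapping[str, Sequence[float]],
    n_perm: int = 1000,
    seed: int | None = 0,
) -> HeritabilityRecord:
    """H^2 of one trait with a permutation p-value.

    The permutation pools all segregant and parental values, reassigns them
    at random to null groups of the original sizes, and recomputes H^2; the
    p-value is the fraction of null statistics >= the observed one.
    """
    seg = np.asarray(seg_values, dtype=float)
    parents = [np.asarray(v, dtype=float) for v in parent_values_by_parent.values()]
    if seg.size < 3:
        raise ValueError("need >=3 segregant values")
    if any(p.size < 2 for p in parents):
        raise ValueError("need >=2 replicate values per parent")

    def _h2(seg_v: np.ndarray, parent_vs: list[np.ndarray]) -> tuple[float, float, float]:
        s2_seg = float(np.var(seg_v, ddof=1))
        dfs = np.array([p.size - 1 for p in parent_vs], dtype=float)
        s2s = np.array([np.var(p, ddof=1) for p in parent_vs])
        s2_par = float((dfs * s2s).sum() / dfs.sum())
        if s2_seg == 0.0:
            return np.nan, s2_seg, s2_par
        return (s2_seg - s2_par) / s2_seg, s2_seg, s2_par

    h2, s2_seg, s2_par = _h2(seg, parents)
    if not np.isfinite(h2):
        return HeritabilityRecord(
            trait="", h2=np.nan, sigma2_seg=s2_seg, sigma2_parent_pooled=s2_par,
            p_perm=np.nan, defined=False,
        )
    rng = np.random.default_rng(seed)
    pool = np.concatenate([seg] + parents)
    sizes = [p.size for p in parents]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        null_parents, off = [], seg.size
        null_seg = perm[: seg.size]
        for s in sizes:
            null_parents.append(perm[off : off + s])
            off += s
        h2_null, _, _ = _h2(null_seg, null_parents)
        if np.isfinite(h2_null) and h2_null >= h2:
            hits += 1
    return HeritabilityRecord(
        trait="", h2=h2, sigma2_seg=s2_seg, sigma2_parent_pooled=s2_par,
        p_perm=hits / n_perm,
    )


# ---------------------------------------------------------------------------
# linkage statistic


def linkage_t(trait_values: Sequence[float], genotype_vector: Sequence[float]) -> float:
    """Pooled-variance two-sample Student t between the two allele groups.

    Sign follows mean(allele 1) - mean(allele 0).  A monomorphic marker
    raises; zero pooled variance with distinct means returns a large finite
    statistic (+/- ``T_DEGENERATE``) with a warning.
    """
    y = np.asarray(trait_values, dtype=float)
    g = np.asarray(genotype_vector, dtype=float)
    obs = ~np.isnan(y) & ~np.isnan(g)
    y, g = y[obs], g[obs]
    y0, y1 = y[g == 0], y[g == 1]
    if y0.size == 0 or y1.size == 0:
        raise ValueError("monomorphic marker: one allele group is empty")
    diff = y1.mean() - y0.mean()
    n0, n1 = y0.size, y1.size
    ss = ((y0 - y0.mean()) ** 2).sum() + ((y1 - y1.mean()) ** 2).sum()
    if n0 + n1 <= 2 or ss == 0.0:
        if diff == 0.0:
            return 0.0
        warnings.warn(
            "zero pooled variance; returning large finite t", DegenerateGroupWarning
        )
        return float(np.sign(diff) * T_DEGENERATE)
    s2 = ss / (n0 + n1 - 2)
    return float(diff / np.sqrt(s2 * (1.0 / n0 + 1.0 / n1)))


def _t_all_markers(G: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """t statistics for every marker x trait-column pair.

    G: markers x strains in {0,1}; Y: strains x B trait columns.
    Returns markers x B; NaN where a marker is monomorphic, large finite
    where pooled variance vanishes with distinct means.
    """
    n = G.shape[1]
    n1 = G.sum(axis=1, keepdims=True)
    n0 = n - n1
    s1 = G @ Y
    stot = Y.sum(axis=0, keepdims=True)
    s0 = stot - s1
    q1 = G @ (Y**2)
    qtot = (Y**2).sum(axis=0, keepdims=True)
    q0 = qtot - q1
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = s1 / n1
        m0 = s0 / n0
        ss = (q1 - n1 * m1**2) + (q0 - n0 * m0**2)
        ss = np.maximum(ss, 0.0)
        s2 = ss / (n - 2)
        t = (m1 - m0) / np.sqrt(s2 * (1.0 / n0 + 1.0 / n1))
    diff = m1 - m0
    degen = (ss == 0.0) & np.isfinite(diff) & (diff != 0.0)
    t = np.where(degen, np.sign(diff) * T_DEGENERATE, t)
    mono = (n1 == 0) | (n0 == 0)
    t = np.where(mono, np.nan, t)
    t = np.where(np.isfinite(diff) & (diff == 0.0), 0.0, t)
    return t


def map_qtls(
    genotypes: GenotypeMatrix,
    traits: pd.DataFrame,
    n_perm: int = 1000,
    fdr_level: float = 0.05,
    seed: int | None = 0,
    null_pooling: str = "trait",
    conservative_p: bool = False,
    return_all: bool = False,
) -> list[EqtlHit] | tuple[list[EqtlHit], pd.DataFrame]:
    """Permutation-based linkage mapping of every trait against every marker.

    Per trait, ``n_perm`` permutations of the strain labels build a null |t|
    pool (by default pooled across all markers of the trait); the p-value of
    a marker is the plain frequency of null |t*| >= observed |t|.  BH is
    applied across all marker x trait tests and hits with q < ``fdr_level``
    are returned.  Works identically for expression (eQTL) and compound
    response (QTL) traits.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if null_pooling not in ("trait", "pair"):
        raise ValueError("null_pooling must be 'trait' or 'pair'")
    common = traits.columns.intersection(genotypes.strains)
    if len(common) < 4:
        raise ValueError("too few shared strains between genotypes and traits")
    G = genotypes.calls.loc[:, common].to_numpy(dtype=float)
    Y = traits.loc[:, common].to_numpy(dtype=float).T  # strains x traits
    rng = np.random.default_rng(seed)
    n = G.shape[1]

    rows = []
    for j, trait in enumerate(traits.index):
        y = Y[:, [j]]
        t_obs = _t_all_markers(G, y)[:, 0]
        perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
        t_null = np.abs(_t_all_markers(G, y[perm_idx[:, :], 0].T))
        abs_obs = np.abs(t_obs)
        if null_pooling == "trait":
            pool = np.sort(t_null[np.isfinite(t_null)], axis=None)
            npool = pool.size
            cnt = npool - np.searchsorted(pool, abs_obs, side="left")
            p = (cnt + 1) / (npool + 1) if conservative_p else cnt / npool
        else:
            cnt = (t_null >= abs_obs[:, None]).sum(axis=1)
            p = (cnt + 1) / (n_perm + 1) if conservative_p else cnt / n_perm
        for i, marker in enumerate(genotypes.markers):
            if np.isnan(t_obs[i]):
                continue
            rows.append((marker, trait, t_obs[i], p[i]))
    table = pd.DataFrame(rows, columns=["marker", "trait", "t_stat", "p_perm"])
    table["q"] = benjamini_hochberg(table["p_perm"].to_numpy())
    hits = [
        EqtlHit(r.marker, r.trait, float(r.t_stat), float(r.p_perm), float(r.q))
        for r in table.itertuples(index=False)
        if r.q < fdr_level
    ]
    if return_all:
        return hits, table
    return hits


# ---------------------------------------------------------------------------
# cis/trans classification


def classify_cis_trans(
    hits: Iterable[EqtlHit],
    marker_map: pd.DataFrame,
    gene_positions: pd.DataFrame,
    window_bp: int = 10_000,
) -> list[EqtlHit]:
    """Label each hit cis (marker within ``window_bp`` of the trait gene's
    span, same chromosome), trans otherwise, unknown if the gene is
    unplaced."""
    out = []
    for h in hits:
        if h.trait not in gene_positions.index or h.marker not in marker_map.index:
            out.append(EqtlHit(h.marker, h.trait, h.t_stat, h.p_perm, h.q, "unknown"))
            continue
        g = gene_positions.loc[h.trait]
        mchrom = marker_map.at[h.marker, "chromosome"]
        mpos = int(marker_map.at[h.marker, "position"])
        if g["chromosome"] != mchrom:
            label = "trans"
        else:
            start, end = int(g["start"]), int(g["end"])
            if start <= mpos <= end:
                dist = 0
            else:
                dist = min(abs(mpos - start), abs(mpos - end))
            label = "cis" if dist <= window_bp else "trans"
        out.append(EqtlHit(h.marker, h.trait, h.t_stat, h.p_perm, h.q, label))
    return out


# ---------------------------------------------------------------------------
# imputation and multiple testing


def knn_impute_expression(matrix: pd.DataFrame, k: int = 15) -> pd.DataFrame:
    """Fill missing expression values from the k nearest rows.

    Distances are Euclidean over co-observed columns (nan-euclidean); a
    missing entry becomes the mean of the k nearest rows' values in that
    column.  Observed entries are untouched.
    """
    arr = matrix.to_numpy(dtype=float)
    all_missing = np.isnan(arr).all(axis=1)
    if all_missing.any():
        row = matrix.index[np.flatnonzero(all_missing)[0]]
        raise ValueError(f"row {row!r} has no observed values; cannot impute")
    if not np.isnan(arr).any():
        return matrix.copy()
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(arr)
    return pd.DataFrame(filled, index=matrix.index, columns=matrix.columns)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up BH q-values (monotone, clipped to 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
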