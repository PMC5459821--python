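"""Diversity, comparison and membership statistics.

Rarefaction, alpha diversity (observed OTUs, Chao1, Shannon, Simpson, Good's
coverage), Welch's t-test, Euclidean profile distances with UPGMA
dendrograms, core-microbiome ubiquity screens and indicator-value (IndVal)
analysis with permutation p-values.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .cluster import OtuTable
from .regions import TreeNode

__all__ = [
    "AlphaDiversity",
    "CoreMembership",
    "IndvalResult",
    "rarefy",
    "alpha_diversity",
    "welch_test",
    "profile_distance",
    "upgma",
    "core_microbiome",
    "indval",
]


# ---------------------------------------------------------------------------
# Rarefaction and alpha diversity
# ---------------------------------------------------------------------------


def rarefy(table: OtuTable, depth: int, seed: int = 0) -> OtuTable:
    """Subsample every sample, without replacement, to exactly ``depth`` reads.

    Samples with fewer than ``depth`` reads are dropped with a warning.
    Deterministic for a fixed seed.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    kept_samples: list[str] = []
    rows: list[np.ndarray] = []
    for i, sample_id in enumerate(table.sample_ids):
        row = table.counts[i]
        total = int(row.sum())
        if total < depth:
            warnings.warn(
                f"sample {sample_id} has {total} < depth {depth} reads; dropped",
                stacklevel=2,
            )
            continue
        if total == depth:
            sub = row.copy()
        else:
            sub = rng.multivariate_hypergeometric(row, depth)
        kept_samples.append(sample_id)
        rows.append(np.asarray(sub, dtype=np.int64))
    if not rows:
        raise ValueError("no sample reaches the rarefaction depth")
    counts = np.vstack(rows)
    return OtuTable(
        list(table.otu_ids), kept_samples, counts, dict(table.centroids), dict(table.provenance)
    ).drop_empty_otus()


@dataclass
class AlphaDiversity:
    sample_id: str
    observed_otus: int
    chao1: float
    shannon: float
    simpson: float
    goods_coverage: float
    singletons: int
    doubletons: int
    n_reads: int


def alpha_diversity(
    counts: Sequence[int] | np.ndarray,
    sample_id: str = "sample",
    *,
    shannon_base: float = 2.0,
    chao1_bias_corrected: bool = True,
) -> AlphaDiversity:
    """Alpha-diversity panel for one sample's OTU count vector.

    Shannon uses log base 2 by default; Simpson is the Gini-Simpson form
    ``1 - sum(p_i^2)``; Chao1 is bias-corrected
    ``S + F1*(F1-1) / (2*(F2+1))`` by default, with the classic
    ``S + F1^2 / (2*F2)`` form available (falling back to the bias-corrected
    term when F2 = 0); Good's coverage is ``1 - F1/N``.
    """
    vec = np.asarray(counts, dtype=np.int64)
    if (vec < 0).any():
        raise ValueError("negative counts")
    n = int(vec.sum())
    if n < 1:
        raise ValueError("all-zero count vector")
    nz = vec[vec > 0]
    s_obs = int(nz.size)
    f1 = int((nz == 1).sum())
    f2 = int((nz == 2).sum())
    if chao1_bias_corrected or f2 == 0:
        chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    else:
        chao1 = s_obs + f1 * f1 / (2.0 * f2)
    p = nz / n
    shannon = float(-(p * (np.log(p) / math.log(shannon_base))).sum())
    simpson = float(1.0 - (p**2).sum())
    goods = 1.0 - f1 / n
    return AlphaDiversity(sample_id, s_obs, chao1, shannon, simpson, goods, f1, f2, n)


def alpha_diversity_table(table: OtuTable, **kwargs) -> pd.DataFrame:
    rows = []
    for i, sample_id in enumerate(table.sample_ids):
        a = alpha_diversity(table.counts[i], sample_id, **kwargs)
        rows.append(
            {
                "sample_id": a.sample_id,
                "n_reads": a.n_reads,
                "observed_otus": a.observed_otus,
                "chao1": a.chao1,
                "simpson": a.simpson,
                "shannon": a.shannon,
                "goods_coverage": a.goods_coverage,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Welch's t-test
# ---------------------------------------------------------------------------


def welch_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: returns ``(t, df, two_sided_p)``.

    Undefined (all-NaN) when both groups have zero variance, unless the
    means are also equal, in which case ``t = 0, p = 1``.
    """
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if xa.size < 2 or ya.size < 2:
        raise ValueError("need at least 2 values per group")
    vx, vy = xa.var(ddof=1), ya.var(ddof=1)
    n, m = xa.size, ya.size
    se2 = vx / n + vy / m
    if se2 == 0.0:
        if xa.mean() == ya.mean():
            return 0.0, float("nan"), 1.0
        return float("nan"), float("nan"), float("nan")
    t = (xa.mean() - ya.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / n) ** 2 / (n - 1) + (vy / m) ** 2 / (m - 1))
    p = 2.0 * sp_stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


# ---------------------------------------------------------------------------
# Profile distances and UPGMA
# ---------------------------------------------------------------------------


def profile_distance(
    table: OtuTable,
    lineages: Mapping[str, Mapping[str, str]],
    rank: str = "order",
) -> tuple[np.ndarray, list[str]]:
    """Euclidean distance matrix on rank-aggregated relative abundances.

    ``lineages`` maps otu_id -> rank -> taxon; OTUs without a lineage entry
    are pooled under an explicit "unclassified" bucket.
    """
    taxa: dict[str, int] = {}
    cols: list[int] = []
    for otu in table.otu_ids:
        taxon = lineages.get(otu, {}).get(rank, "unclassified")
        cols.append(taxa.setdefault(taxon, len(taxa)))
    agg = np.zeros((len(table.sample_ids), len(taxa)))
    for j, t in enumerate(cols):
        agg[:, t] += table.counts[:, j]
    totals = agg.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("sample with zero reads")
    rel = agg / totals
    n = rel.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(rel[i] - rel[j]))
            dist[i, j] = dist[j, i] = d
    return dist, list(table.sample_ids)


def upgma(dist: np.ndarray, names: Sequence[str]) -> TreeNode:
    """Average-linkage agglomerative dendrogram (ultrametric).

    Merge heights are half the (unweighted) average inter-cluster distance,
    so leaf-to-root path lengths are equal within every subtree.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.shape[0] != dist.shape[1] or not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(dist), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    clusters: dict[int, tuple[TreeNode, float, int]] = {
        i: (TreeNode(name=str(nm)), 0.0, 1) for i, nm in enumerate(names)
    }
    d = {(i, j): dist[i, j] for i in range(len(names)) for j in range(i + 1, len(names))}
    next_id = len(names)
    while len(clusters) > 1:
        (i, j), dij = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        node_i, h_i, n_i = clusters[i]
        node_j, h_j, n_j = clusters[j]
        height = dij / 2.0
        parent = TreeNode(
            children=[(node_i, height - h_i), (node_j, height - h_j)]
        )
        del clusters[i], clusters[j]
        new_d = {}
        for k in clusters:
            dik = d[tuple(sorted((i, k)))]
            djk = d[tuple(sorted((j, k)))]
            new_d[k] = (n_i * dik + n_j * djk) / (n_i + n_j)
        d = {key: v for key, v in d.items() if i not in key and j not in key}
        for k, v in new_d.items():
            d[tuple(sorted((k, next_id)))] = v
        clusters[next_id] = (parent, height, n_i + n_j)
        next_id += 1
    (root, _h, _n) = next(iter(clusters.values()))
    return root


# ---------------------------------------------------------------------------
# Core microbiome
# ---------------------------------------------------------------------------


@dataclass
class CoreMembership:
    species: str
    ubiquity_pct: float  # % of samples with presence
    mean_relative_abundance_pct: float
    per_site_abundance_pct: dict[str, float]


def core_microbiome(
    table: pd.DataFrame,
    ubiquity_threshold_pct: float,
    sites: Optional[Mapping[str, str]] = None,
) -> list[CoreMembership]:
    """Ubiquity screen on a species x sample abundance table.

    ``table`` is indexed by species with one column per sample (counts or
    relative abundances).  A species is a member when present (value >= 1
    for counts, > 0 generally) in at least ``ceil(threshold * n / 100)``
    samples, irrespective of abundance.  Output is sorted by decreasing
    ubiquity then mean relative abundance.
    """
    if not 0.0 < ubiquity_threshold_pct <= 100.0:
        raise ValueError("threshold must be in (0, 100]")
    if table.empty:
        raise ValueError("empty table")
    n_samples = table.shape[1]
    needed = math.ceil(ubiquity_threshold_pct * n_samples / 100.0)
    rel = table.div(table.sum(axis=0), axis=1) * 100.0
    present = table > 0
    members: list[CoreMembership] = []
    for species in table.index:
        n_present = int(present.loc[species].sum())
        if n_present < needed:
            continue
        per_site: dict[str, float] = {}
        if sites:
            by_site: dict[str, list[float]] = {}
            for sample in table.columns:
                by_site.setdefault(sites[sample], []).append(float(rel.loc[species, sample]))
            per_site = {s: float(np.mean(v)) for s, v in by_site.items()}
        members.append(
            CoreMembership(
                species=str(species),
                ubiquity_pct=100.0 * n_present / n_samples,
                mean_relative_abundance_pct=float(rel.loc[species].mean()),
                per_site_abundance_pct=per_site,
            )
        )
    members.sort(key=lambda m: (-m.ubiquity_pct, -m.mean_relative_abundance_pct, m.species))
    return members


def write_core(members: Sequence[CoreMembership], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["species", "ubiquity_pct", "mean_relative_abundance_pct"])
        for m in members:
            writer.writerow([m.species, f"{m.ubiquity_pct:.1f}", f"{m.mean_relative_abundance_pct:.3f}"])


# ---------------------------------------------------------------------------
# Indicator species analysis
# ---------------------------------------------------------------------------


@dataclass
class IndvalResult:
    species: str
    group: str
    specificity: float  # A
    fidelity: float  # B
    indval: float  # A * B, 0-1 scale
    p_value: float


def indval(
    table: pd.DataFrame,
    groups: Mapping[str, str],
    n_perm: int = 999,
    seed: int = 0,
    *,
    scale_100: bool = False,
    exhaustive: bool = False,
) -> list[IndvalResult]:
    """Dufrene-Legendre indicator values with permutation p-values.

    For species i and group j, specificity ``A = mean abundance in j /
    sum over groups of mean abundances`` and fidelity ``B = fraction of
    group-j samples where i is present``; ``IndVal = A * B``.  The null
    distribution permutes group labels over samples; each row's p-value is
    ``(1 + #{permuted max-group IndVal >= observed}) / (1 + n_perm)``.
    With ``exhaustive=True`` every label permutation is enumerated instead of
    sampling ``n_perm`` random ones (only sensible for toy sample counts).
    """
    group_of = dict(groups)
    labels = [group_of[s] for s in table.columns]
    group_names = sorted(set(labels))
    if len(group_names) < 2:
        raise ValueError("need at least 2 groups")
    for g in group_names:
        if labels.count(g) == 0:  # pragma: no cover - unreachable by construction
            raise ValueError(f"group {g} has no samples")

    data = table.to_numpy(dtype=float)
    label_arr = np.array(labels)

    def ab_matrices(lab: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        means = np.stack([data[:, lab == g].mean(axis=1) for g in group_names], axis=1)
        pres = np.stack([(data[:, lab == g] > 0).mean(axis=1) for g in group_names], axis=1)
        denom = means.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.where(denom > 0, means / denom, 0.0)
        return a, pres

    obs_a, obs_b = ab_matrices(label_arr)
    observed = obs_a * obs_b

    exceed = np.zeros_like(observed)
    if exhaustive:
        from itertools import permutations as iter_permutations

        n_done = 0
        for perm in iter_permutations(label_arr):
            pa, pb = ab_matrices(np.array(perm))
            exceed += (pa * pb).max(axis=1, keepdims=True) >= observed
            n_done += 1
        p_values = (1.0 + exceed) / (1.0 + n_done)
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = rng.permutation(label_arr)
            pa, pb = ab_matrices(perm)
            perm_max = (pa * pb).max(axis=1, keepdims=True)
            exceed += perm_max >= observed
        p_values = (1.0 + exceed) / (1.0 + n_perm)

    scale = 100.0 if scale_100 else 1.0
    results: list[IndvalResult] = []
    for i, species in enumerate(table.index):
        for j, g in enumerate(group_names):
            results.append(
                IndvalResult(
                    species=str(species),
                    group=g,
                    specificity=float(obs_a[i, j]),
                    fidelity=float(obs_b[i, j]),
                    indval=float(observed[i, j]) * scale,
                    p_value=float(p_values[i, j]),
                )
            )
    return results


def write_indval(results: Sequence[IndvalResult], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["species", "group", "A", "B", "indval", "p_value"])
        for r in results:
            writer.writerow(
                [r.species, r.group, f"{r.specificity:.4f}", f"{r.fidelity:.4f}", f"{r.indval:.4f}", f"{r.p_value:.4f}"]
            )
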