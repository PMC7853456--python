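"""Haplotype-level analyses around a duplicated locus.

The duplication itself cannot be phased, so haplotype work proceeds via
*tagging variants*: diploid-region SNPs in near-perfect linkage with the
focal resistance allele.  This module finds such variants, clusters the
surrounding haplotypes into minimum-spanning-tree networks, and computes
the sweep statistics used to characterise the selected haplotype —
Garud's H1/H12/H2, haplotype diversity and EHH decay — together with
leave-one-haplotype-out jackknife errors for flank averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from dupsweep.io import HaplotypeMatrix


class HaplotypeError(ValueError):
    pass


def _hm_window(hm: HaplotypeMatrix, start: int, stop: int) -> HaplotypeMatrix:
    """Variant-index slice [start, stop) of a haplotype matrix."""
    return HaplotypeMatrix(
        chrom=hm.chrom,
        positions=hm.positions[start:stop],
        haplotypes=hm.haplotypes[start:stop],
        haplotype_ids=hm.haplotype_ids,
    )


# --------------------------------------------------------------------------
# Rogers–Huff r


def rogers_huff_r(dosages_x: np.ndarray, dosages_y: np.ndarray) -> float:
    """Rogers–Huff composite LD: Pearson correlation of genotype dosages.

    Missing entries (NaN) are pairwise-deleted.  Returns NaN when either
    vector has zero variance over the complete pairs.
    """
    x = np.asarray(dosages_x, float)
    y = np.asarray(dosages_y, float)
    if x.shape != y.shape:
        raise HaplotypeError("dosage vectors must be the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


# --------------------------------------------------------------------------
# tagging variants


@dataclass
class TaggingCriteria:
    """Filters that qualify a variant as a proxy for the focal allele.

    A tagging variant must be in near-perfect LD with the focal site
    (|r| > ``r_threshold``), lie in a window whose mean haplotype score
    and normalised coverage are both ≈ 2 (effectively diploid, hence
    phaseable), and be present in the phased variant set.
    """

    r_threshold: float = 0.95
    flank_bp: int = 300
    diploid_target: float = 2.0
    diploid_tolerance: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.r_threshold <= 1:
            raise HaplotypeError("r_threshold must be in (0, 1]")
        if self.diploid_tolerance <= 0:
            raise HaplotypeError("diploid tolerance must be positive")


def find_tagging_variants(
    dosages: np.ndarray,
    positions: np.ndarray,
    focal_index: int,
    window_tracks: pd.DataFrame,
    phased_positions: np.ndarray,
    criteria: TaggingCriteria | None = None,
) -> list[int]:
    """Return variant indices usable as tagging variants for the focal site.

    Parameters
    ----------
    dosages : variants × samples genotype dosages.
    window_tracks : DataFrame with columns start, end (1-based inclusive
        bp), haplotype_score, coverage; each variant is filtered on the
        track window containing its position.
    phased_positions : positions present in the phased set.
    """
    criteria = criteria or TaggingCriteria()
    positions = np.asarray(positions)
    phased = set(int(p) for p in np.asarray(phased_positions))
    focal = dosages[focal_index]
    out = []
    for i in range(dosages.shape[0]):
        if i == focal_index:
            continue
        r = rogers_huff_r(focal, dosages[i])
        if not np.isfinite(r) or abs(r) <= criteria.r_threshold:
            continue
        pos = int(positions[i])
        if pos not in phased:
            continue
        row = window_tracks[
            (window_tracks["start"] <= pos) & (window_tracks["end"] >= pos)
        ]
        if row.empty:
            continue
        hs = float(row["haplotype_score"].iloc[0])
        cov = float(row["coverage"].iloc[0])
        if (
            abs(hs - criteria.diploid_target) <= criteria.diploid_tolerance
            and abs(cov - criteria.diploid_target) <= criteria.diploid_tolerance
        ):
            out.append(i)
    return out


# --------------------------------------------------------------------------
# haplotype clustering and MST networks


@dataclass
class NetworkNode:
    node_id: int
    size: int
    member_ids: list[str]
    tag_allele: int | None = None
    populations: dict[str, int] = field(default_factory=dict)


@dataclass
class HaplotypeNetwork:
    nodes: list[NetworkNode]
    edges: list[tuple[int, int, int]]          # (node, node, hamming distance)
    dropped_edges: list[tuple[int, int, int]]  # MST edges with distance > 1


def _cluster_identical(haps: np.ndarray, ids: Sequence[str]):
    """Group identical haplotype columns; clusters ordered by first member."""
    keys: dict[bytes, int] = {}
    members: list[list[int]] = []
    for j in range(haps.shape[1]):
        key = haps[:, j].tobytes()
        if key not in keys:
            keys[key] = len(members)
            members.append([])
        members[keys[key]].append(j)
    reps = np.stack([haps[:, m[0]] for m in members], axis=1)
    return reps, members


def _kruskal_mst(n: int, dist: np.ndarray) -> list[tuple[int, int, int]]:
    """Deterministic MST: edges sorted by (weight, i, j); union-find."""
    edges = sorted(
        (int(dist[i, j]), i, j) for i in range(n) for j in range(i + 1, n)
    )
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    out = []
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            out.append((i, j, w))
            if len(out) == n - 1:
                break
    return out


def build_haplotype_network(
    hm: HaplotypeMatrix,
    tag_alleles: Sequence[int] | None = None,
    populations: Sequence[str] | None = None,
    max_edge_distance: int = 1,
) -> HaplotypeNetwork:
    """Cluster identical haplotypes and link clusters by an MST.

    Identical haplotypes collapse into one node; a minimum spanning tree
    is built over pairwise Hamming distances between cluster
    representatives (ties broken by lexicographic node index, so the
    network is deterministic), and MST edges longer than
    ``max_edge_distance`` substitutions are removed, fragmenting the
    tree into connected components of closely related haplotypes.
    """
    if hm.n_variants == 0 or hm.n_haplotypes == 0:
        raise HaplotypeError("empty haplotype window")
    reps, members = _cluster_identical(hm.haplotypes, hm.haplotype_ids)
    n = len(members)
    nodes = []
    for k, mem in enumerate(members):
        tag = None
        if tag_alleles is not None:
            tag = int(np.round(np.mean([tag_alleles[j] for j in mem])))
        pops: dict[str, int] = {}
        if populations is not None:
            for j in mem:
                pops[populations[j]] = pops.get(populations[j], 0) + 1
        nodes.append(
            NetworkNode(
                node_id=k,
                size=len(mem),
                member_ids=[hm.haplotype_ids[j] for j in mem],
                tag_allele=tag,
                populations=pops,
            )
        )
    if n == 1:
        return HaplotypeNetwork(nodes=nodes, edges=[], dropped_edges=[])
    dist = np.zeros((n, n), dtype=int)
    for i in range(n):
        diff = (reps[:, i][:, None] != reps[:, i + 1:]).sum(axis=0)
        dist[i, i + 1:] = diff
        dist[i + 1:, i] = diff
    mst = _kruskal_mst(n, dist)
    kept = [e for e in mst if e[2] <= max_edge_distance]
    dropped = [e for e in mst if e[2] > max_edge_distance]
    return HaplotypeNetwork(nodes=nodes, edges=kept, dropped_edges=dropped)


# --------------------------------------------------------------------------
# sweep statistics


def _cluster_freqs(haps: np.ndarray) -> np.ndarray:
    """Sorted (descending) frequencies of identical-haplotype clusters."""
    _, members = _cluster_identical(haps, [str(i) for i in range(haps.shape[1])])
    sizes = np.array(sorted((len(m) for m in members), reverse=True), float)
    return sizes / haps.shape[1]


def garud_h(haps: np.ndarray) -> tuple[float, float, float, float]:
    """Garud's haplotype-homozygosity statistics (H1, H12, H2, H2/H1).

    H1 = Σpᵢ²; H12 = (p1+p2)² + Σ_{i≥3}pᵢ²; H2 = H1 − p1².  H12 folds
    the two most frequent haplotypes together, making soft sweeps (two
    high-frequency haplotypes) look as extreme as hard ones.
    """
    haps = np.asarray(haps)
    if haps.ndim != 2 or haps.shape[1] < 2:
        raise HaplotypeError("need >= 2 haplotypes")
    p = _cluster_freqs(haps)
    h1 = float((p ** 2).sum())
    if len(p) >= 2:
        h12 = float((p[0] + p[1]) ** 2 + (p[2:] ** 2).sum())
    else:
        h12 = h1
    h2 = h1 - float(p[0] ** 2)
    ratio = h2 / h1 if h1 > 0 else 0.0
    return h1, h12, h2, ratio


def haplotype_diversity(haps: np.ndarray) -> float:
    """Unbiased haplotype heterozygosity (1 − Σpᵢ²)·n/(n−1)."""
    haps = np.asarray(haps)
    n = haps.shape[1]
    if n < 2:
        raise HaplotypeError("need >= 2 haplotypes")
    p = _cluster_freqs(haps)
    return float((1.0 - (p ** 2).sum()) * n / (n - 1))


def moving_statistic(
    hm: HaplotypeMatrix,
    stat: Callable[[np.ndarray], float],
    window_size: int = 500,
    overlap_fraction: float = 0.2,
    step_mode: str = "share",
) -> pd.DataFrame:
    """Apply a haplotype-window statistic along the matrix.

    ``step_mode='share'`` (default) makes adjacent windows share
    ``overlap_fraction`` of their variants (step = window·(1−overlap));
    ``step_mode='step'`` reads the fraction as the step itself
    (step = window·overlap).
    """
    if step_mode == "share":
        step = max(1, int(round(window_size * (1 - overlap_fraction))))
    elif step_mode == "step":
        step = max(1, int(round(window_size * overlap_fraction)))
    else:
        raise HaplotypeError(f"unknown step_mode {step_mode!r}")
    rows = []
    start = 0
    w = 0
    while start + window_size <= hm.n_variants:
        sub = hm.haplotypes[start:start + window_size]
        rows.append(
            {
                "window_index": w,
                "first_variant": start,
                "last_variant": start + window_size - 1,
                "first_pos": int(hm.positions[start]),
                "last_pos": int(hm.positions[start + window_size - 1]),
                "value": stat(sub),
            }
        )
        start += step
        w += 1
    return pd.DataFrame(rows)


def ehh_decay(
    haps: np.ndarray, core_index: int, direction: str = "right"
) -> np.ndarray:
    """Extended haplotype homozygosity from a core variant outward.

    EHH at step x is the probability that two randomly drawn haplotypes
    are identical over every variant from the core through x:
    Σ_c C(n_c, 2) / C(n, 2) over clusters of identity.  EHH(core) uses
    the core variant alone and the sequence is non-increasing.
    """
    haps = np.asarray(haps)
    n = haps.shape[1]
    if n < 2:
        raise HaplotypeError("need >= 2 haplotypes")
    if direction == "right":
        span = range(core_index, haps.shape[0])
    elif direction == "left":
        span = range(core_index, -1, -1)
    else:
        raise HaplotypeError("direction must be 'right' or 'left'")
    total_pairs = n * (n - 1) / 2
    keys = [b"" for _ in range(n)]
    out = []
    for idx in span:
        row = haps[idx]
        keys = [keys[j] + bytes([row[j]]) for j in range(n)]
        counts: dict[bytes, int] = {}
        for k in keys:
            counts[k] = counts.get(k, 0) + 1
        pairs = sum(c * (c - 1) / 2 for c in counts.values())
        out.append(pairs / total_pairs)
    return np.asarray(out)


# --------------------------------------------------------------------------
# flank averages with sample jackknife


def flank_average_with_jackknife(
    haps: np.ndarray,
    stat: Callable[[np.ndarray], float],
) -> tuple[float, float]:
    """Statistic over a haplotype set with leave-one-haplotype-out SE.

    The jackknife treats haplotypes (columns) as the resampling unit;
    SE = sqrt((n−1)/n · Σ(θ̂₋ⱼ − θ̄)²).
    """
    haps = np.asarray(haps)
    n = haps.shape[1]
    if n < 2:
        raise HaplotypeError("need >= 2 haplotypes for the jackknife")
    full = float(stat(haps))
    loo = np.empty(n)
    for j in range(n):
        loo[j] = stat(np.delete(haps, j, axis=1))
    se = float(np.sqrt((n - 1) / n * ((loo - loo.mean()) ** 2).sum()))
    return full, se
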