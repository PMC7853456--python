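"""Patterson's D introgression tests and three-population branch lengths.

D is computed from population allele frequencies (not single genomes):
per site, with alternate-allele frequencies p_A, p_B, p_C and outgroup
frequency p_O,

    ABBA = (1 − p_A)·p_B·p_C·(1 − p_O)
    BABA = p_A·(1 − p_B)·p_C·(1 − p_O)

and a window or region D is the ratio of sums Σ(ABBA − BABA)/Σ(ABBA + BABA).
Significance comes from a block jackknife over consecutive variant
blocks (Z = D/SE, two-sided normal p).  Sites where the outgroup is
polymorphic are retained with p_O as observed rather than being forced
to the ancestral state.

Branch lengths re-use the PBS construction: L_X = (T_XY + T_XZ − T_YZ)/2
with T = −ln(1 − F_ST), which orients the direction of shared ancestry
between duplicated and wild-type groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from dupsweep.io import WindowedStat
from dupsweep.scan import (
    ScanError,
    _branch_t,
    _window_slices,
    hudson_fst,
)


@dataclass
class DTestResult:
    d: float
    se: float
    z: float
    p: float
    n_sites: int
    windows: list[WindowedStat]
    labels: tuple[str, str, str, str] = ("A", "B", "C", "O")


@dataclass
class BranchLengths:
    """Region-average branch length per group, with jackknife SEs."""

    groups: tuple[str, str, str]
    lengths: dict[str, float]
    ses: dict[str, float]
    window_lengths: dict[str, np.ndarray]


def _freqs(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return counts[:, 1] / counts.sum(axis=1)


def abba_baba_components(
    counts_a, counts_b, counts_c, counts_o
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site ABBA and BABA expectations from allele frequencies."""
    pa, pb, pc, po = (_freqs(c) for c in (counts_a, counts_b, counts_c, counts_o))
    abba = (1 - pa) * pb * pc * (1 - po)
    baba = pa * (1 - pb) * pc * (1 - po)
    return abba, baba


def patterson_d(
    counts_a,
    counts_b,
    counts_c,
    counts_o,
    window_size: int = 5000,
    step_fraction: float = 0.2,
    positions: np.ndarray | None = None,
) -> list[WindowedStat]:
    """Windowed Patterson's D (ratio of sums inside each window).

    ``step_fraction`` is the step as a fraction of the window size.
    Windows with a zero denominator get ``value=nan``.
    """
    abba, baba = abba_baba_components(counts_a, counts_b, counts_c, counts_o)
    if positions is None:
        positions = np.arange(1, len(abba) + 1)
    step = max(1, int(round(window_size * step_fraction)))
    out = []
    for w, (lo, hi) in enumerate(_window_slices(len(abba), window_size, step)):
        num = abba[lo:hi] - baba[lo:hi]
        den = abba[lo:hi] + baba[lo:hi]
        ok = np.isfinite(num) & np.isfinite(den)
        dsum = den[ok].sum()
        value = float(num[ok].sum() / dsum) if ok.any() and dsum > 0 else np.nan
        out.append(
            WindowedStat(
                window_index=w, first_variant=lo, last_variant=hi - 1,
                first_pos=int(positions[lo]), last_pos=int(positions[hi - 1]),
                value=value,
            )
        )
    return out


def region_d_with_jackknife(
    counts_a,
    counts_b,
    counts_c,
    counts_o,
    block_length: int = 100,
    labels: tuple[str, str, str, str] = ("A", "B", "C", "O"),
) -> DTestResult:
    """Region-average D as a ratio of sums, with block-jackknife SE.

    The region statistic is Σ(ABBA−BABA)/Σ(ABBA+BABA) over all sites;
    the SE comes from leave-one-block-out recomputation of that ratio
    over consecutive blocks of ``block_length`` variants.
    """
    abba, baba = abba_baba_components(counts_a, counts_b, counts_c, counts_o)
    ok = np.isfinite(abba) & np.isfinite(baba)
    num = (abba - baba)[ok]
    den = (abba + baba)[ok]
    n_blocks = int(np.ceil(len(num) / block_length))
    if n_blocks < 2:
        raise ScanError("need at least 2 jackknife blocks in the region")
    d = float(num.sum() / den.sum())
    loo = np.empty(n_blocks)
    for b in range(n_blocks):
        mask = np.ones(len(num), bool)
        mask[b * block_length:(b + 1) * block_length] = False
        loo[b] = num[mask].sum() / den[mask].sum()
    se = float(np.sqrt((n_blocks - 1) / n_blocks * ((loo - loo.mean()) ** 2).sum()))
    if se == 0:
        z = 0.0 if d == 0 else np.inf * np.sign(d)
        p = 1.0 if d == 0 else 0.0
    else:
        z = d / se
        p = float(2 * scipy.stats.norm.sf(abs(z)))
    windows = patterson_d(
        counts_a, counts_b, counts_c, counts_o,
        window_size=min(block_length, len(num)), step_fraction=1.0,
    )
    return DTestResult(
        d=d, se=se, z=float(z), p=p, n_sites=int(ok.sum()),
        windows=windows, labels=labels,
    )


def three_pop_branch_lengths(
    counts_x,
    counts_y,
    counts_z,
    window_size: int = 100,
    groups: tuple[str, str, str] = ("dup", "wtA", "wtB"),
) -> BranchLengths:
    """Per-group branch lengths in non-overlapping variant windows.

    For each window, pairwise Hudson F_ST values are converted to
    T = −ln(1 − F_ST) and each group's branch is
    L_X = (T_XY + T_XZ − T_YZ)/2; L_X + L_Y = T_XY by construction.
    Region averages use a block jackknife over windows.
    """
    fxy = hudson_fst(counts_x, counts_y, window_size)
    fxz = hudson_fst(counts_x, counts_z, window_size)
    fyz = hudson_fst(counts_y, counts_z, window_size)
    t_xy = np.array([_branch_t(w.value) for w in fxy])
    t_xz = np.array([_branch_t(w.value) for w in fxz])
    t_yz = np.array([_branch_t(w.value) for w in fyz])
    lx = (t_xy + t_xz - t_yz) / 2
    ly = (t_xy + t_yz - t_xz) / 2
    lz = (t_xz + t_yz - t_xy) / 2
    window_lengths = {groups[0]: lx, groups[1]: ly, groups[2]: lz}
    lengths, ses = {}, {}
    for g, vals in window_lengths.items():
        finite = vals[np.isfinite(vals)]
        if len(finite) < 2:
            raise ScanError("need >= 2 windows for branch-length jackknife")
        mean = float(finite.mean())
        n = len(finite)
        loo = (finite.sum() - finite) / (n - 1)
        ses[g] = float(np.sqrt((n - 1) / n * ((loo - loo.mean()) ** 2).sum()))
        lengths[g] = mean
    return BranchLengths(
        groups=groups, lengths=lengths, ses=ses, window_lengths=window_lengths
    )
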