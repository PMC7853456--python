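"""Windowed differentiation scans and supporting numerics.

Implements Hudson's F_ST estimator (ratio of per-site sums inside each
window), the population branch statistic PBS = (T_AB + T_AC − T_BC)/2
with T = −ln(1 − F_ST), genome-wide standardisation with false-discovery
control, block-jackknife standard errors for windowed averages, LD
pruning on the Rogers–Huff r statistic and Patterson-scaled PCA.

Windows are counted in segregating variants, not base pairs; trailing
partial windows are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from dupsweep.io import GenotypeMatrix, WindowedStat

FST_CLAMP = 1.0 - 1e-12


class ScanError(ValueError):
    pass


@dataclass
class ScanResult:
    windows: list[WindowedStat]
    mean: float | None = None
    sd: float | None = None
    fdr_threshold: float = 0.001
    significant: list[bool] = field(default_factory=list)


# --------------------------------------------------------------------------
# Hudson F_ST and PBS


def _freq_and_n(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts[:, 1] / n
    return p, n


def hudson_fst_components(
    counts_a: np.ndarray, counts_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Hudson numerator and denominator.

    num = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)
    den = p1(1−p2) + p2(1−p1)
    where n are called allele counts per site.
    """
    p1, n1 = _freq_and_n(counts_a)
    p2, n2 = _freq_and_n(counts_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (n1 - 1)
            - p2 * (1 - p2) / (n2 - 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def _window_slices(n_variants: int, size: int, step: int | None = None):
    step = step or size
    if size < 1 or step < 1:
        raise ScanError("window size and step must be >= 1")
    start = 0
    while start + size <= n_variants:
        yield start, start + size
        start += step


def hudson_fst(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    window_size: int,
    positions: np.ndarray | None = None,
    step: int | None = None,
) -> list[WindowedStat]:
    """Windowed Hudson F_ST as a ratio of per-site sums.

    A window where one population has fewer than 2 called alleles at
    every site (numerator undefined) or a zero denominator gets
    ``value=nan`` rather than a fabricated number.
    """
    counts_a = np.asarray(counts_a, float)
    counts_b = np.asarray(counts_b, float)
    if counts_a.shape != counts_b.shape:
        raise ScanError("populations must share the variant set")
    num, den = hudson_fst_components(counts_a, counts_b)
    if positions is None:
        positions = np.arange(1, len(num) + 1)
    out = []
    for w, (lo, hi) in enumerate(_window_slices(len(num), window_size, step)):
        nw, dw = num[lo:hi], den[lo:hi]
        ok = np.isfinite(nw) & np.isfinite(dw)
        value = float(nw[ok].sum() / dw[ok].sum()) if ok.any() and dw[ok].sum() != 0 else np.nan
        out.append(
            WindowedStat(
                window_index=w,
                first_variant=lo,
                last_variant=hi - 1,
                first_pos=int(positions[lo]),
                last_pos=int(positions[hi - 1]),
                value=value,
            )
        )
    return out


def _branch_t(fst: float) -> float:
    """T = −ln(1 − F_ST), with F_ST clamped below 1 and above a small
    negative floor never applied (negative estimates are kept)."""
    f = min(fst, FST_CLAMP)
    return -np.log(1.0 - f)


def pbs(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    counts_c: np.ndarray,
    window_size: int,
    positions: np.ndarray | None = None,
    step: int | None = None,
) -> list[WindowedStat]:
    """Population branch statistic of population A per window."""
    fab = hudson_fst(counts_a, counts_b, window_size, positions, step)
    fac = hudson_fst(counts_a, counts_c, window_size, positions, step)
    fbc = hudson_fst(counts_b, counts_c, window_size, positions, step)
    out = []
    for wab, wac, wbc in zip(fab, fac, fbc):
        if any(np.isnan(w.value) for w in (wab, wac, wbc)):
            value = np.nan
        else:
            if max(wab.value, wac.value, wbc.value) >= FST_CLAMP:
                warnings.warn("window F_ST at or above 1; clamped before log")
            value = (
                _branch_t(wab.value) + _branch_t(wac.value) - _branch_t(wbc.value)
            ) / 2.0
        out.append(
            WindowedStat(
                window_index=wab.window_index,
                first_variant=wab.first_variant,
                last_variant=wab.last_variant,
                first_pos=wab.first_pos,
                last_pos=wab.last_pos,
                value=value,
            )
        )
    return out


# --------------------------------------------------------------------------
# standardisation + FDR


def local_fdr_empirical_null(p: np.ndarray) -> np.ndarray:
    """Two-component local FDR with an empirical standard-normal null.

    fdr(z) ≈ π0·f0(z)/f(z) with f estimated by a Gaussian KDE over the
    observed z values and π0 estimated conservatively from the p-value
    histogram above 0.5.  Exposed as an alternative to Benjamini–Hochberg.
    """
    p = np.asarray(p, float)
    z = scipy.stats.norm.isf(np.clip(p, 1e-300, 1.0) / 2)
    pi0 = min(1.0, 2.0 * np.mean(p > 0.5))
    kde = scipy.stats.gaussian_kde(z)
    f = np.maximum(kde(z), 1e-300)
    f0 = 2 * scipy.stats.norm.pdf(z)  # density of |Z| under the null
    return np.clip(pi0 * f0 / f, 0.0, 1.0)


def standardise_and_fdr(
    windows: list[WindowedStat],
    fdr_threshold: float = 0.001,
    method: str = "bh",
) -> ScanResult:
    """Standardise window values to unit variance, derive two-sided
    normal p-values, and control the FDR.

    Significance is declared for windows with standardised value > 0
    and FDR below the threshold (positive tail only: differentiation in
    the focal population).
    """
    values = np.array([w.value for w in windows], float)
    finite = np.isfinite(values)
    if finite.sum() < 20:
        raise ScanError("need at least 20 finite windows to standardise")
    mean = float(values[finite].mean())
    sd = float(values[finite].std(ddof=0))
    if sd == 0:
        raise ScanError("zero variance across windows; cannot standardise")
    z = (values - mean) / sd
    p = 2 * scipy.stats.norm.sf(np.abs(z))
    if method == "bh":
        fdr = np.full_like(p, np.nan)
        fdr[finite] = multipletests(p[finite], method="fdr_bh")[1]
    elif method == "local":
        fdr = np.full_like(p, np.nan)
        fdr[finite] = local_fdr_empirical_null(p[finite])
    else:
        raise ScanError(f"unknown FDR method {method!r}")
    significant = []
    for i, w in enumerate(windows):
        w.z = float(z[i]) if finite[i] else None
        w.p = float(p[i]) if finite[i] else None
        w.fdr = float(fdr[i]) if finite[i] else None
        significant.append(bool(finite[i] and z[i] > 0 and fdr[i] < fdr_threshold))
    return ScanResult(
        windows=windows, mean=mean, sd=sd,
        fdr_threshold=fdr_threshold, significant=significant,
    )


# --------------------------------------------------------------------------
# block jackknife


def block_jackknife_mean(
    values: np.ndarray, block_length: int
) -> tuple[float, float]:
    """Block-jackknife mean and standard error of a sequence.

    Blocks are consecutive, non-overlapping runs of ``block_length``
    values (a trailing short block is kept).  SE uses the delete-one
    jackknife formula sqrt((B−1)/B · Σ(θ̂₋ᵢ − θ̄)²).
    """
    values = np.asarray(values, float)
    if block_length < 1:
        raise ScanError("block length must be >= 1")
    n_blocks = int(np.ceil(len(values) / block_length))
    if n_blocks < 2:
        raise ScanError("need at least 2 blocks for the jackknife")
    mean = float(values.mean())
    loo = np.empty(n_blocks)
    for b in range(n_blocks):
        mask = np.ones(len(values), bool)
        mask[b * block_length:(b + 1) * block_length] = False
        loo[b] = values[mask].mean()
    se = float(np.sqrt((n_blocks - 1) / n_blocks * ((loo - loo.mean()) ** 2).sum()))
    return mean, se


def block_jackknife_ratio(
    numerators: np.ndarray, denominators: np.ndarray, block_length: int
) -> tuple[float, float]:
    """Jackknife for a ratio-of-sums statistic Σnum/Σden over blocks."""
    num = np.asarray(numerators, float)
    den = np.asarray(denominators, float)
    if num.shape != den.shape:
        raise ScanError("numerator and denominator must align")
    n_blocks = int(np.ceil(len(num) / block_length))
    if n_blocks < 2:
        raise ScanError("need at least 2 blocks for the jackknife")
    total = float(num.sum() / den.sum())
    loo = np.empty(n_blocks)
    for b in range(n_blocks):
        mask = np.ones(len(num), bool)
        mask[b * block_length:(b + 1) * block_length] = False
        loo[b] = num[mask].sum() / den[mask].sum()
    se = float(np.sqrt((n_blocks - 1) / n_blocks * ((loo - loo.mean()) ** 2).sum()))
    return total, se


# --------------------------------------------------------------------------
# LD pruning and PCA


def _pairwise_r(dosages: np.ndarray) -> np.ndarray:
    """Rogers–Huff r between all variant pairs (rows = variants)."""
    d = np.asarray(dosages, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(d)
    return r


def ld_prune(
    gm: GenotypeMatrix,
    window_bp: int = 500,
    step_bp: int = 200,
    r_threshold: float = 0.1,
    iterations: int = 10,
) -> np.ndarray:
    """Indices of variants retained after iterative LD pruning.

    Within each sliding bp window, a variant is dropped when its squared
    Rogers–Huff correlation with an earlier retained variant exceeds the
    squared threshold.  The pass repeats for the configured number of
    iterations (idempotent once converged).
    """
    positions = gm.positions
    dosages = gm.dosages()
    # pairwise-delete missing by mean-filling for the correlation only
    col_mean = np.nanmean(dosages, axis=1, keepdims=True)
    filled = np.where(np.isnan(dosages), col_mean, dosages)
    retained = np.arange(gm.n_variants)
    for _ in range(iterations):
        keep = np.ones(len(retained), bool)
        pos = positions[retained]
        start = pos.min() if len(pos) else 0
        stop = pos.max() if len(pos) else 0
        w = start
        while w <= stop:
            in_win = np.nonzero((pos >= w) & (pos < w + window_bp) & keep)[0]
            if len(in_win) > 1:
                sub = filled[retained[in_win]]
                with np.errstate(invalid="ignore", divide="ignore"):
                    r = np.corrcoef(sub)
                for jj in range(1, len(in_win)):
                    if not keep[in_win[jj]]:
                        continue
                    for ii in range(jj):
                        if not keep[in_win[ii]]:
                            continue
                        rij = r[ii, jj]
                        if np.isfinite(rij) and rij ** 2 > r_threshold ** 2:
                            keep[in_win[jj]] = False
                            break
            w += step_bp
        new_retained = retained[keep]
        if len(new_retained) == len(retained):
            break
        retained = new_retained
    return retained


def pca_patterson(
    gm: GenotypeMatrix, n_components: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of alternate-allele dosages with Patterson normalisation.

    Each variant is centred on its mean dosage and scaled by
    sqrt(p̂(1−p̂)) where p̂ is the alternate-allele frequency estimate;
    monomorphic variants are excluded with a warning.  Returns
    (coordinates, explained_variance_fraction); coordinates are the left
    singular vectors scaled by the singular values (samples × components).
    """
    dosages = gm.dosages()  # variants × samples
    col_mean = np.nanmean(dosages, axis=1, keepdims=True)
    filled = np.where(np.isnan(dosages), col_mean, dosages)
    p_hat = filled.mean(axis=1) / 2.0
    poly = (p_hat > 0) & (p_hat < 1)
    if not poly.all():
        warnings.warn(f"excluding {int((~poly).sum())} monomorphic variants from PCA")
    if poly.sum() < 2 or gm.n_samples < 2:
        raise ScanError("need >= 2 polymorphic variants and >= 2 samples")
    x = filled[poly]
    p = p_hat[poly][:, None]
    scaled = (x - x.mean(axis=1, keepdims=True)) / np.sqrt(p * (1 - p))
    # samples × variants orientation for the SVD
    u, s, _ = np.linalg.svd(scaled.T, full_matrices=False)
    k = min(n_components, len(s))
    coords = u[:, :k] * s[:k]
    explained = (s ** 2) / (s ** 2).sum()
    return coords, explained[:k]
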