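"""Synthetic cohorts with the statistical structure the pipeline assumes.

Four generators, one per downstream stage:

* :func:`simulate_cohort` — copy-number/dosage cohorts: each sample gets
  a true locus copy number C and resistant copies S, binomially sampled
  allele-supporting reads at the focal SNP (~30× by default), and a
  logistic survival phenotype in the number of resistant copies.
* :func:`simulate_sweep` — haplotypes under a hard sweep: swept
  haplotypes copy one core haplotype with identity decaying with
  distance from the focal variant; the background is drawn from site
  frequencies.  A copying model, not a coalescent — the statistics it
  feeds (H12, EHH, diversity) depend only on haplotype-identity
  structure.
* :func:`simulate_three_pop` — Balding–Nichols allele-frequency
  structure for three populations plus an outgroup, with an optional
  introgressed tract where the recipient's frequencies are a mixture of
  its own and the donor's.
* :func:`emit_reads` — error-free reads tiled over per-sample locus
  sequences, so duplication-junction k-mers occur only in carriers.

Every generator takes one seeded ``numpy.random.Generator`` per call;
identical config + seed gives byte-identical output.  Truth tables
record all latent values so parameter-recovery tests never peek at the
generator internals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dupsweep.io import GenotypeMatrix, HaplotypeMatrix, write_fasta


class SimConfigError(ValueError):
    pass


# --------------------------------------------------------------------------
# cohort


@dataclass
class CohortSimConfig:
    """Study conditions for the dosage/phenotype cohort.

    Defaults emulate the sequenced survival-assay cohort: ~30× depth,
    duplications of up to 4–5 copies at appreciable frequency, a
    resistant haplotype common enough that heterogeneous duplications
    dominate, and a logistic survival curve that rises steeply with the
    number of resistant copies.
    """

    n_samples: int = 500
    copy_number_probs: dict[int, float] = field(
        default_factory=lambda: {2: 0.30, 3: 0.30, 4: 0.30, 5: 0.10}
    )
    resistant_frequency: float = 0.45
    depth_mean: float = 30.0
    beta0: float = -2.0
    beta_s: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.copy_number_probs:
            raise SimConfigError("copy-number distribution is empty")
        if max(self.copy_number_probs) < 2:
            raise SimConfigError("C_max must be >= 2")
        if min(self.copy_number_probs) < 1:
            raise SimConfigError("copy numbers must be >= 1")
        total = sum(self.copy_number_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise SimConfigError(f"copy-number probabilities sum to {total}, not 1")
        if self.depth_mean <= 0:
            raise SimConfigError("depth must be positive")
        if not 0 <= self.resistant_frequency <= 1:
            raise SimConfigError("resistant frequency must be in [0, 1]")


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a cohort of (C, S, reads, phenotype) samples.

    Returns (genotypes, copy_numbers, depths, phenotypes, truth):

    * genotypes: one focal biallelic variant; GT is 0/0, 0/1 or 1/1 by
      whether S is 0, intermediate, or C; AD holds the simulated reads.
    * copy_numbers: sample_id, copy_number (the true C — upstream CNV
      calls are an input to the real pipeline, so truth is handed over).
    * depths: sample_id, ref_reads, alt_reads at the focal site.
    * phenotypes: sample_id, phenotype (1 = alive), population.
    * truth: sample_id, C, S, alt_fraction_expected, p_survive.
    """
    rng = np.random.default_rng(config.seed)
    cs = np.array(sorted(config.copy_number_probs))
    probs = np.array([config.copy_number_probs[c] for c in cs], float)
    C = rng.choice(cs, size=config.n_samples, p=probs)
    S = rng.binomial(C, config.resistant_frequency)
    depth = rng.poisson(config.depth_mean, size=config.n_samples)
    alt = rng.binomial(depth, S / C)
    ref = depth - alt
    logit = config.beta0 + config.beta_s * S
    p_survive = 1.0 / (1.0 + np.exp(-logit))
    phen = rng.binomial(1, p_survive)
    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]
    gt = np.zeros((1, config.n_samples, 2), dtype=np.int8)
    gt[0, S == C, :] = 1
    gt[0, (S > 0) & (S < C), 1] = 1
    ad = np.stack([ref, alt], axis=1)[None, :, :]
    gm = GenotypeMatrix(
        chrom="2R",
        positions=np.array([3489405]),
        genotypes=gt,
        sample_ids=sample_ids,
        allele_depths=ad,
    )
    copies = pd.DataFrame({"sample_id": sample_ids, "copy_number": C})
    depths = pd.DataFrame(
        {"sample_id": sample_ids, "ref_reads": ref, "alt_reads": alt}
    )
    phenotypes = pd.DataFrame(
        {"sample_id": sample_ids, "phenotype": phen, "population": "simCI"}
    )
    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "C": C,
            "S": S,
            "alt_fraction_expected": S / C,
            "p_survive": p_survive,
        }
    )
    return gm, copies, depths, phenotypes, truth


# --------------------------------------------------------------------------
# sweep


@dataclass
class SweepSimConfig:
    """A hard sweep as a haplotype-copying process.

    Swept haplotypes are copies of one core haplotype; at each site the
    copy switches to an independent background draw with probability
    1 − exp(−recombination_scale · distance-from-focal), plus an
    independent per-site mutation flip.
    """

    n_haplotypes: int = 200
    n_variants: int = 500
    focal_index: int = 250
    swept_frequency: float = 0.5
    mutation_prob: float = 0.001
    recombination_scale: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.swept_frequency <= 1:
            raise SimConfigError("swept frequency must be in (0, 1]")
        if not 0 <= self.focal_index < self.n_variants:
            raise SimConfigError("focal index out of range")


def simulate_sweep(config: SweepSimConfig) -> HaplotypeMatrix:
    """Generate a haplotype matrix with a hard sweep at the focal variant."""
    rng = np.random.default_rng(config.seed)
    n_var, n_hap = config.n_variants, config.n_haplotypes
    freqs = rng.uniform(0.05, 0.95, size=n_var)
    core = (rng.uniform(size=n_var) < freqs).astype(np.int8)
    core[config.focal_index] = 1
    n_swept = int(round(config.swept_frequency * n_hap))
    haps = np.empty((n_var, n_hap), dtype=np.int8)
    # background haplotypes: independent draws from site frequencies
    bg = (rng.uniform(size=(n_var, n_hap)) < freqs[:, None]).astype(np.int8)
    bg[config.focal_index, :] = 0
    haps[:, n_swept:] = bg[:, n_swept:]
    # swept haplotypes: copy the core, switching to background with
    # probability increasing in distance from the focal site
    dist = np.abs(np.arange(n_var) - config.focal_index)
    p_switch = 1.0 - np.exp(-config.recombination_scale * dist)
    for j in range(n_swept):
        switch = rng.uniform(size=n_var) < p_switch
        hap = np.where(switch, bg[:, j], core)
        if config.mutation_prob > 0:
            flips = rng.uniform(size=n_var) < config.mutation_prob
            hap = np.where(flips, 1 - hap, hap)
        hap[config.focal_index] = 1
        haps[:, j] = hap.astype(np.int8)
    ids = [f"H{j:04d}" for j in range(n_hap)]
    return HaplotypeMatrix(
        chrom="2R",
        positions=np.arange(1, n_var + 1) * 10,
        haplotypes=haps,
        haplotype_ids=ids,
    )


# --------------------------------------------------------------------------
# three populations


@dataclass
class ThreePopSimConfig:
    """Hierarchical Balding–Nichols frequencies for (A, B, C, O).

    Site frequencies for each population are Beta draws around a shared
    ancestral frequency with population-specific drift F; inside the
    introgressed tract the recipient A's frequency is the mixture
    (1 − m)·p_A + m·p_C.
    """

    n_sites: int = 5000
    n_per_pop: int = 40
    drift: dict[str, float] = field(
        default_factory=lambda: {"A": 0.05, "B": 0.05, "C": 0.15, "O": 0.4}
    )
    tract: tuple[int, int] = (2000, 2500)   # 0-based half-open site range
    admixture: float = 0.0
    tract_extra_drift_a: float | None = None  # extra B-N drift on A inside tract
    seed: int = 0

    def __post_init__(self) -> None:
        for pop, f in self.drift.items():
            if not 0 < f < 1:
                raise SimConfigError(f"drift F for {pop} must be in (0, 1)")
        if self.tract_extra_drift_a is not None and not 0 < self.tract_extra_drift_a < 1:
            raise SimConfigError("tract_extra_drift_a must be in (0, 1)")
        lo, hi = self.tract
        if not 0 <= lo <= hi <= self.n_sites:
            raise SimConfigError("tract bounds outside site range")
        if not 0 <= self.admixture <= 1:
            raise SimConfigError("admixture fraction must be in [0, 1]")


def _balding_nichols(rng, ancestral: np.ndarray, F: float) -> np.ndarray:
    a = ancestral * (1 - F) / F
    b = (1 - ancestral) * (1 - F) / F
    return rng.beta(a, b)


def simulate_three_pop(config: ThreePopSimConfig) -> dict[str, np.ndarray]:
    """Per-population (ref, alt) allele-count arrays, shape (n_sites, 2)."""
    rng = np.random.default_rng(config.seed)
    anc = rng.uniform(0.05, 0.95, size=config.n_sites)
    freqs = {
        pop: _balding_nichols(rng, anc, F) for pop, F in config.drift.items()
    }
    lo, hi = config.tract
    if config.admixture > 0:
        m = config.admixture
        freqs["A"] = freqs["A"].copy()
        freqs["A"][lo:hi] = (1 - m) * freqs["A"][lo:hi] + m * freqs["C"][lo:hi]
    if config.tract_extra_drift_a is not None and hi > lo:
        freqs["A"] = freqs["A"].copy()
        freqs["A"][lo:hi] = _balding_nichols(
            rng, np.clip(freqs["A"][lo:hi], 1e-6, 1 - 1e-6),
            config.tract_extra_drift_a,
        )
    counts = {}
    n_alleles = 2 * config.n_per_pop
    for pop, p in freqs.items():
        alt = rng.binomial(n_alleles, p)
        counts[pop] = np.stack([n_alleles - alt, alt], axis=1)
    return counts


# --------------------------------------------------------------------------
# reads


def emit_reads(
    sample_sequences: dict[str, str],
    out_dir: str | Path,
    read_length: int = 100,
    depth: float = 10.0,
    seed: int = 0,
    k_warn: int | None = None,
    circular: bool = False,
) -> dict[str, Path]:
    """Tile error-free reads over each sample's locus sequence.

    Reads start at uniform random offsets; the number of reads per
    sample is ``round(depth · len(seq) / read_length)``.  Returns a map
    of sample id to the FASTA written.  ``depth=0`` produces an empty
    file.  If ``k_warn`` is given and exceeds the read length, a
    warning is raised because downstream k-mer counting would skip every
    read.

    With ``circular=True`` reads may wrap from the end of the sequence
    back to its start.  A linear template has a terminal zone (the last
    ~read_length bp) where coverage decays to zero, so presence/absence
    of terminal k-mers across samples is dominated by sampling noise —
    an artifact of simulating an excised locus rather than a whole
    molecule.  Circular tiling gives uniform coverage; the artificial
    end-to-start junction it introduces is shared by every sample and
    is removed by the downstream variance filter.
    """
    if k_warn is not None and read_length < k_warn:
        warnings.warn(
            f"read length {read_length} < k={k_warn}: all reads will be "
            "skipped by the k-mer counter"
        )
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sid, seq in sample_sequences.items():
        path = out_dir / f"{sid}.fasta"
        n_reads = int(round(depth * len(seq) / read_length))
        if n_reads == 0 or len(seq) < read_length:
            path.write_text("")
        else:
            records = []
            if circular:
                doubled = seq + seq
                starts = rng.integers(0, len(seq), size=n_reads)
                for i, s in enumerate(sorted(starts)):
                    records.append((f"{sid}_read{i}", doubled[s:s + read_length]))
            else:
                starts = rng.integers(0, len(seq) - read_length + 1, size=n_reads)
                for i, s in enumerate(sorted(starts)):
                    records.append((f"{sid}_read{i}", seq[s:s + read_length]))
            write_fasta(records, path)
        paths[sid] = path
    return paths


def junction_cohort_sequences(
    rng_or_seed: int | np.random.Generator,
    n_carriers: int = 10,
    n_noncarriers: int = 10,
    locus_length: int = 2000,
    wt_deletion: int | None = None,
) -> tuple[dict[str, str], str, tuple[int, int]]:
    """Build per-sample locus sequences with/without a duplication junction.

    The reference locus is a random sequence whose central tract is the
    duplicated allele; carriers get a tandem duplication of that tract,
    creating a junction sequence absent from non-carriers.  Non-carriers
    additionally lack a short internal segment of the tract
    (``wt_deletion`` bp, default tract/5) — emulating a resistance
    allele that carries sequence the wild-type haplotype does not, so
    that carrier-specific k-mers include verbatim tract sequence (which
    places exactly on the reference) as well as junction-spanning k-mers
    (which place nowhere, since the junction only exists in the
    duplicated allele).  Returns (sample sequences, reference sequence,
    0-based half-open tract bounds on the reference).
    """
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    bases = np.array(list("ACGT"))
    ref = "".join(rng.choice(bases, size=locus_length))
    lo, hi = locus_length // 4, 3 * locus_length // 4
    dup = ref[:hi] + ref[lo:]  # tandem duplication of the central tract
    if wt_deletion is None:
        wt_deletion = (hi - lo) // 5
    mid = (lo + hi) // 2
    d_lo, d_hi = mid - wt_deletion // 2, mid + wt_deletion // 2
    wt = ref[:d_lo] + ref[d_hi:]
    seqs = {}
    for i in range(n_carriers):
        seqs[f"CAR{i:03d}"] = dup
    for i in range(n_noncarriers):
        seqs[f"NON{i:03d}"] = wt
    return seqs, ref, (lo, hi)
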