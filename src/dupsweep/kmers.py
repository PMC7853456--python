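"""Reference-free k-mer genotype–phenotype association.

The pipeline: count canonical k-mers per sample (2-bit integer
encoding), keep k-mers that vary across the cohort (present in at least
``min_present`` samples and absent in at least ``min_absent``), test
each retained k-mer's normalised frequency against the binary phenotype
with Spearman's rank correlation under FDR control, greedily assemble
significant k-mers by perfect suffix–prefix overlaps of at least 10 bp,
place assembled contigs on a reference by exact matching on both
strands, and flag contigs whose frequencies track locus copy number
through a within-phenotype-group residual correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from dupsweep.io import read_fasta

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class KmerConfigError(ValueError):
    pass


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_kmer(kmer: str) -> int:
    """Pack an A/C/G/T string into a 2-bit integer (A=0..T=3, big-endian)."""
    code = 0
    for base in kmer:
        code = (code << 2) | _BASE_CODE[base]
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_CODE_BASE[code & 3])
        code >>= 2
    return "".join(reversed(out))


def canonical_code(kmer: str) -> int:
    """Integer code of min(kmer, revcomp(kmer)) — strand-independent."""
    rc = revcomp(kmer)
    return encode_kmer(kmer if kmer <= rc else rc)


def _validate_k(k: int) -> None:
    if k % 2 == 0:
        raise KmerConfigError(
            f"k must be odd (even k admits reverse-complement palindromes), got {k}"
        )
    if k > 31:
        raise KmerConfigError(f"k must be <= 31 for 2-bit packing in 64 bits, got {k}")
    if k < 1:
        raise KmerConfigError("k must be positive")


def count_sequence_kmers(seq: str, k: int) -> dict[int, int]:
    """Canonical k-mer counts of one sequence; windows containing N skipped."""
    _validate_k(k)
    seq = seq.upper()
    counts: dict[int, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" in kmer:
            continue
        code = canonical_code(kmer)
        counts[code] = counts.get(code, 0) + 1
    return counts


@dataclass
class KmerTable:
    """Canonical k-mer code × sample count matrix with retention flags."""

    k: int
    codes: np.ndarray                # sorted unique canonical codes
    counts: np.ndarray               # kmers × samples
    sample_ids: list[str]
    retained: np.ndarray | None = None
    short_reads_skipped: int = 0

    @property
    def n_kmers(self) -> int:
        return len(self.codes)

    def sequences(self) -> list[str]:
        return [decode_kmer(int(c), self.k) for c in self.codes]

    def normalised_frequencies(self, denominator: str = "retained") -> np.ndarray:
        """Counts divided by the per-sample total of variant k-mers.

        ``denominator='retained'`` (default) sums counts of retained
        k-mers only; ``'all'`` uses the pre-filter totals — the two
        readings of "total number of variant k-mers in each sample".
        """
        if denominator == "retained":
            if self.retained is None:
                raise KmerConfigError("run filter_variant_kmers before normalising")
            totals = self.counts[self.retained].sum(axis=0).astype(float)
        elif denominator == "all":
            totals = self.counts.sum(axis=0).astype(float)
        else:
            raise KmerConfigError(f"unknown denominator {denominator!r}")
        totals[totals == 0] = np.nan
        return self.counts / totals[None, :]


def count_kmers(
    sample_fastas: dict[str, str | Path] | Sequence[tuple[str, str | Path]],
    k: int = 31,
) -> KmerTable:
    """Count canonical k-mers per sample from FASTA read files.

    Reads shorter than k are skipped (tallied in
    ``short_reads_skipped``); empty files yield all-zero columns.
    """
    _validate_k(k)
    items = list(sample_fastas.items()) if isinstance(sample_fastas, dict) else list(sample_fastas)
    per_sample: list[dict[int, int]] = []
    skipped = 0
    for _, path in items:
        counts: dict[int, int] = {}
        path = Path(path)
        if path.stat().st_size > 0:
            for _, seq in read_fasta(path, strict=False):
                if len(seq) < k:
                    skipped += 1
                    continue
                for code, c in count_sequence_kmers(seq, k).items():
                    counts[code] = counts.get(code, 0) + c
        per_sample.append(counts)
    all_codes = sorted(set().union(*per_sample)) if per_sample else []
    codes = np.array(all_codes, dtype=np.int64)
    index = {c: i for i, c in enumerate(all_codes)}
    mat = np.zeros((len(all_codes), len(items)), dtype=np.int64)
    for j, counts in enumerate(per_sample):
        for code, c in counts.items():
            mat[index[code], j] = c
    return KmerTable(
        k=k, codes=codes, counts=mat,
        sample_ids=[sid for sid, _ in items],
        short_reads_skipped=skipped,
    )


def filter_variant_kmers(
    table: KmerTable, min_present: int = 3, min_absent: int = 3
) -> KmerTable:
    """Flag k-mers that segregate: present (count>0) in >= min_present
    samples and absent in >= min_absent."""
    n = len(table.sample_ids)
    if n < min_present + min_absent:
        raise KmerConfigError(
            f"need at least {min_present + min_absent} samples, have {n}"
        )
    present = (table.counts > 0).sum(axis=1)
    table.retained = (present >= min_present) & ((n - present) >= min_absent)
    return table


# --------------------------------------------------------------------------
# association


def _spearman(freq: np.ndarray, phen: np.ndarray) -> tuple[float, float]:
    """Spearman rho with midranks; exact permutation p for n <= 10."""
    n = len(freq)
    if n <= 10:
        res = scipy.stats.spearmanr(freq, phen)
        rho = float(res.statistic)
        # exact permutation distribution of |rho|
        from itertools import permutations

        ranks_f = scipy.stats.rankdata(freq)
        ranks_p = scipy.stats.rankdata(phen)
        obs = abs(np.corrcoef(ranks_f, ranks_p)[0, 1])
        count = 0
        total = 0
        for perm in permutations(range(n)):
            r = abs(np.corrcoef(ranks_f, ranks_p[list(perm)])[0, 1])
            count += r >= obs - 1e-12
            total += 1
        return rho, count / total
    res = scipy.stats.spearmanr(freq, phen)
    return float(res.statistic), float(res.pvalue)


def associate(
    table: KmerTable,
    phenotypes: np.ndarray,
    fdr_threshold: float = 0.001,
    denominator: str = "retained",
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Spearman association of retained k-mer frequencies with phenotype.

    Returns a DataFrame indexed like the retained k-mers with columns
    code, sequence, rho, p, fdr, significant.  K-mers with constant
    frequency across samples are excluded (column ``excluded_constant``
    on the table row is implied by their absence; a tally is attached
    as ``DataFrame.attrs['n_constant']``).
    """
    if table.retained is None:
        raise KmerConfigError("run filter_variant_kmers first")
    phen = np.asarray(phenotypes, float)
    if len(phen) != len(table.sample_ids):
        raise KmerConfigError("phenotype vector does not match samples")
    freqs = table.normalised_frequencies(denominator=denominator)
    # a sample with zero variant k-mers has frequency 0 for every
    # retained k-mer (0/0 from the table is an empty sample, not missing)
    freqs = np.where(np.isnan(freqs), 0.0, freqs)
    idx = np.nonzero(table.retained)[0]
    rows = []
    n_constant = 0
    for i in idx:
        f = freqs[i]
        if np.nanstd(f) == 0:
            n_constant += 1
            continue
        rho, p = _spearman(f, phen)
        rows.append({"kmer_index": int(i), "code": int(table.codes[i]),
                     "sequence": decode_kmer(int(table.codes[i]), table.k),
                     "rho": rho, "p": p})
    df = pd.DataFrame(rows)
    if not df.empty:
        if fdr_method == "bh":
            df["fdr"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        else:
            raise KmerConfigError(f"unknown fdr method {fdr_method!r}")
        df["significant"] = df["fdr"] < fdr_threshold
    else:
        df = pd.DataFrame(
            columns=["kmer_index", "code", "sequence", "rho", "p", "fdr", "significant"]
        )
    df.attrs["n_constant"] = n_constant
    return df


# --------------------------------------------------------------------------
# assembly


@dataclass
class AssembledKmer:
    contig: str
    members: list[str] = field(default_factory=list)
    mean_frequency: np.ndarray | None = None   # per-sample mean over members
    placements: list[tuple[str, int, str]] = field(default_factory=list)
    residual_r: float | None = None
    residual_p: float | None = None


def _best_overlap(x: str, y: str, min_overlap: int) -> tuple[int, str] | None:
    """Longest perfect suffix(x)/prefix(y') overlap over orientations of y.

    Returns (overlap_length, merged_sequence) or None.  Considers both
    x→y and y→x joins and both orientations of y; a containment
    (one sequence inside the other) counts as a full-length overlap.
    """
    best: tuple[int, str] | None = None
    for y_or in (y, revcomp(y)):
        if y_or in x:
            cand = (len(y_or), x)
            if best is None or cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                best = cand
            continue
        if x in y_or:
            cand = (len(x), y_or)
            if best is None or cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                best = cand
            continue
        max_o = min(len(x), len(y_or)) - 1
        for o in range(max_o, min_overlap - 1, -1):
            if x[-o:] == y_or[:o]:
                cand = (o, x + y_or[o:])
                if best is None or cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                    best = cand
                break
        for o in range(max_o, min_overlap - 1, -1):
            if y_or[-o:] == x[:o]:
                cand = (o, y_or + x[o:])
                if best is None or cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                    best = cand
                break
    return best


def assemble_significant(
    sequences: Sequence[str],
    frequencies: np.ndarray | None = None,
    min_overlap: int = 10,
) -> list[AssembledKmer]:
    """Greedy perfect-overlap assembly of significant k-mers.

    Repeatedly merges the pair with the longest perfect overlap of at
    least ``min_overlap`` bp (ties broken by lexicographic order of the
    merged sequence, then of the inputs), until no pair can merge.
    Contigs keep the orientation of their first member.  ``frequencies``
    is an optional kmers × samples matrix of normalised frequencies;
    each contig's per-sample frequency is the mean over its members.
    """
    items: list[tuple[str, list[int]]] = [
        (seq, [i]) for i, seq in enumerate(sequences)
    ]
    while True:
        best = None  # (overlap, merged, ai, bi)
        for ai in range(len(items)):
            for bi in range(ai + 1, len(items)):
                got = _best_overlap(items[ai][0], items[bi][0], min_overlap)
                if got is None:
                    continue
                o, merged = got
                key = (o, merged)
                if best is None or o > best[0] or (o == best[0] and merged < best[1]):
                    best = (o, merged, ai, bi)
        if best is None:
            break
        _, merged, ai, bi = best
        members = items[ai][1] + items[bi][1]
        items = [it for idx, it in enumerate(items) if idx not in (ai, bi)]
        items.append((merged, members))
        items.sort(key=lambda t: t[0])
    out = []
    for seq, member_idx in items:
        mean_f = None
        if frequencies is not None:
            mean_f = np.asarray(frequencies)[member_idx].mean(axis=0)
        out.append(
            AssembledKmer(
                contig=seq,
                members=[sequences[i] for i in member_idx],
                mean_frequency=mean_f,
            )
        )
    return out


def place_contigs(
    contigs: Iterable[AssembledKmer],
    reference: Sequence[tuple[str, str]],
) -> None:
    """Exact-match placement of contigs on both strands of a reference.

    Updates each contig's ``placements`` in place with every hit as
    (contig_id, 1-based start, strand); unplaced contigs keep an empty
    list.
    """
    for asm in contigs:
        hits: list[tuple[str, int, str]] = []
        for rid, ref in reference:
            for strand, query in (("+", asm.contig), ("-", revcomp(asm.contig))):
                start = ref.find(query)
                while start != -1:
                    hits.append((rid, start + 1, strand))
                    start = ref.find(query, start + 1)
        asm.placements = sorted(hits)


def copy_number_residual_correlation(
    contig_freqs: np.ndarray,
    copy_numbers: np.ndarray,
    phenotypes: np.ndarray,
) -> tuple[float, float]:
    """Pearson correlation of within-phenotype-group residuals.

    Both the contig frequency and the locus copy number are centred on
    their phenotype-group means; the pooled residuals are then
    correlated.  This removes the confounding shared association with
    phenotype: a surviving positive correlation indicates the contig's
    abundance physically tracks locus copy number.
    """
    f = np.asarray(contig_freqs, float)
    c = np.asarray(copy_numbers, float)
    y = np.asarray(phenotypes)
    if not (len(f) == len(c) == len(y)):
        raise KmerConfigError("vectors must align on samples")
    rf = np.empty_like(f)
    rc = np.empty_like(c)
    for g in np.unique(y):
        mask = y == g
        if mask.sum() < 3:
            raise KmerConfigError("each phenotype group needs >= 3 samples")
        rf[mask] = f[mask] - f[mask].mean()
        rc[mask] = c[mask] - c[mask].mean()
    if rf.std() == 0 or rc.std() == 0:
        return np.nan, np.nan
    r, p = scipy.stats.pearsonr(rf, rc)
    return float(r), float(p)
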