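"""Readers, writers and in-memory containers shared by all pipeline stages.

Conventions
-----------
* Coordinates are 1-based inclusive on disk (VCF convention); window
  arithmetic inside the package uses 0-based variant indices with
  half-open ranges.
* Genotype codes are 0 (reference), 1 (alternate) and -1 (missing).
* Missing genotypes are excluded from allele counts: frequency
  denominators shrink rather than being imputed.
* Variants without an AD field carry ``allele_depths=None`` — callers get
  an explicit "no depth" signal, never fabricated zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class VcfValidationError(ValueError):
    """Raised for VCF records that violate the biallelic/strict contract."""


class PhenotypeError(ValueError):
    """Raised for malformed phenotype tables."""


class FastaError(ValueError):
    """Raised for malformed FASTA input."""


# --------------------------------------------------------------------------
# containers


@dataclass
class GenotypeMatrix:
    """Biallelic variant × sample genotype calls with optional read depths.

    Attributes
    ----------
    chrom : str
        Contig label shared by all variants.
    positions : ndarray of int
        1-based coordinates, strictly increasing.
    genotypes : ndarray, shape (n_variants, n_samples, 2)
        Allele codes in {-1, 0, 1}.
    allele_depths : ndarray or None, shape (n_variants, n_samples, 2)
        Per-sample (ref, alt) read counts, or None when the source had
        no AD field.
    sample_ids : list of str
    """

    chrom: str
    positions: np.ndarray
    genotypes: np.ndarray
    sample_ids: list[str]
    allele_depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 3 or self.genotypes.shape[2] != 2:
            raise VcfValidationError(
                f"genotypes must be (variants, samples, 2), got {self.genotypes.shape}"
            )
        if len(self.positions) != self.genotypes.shape[0]:
            raise VcfValidationError("positions and genotypes disagree on variant count")
        if np.any(np.diff(self.positions) <= 0):
            raise VcfValidationError("positions must be strictly increasing")
        bad = ~np.isin(self.genotypes, (-1, 0, 1))
        if bad.any():
            raise VcfValidationError("genotype codes must be in {-1, 0, 1}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise VcfValidationError("sample ids must be unique")
        if self.genotypes.shape[1] != len(self.sample_ids):
            raise VcfValidationError("genotypes and sample_ids disagree on sample count")
        if self.allele_depths is not None:
            self.allele_depths = np.asarray(self.allele_depths, dtype=np.int64)
            if self.allele_depths.shape != self.genotypes.shape:
                raise VcfValidationError("allele_depths shape must match genotypes")
            if (self.allele_depths < 0).any():
                raise VcfValidationError("allele_depths must be non-negative")

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    def allele_counts(self) -> np.ndarray:
        """Per-variant (ref, alt) allele counts over non-missing calls."""
        g = self.genotypes
        called = g >= 0
        alt = np.where(called, g, 0).sum(axis=(1, 2))
        total = called.sum(axis=(1, 2))
        return np.stack([total - alt, alt], axis=1)

    def dosages(self) -> np.ndarray:
        """Variant × sample alternate-allele dosage; NaN where any call missing."""
        g = self.genotypes.astype(float)
        d = g.sum(axis=2)
        d[np.any(self.genotypes < 0, axis=2)] = np.nan
        return d

    def to_haplotypes(self) -> "HaplotypeMatrix":
        """Split fully-called diploid genotypes into 2n haplotypes.

        Requires no missing calls (phased input is assumed upstream).
        """
        if (self.genotypes < 0).any():
            raise VcfValidationError("cannot haplotypise genotypes with missing calls")
        n_var, n_samp, _ = self.genotypes.shape
        haps = self.genotypes.reshape(n_var, n_samp * 2)
        ids = [f"{s}_{i}" for s in self.sample_ids for i in (0, 1)]
        return HaplotypeMatrix(
            chrom=self.chrom, positions=self.positions.copy(),
            haplotypes=haps.astype(np.int8), haplotype_ids=ids,
        )


@dataclass
class HaplotypeMatrix:
    """Phased binary variant × haplotype matrix."""

    chrom: str
    positions: np.ndarray
    haplotypes: np.ndarray  # (n_variants, n_haplotypes), values in {0,1}
    haplotype_ids: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise VcfValidationError("haplotype entries must be 0/1")
        if self.haplotypes.shape[0] != len(self.positions):
            raise VcfValidationError("positions and haplotypes disagree on variant count")
        if self.haplotypes.shape[1] != len(self.haplotype_ids):
            raise VcfValidationError("haplotype ids disagree with matrix width")

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class WindowedStat:
    """One window of a scan statistic, in variant-index coordinates."""

    window_index: int
    first_variant: int      # 0-based, inclusive
    last_variant: int       # 0-based, inclusive
    first_pos: int          # 1-based bp
    last_pos: int
    value: float
    se: float | None = None
    z: float | None = None
    p: float | None = None
    fdr: float | None = None


def windowed_stats_frame(windows: Sequence[WindowedStat]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "window_index": [w.window_index for w in windows],
            "first_variant": [w.first_variant for w in windows],
            "last_variant": [w.last_variant for w in windows],
            "first_pos": [w.first_pos for w in windows],
            "last_pos": [w.last_pos for w in windows],
            "value": [w.value for w in windows],
            "se": [w.se for w in windows],
            "z": [w.z for w in windows],
            "p": [w.p for w in windows],
            "fdr": [w.fdr for w in windows],
        }
    )


# --------------------------------------------------------------------------
# VCF

_GT_CODE = {None: -1, 0: 0, 1: 1}


def read_vcf(path: str | Path, strict: bool = True) -> GenotypeMatrix:
    """Read a single-contig biallelic VCF into a :class:`GenotypeMatrix`.

    Multiallelic records raise :class:`VcfValidationError` under strict
    mode (the default); with ``strict=False`` they are skipped.  If no
    record in the file carries AD, ``allele_depths`` is None so that
    downstream dosage estimation receives an explicit "no depth" signal
    instead of fabricated zero counts.
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VcfValidationError(f"cannot parse VCF {path!r}: {exc}") from exc
    samples = list(vf.header.samples)
    positions: list[int] = []
    chroms: set[str] = set()
    gts: list[list[tuple[int, int]]] = []
    ads: list[list[tuple[int, int]]] = []
    any_ad = False
    has_ad_field = "AD" in vf.header.formats
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            if strict:
                raise VcfValidationError(
                    f"non-biallelic record at {rec.chrom}:{rec.pos} "
                    f"(alts={rec.alts})"
                )
            continue
        chroms.add(rec.chrom)
        positions.append(rec.pos)
        row_gt = []
        row_ad = []
        for s in samples:
            call = rec.samples[s]
            alleles = call.get("GT", (None, None))
            if alleles is None:
                alleles = (None, None)
            a = tuple(_GT_CODE.get(x, -1) for x in alleles)
            if len(a) == 1:
                a = (a[0], a[0])
            row_gt.append(a)
            ad = call.get("AD") if has_ad_field else None
            if ad is not None and ad[0] is not None:
                any_ad = True
                row_ad.append((int(ad[0]), int(ad[1])))
            else:
                row_ad.append((0, 0))
        gts.append(row_gt)
        ads.append(row_ad)
    vf.close()
    if len(chroms) > 1:
        raise VcfValidationError(f"expected a single contig, found {sorted(chroms)}")
    chrom = chroms.pop() if chroms else "NA"
    genotypes = np.array(gts, dtype=np.int8).reshape(len(positions), len(samples), 2)
    depths = (
        np.array(ads, dtype=np.int64).reshape(len(positions), len(samples), 2)
        if any_ad
        else None
    )
    return GenotypeMatrix(
        chrom=chrom,
        positions=np.array(positions, dtype=np.int64),
        genotypes=genotypes,
        sample_ids=samples,
        allele_depths=depths,
    )


def write_vcf(
    gm: GenotypeMatrix,
    path: str | Path,
    ref_alleles: Sequence[str] | None = None,
    alt_alleles: Sequence[str] | None = None,
    phased: bool = False,
) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF 4.2 file."""
    refs = ref_alleles if ref_alleles is not None else ["A"] * gm.n_variants
    alts = alt_alleles if alt_alleles is not None else ["T"] * gm.n_variants
    sep = "|" if phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={gm.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gm.allele_depths is not None:
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,'
                'Description="Allelic depths">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        fmt = "GT:AD" if gm.allele_depths is not None else "GT"
        for i in range(gm.n_variants):
            fields = [
                gm.chrom, str(int(gm.positions[i])), ".", refs[i], alts[i],
                ".", "PASS", ".", fmt,
            ]
            for j in range(gm.n_samples):
                a, b = gm.genotypes[i, j]
                gt = sep.join("." if x < 0 else str(int(x)) for x in (a, b))
                if gm.allele_depths is not None:
                    r, t = gm.allele_depths[i, j]
                    fields.append(f"{gt}:{int(r)},{int(t)}")
                else:
                    fields.append(gt)
            fh.write("\t".join(fields) + "\n")


# --------------------------------------------------------------------------
# phenotypes

_PHENOTYPE_VOCAB = {"0": 0, "1": 1, "dead": 0, "alive": 1}


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a sample_id/phenotype/population TSV.

    Accepts 0/1 or the alive/dead synonyms (alive → 1 = resistant).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "phenotype", "population"}
    if not required.issubset(df.columns):
        raise PhenotypeError(
            f"phenotype table must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise PhenotypeError(f"duplicate sample ids: {dupes}")
    phen = []
    for raw in df["phenotype"]:
        key = str(raw).strip().lower()
        if key not in _PHENOTYPE_VOCAB:
            raise PhenotypeError(
                f"phenotype {raw!r} not in vocabulary {{0,1,alive,dead}}"
            )
        phen.append(_PHENOTYPE_VOCAB[key])
    out = pd.DataFrame(
        {
            "sample_id": df["sample_id"].astype(str),
            "phenotype": np.array(phen, dtype=int),
            "population": df["population"].astype(str),
        }
    )
    return out


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_copy_numbers(path: str | Path) -> pd.DataFrame:
    """Read a per-sample locus copy-number TSV (sample_id, copy_number)."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns or "copy_number" not in df.columns:
        raise PhenotypeError("copy-number table needs sample_id and copy_number columns")
    if df["sample_id"].duplicated().any():
        raise PhenotypeError("duplicate sample ids in copy-number table")
    df["sample_id"] = df["sample_id"].astype(str)
    df["copy_number"] = df["copy_number"].astype(int)
    return df


# --------------------------------------------------------------------------
# FASTA

_FASTA_ALPHABET = set("ACGTN")


def read_fasta(path: str | Path, strict: bool = True) -> list[tuple[str, str]]:
    """Read FASTA records as ordered (id, uppercased sequence) tuples."""
    records = [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FastaError(f"no FASTA records in {path!r}")
    if strict:
        for rid, seq in records:
            illegal = set(seq) - _FASTA_ALPHABET
            if illegal:
                raise FastaError(
                    f"record {rid!r} contains illegal characters {sorted(illegal)}"
                )
    return records


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
        str(path),
        "fasta",
    )
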