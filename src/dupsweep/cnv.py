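"""Copy-number-aware resistant-allele dosage estimation.

A sample with ``C`` copies of the locus carries an unknown number
``S`` (0 ≤ S ≤ C) of resistant-allele copies.  With unbiased short-read
coverage the expected fraction of reads supporting the resistant allele
at the focal SNP is S/C, so S is recovered as the integer dosage whose
expected read fraction is closest to the observed one.  Samples are then
classified into duplication configurations (wild-type single copy,
heterogeneous duplication carrying both alleles, homogeneous resistant
or homogeneous wild-type duplication) and into a predicted resistance
class: resistant when resistant copies are at least as numerous as
wild-type copies (and at least one is present), susceptible otherwise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd


class NoDepthError(ValueError):
    """Raised when a read fraction is requested for a sample with no reads."""


class DuplicationConfiguration(str, enum.Enum):
    WT_SINGLE = "WT_SINGLE"
    HET_DUP = "HET_DUP"
    HOM_DUP_ALT = "HOM_DUP_ALT"
    HOM_DUP_WT = "HOM_DUP_WT"


@dataclass
class CopyNumberRecord:
    sample_id: str
    C: int
    S: int
    alt_fraction: float
    ref_reads: int | None = None
    alt_reads: int | None = None

    def __post_init__(self) -> None:
        if self.C < 1:
            raise ValueError(f"locus copy number must be >= 1, got C={self.C}")
        if not 0 <= self.S <= self.C:
            raise ValueError(f"need 0 <= S <= C, got S={self.S}, C={self.C}")

    @property
    def configuration(self) -> DuplicationConfiguration:
        return classify_configuration(self.C, self.S)

    @property
    def predicted_class(self) -> str:
        return predict_resistance(self.C, self.S)


def alt_fraction(ref_reads: int, alt_reads: int) -> float:
    """Fraction of reads supporting the alternate (resistant) allele."""
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = ref_reads + alt_reads
    if total == 0:
        raise NoDepthError("no reads at focal site; alt fraction undefined")
    return alt_reads / total


def estimate_resistant_copies(C: int, frac: float) -> int:
    """Integer dosage S minimising |frac − S/C| over S ∈ {0..C}.

    Ties are broken toward the smaller S (conservative toward wild type).
    ``frac`` may come from sequencing read depths or from an allele-specific
    qPCR signal ratio — the estimator is agnostic to its source.
    """
    if C < 1:
        raise ValueError(f"locus copy number must be >= 1, got C={C}")
    if not 0.0 <= frac <= 1.0:
        raise ValueError(f"alt fraction must be in [0, 1], got {frac}")
    candidates = np.arange(C + 1)
    distances = np.abs(frac - candidates / C)
    # argmin returns the first (smallest-S) minimiser, which is the tie rule
    return int(candidates[np.argmin(distances)])


def classify_configuration(C: int, S: int) -> DuplicationConfiguration:
    """Assign the duplication configuration implied by (C, S)."""
    if not 0 <= S <= C:
        raise ValueError(f"need 0 <= S <= C, got S={S}, C={C}")
    if S == 0:
        # non-duplicated wild type, or a duplication carrying only wt copies
        return (
            DuplicationConfiguration.WT_SINGLE
            if C <= 2
            else DuplicationConfiguration.HOM_DUP_WT
        )
    if S == C:
        return DuplicationConfiguration.HOM_DUP_ALT
    return DuplicationConfiguration.HET_DUP


def predict_resistance(C: int, S: int) -> str:
    """Classify by allele balance: resistant iff S ≥ C − S and S > 0."""
    if not 0 <= S <= C:
        raise ValueError(f"need 0 <= S <= C, got S={S}, C={C}")
    if S > 0 and S >= C - S:
        return "resistant"
    return "susceptible"


def genotype_cohort(
    copy_numbers: pd.DataFrame,
    depths: pd.DataFrame,
) -> pd.DataFrame:
    """Estimate S for every sample with both a copy number and focal depths.

    Parameters
    ----------
    copy_numbers : DataFrame with sample_id, copy_number
    depths : DataFrame with sample_id, ref_reads, alt_reads

    Returns
    -------
    DataFrame with sample_id, C, ref_reads, alt_reads, alt_fraction, S,
    configuration, predicted_class.  Samples with zero total depth are
    dropped with a warning column rather than silently assigned S=0.
    """
    merged = copy_numbers.merge(depths, on="sample_id", how="inner")
    rows = []
    for rec in merged.itertuples(index=False):
        total = rec.ref_reads + rec.alt_reads
        if total == 0:
            continue
        frac = rec.alt_reads / total
        S = estimate_resistant_copies(int(rec.copy_number), frac)
        rows.append(
            {
                "sample_id": rec.sample_id,
                "C": int(rec.copy_number),
                "ref_reads": int(rec.ref_reads),
                "alt_reads": int(rec.alt_reads),
                "alt_fraction": frac,
                "S": S,
                "configuration": classify_configuration(int(rec.copy_number), S).value,
                "predicted_class": predict_resistance(int(rec.copy_number), S),
            }
        )
    return pd.DataFrame(rows)
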