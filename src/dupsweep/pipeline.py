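"""Workflow orchestration: the two headline analyses chained end to end.

``run_association_workflow`` chains dosage genotyping into the
association battery (per-genotype survival tables, Fisher/Woolf, GLMs,
BIC stepwise reduction, and the allele-balance resistance classifier's
confusion matrix).  ``run_locus_characterisation`` chains the
haplotype-level analyses (tagging variants → networks → sweep profiles →
EHH) with the introgression tests.  Both emit plain dict reports that
serialise to JSON, embed the resolved configuration and seed, and are
deterministic for identical inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from dupsweep import association, cnv, haplotypes, introgression
from dupsweep.io import HaplotypeMatrix
from dupsweep import __version__

logger = logging.getLogger("dupsweep")


@dataclass
class PipelineConfig:
    focal_site: int = 3489405
    duplication_start: int = 3436800   # 1-based inclusive
    duplication_end: int = 3639600
    sweep_window: int = 500
    sweep_overlap: float = 0.2
    d_window: int = 5000
    d_step_fraction: float = 0.2
    d_block: int = 100
    fdr_threshold: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duplication_start >= self.duplication_end:
            raise ValueError("duplication start must precede end")


def _provenance(config: PipelineConfig) -> dict:
    return {"version": __version__, "config": asdict(config)}


def run_association_workflow(
    config: PipelineConfig,
    copy_numbers: pd.DataFrame,
    depths: pd.DataFrame,
    phenotypes: pd.DataFrame,
) -> dict:
    """Dosage genotyping plus the genotype–phenotype association battery."""
    calls = cnv.genotype_cohort(copy_numbers, depths)
    merged = calls.merge(phenotypes, on="sample_id", how="left")
    missing = merged[merged["phenotype"].isna()]["sample_id"].tolist()
    if missing:
        logger.warning("excluding %d samples without phenotype", len(missing))
    merged = merged.dropna(subset=["phenotype"]).copy()
    merged["phenotype"] = merged["phenotype"].astype(int)

    survival = (
        merged.groupby("S")["phenotype"]
        .agg(n="count", alive="sum")
        .reset_index()
    )
    survival["survival_rate"] = survival["alive"] / survival["n"]

    # carrier (S > 0) vs wild-type 2x2 test
    carrier = merged["S"] > 0
    alive = merged["phenotype"] == 1
    table = association.ContingencyTable2x2(
        a=int((carrier & alive).sum()), b=int((carrier & ~alive).sum()),
        c=int((~carrier & alive).sum()), d=int((~carrier & ~alive).sum()),
    )
    fisher_p = association.fisher_exact(table)
    orr, lo, hi = association.woolf_or(table, correction=True)

    # GLMs on S and C, plus BIC-reduced joint model
    y = merged["phenotype"].to_numpy()
    design = pd.DataFrame({"S": merged["S"].astype(float),
                           "C": merged["C"].astype(float)})
    fit_s = association.fit_binomial_glm(y, design[["S"]])
    fit_c = association.fit_binomial_glm(y, design[["C"]])
    minimal = association.stepwise_bic(y, design)

    # allele-balance classifier vs observed phenotype
    pred = merged["predicted_class"] == "resistant"
    confusion = {
        "tp": int((pred & alive).sum()), "fp": int((pred & ~alive).sum()),
        "fn": int((~pred & alive).sum()), "tn": int((~pred & ~alive).sum()),
    }
    return {
        "provenance": _provenance(config),
        "n_samples": int(len(merged)),
        "excluded_no_phenotype": missing,
        "s_calls": calls.to_dict(orient="list"),
        "survival_by_s": survival.to_dict(orient="list"),
        "carrier_test": {
            "table": [[table.a, table.b], [table.c, table.d]],
            "fisher_p": fisher_p,
            "woolf_or": orr, "ci": [lo, hi],
        },
        "glm_s": {
            "or": fit_s.odds_ratios.loc["S", "OR"],
            "p_vs_null": association.lr_test_vs_null(fit_s),
            "separation": fit_s.separation,
        },
        "glm_c": {
            "or": fit_c.odds_ratios.loc["C", "OR"],
            "p_vs_null": association.lr_test_vs_null(fit_c),
            "separation": fit_c.separation,
        },
        "minimal_model_terms": minimal.terms,
        "minimal_model_bic": minimal.bic,
        "confusion": confusion,
    }


def run_locus_characterisation(
    config: PipelineConfig,
    haps: HaplotypeMatrix,
    carrier_mask: np.ndarray,
    counts_a_dup: np.ndarray,
    counts_a_nondup: np.ndarray,
    counts_b: np.ndarray,
    counts_c: np.ndarray,
    counts_o: np.ndarray,
) -> dict:
    """Haplotype sweep profile plus the paired introgression test.

    ``carrier_mask`` marks haplotypes carrying the focal resistance
    allele.  The D test is run twice — with the duplicated and the
    non-duplicated subgroup as population A — mirroring the design that
    localises introgression to the duplication carriers.
    """
    carrier_mask = np.asarray(carrier_mask, bool)
    h12_carrier = haplotypes.moving_statistic(
        haps_subset(haps, carrier_mask),
        lambda h: haplotypes.garud_h(h)[1],
        window_size=config.sweep_window,
        overlap_fraction=config.sweep_overlap,
    )
    h12_background = haplotypes.moving_statistic(
        haps_subset(haps, ~carrier_mask),
        lambda h: haplotypes.garud_h(h)[1],
        window_size=config.sweep_window,
        overlap_fraction=config.sweep_overlap,
    )
    d_dup = introgression.region_d_with_jackknife(
        counts_a_dup, counts_b, counts_c, counts_o, block_length=config.d_block,
        labels=("A_dup", "B", "C", "O"),
    )
    d_nondup = introgression.region_d_with_jackknife(
        counts_a_nondup, counts_b, counts_c, counts_o, block_length=config.d_block,
        labels=("A_nondup", "B", "C", "O"),
    )

    # network over the focal window, tagged by the central variant
    focal = haps.n_variants // 2
    half = min(30, focal)
    net = haplotypes.build_haplotype_network(
        haplotypes._hm_window(haps, focal - half, focal + half + 1),
        tag_alleles=haps.haplotypes[focal],
    )
    largest = max(net.nodes, key=lambda n: n.size)

    # EHH decay from the focal variant per carrier group (area under curve)
    ehh_auc = {}
    for label, mask in (("carrier", carrier_mask), ("background", ~carrier_mask)):
        sub = haps.haplotypes[:, mask]
        auc = float(
            np.sum(haplotypes.ehh_decay(sub, focal, "right"))
            + np.sum(haplotypes.ehh_decay(sub, focal, "left"))
        )
        ehh_auc[label] = auc

    # flank H12 with haplotype-jackknife SE per group
    flank = {}
    for label, mask in (("carrier", carrier_mask), ("background", ~carrier_mask)):
        mean, se = haplotypes.flank_average_with_jackknife(
            haps.haplotypes[focal - half:focal + half + 1][:, mask],
            lambda h: haplotypes.garud_h(h)[1],
        )
        flank[label] = {"h12": mean, "se": se}

    bl = introgression.three_pop_branch_lengths(
        counts_a_dup, counts_a_nondup, counts_c,
        window_size=max(2, config.d_block),
        groups=("dup", "nondup", "other_species"),
    )
    return {
        "provenance": _provenance(config),
        "h12_carrier_mean": float(h12_carrier["value"].mean()),
        "h12_background_mean": float(h12_background["value"].mean()),
        "network": {
            "n_nodes": len(net.nodes),
            "n_edges": len(net.edges),
            "largest_cluster_size": largest.size,
            "largest_cluster_tag_allele": largest.tag_allele,
        },
        "ehh_auc": ehh_auc,
        "flank_h12": flank,
        "branch_lengths": {
            g: {"L": bl.lengths[g], "se": bl.ses[g]} for g in bl.groups
        },
        "d_duplicated": {"d": d_dup.d, "se": d_dup.se, "z": d_dup.z, "p": d_dup.p},
        "d_nonduplicated": {
            "d": d_nondup.d, "se": d_nondup.se, "z": d_nondup.z, "p": d_nondup.p,
        },
    }


def haps_subset(hm: HaplotypeMatrix, mask: np.ndarray) -> HaplotypeMatrix:
    """View of a haplotype matrix restricted to a haplotype mask."""
    mask = np.asarray(mask, bool)
    return HaplotypeMatrix(
        chrom=hm.chrom,
        positions=hm.positions,
        haplotypes=hm.haplotypes[:, mask],
        haplotype_ids=[h for h, m in zip(hm.haplotype_ids, mask) if m],
    )


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def write_report(report: dict, path: str | Path) -> None:
    """Serialise a report to JSON (floats rounded to 6 decimals for
    readable, diff-stable output)."""
    Path(path).write_text(
        json.dumps(_round_floats(report), indent=2, sort_keys=True, default=float)
    )
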