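#!/usr/bin/env python
"""Generate the synthetic survival-assay cohort used by the downstream
association analyses.

Emulates the study conditions of the sequenced cohort: ~30x depth at the
focal resistance SNP, locus copy numbers between 2 and 5, a resistant
haplotype at intermediate frequency, and survival following a logistic
curve in the number of resistant copies.  Writes VCF/TSV inputs plus the
latent truth table under results/cohort/.
"""

from pathlib import Path

from dupsweep import io as dio
from dupsweep import simulate

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 7


def main() -> None:
    cfg = simulate.CohortSimConfig(n_samples=500, depth_mean=30, seed=SEED)
    gm, copies, depths, phen, truth = simulate.simulate_cohort(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    dio.write_vcf(gm, OUT / "cohort.vcf")
    copies.to_csv(OUT / "copy_numbers.tsv", sep="\t", index=False)
    depths.to_csv(OUT / "depths.tsv", sep="\t", index=False)
    dio.write_phenotypes(phen, OUT / "phenotypes.tsv")
    truth.to_csv(OUT / "truth.tsv", sep="\t", index=False, float_format="%.5g")
    print(
        f"cohort: {cfg.n_samples} samples, "
        f"{(truth['C'] > 2).mean():.0%} duplicated (C>2), "
        f"{phen['phenotype'].mean():.0%} alive; written to {OUT}"
    )


if __name__ == "__main__":
    main()
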