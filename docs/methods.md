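# Methods

This note records the models the package implements, the assumptions
they rest on, the defaults and why, and what the synthetic cohorts do
and do not establish about real data.

## Dosage model

A sample has `C ≥ 1` copies of the locus, `S` of them resistant
(0 ≤ S ≤ C). Reads at the focal SNP are assumed unbiased between
alleles, so the alternate-read count is Binomial(depth, S/C) and `S`
is estimated as the integer minimising |f_alt − S/C|. Ties are broken
toward the smaller `S`, i.e. conservatively toward wild type; no tie
rule is forced by the model and the choice only matters on the exact
midpoints of the S/C grid. `C = 0` (homozygous deletion) is outside
the model and rejected. The estimator is agnostic to where `f_alt`
comes from — sequencing depths or an allele-specific qPCR signal ratio
work identically.

At 30× depth the estimator is reliable for moderate copy numbers:
grid spacing is 1/C, so misassignment requires a binomial deviation of
about 1/(2C), and recovery of the true `S` exceeds 90% for C ≤ 4
(checked against simulated truth). Accuracy degrades as C grows;
above C ≈ 6 at 30× the grid is finer than the sampling noise.

The resistance classifier (resistant iff `S ≥ C − S` and `S > 0`)
encodes the allele-balance rule that a duplication with at least as
many resistant as wild-type copies behaves as resistant. The
configuration enum treats `C ≤ 2` non-duplicated carriers as HET/HOM
by allele content; only `S = 0, C ≤ 2` is WT_SINGLE.

## Association

* Fisher's exact p is two-sided by the "probability ≤ observed" rule
  (scipy's convention, matching R's `fisher.test`).
* The Woolf odds ratio applies the Haldane–Anscombe correction by
  adding 0.5 to all four cells whenever requested, not only when a
  zero is present. This is what classical epidemiological software
  does and is required to reproduce published corrected values
  exactly.
* GLMs are binomial with a logit link, fitted by IRLS (deviance
  tolerance 1e-10, max 100 iterations) via statsmodels. Complete
  separation is flagged at |β| > 15 on the logit scale; the fit is
  returned with its astronomically large odds ratio rather than
  clipped, so downstream tables can show the flag.
* BIC stepwise reduction is backward-only: at each step drop the
  column whose removal most lowers `−2ℓ + k·ln n`; ties resolve to
  the earlier column, making the procedure deterministic. Perfectly
  collinear duplicates resolve naturally (dropping one never costs
  likelihood).

## Windowed scans

Windows are counted in segregating variants, never base pairs, and
trailing partial windows are dropped. Hudson's F_ST uses the
finite-sample per-site estimator

    num = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)
    den = p1(1−p2) + p2(1−p1)

summed over the window (ratio of sums). A consequence worth knowing:
F_ST of a population against itself is −1/(n−1), slightly negative,
so PBS of two identical populations is a small negative number rather
than exactly zero. F_ST is clamped below 1 − 1e-12 before
`T = −ln(1 − F_ST)`.

Standardisation divides by the genome-wide standard deviation of the
window values; two-sided normal p-values then pass through
Benjamini–Hochberg by default (FDR threshold 0.001), with a
two-component empirical-null local-FDR estimator exposed as an
alternative because published scans of this kind often use local FDR
tools whose tuning is rarely stated. Significance additionally
requires a positive standardised value (differentiation in the focal
population, not the outgroup).

LD pruning drops a variant when its squared Rogers–Huff correlation
with an earlier retained variant inside a 500 bp window (200 bp step)
exceeds 0.1², repeated for 10 iterations. PCA centres dosages per
variant and scales by √(p̂(1−p̂)) before the SVD.

## Haplotype analyses

Tagging variants stand in for the unphaseable duplication: a variant
qualifies when |r| > 0.95 against the focal site, it lies in a window
whose mean haplotype score and normalised coverage are both within
0.25 of 2 (effectively diploid, hence phaseable), and it is present
in the phased set. The number of tagging variants is data-dependent
and never hard-coded.

Networks collapse identical haplotypes into nodes and connect nodes
with a Kruskal MST over Hamming distances; equal-weight edges are
ordered by (weight, node index, node index) so the tree is
deterministic; MST edges longer than one substitution are then
removed, fragmenting the network into tight clusters.

Garud's statistics use cluster frequencies of identical haplotypes:
H1 = Σp², H12 = (p1+p2)² + Σ_{i≥3}p², H2 = H1 − p1². Haplotype
diversity carries the n/(n−1) unbiased correction. The "20% overlap"
of published windowed profiles is ambiguous; the default reading is
step = window × 0.8 (adjacent windows share 20% of their variants)
with the alternative (step = 20% of window) selectable. EHH from a
core variant is Σ C(n_c,2)/C(n,2) over clusters identical from the
core out to the query variant, and is non-increasing by construction.
Flank averages carry leave-one-haplotype-out jackknife errors.

## Introgression

D is computed from population allele frequencies, not single genomes;
sites where the outgroup is polymorphic keep their observed outgroup
frequency rather than being forced ancestral. The region statistic is
a ratio of sums over all sites (not a mean of window values), which
matches the jackknife construction and avoids small-window
instability; the block jackknife (default 100 variants per block)
yields SE, Z = D/SE and a two-sided normal p.

Note the sign convention: with `ABBA = (1−p_A)p_B p_C (1−p_O)`,
introgression between A and C inflates BABA and drives D negative.
Tests and drivers therefore interpret tract signal through |D| and
its significance, plus the A/B-swap antisymmetry.

The jackknife Z is only approximately normal; with fewer than ~20
blocks it is noticeably t-like and a 3σ rule over-rejects. Calibration
checks therefore use regions with at least 20 blocks.

Branch lengths reuse the PBS construction per window of 100 variants;
`L_X + L_Y = T_XY` holds exactly per window, and region averages carry
a jackknife over windows.

## k-mer association

Canonical form is the lexicographic minimum of a k-mer and its
reverse complement; k must be odd (even k admits reverse-complement
palindromes, which would make canonical counts ambiguous) and ≤ 31
for 2-bit packing in a 64-bit word. Presence means count > 0.
Retention requires presence in ≥ 3 and absence in ≥ 3 samples.

Normalised frequency divides each count by the per-sample total of
*retained* k-mer counts by default; the pre-filter denominator is
selectable since either reading of "total variant k-mers" is
defensible. A sample with zero variant k-mers is treated as frequency
0 for every retained k-mer. Spearman uses midranks, with an exact
permutation p for n ≤ 10 and the t-approximation otherwise.

Assembly greedily merges the pair with the longest perfect overlap
≥ 10 bp, orientation-aware, ties broken lexicographically, to a fixed
point; a contained sequence merges at full length. Placement is exact
substring search on both strands — a deliberate narrowing of scope:
junction-spanning contigs exist only in the rearranged allele and are
reported unplaced, which is the exact-match analogue of unaligned
k-mers in a read-mapping pipeline. The copy-number diagnostic
residualises contig frequency and locus copy number about their
phenotype-group means before correlating, removing the confounding
shared association with phenotype.

## Synthetic cohorts

The generators produce the statistical structure each stage consumes,
nothing more:

* **Cohort** (default n = 500, depth Poisson(30), C ∈ {2..5} with
  probabilities 0.3/0.3/0.3/0.1, resistant-haplotype frequency 0.45,
  logistic survival β0 = −2, β_S = 1.2): read fractions are simulated
  at the single focal SNP only, since that is the only quantity the
  dosage model consumes. The copy-number distribution is
  config-exposed; published cohorts show duplications are common with
  most resistant samples at 3–5 copies, and the defaults reflect
  that, but the exact within-cohort distribution is not pinned down
  by any printed table.
* **Sweep** (copying model): swept haplotypes copy one core
  haplotype, switching to an independent background draw per site
  with probability 1 − exp(−r·d) at distance d from the focal
  variant, plus a per-site mutation flip. This is not a coalescent —
  it has no genealogy and no linkage beyond the core — but the
  statistics under test (H12, EHH, diversity) depend only on
  haplotype-identity structure, which the model controls directly.
  Identity decays per-site, so windows much longer than 1/r contain
  essentially no identical swept pairs; profiles should use windows
  of order 1/(r·window) accordingly.
* **Three populations** (Balding–Nichols): per-population frequencies
  are Beta draws around shared ancestral frequencies (drift F per
  population); an introgressed tract mixes the recipient's frequency
  with the donor's; an optional extra-drift tract in the focal
  population creates a differentiated window for PBS spike tests.
  Sites are exchangeable and unlinked, so block-jackknife behaviour
  under linkage is *not* exercised.
* **Reads** are error-free tilings at uniform random offsets. Linear
  templates have a terminal zone of decaying coverage whose
  presence/absence noise is an artifact of simulating an excised
  locus; circular tiling (used by the k-mer drivers) removes it.
  Junction cohorts give carriers a tandem duplication of the central
  tract and non-carriers a short internal deletion, so
  carrier-specific k-mers include both junction-spanning sequence
  (unplaceable by exact match) and verbatim tract sequence
  (placeable).

Because the generators are structural emulations, passing tests show
that each estimator recovers the quantities its model defines under
its own assumptions — they do not validate robustness to sequencing
error, mapping bias, linked selection, or population structure beyond
what is modelled.

## Problem sizes

Default test and driver sizes are chosen so the full suite runs in
well under a minute of compute per module on one core: cohorts of
500 samples, sweeps of 100–200 haplotypes × a few hundred variants,
scans of 30 000 sites, k-mer cohorts of ~20 samples over 1–2 kb loci,
and 50–500 seeded replicates for calibration and power checks. The
published analyses ran on three orders of magnitude more data; every
statistic here is size-agnostic and the replicate counts are enough to
resolve the rates being asserted (e.g. a 95% rate over 200 paired
replicates).

## Known limitations

* Dosage estimation assumes unbiased allele sampling; reference bias
  would shift f_alt systematically and is not modelled.
* The local-FDR estimator is a simple two-component KDE scheme, not a
  reimplementation of any particular published tool.
* Exact-match placement cannot place contigs containing variant or
  junction sequence; that is a documented scope decision, not a
  defect.
* The k-mer counter is an in-memory dictionary counter, suitable for
  the simulated cohorts; it makes no attempt at disk-backed counting
  for billions of k-mers.
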