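# Methods

This note documents the models behind `ssmap`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic screens can
and cannot tell you about real data.

## The simulated screen

The generator emulates a second-site suppressor screen in a selfing
diploid:

1. **Genome.** A miniature reference of five 3-Mb chromosomes with 36% GC
   (Arabidopsis-like base composition), generated i.i.d. per base from the
   genome seed. Five chromosomes preserve per-chromosome candidate plots at
   desk scale.
2. **Mutagenesis.** EMS produces almost exclusively G:C→A:T transitions, so
   induced mutations are drawn uniformly over G/C sites, as G→A or C→T
   only, with a Poisson(λ) total. Default λ = 700, matching the ~700–800
   mutagen-unique SNPs typically segregating in such screens. One induced
   mutation is tagged causal. A further ~4800 `background` SNPs (any
   substitution, homozygous in both crossing parents) model the shared
   variation relative to the reference assembly that the shared-SNP filter
   must remove; 4800 + 700 reproduces a realistic ~5500-SNP raw call set.
3. **Meiosis.** The suppressor line is backcrossed to its parent; the F1 is
   heterozygous everywhere, and each BC1F2 plant fuses two independent F1
   gametes. Crossovers follow the Haldane model — count ~ Poisson(map
   length in Morgans), breakpoints uniform, no interference — so the
   recombinant fraction at distance *d* cM is r = ½(1 − e^(−2d/100)).
   Default map length is **90 cM per chromosome**: the miniature preserves
   the genetic length of real Arabidopsis chromosomes (~70–120 cM) rather
   than their physical cM/Mb ratio, because everything that matters here —
   hitchhiker decay around the causal locus, marker informativeness — lives
   on the cM scale.
4. **Phenotype and selection.** Leaf number at bolting is
   μ_bg + 2·e·(dosage = 2) + 2·e·h·(dosage = 1) + N(0, σ²), with defaults
   μ_bg = 20 leaves, allele effect e = 3, noise σ = 1.5. These produce
   overlapping genotype distributions so the selection rule — keep plants
   with ≥ 25% more leaves than the background mean, capped at the m
   latest-flowering — is non-trivial. Defaults N = 115 plants, pool m = 35.
   With h = 0 (recessive) the expected pool is the ~N/4 homozygotes; with
   h = 1 (dominant) ~3N/4 plants qualify and the cap keeps a random
   genotype mixture of carriers, {hom 1/3, het 2/3}.
5. **Pooled sequencing.** Per site, read depth ~ Poisson(60) and
   non-reference reads ~ Binomial(depth, p(1−ε) + (1−p)ε) with ε = 0.001
   (Illumina-like). The background pool is sequenced from non-recombinant
   parental plants. Output is one single-sample VCF v4.2 per pool with
   AD/DP, plus a tab-separated truth table.

**Randomness policy.** One master seed; named CRC32-derived sub-streams per
stage (`ssmap.rng.stage_rng`), so any stage reproduces in isolation and
identical seeds give byte-identical files.

## The mapping statistic

SNP index = alt / (ref + alt); ΔSNP index = index_bg − index_mut, chosen so
mutant-unique SNPs approach −1 and the candidate rule is Δ ≤ −0.7.
Filters remove, with exactly one reason each and in a fixed precedence
(multi-allelic → low-quality → low-depth → shared-with-background):
multi-allelic rows, QUAL < 20, total depth < 10, and sites whose alternate
allele is genuinely present in the background pool (≥ 2 alt reads **and**
≥ 10% alt frequency — an absolute-plus-relative floor so isolated error
reads do not count as presence). Read-level artifacts ("multiple-hit
reads") cannot be re-filtered from a VCF; the quality/multi-allelic proxies
above stand in for them. A surviving site is background-absent by
construction and contributes index_bg = 0 to Δ. Candidates are sorted by Δ,
ties broken by (chrom, pos) for determinism. Per-SNP values are plotted
raw; a sliding-window smoother exists (`windowed_delta`) but defaults off.

**Resolution limit.** In a selected pool of ~29 homozygotes (58 gametes),
every induced SNP with zero recombinant gametes to the causal locus — on
average 2ρ·100/58 per side for SNP density ρ per cM, i.e. roughly 5–10
sites under the defaults — has true pool frequency exactly 1 and is
statistically indistinguishable from the causal SNP. Moreover the causal
site itself shows at least one apparent reference read with probability
1 − e^(−depth·ε) ≈ 5.8%, in which case a perfectly linked hitchhiker can
rank strictly below it. The meaningful recovery statement, used in the
deterministic tests, is therefore that the causal SNP lies within
sequencing noise (≤ 0.05, about three error reads at 60×) of the
chromosomal minimum; demanding the strict minimum caps the success rate at
about e^(−0.06) ≈ 94% no matter the seed. Candidate *regions*, not single
SNPs, are what bulk segregant analysis resolves — which is exactly why the
workflow continues with linkage mapping and per-SNP genotyping.

## Codon annotation

Gene models are single-transcript ordered CDS segment lists (GFF3-style
1-based inclusive coordinates; total length divisible by 3). On the +
strand the CDS coordinate is the offset in the concatenated segments; on
the − strand it is counted from the 3′-most genomic base, with genomic
bases complemented before codon lookup. Translation uses the standard
nuclear code; classes are synonymous / missense / nonsense, and anything
outside a CDS (UTRs, introns, intergenic) is `non-coding`. A reference
mismatch between variant and CDS sequence raises a data-integrity error
reporting both bases. Stop-loss changes are reported as missense.

## Linkage mapping in selected pools

Because the mapping individuals are phenotype-selected, the estimators
condition on the trait-locus genotype distribution:

* `selected_recessive` — all selected plants are homozygous carriers, so
  each of the 2n marker alleles is recombinant independently with
  probability r: r̂ = (#H + 2·#B)/(2n), SE = √(r̂(1−r̂)/2n). This counting
  estimator is exactly the maximum of the binomial likelihood.
* `selected_dominant` — the trait genotype is {hom 1/3, het 2/3}; marker
  genotype probabilities are the corresponding two-component mixture
  ((1−r)², 2r(1−r), r² given hom; r(1−r), (1−r)²+r², r(1−r) given het) and
  r̂ maximizes the mixture likelihood by bounded one-dimensional search,
  with SE from the observed information (central second difference).

Estimates are clamped to [0, 0.5]; a raw estimate above 0.5 (or a boundary
maximum) sets an `unlinked` flag. Missing genotypes are dropped pairwise
per marker. Markers are ranked by r̂ ascending, ties by (chrom, pos). A
Pearson χ² against 1:2:1 (`segregation_chi2`) is provided as a marker
quality check for unselected F2 data. Dominant-scored (presence/absence)
marker systems are not modeled; calls must be codominant A/H/B.

## CAPS/dCAPS design

The packaged table lists 36 common 4–6-bp cutters as (name, IUPAC site,
top-strand cut offset); it is a plain TSV and user-extensible. For every
enzyme and every placement of its site across the SNP, the design counts
the substitutions needed in the genotyping primer (3′ end abutting the SNP)
to complete the site. Constraints: the site must span the SNP (otherwise
digestion cannot discriminate), substitutions are only allowed in the
primer 5′ of the SNP and never at the 3′-terminal base (extension
fidelity), and at most `max_mismatch` (default 2) substitutions. A
placement qualifies when exactly one allele satisfies the site's IUPAC code
at the SNP. Every candidate is then verified by in-silico digestion of both
engineered amplicons — the self-oracle also executed in the tests — and
fragment sets must differ. Digestion scans the forward strand with the
IUPAC-expanded pattern (and the reverse-complement pattern when it differs,
for non-palindromic sites), cuts at start + offset, and always partitions
the amplicon length exactly. Only the left-primer orientation is searched;
a right-primer design is the mirror image on the reverse complement. Primer
thermodynamics (Tm, dimers, hairpins) are out of scope.

## Pipeline

`run_screen` chains simulate (or user VCF ingestion) → ΔSNP mapping →
annotation of the top candidate region (against a synthetic 306-codon gene
model placed over it, since simulated genomes carry no annotation) →
linkage ranking with two markers per chromosome → dCAPS design for the top
candidate, writing only plain-text intermediates (VCF/TSV/CSV/JSON) so each
stage can be re-run and inspected independently. The resolved configuration
and all seeds are logged; identical config + seed ⇒ byte-identical
summaries. CLI exit codes: 0 success, 2 input error, 3 stage failure.

## What the synthetic screens do not capture

Real pooled resequencing adds alignment and mapping-bias artifacts, indels
and structural variants, multi-allelic sites, GC-dependent and position-
dependent coverage, contamination between pools, and phenotype
misclassification that is correlated (environment) rather than i.i.d.
Gaussian. The generator models none of these — variant calling is upstream
of this package — so passing tests demonstrate correctness of the
statistics and the selection/linkage logic under the stated model, not
robustness to upstream calling errors. Problem sizes in the tests and the
acceptance script (200 replicate screens, populations of 115–400) were
chosen to make replicate Monte-Carlo error small relative to the tested
effects while remaining desk-scale.
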