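"""Replicated synthetic-screen experiments.

These functions wire the simulator and the mapping statistic together into
the experiments the package is built around: how strongly a recessive versus
a dominant suppressor mutation is enriched in a phenotype-selected BC1F2
pool, and how reliably the causal SNP is recovered from the ΔSNP-index
profile.  They are used by the analysis drivers, the acceptance checks and
the test suite.

Study conditions (the defaults throughout): a BC1F2 population of 115
plants, a selected pool of 35, pooled sequencing at ~60x with a 0.1%
per-read error rate, ~700 EMS-induced G:C->A:T SNPs plus ~4800 shared
background SNPs on a five-chromosome 3-Mb-per-chromosome genome with 90 cM
per chromosome.

Analytic expectations: with full dominance the selected pool's genotype
distribution at the causal locus is {homozygous: 1/3, heterozygous: 2/3},
so the causal allele frequency tends to 1/3*1 + 2/3*1/2 = 2/3 and the ΔSNP
index to -2/3; with recessive action every selected plant is homozygous and
the ΔSNP index tends to -1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import annotate, simulate, snpindex
from .errors import InputError
from .rng import as_rng

__all__ = [
    "ScreenResult",
    "default_genome",
    "default_mutations",
    "run_single_screen",
    "causal_delta_replicates",
    "causal_recovery_replicates",
    "rf_recovery_replicates",
    "codon228_worked_example",
    "uniqueness_limit_delta",
]

LAMBDA_MUT = 700.0  # expected EMS-unique SNP load of the screen
N_BACKGROUND = 4800  # shared parental SNPs relative to the reference
MAP_LENGTH_CM = 90.0  # per-chromosome genetic length


def default_genome(seed: int = 0) -> simulate.GenomeSpec:
    return simulate.arabidopsis_like_genome(seed=seed)


def _nearest_gc(genome: simulate.GenomeSpec, chrom: str, pos: int) -> int:
    """First G/C site at or after ``pos`` (EMS can only hit G/C)."""
    seq = genome.sequence(chrom)
    for p in range(pos, len(seq) + 1):
        if chr(seq[p - 1]) in "GC":
            return p
    raise InputError(f"no G/C site at or after {chrom}:{pos}")


def default_mutations(
    genome: simulate.GenomeSpec,
    seed: int | np.random.Generator | None = None,
    lambda_mut: float = LAMBDA_MUT,
    n_background: int = N_BACKGROUND,
) -> simulate.MutationSet:
    """EMS-induced plus shared background SNPs, with one causal entry.

    The causal SNP is a randomly chosen induced mutation, mirroring a screen
    in which any one EMS hit may be the suppressor.
    """
    rng = as_rng(seed)
    induced = simulate.mutagenize(genome, lambda_mut, rng)
    if len(induced) == 0:
        raise InputError("no induced mutations to choose a causal SNP from")
    background = simulate.background_variants(genome, n_background, rng)
    merged = simulate.MutationSet.merge(induced, background)
    induced_entries = list(merged.by_origin("induced"))
    causal = induced_entries[int(rng.integers(len(induced_entries)))]
    return merged.with_causal(causal.chrom, causal.pos)


@dataclass
class ScreenResult:
    """One realized screen: population, selection, and pooled read counts."""

    mutations: simulate.MutationSet
    plants: list
    phenotypes: np.ndarray
    selected: np.ndarray
    mut_records: list
    bg_records: list
    freq_mut_pool: np.ndarray
    freq_bg_pool: np.ndarray


def run_single_screen(
    genome: simulate.GenomeSpec,
    mutations: simulate.MutationSet,
    model: simulate.PhenotypeModel,
    pool: simulate.PoolSpec,
    map_length_cm: float = MAP_LENGTH_CM,
    seed: int | np.random.Generator | None = None,
    n_bg_plants: int = 30,
) -> ScreenResult:
    """Grow, phenotype, select and sequence one BC1F2 screen."""
    rng = as_rng(seed)
    plants = simulate.make_bc1f2(genome, pool.n_population, map_length_cm, rng)
    phenotypes = simulate.assign_phenotypes(plants, model, mutations, seed=rng)
    selected = simulate.select_pool(phenotypes, pool, model.mu_bg)
    pool_plants = [plants[i] for i in selected]
    bg_plants = simulate.pure_background_plants(genome, n_bg_plants)
    mut_records = simulate.pool_read_counts(pool_plants, mutations, pool, rng)
    bg_records = simulate.pool_read_counts(bg_plants, mutations, pool, rng)
    return ScreenResult(
        mutations=mutations,
        plants=plants,
        phenotypes=phenotypes,
        selected=selected,
        mut_records=mut_records,
        bg_records=bg_records,
        freq_mut_pool=simulate.pool_allele_freqs(pool_plants, mutations),
        freq_bg_pool=simulate.pool_allele_freqs(bg_plants, mutations),
    )


def _causal_record(result: ScreenResult, records) -> snpindex.SnpIndexRecord:
    causal = result.mutations.causal
    for r in records:
        if r.chrom == causal.chrom and r.pos == causal.pos:
            return r
    raise AssertionError("causal site missing from the index table")


def causal_delta_replicates(
    n_reps: int,
    h: float,
    seed: int,
    model: simulate.PhenotypeModel | None = None,
    pool: simulate.PoolSpec | None = None,
) -> np.ndarray:
    """ΔSNP index at the causal locus across replicate screens.

    One genome and mutation set are drawn once; population growth,
    selection and sequencing are replicated ``n_reps`` times.
    """
    rng = as_rng(seed)
    model = model or simulate.PhenotypeModel(h=h)
    if model.h != h:
        model = simulate.PhenotypeModel(
            mu_bg=model.mu_bg, effect=model.effect, h=h, sigma=model.sigma
        )
    pool = pool or simulate.PoolSpec()
    genome = default_genome(seed=int(rng.integers(2**31)))
    mutations = default_mutations(genome, rng)
    deltas = np.empty(n_reps)
    for i in range(n_reps):
        result = run_single_screen(genome, mutations, model, pool, seed=rng)
        records = snpindex.build_snpindex_records(
            result.mut_records, result.bg_records
        )
        deltas[i] = _causal_record(result, records).delta
    return deltas


def causal_recovery_replicates(n_reps: int, seed: int) -> np.ndarray:
    """Does the causal SNP attain the minimum Δ on its chromosome? (recessive)

    Returns a boolean array over replicates.  A replicate counts as a
    recovery when the causal site's ΔSNP index equals the minimum across its
    chromosome - perfectly linked hitchhiking SNPs can tie it, which is the
    resolution limit of bulk-segregant mapping.
    """
    rng = as_rng(seed)
    model = simulate.PhenotypeModel(h=0.0)
    pool = simulate.PoolSpec()
    genome = default_genome(seed=int(rng.integers(2**31)))
    mutations = default_mutations(genome, rng)
    causal = mutations.causal
    hits = np.zeros(n_reps, dtype=bool)
    for i in range(n_reps):
        result = run_single_screen(genome, mutations, model, pool, seed=rng)
        records = snpindex.build_snpindex_records(
            result.mut_records, result.bg_records
        )
        on_chrom = [
            r.delta
            for r in records
            if r.chrom == causal.chrom and r.filter_status == "PASS"
        ]
        causal_delta = _causal_record(result, records).delta
        hits[i] = np.isfinite(causal_delta) and causal_delta <= min(on_chrom)
    return hits


def rf_recovery_replicates(
    n_reps: int,
    seed: int,
    distance_cm: float = 10.0,
    n_population: int = 400,
    pool_size: int = 100,
) -> np.ndarray:
    """Estimated recombination fraction to a marker at a known map distance.

    Simulates recessive screens on the default genome, genotypes the
    selected (homozygous) plants at a marker ``distance_cm`` away from the
    causal locus, and estimates r by allele counting.  Under the Haldane map
    the true value is r = (1 - exp(-2 d/100)) / 2.
    """
    from .linkage import MarkerTable, estimate_rf
    import pandas as pd

    rng = as_rng(seed)
    genome = default_genome(seed=int(rng.integers(2**31)))
    chrom, length = genome.chromosomes[0]
    causal_pos = _nearest_gc(genome, chrom, length // 3)
    marker_pos = causal_pos + int(round(distance_cm / MAP_LENGTH_CM * length))
    causal = simulate.Mutation(
        chrom,
        causal_pos,
        genome.base(chrom, causal_pos),
        {"G": "A", "C": "T"}[genome.base(chrom, causal_pos)],
        "causal",
    )
    mutations = simulate.MutationSet([causal])
    model = simulate.PhenotypeModel(h=0.0)
    pool = simulate.PoolSpec(n_population=n_population, pool_size=pool_size)
    marker_map = pd.DataFrame(
        {"marker": ["m1"], "chrom": [chrom], "pos": [marker_pos]}
    )
    rhats = np.empty(n_reps)
    for i in range(n_reps):
        plants = simulate.make_bc1f2(genome, n_population, MAP_LENGTH_CM, rng)
        phen = simulate.assign_phenotypes(plants, model, mutations, seed=rng)
        selected = simulate.select_pool(phen, pool, model.mu_bg)
        geno = simulate.genotype_markers(
            [plants[j] for j in selected], [("m1", chrom, marker_pos)]
        )
        table = MarkerTable(genotypes=geno, markers=marker_map)
        rhats[i] = estimate_rf(table, "m1", "selected_recessive").rhat
    return rhats


def codon228_worked_example() -> annotate.VariantEffect:
    """The screen's flagship annotation: C->T at CDS position 683.

    A single-exon plus-strand model of a 306-codon protein with alanine
    codons (GCT) throughout; the substitution falls in codon 228 at codon
    position 2 and converts alanine to valine.
    """
    n_codons = 306
    cds = "GCT" * n_codons
    gene = annotate.GeneModel(
        gene_id="had_gene",
        chrom="chr5",
        strand="+",
        segments=((101, 100 + 3 * n_codons),),
    )
    genomic_pos = 101 + 683 - 1
    cds_pos = annotate.map_genomic_to_cds(gene, genomic_pos)
    return annotate.classify_variant(gene, cds_pos, "C", "T", cds)


def uniqueness_limit_delta() -> float:
    """ΔSNP index of a mutant-fixed, background-absent site (the -1 limit)."""
    return snpindex.delta_snp_index(None, 1.0)
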