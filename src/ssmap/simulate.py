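"""Synthetic suppressor-screen generator.

Emulates the data-generating process of a second-site suppressor screen in a
selfing plant: EMS mutagenesis of a parental line (inducing G:C->A:T
transitions), a backcross of the suppressor mutant to that parent, selfing of
the F1 to obtain a BC1F2 population in which every induced mutation
segregates 1:2:1, phenotype-based selection of a pool of late-flowering
segregants, and pooled short-read sequencing of the selected pool and of the
parental background.

Meiosis follows the Haldane model: crossover counts are Poisson with mean
equal to the chromosome map length in Morgans and breakpoints are uniform,
i.e. no interference.  Pooled sequencing draws a Poisson read depth per site
and binomial non-reference read counts around the true pool allele
frequency, with a symmetric per-read error rate.

The generator writes one VCF per pool (v4.2, AD/DP FORMAT fields) plus a
tab-separated ground-truth table, which together are the inputs of the
mapping stages.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, SelectionError
from .rng import as_rng
from .snpindex import VariantRecord

__all__ = [
    "MUTANT",
    "BACKGROUND",
    "GenomeSpec",
    "Mutation",
    "MutationSet",
    "Haplotype",
    "PlantGenotype",
    "PhenotypeModel",
    "PoolSpec",
    "arabidopsis_like_genome",
    "mutagenize",
    "background_variants",
    "make_bc1f2",
    "pure_background_plants",
    "assign_phenotypes",
    "select_pool",
    "pool_allele_freqs",
    "pool_read_counts",
    "genotype_markers",
    "write_vcf",
    "write_truth_table",
    "write_truth_and_vcf",
]

#: founder labels carried by recombinant haplotype segments
MUTANT, BACKGROUND = 0, 1

_COMPLEMENTABLE = {"A", "C", "G", "T"}
_EMS_ALT = {"G": "A", "C": "T"}  # EMS: G:C -> A:T transitions only


@dataclass(eq=False)
class GenomeSpec:
    """A miniature reference genome defined by chromosome sizes and GC content.

    Sequences are generated lazily per chromosome from the genome seed, so a
    spec with the same parameters always yields byte-identical sequence.
    """

    chromosomes: tuple[tuple[str, int], ...]
    gc_fraction: float = 0.36
    seed: int = 0
    _seq_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.chromosomes = tuple((str(n), int(l)) for n, l in self.chromosomes)
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise InputError("chromosome names must be unique")
        if any(l <= 0 for _, l in self.chromosomes):
            raise InputError("chromosome lengths must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise InputError("GC fraction must lie in [0, 1]")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        for n, l in self.chromosomes:
            if n == chrom:
                return l
        raise KeyError(chrom)

    def sequence(self, chrom: str) -> np.ndarray:
        """Chromosome sequence as an array of ASCII codes (A/C/G/T)."""
        if chrom not in self._seq_cache:
            idx = self.names.index(chrom)
            rng = np.random.default_rng(
                np.random.SeedSequence([int(self.seed) & 0x7FFFFFFF, idx])
            )
            gc = self.gc_fraction
            p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
            bases = np.frombuffer(b"ACGT", dtype=np.uint8)
            self._seq_cache[chrom] = rng.choice(bases, size=self.length(chrom), p=p)
        return self._seq_cache[chrom]

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return chr(self.sequence(chrom)[pos - 1])


def arabidopsis_like_genome(seed: int = 0, gc_fraction: float = 0.36) -> GenomeSpec:
    """Five 3-Mb chromosomes: a desk-scale Arabidopsis-like miniature."""
    return GenomeSpec(
        chromosomes=tuple((f"chr{i}", 3_000_000) for i in range(1, 6)),
        gc_fraction=gc_fraction,
        seed=seed,
    )


@dataclass(frozen=True, order=True)
class Mutation:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    origin: str  # background | induced | causal

    def __post_init__(self):
        if self.ref == self.alt:
            raise InputError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.origin not in ("background", "induced", "causal"):
            raise InputError(f"unknown origin tag {self.origin!r}")
        if self.origin in ("induced", "causal") and _EMS_ALT.get(self.ref) != self.alt:
            raise InputError(
                f"EMS mutation at {self.chrom}:{self.pos} must be G->A or C->T, "
                f"got {self.ref}->{self.alt}"
            )


class MutationSet:
    """An ordered, position-unique collection of segregating SNPs."""

    def __init__(self, entries: Iterable[Mutation]):
        entries = sorted(entries, key=lambda m: (m.chrom, m.pos))
        seen: set[tuple[str, int]] = set()
        for m in entries:
            key = (m.chrom, m.pos)
            if key in seen:
                raise InputError(f"duplicate mutation position {m.chrom}:{m.pos}")
            seen.add(key)
        self.entries: tuple[Mutation, ...] = tuple(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, MutationSet) and self.entries == other.entries

    def by_origin(self, *origins: str) -> "MutationSet":
        return MutationSet(m for m in self.entries if m.origin in origins)

    @property
    def causal(self) -> Mutation | None:
        hits = [m for m in self.entries if m.origin == "causal"]
        if len(hits) > 1:
            raise InputError("more than one causal mutation")
        return hits[0] if hits else None

    def with_causal(self, chrom: str, pos: int) -> "MutationSet":
        """Retag one induced mutation as the causal one."""
        out = []
        found = False
        for m in self.entries:
            if m.chrom == chrom and m.pos == pos:
                if m.origin not in ("induced", "causal"):
                    raise InputError("causal mutation must be an induced SNP")
                out.append(Mutation(m.chrom, m.pos, m.ref, m.alt, "causal"))
                found = True
            elif m.origin == "causal":
                out.append(Mutation(m.chrom, m.pos, m.ref, m.alt, "induced"))
            else:
                out.append(m)
        if not found:
            raise InputError(f"no mutation at {chrom}:{pos}")
        return MutationSet(out)

    @classmethod
    def merge(cls, *sets: "MutationSet") -> "MutationSet":
        """Union of mutation sets; induced/causal entries win position clashes."""
        by_pos: dict[tuple[str, int], Mutation] = {}
        for s in sets:
            for m in s:
                key = (m.chrom, m.pos)
                prev = by_pos.get(key)
                if prev is None or (prev.origin == "background" != m.origin):
                    by_pos[key] = m
        return cls(by_pos.values())


def mutagenize(
    genome: GenomeSpec,
    lambda_mut: float,
    seed: int | np.random.Generator | None = None,
) -> MutationSet:
    """Draw EMS-induced mutations over the genome.

    The number of mutations is Poisson(``lambda_mut``); positions are uniform
    over the genome's G/C sites and every mutation is a G->A or C->T
    transition, the EMS signature.
    """
    if lambda_mut < 0:
        raise InputError("lambda_mut must be non-negative")
    rng = as_rng(seed)
    total = int(rng.poisson(lambda_mut))
    if total == 0:
        return MutationSet([])
    eligible = {}
    for chrom in genome.names:
        seq = genome.sequence(chrom)
        eligible[chrom] = np.flatnonzero((seq == ord("G")) | (seq == ord("C")))
    n_eligible = np.array([len(eligible[c]) for c in genome.names])
    if n_eligible.sum() == 0:
        raise InputError(
            "genome has no G/C sites; the EMS mutation spectrum is impossible"
        )
    if total > n_eligible.sum():
        raise InputError("more mutations requested than eligible G/C sites")
    counts = rng.multinomial(total, n_eligible / n_eligible.sum())
    entries = []
    for chrom, k in zip(genome.names, counts):
        if k == 0:
            continue
        picks = rng.choice(len(eligible[chrom]), size=int(k), replace=False)
        seq = genome.sequence(chrom)
        for i in np.sort(picks):
            pos = int(eligible[chrom][i]) + 1
            ref = chr(seq[pos - 1])
            entries.append(Mutation(chrom, pos, ref, _EMS_ALT[ref], "induced"))
    return MutationSet(entries)


def background_variants(
    genome: GenomeSpec,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> MutationSet:
    """Pre-existing SNPs of the parental background relative to the reference.

    These are natural polymorphisms (any substitution) carried homozygously
    by both crossing parents, so they appear in both pools and are the target
    of the shared-SNP filter.
    """
    if n < 0:
        raise InputError("n must be non-negative")
    rng = as_rng(seed)
    lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
    counts = rng.multinomial(int(n), lengths / lengths.sum())
    entries = []
    bases = "ACGT"
    for (chrom, length), k in zip(genome.chromosomes, counts):
        if k == 0:
            continue
        pos = rng.choice(length, size=int(k), replace=False) + 1
        seq = genome.sequence(chrom)
        for p in np.sort(pos):
            ref = chr(seq[p - 1])
            alts = [b for b in bases if b != ref]
            alt = alts[int(rng.integers(len(alts)))]
            entries.append(Mutation(chrom, int(p), ref, alt, "background"))
    return MutationSet(entries)


@dataclass(frozen=True)
class Haplotype:
    """A recombinant gamete: crossover breakpoints plus the starting founder."""

    crossovers: tuple[float, ...]
    first: int  # founder label of the leftmost segment

    def founders_at(self, positions: np.ndarray) -> np.ndarray:
        """Founder label at each (1-based) position, vectorized."""
        xo = np.asarray(self.crossovers, dtype=float)
        n_before = np.searchsorted(xo, np.asarray(positions, dtype=float))
        return np.where(n_before % 2 == 0, self.first, 1 - self.first)


@dataclass
class PlantGenotype:
    """A diploid BC1F2 individual: two recombinant haplotypes per chromosome."""

    haplotypes: dict[str, tuple[Haplotype, Haplotype]]

    def dosage(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Number of mutant-parent haplotypes at each position (0, 1 or 2)."""
        h1, h2 = self.haplotypes[chrom]
        return (h1.founders_at(positions) == MUTANT).astype(int) + (
            h2.founders_at(positions) == MUTANT
        ).astype(int)


def _gamete(length: int, map_length_cm: float, rng: np.random.Generator) -> Haplotype:
    k = int(rng.poisson(map_length_cm / 100.0))
    xo = tuple(np.sort(rng.uniform(0, length, size=k)))
    return Haplotype(crossovers=xo, first=int(rng.integers(2)))


def make_bc1f2(
    genome: GenomeSpec,
    n_plants: int,
    map_length_cm: float = 90.0,
    seed: int | np.random.Generator | None = None,
) -> list[PlantGenotype]:
    """Self an everywhere-heterozygous F1 into a BC1F2 population.

    Each plant is the fusion of two independent F1 gametes; crossovers follow
    the Haldane model (Poisson counts, uniform breakpoints, no interference).
    At any single locus the mutant-allele dosage segregates 1:2:1.
    """
    if n_plants <= 0:
        raise InputError("n_plants must be positive")
    if map_length_cm < 0:
        raise InputError("map length must be non-negative")
    rng = as_rng(seed)
    plants = []
    for _ in range(n_plants):
        haps = {}
        for chrom, length in genome.chromosomes:
            haps[chrom] = (
                _gamete(length, map_length_cm, rng),
                _gamete(length, map_length_cm, rng),
            )
        plants.append(PlantGenotype(haplotypes=haps))
    return plants


def pure_background_plants(genome: GenomeSpec, n: int) -> list[PlantGenotype]:
    """Non-recombinant plants of the parental background (the reference pool)."""
    haps = {
        chrom: (Haplotype((), BACKGROUND), Haplotype((), BACKGROUND))
        for chrom, _ in genome.chromosomes
    }
    return [PlantGenotype(haplotypes=dict(haps)) for _ in range(n)]


@dataclass(frozen=True)
class PhenotypeModel:
    """Leaf number at bolting as a function of causal-allele dosage.

    Genotype means are ``mu_bg`` (dosage 0), ``mu_bg + 2*effect*h``
    (dosage 1) and ``mu_bg + 2*effect`` (dosage 2); ``h = 1`` is full
    dominance (heterozygote equals mutant homozygote), ``h = 0`` recessive.
    """

    mu_bg: float = 20.0
    effect: float = 3.0
    h: float = 0.0
    sigma: float = 1.5

    def __post_init__(self):
        if self.sigma < 0:
            raise InputError("sigma must be non-negative")
        if not 0.0 <= self.h <= 1.0:
            raise InputError("dominance coefficient h must lie in [0, 1]")

    def genotype_mean(self, dosage: np.ndarray) -> np.ndarray:
        d = np.asarray(dosage)
        return (
            self.mu_bg
            + 2.0 * self.effect * (d == 2)
            + 2.0 * self.effect * self.h * (d == 1)
        )


def assign_phenotypes(
    plants: Sequence[PlantGenotype],
    model: PhenotypeModel,
    mutations: MutationSet,
    causal: tuple[str, int] | None = None,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Leaf numbers: genotype mean at the causal locus plus Gaussian noise."""
    causal_mut = mutations.causal
    if causal is not None:
        matches = [
            m for m in mutations if (m.chrom, m.pos) == tuple(causal) and m.origin == "causal"
        ]
        if not matches:
            raise InputError(f"causal position {causal} is not tagged causal")
        causal_mut = matches[0]
    if causal_mut is None:
        raise InputError("mutation set contains no causal entry")
    rng = as_rng(seed)
    pos = np.array([causal_mut.pos])
    dosage = np.array([int(p.dosage(causal_mut.chrom, pos)[0]) for p in plants])
    means = model.genotype_mean(dosage)
    noise = rng.normal(0.0, model.sigma, size=len(plants)) if model.sigma > 0 else 0.0
    return means + noise


@dataclass(frozen=True)
class PoolSpec:
    """Population size, selection rule, pool size and sequencing parameters."""

    n_population: int = 115
    pool_size: int = 35
    threshold_fraction: float = 0.25  # select >= (1 + fraction) * mu_bg
    top_k: int | None = None  # alternative rule: take the k latest-flowering
    depth: float = 60.0
    error_rate: float = 0.001
    seed: int | None = None

    def __post_init__(self):
        if self.pool_size > self.n_population:
            raise InputError("pool size cannot exceed population size")
        if self.depth <= 0:
            raise InputError("sequencing depth must be positive")
        if not 0.0 <= self.error_rate <= 0.1:
            raise InputError("error rate must lie in [0, 0.1]")


def select_pool(
    phenotypes: np.ndarray, spec: PoolSpec, mu_bg: float
) -> np.ndarray:
    """Indices of plants selected for the sequencing pool.

    The threshold rule keeps every plant flowering with at least
    ``(1 + threshold_fraction) * mu_bg`` leaves; if more than ``pool_size``
    qualify, the latest-flowering ``pool_size`` are kept.  With ``top_k``
    set, the k latest-flowering plants are taken instead.
    """
    phenotypes = np.asarray(phenotypes, dtype=float)
    if spec.top_k is not None:
        order = np.lexsort((np.arange(len(phenotypes)), -phenotypes))
        return np.sort(order[: spec.top_k])
    cutoff = (1.0 + spec.threshold_fraction) * mu_bg
    qualifying = np.flatnonzero(phenotypes >= cutoff)
    if qualifying.size == 0:
        raise SelectionError(
            f"no plant shows the suppressor phenotype (>= {cutoff:g} leaves)"
        )
    if qualifying.size > spec.pool_size:
        order = np.lexsort((qualifying, -phenotypes[qualifying]))
        qualifying = qualifying[order[: spec.pool_size]]
    return np.sort(qualifying)


def pool_allele_freqs(
    plants: Sequence[PlantGenotype], mutations: MutationSet
) -> np.ndarray:
    """True non-reference allele frequency of the pool at every mutation site.

    Background-origin SNPs are homozygous in both founders, hence fixed in
    any pool; induced/causal SNPs ride on mutant-parent haplotype segments.
    """
    if len(plants) == 0:
        raise InputError("empty plant pool")
    freqs = np.empty(len(mutations))
    entries = list(mutations)
    by_chrom: dict[str, list[int]] = {}
    for i, m in enumerate(entries):
        by_chrom.setdefault(m.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        pos = np.array([entries[i].pos for i in idxs])
        total = np.zeros(len(idxs), dtype=int)
        for p in plants:
            total += p.dosage(chrom, pos)
        freqs[idxs] = total / (2.0 * len(plants))
    for i, m in enumerate(entries):
        if m.origin == "background":
            freqs[i] = 1.0
    return freqs


def pool_read_counts(
    plants: Sequence[PlantGenotype],
    mutations: MutationSet,
    spec: PoolSpec,
    seed: int | np.random.Generator | None = None,
) -> list[VariantRecord]:
    """Pooled-sequencing read counts at every mutation site.

    Per site: depth ~ Poisson(spec.depth); non-reference reads ~
    Binomial(depth, p*(1-e) + (1-p)*e) where p is the true pool frequency
    and e the per-read error rate.
    """
    rng = as_rng(seed)
    freqs = pool_allele_freqs(plants, mutations)
    eps = spec.error_rate
    p_read = freqs * (1.0 - eps) + (1.0 - freqs) * eps
    depths = rng.poisson(spec.depth, size=len(freqs))
    alts = rng.binomial(depths, p_read)
    return [
        VariantRecord(
            chrom=m.chrom,
            pos=m.pos,
            ref=m.ref,
            alt=m.alt,
            ref_depth=int(d - a),
            alt_depth=int(a),
            qual=60.0,
        )
        for m, d, a in zip(mutations, depths, alts)
    ]


_MARKER_CODE = {2: "A", 1: "H", 0: "B"}


def genotype_markers(
    plants: Sequence[PlantGenotype],
    markers: Sequence[tuple[str, str, int]],
) -> pd.DataFrame:
    """Codominant marker calls (A/H/B) for each plant at each marker.

    ``markers`` is a sequence of ``(marker_id, chrom, pos)``.  A = homozygous
    mutant-parent, H = heterozygous, B = homozygous other-parent.
    """
    data = {}
    for marker_id, chrom, pos in markers:
        pos_arr = np.array([pos])
        data[marker_id] = [
            _MARKER_CODE[int(p.dosage(chrom, pos_arr)[0])] for p in plants
        ]
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# output plumbing: VCF + ground truth
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=ssmap-simulate
{contigs}##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_vcf(
    records: Sequence[VariantRecord],
    genome: GenomeSpec,
    path,
    sample: str = "pool",
) -> None:
    """Write pool read counts as a single-sample VCF v4.2 with AD/DP."""
    if not records:
        raise InputError("refusing to write an empty VCF")
    contigs = "".join(
        f"##contig=<ID={name},length={length}>\n" for name, length in genome.chromosomes
    )
    recs = sorted(records, key=lambda r: (r.chrom, r.pos))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs, sample=sample))
        for r in recs:
            qual = "." if r.qual is None else f"{r.qual:g}"
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{qual}\tPASS\t.\t"
                f"AD:DP\t{r.ref_depth},{r.alt_depth}:{r.depth}\n"
            )


def write_truth_table(
    mutations: MutationSet,
    freq_mut_pool: np.ndarray,
    freq_bg_pool: np.ndarray,
    path,
) -> None:
    df = pd.DataFrame(
        {
            "chrom": [m.chrom for m in mutations],
            "pos": [m.pos for m in mutations],
            "ref": [m.ref for m in mutations],
            "alt": [m.alt for m in mutations],
            "origin": [m.origin for m in mutations],
            "freq_mut_pool": freq_mut_pool,
            "freq_bg_pool": freq_bg_pool,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_truth_and_vcf(
    mut_records: Sequence[VariantRecord],
    bg_records: Sequence[VariantRecord],
    mutations: MutationSet,
    freq_mut_pool: np.ndarray,
    freq_bg_pool: np.ndarray,
    genome: GenomeSpec,
    outdir,
) -> dict[str, str]:
    """Emit both pool VCFs and the ground-truth table into ``outdir``."""
    import os

    os.makedirs(str(outdir), exist_ok=True)
    paths = {
        "mut_vcf": os.path.join(str(outdir), "mutant_pool.vcf"),
        "bg_vcf": os.path.join(str(outdir), "background_pool.vcf"),
        "truth": os.path.join(str(outdir), "truth.tsv"),
    }
    write_vcf(mut_records, genome, paths["mut_vcf"], sample="mutant_pool")
    write_vcf(bg_records, genome, paths["bg_vcf"], sample="background_pool")
    write_truth_table(mutations, freq_mut_pool, freq_bg_pool, paths["truth"])
    return paths
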