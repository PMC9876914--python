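"""End-to-end orchestration of the suppressor-screen mapping pipeline.

``run_screen`` executes simulate -> SNP-index mapping -> codon annotation ->
linkage mapping -> dCAPS design, writing plain-text intermediates (VCF, TSV,
CSV) into a run directory so every stage can be re-run independently, plus a
machine-readable ``summary.json`` and a log of seeds, versions and the
resolved configuration.  Identical configuration and seed give byte-identical
summaries.
"""
from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__, annotate, dcaps, linkage, simulate, snpindex
from .errors import InputError, SsmapError, StageError
from .rng import stage_rng

__all__ = ["RunConfig", "run_screen"]


@dataclass
class RunConfig:
    """All stage parameters, with defaults matching the study conditions."""

    seed: int = 1
    outdir: str = "ssmap_run"
    # genome
    n_chromosomes: int = 5
    chrom_length: int = 3_000_000
    gc_fraction: float = 0.36
    # mutagenesis
    lambda_mut: float = 700.0
    n_background_snps: int = 4800
    # population and selection
    map_length_cm: float = 90.0
    n_plants: int = 115
    pool_size: int = 35
    threshold_fraction: float = 0.25
    # phenotype model
    mu_bg: float = 20.0
    effect: float = 3.0
    dominance_h: float = 0.0
    sigma: float = 1.5
    # sequencing
    depth: float = 60.0
    error_rate: float = 0.001
    # snpindex stage
    min_depth: int = 10
    min_qual: float = 20.0
    delta_threshold: float = -0.7
    # linkage stage
    markers_per_chromosome: int = 2
    # dcaps stage
    max_mismatch: int = 2
    primer_length: int = 20
    dcaps_flank: int = 200
    # stage toggles / external inputs
    mut_vcf: str | None = None  # ingest user VCFs instead of simulating
    bg_vcf: str | None = None
    do_annotate: bool = True
    do_linkage: bool = True
    do_dcaps: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def genome(self) -> simulate.GenomeSpec:
        return simulate.GenomeSpec(
            chromosomes=tuple(
                (f"chr{i}", self.chrom_length)
                for i in range(1, self.n_chromosomes + 1)
            ),
            gc_fraction=self.gc_fraction,
            seed=self.seed,
        )


def _simulate_stage(cfg: RunConfig, outdir: str, log: list[str]):
    from .experiments import default_mutations, run_single_screen

    genome = cfg.genome()
    rng = stage_rng(cfg.seed, "simulate")
    mutations = default_mutations(
        genome, rng, lambda_mut=cfg.lambda_mut, n_background=cfg.n_background_snps
    )
    model = simulate.PhenotypeModel(
        mu_bg=cfg.mu_bg, effect=cfg.effect, h=cfg.dominance_h, sigma=cfg.sigma
    )
    pool = simulate.PoolSpec(
        n_population=cfg.n_plants,
        pool_size=cfg.pool_size,
        threshold_fraction=cfg.threshold_fraction,
        depth=cfg.depth,
        error_rate=cfg.error_rate,
    )
    result = run_single_screen(
        genome, mutations, model, pool, cfg.map_length_cm, seed=rng
    )
    paths = simulate.write_truth_and_vcf(
        result.mut_records,
        result.bg_records,
        mutations,
        result.freq_mut_pool,
        result.freq_bg_pool,
        genome,
        outdir,
    )
    causal = mutations.causal
    log.append(
        f"simulate: {len(mutations)} sites "
        f"({len(mutations.by_origin('induced', 'causal'))} induced), "
        f"{len(result.selected)} of {cfg.n_plants} plants selected, "
        f"causal at {causal.chrom}:{causal.pos}"
    )
    return genome, mutations, result, paths


def _marker_positions(genome: simulate.GenomeSpec, per_chrom: int):
    """Evenly spaced markers per chromosome (rough-mapping layout)."""
    markers = []
    for chrom, length in genome.chromosomes:
        for k in range(per_chrom):
            pos = int(length * (k + 1) / (per_chrom + 1))
            markers.append((f"{chrom}_m{k + 1}", chrom, pos))
    return markers


def run_screen(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the summary dictionary.

    Writes into ``config.outdir``: the resolved config, both pool VCFs and
    the ground truth, the SNP-index table with per-chromosome plot data, the
    candidate list, the effect table, the marker ranking, the dCAPS designs,
    ``summary.json`` and ``log.txt``.
    """
    outdir = str(config.outdir)
    os.makedirs(outdir, exist_ok=True)
    log: list[str] = [f"ssmap {__version__}", f"seed {config.seed}"]
    summary: dict = {"version": __version__, "seed": config.seed}
    config.to_yaml(os.path.join(outdir, "config.resolved.yaml"))

    # --- simulate (or ingest) -------------------------------------------
    genome = mutations = result = None
    if config.mut_vcf is None:
        try:
            genome, mutations, result, _ = _simulate_stage(config, outdir, log)
        except SsmapError as exc:
            raise StageError("simulate", str(exc)) from exc
        mut_records, bg_records = result.mut_records, result.bg_records
    else:
        if config.bg_vcf is None:
            raise InputError("mut_vcf given without bg_vcf")
        mut_records = snpindex.read_variants(config.mut_vcf, "mutant")
        bg_records = snpindex.read_variants(config.bg_vcf, "background")
        log.append(
            f"ingest: {len(mut_records)} mutant / {len(bg_records)} "
            "background variant records"
        )

    # --- snpindex --------------------------------------------------------
    try:
        records = snpindex.build_snpindex_records(
            mut_records,
            bg_records,
            min_depth=config.min_depth,
            min_qual=config.min_qual,
            threshold=config.delta_threshold,
        )
        candidates = snpindex.call_candidates(records, config.delta_threshold)
        snpindex.write_snpindex_table(
            records, os.path.join(outdir, "snp_index.tsv")
        )
        snpindex.write_plot_data(records, outdir)
    except SsmapError as exc:
        raise StageError("snpindex", str(exc)) from exc
    n_pass = sum(r.filter_status == "PASS" for r in records)
    reasons = pd.Series(
        [r.filter_status for r in records if r.filter_status != "PASS"]
    )
    summary["n_sites"] = len(records)
    summary["n_pass"] = n_pass
    summary["n_removed"] = {
        str(k): int(v) for k, v in reasons.value_counts().sort_index().items()
    }
    summary["n_candidates"] = len(candidates)
    summary["candidates"] = [
        {"chrom": c.chrom, "pos": c.pos, "delta": round(c.delta, 6)}
        for c in candidates[:25]
    ]
    log.append(
        f"snpindex: {n_pass}/{len(records)} sites pass filters, "
        f"{len(candidates)} candidates at delta <= {config.delta_threshold}"
    )

    if mutations is not None and mutations.causal is not None:
        causal = mutations.causal
        causal_rec = next(
            (r for r in records if (r.chrom, r.pos) == (causal.chrom, causal.pos)),
            None,
        )
        chrom_min = min(
            (
                r.delta
                for r in records
                if r.chrom == causal.chrom and r.filter_status == "PASS"
            ),
            default=float("nan"),
        )
        summary["causal"] = {
            "chrom": causal.chrom,
            "pos": causal.pos,
            "delta": round(causal_rec.delta, 6) if causal_rec else None,
            "is_candidate": bool(causal_rec.candidate) if causal_rec else False,
            "chromosome_min_delta": round(chrom_min, 6),
            "attains_chromosome_min": bool(
                causal_rec is not None and causal_rec.delta <= chrom_min
            ),
        }

    # --- annotate the top candidate region ------------------------------
    if config.do_annotate and candidates and genome is not None:
        try:
            top = candidates[0]
            gene = _gene_model_around(genome, top.chrom, top.pos)
            chrom_seq = genome.sequence(top.chrom).tobytes().decode()
            effects = annotate.annotate_candidates(
                [c for c in candidates if gene.chrom == c.chrom],
                [gene],
                {top.chrom: chrom_seq},
            )
            effects.to_csv(os.path.join(outdir, "effects.tsv"), sep="\t", index=False)
            first = effects.iloc[0]
            summary["top_candidate_effect"] = {
                k: (None if pd.isna(first[k]) else (int(first[k]) if k in
                    ("pos", "cds_pos", "codon_index", "pos_in_codon") else str(first[k])))
                for k in ("chrom", "pos", "gene_id", "cds_pos", "codon_index",
                          "ref_aa", "alt_aa", "effect")
            }
            log.append(
                f"annotate: top candidate {top.chrom}:{top.pos} -> "
                f"{first['effect']}"
            )
        except SsmapError as exc:
            raise StageError("annotate", str(exc)) from exc

    # --- linkage ---------------------------------------------------------
    if config.do_linkage and result is not None:
        try:
            markers = _marker_positions(genome, config.markers_per_chromosome)
            selected_plants = [result.plants[i] for i in result.selected]
            geno = simulate.genotype_markers(selected_plants, markers)
            marker_map = pd.DataFrame(
                [{"marker": m, "chrom": c, "pos": p} for m, c, p in markers]
            )
            geno.to_csv(os.path.join(outdir, "marker_genotypes.csv"), index=False)
            marker_map.to_csv(os.path.join(outdir, "marker_map.csv"), index=False)
            table = linkage.MarkerTable(genotypes=geno, markers=marker_map)
            model_name = (
                "selected_dominant" if config.dominance_h > 0.5
                else "selected_recessive"
            )
            ranking = linkage.rank_markers(table, model_name)
            ranking.to_csv(os.path.join(outdir, "linkage.tsv"), sep="\t", index=False)
            best = ranking.iloc[0]
            summary["linkage"] = {
                "model": model_name,
                "top_marker": str(best["marker"]),
                "chrom": str(best["chrom"]),
                "rhat": round(float(best["rhat"]), 6),
            }
            log.append(
                f"linkage: lowest recombination frequency with "
                f"{best['marker']} (r = {best['rhat']:.3f})"
            )
        except SsmapError as exc:
            raise StageError("linkage", str(exc)) from exc

    # --- dCAPS assay for the top candidate ------------------------------
    if config.do_dcaps and candidates and genome is not None:
        try:
            top = candidates[0]
            seq = genome.sequence(top.chrom).tobytes().decode()
            lo = max(0, top.pos - 1 - config.dcaps_flank)
            hi = min(len(seq), top.pos + config.dcaps_flank)
            flank5 = seq[lo : top.pos - 1]
            flank3 = seq[top.pos : hi]
            designs = dcaps.design_dcaps(
                flank5,
                (top.ref, top.alt),
                flank3,
                max_mismatch=config.max_mismatch,
                primer_length=config.primer_length,
            )
            rows = [
                {
                    "enzyme": d.enzyme.name,
                    "site": d.enzyme.site,
                    "n_mismatches": d.n_mismatches,
                    "primer": d.primer,
                    "cut_allele": d.cut_allele,
                    "fragments_cut": ",".join(map(str, d.fragments[d.cut_allele])),
                    "fragments_uncut": ",".join(map(str, d.fragments[d.uncut_allele])),
                }
                for d in designs
            ]
            pd.DataFrame(
                rows,
                columns=["enzyme", "site", "n_mismatches", "primer", "cut_allele",
                         "fragments_cut", "fragments_uncut"],
            ).to_csv(os.path.join(outdir, "dcaps.tsv"), sep="\t", index=False)
            summary["dcaps"] = rows[0] if rows else None
            log.append(
                f"dcaps: {len(designs)} assay(s) for {top.chrom}:{top.pos}"
                + (f", best = {rows[0]['enzyme']}" if rows else "")
            )
        except SsmapError as exc:
            raise StageError("dcaps", str(exc)) from exc

    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(outdir, "log.txt"), "w") as fh:
        fh.write("\n".join(log) + "\n")
    return summary


def _gene_model_around(
    genome: simulate.GenomeSpec, chrom: str, pos: int, n_codons: int = 306
) -> annotate.GeneModel:
    """A synthetic single-exon gene model covering a position, for annotation.

    Stands in for real gene annotation when the pipeline runs on simulated
    genomes, which carry no gene models of their own.
    """
    length = genome.length(chrom)
    cds_len = 3 * n_codons
    start = max(1, min(pos - cds_len // 2, length - cds_len + 1))
    return annotate.GeneModel(
        gene_id=f"synthetic_gene_{chrom}_{start}",
        chrom=chrom,
        strand="+",
        segments=((start, start + cds_len - 1),),
    )
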