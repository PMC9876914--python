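"""Codon-level annotation of the recessive screen's candidate SNPs.

Places a synthetic 306-codon gene model over the top candidate and
classifies every candidate on that chromosome; also prints the package's
worked example: a C->T transition at CDS position 683 of an alanine-codon
gene, which falls at position 2 of codon 228 and converts Ala to Val.

Writes results/screen_recessive/effects.tsv.
"""
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common  # noqa: E402

from ssmap import annotate, experiments, snpindex  # noqa: E402
from ssmap.pipeline import _gene_model_around  # noqa: E402


def main():
    eff = experiments.codon228_worked_example()
    print(
        f"worked example: C->T at CDS {eff.cds_pos} -> codon {eff.codon_index} "
        f"position {eff.pos_in_codon}, {eff.ref_codon}->{eff.alt_codon}, "
        f"{eff.ref_aa}{eff.codon_index}{eff.alt_aa} ({eff.effect_class})"
    )

    outdir = common.screen_dir(0.0)
    cand_path = outdir / "candidates.tsv"
    if not cand_path.exists():
        sys.exit("run 02_snpindex_mapping.py first")
    cands = pd.read_csv(cand_path, sep="\t").sort_values("delta")
    top = cands.iloc[0]
    genome = common.study_genome()
    gene = _gene_model_around(genome, top["chrom"], int(top["pos"]))
    chrom_seq = genome.sequence(gene.chrom).tobytes().decode()
    records = [
        snpindex.VariantRecord(r.chrom, int(r.pos), r.ref, r.alt, 0, 1)
        for r in cands.itertuples()
        if r.chrom == gene.chrom
    ]
    effects = annotate.annotate_candidates(records, [gene], {gene.chrom: chrom_seq})
    effects.to_csv(outdir / "effects.tsv", sep="\t", index=False)
    coding = effects[effects["effect"] != "non-coding"]
    print(
        f"annotated {len(effects)} candidates on {gene.chrom}; "
        f"{len(coding)} fall in the synthetic gene model "
        f"({', '.join(coding['effect'].unique()) if len(coding) else 'none'})"
    )
    print(f"wrote {outdir / 'effects.tsv'}")


if __name__ == "__main__":
    main()
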