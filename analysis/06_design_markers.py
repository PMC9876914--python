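"""CAPS/dCAPS genotyping-assay design for the causal SNP.

Takes the causal SNP of the recessive screen with 200 bp of flanking
sequence and searches the packaged restriction-enzyme table for assays that
cut exactly one allele - naturally (CAPS) or after introducing up to two
primer mismatches next to the SNP (dCAPS).  Each design is verified by
in-silico digestion of both allelic amplicons.

Writes results/screen_recessive/dcaps_designs.tsv.
"""
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common  # noqa: E402

from ssmap import dcaps  # noqa: E402

FLANK = 200


def main():
    genome = common.study_genome()
    mutations = common.study_mutations(genome)
    causal = mutations.causal
    seq = genome.sequence(causal.chrom).tobytes().decode()
    flank5 = seq[causal.pos - 1 - FLANK : causal.pos - 1]
    flank3 = seq[causal.pos : causal.pos + FLANK]
    designs = dcaps.design_dcaps(flank5, (causal.ref, causal.alt), flank3)
    rows = [
        {
            "enzyme": d.enzyme.name,
            "site": d.enzyme.site,
            "n_mismatches": d.n_mismatches,
            "primer_3prime_end": d.primer[-10:],
            "cut_allele": d.cut_allele,
            "fragments_cut_allele": ",".join(map(str, d.fragments[d.cut_allele])),
            "fragments_uncut_allele": ",".join(map(str, d.fragments[d.uncut_allele])),
        }
        for d in designs
    ]
    outdir = common.screen_dir(0.0)
    outdir.mkdir(parents=True, exist_ok=True)
    out = outdir / "dcaps_designs.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    print(
        f"causal SNP {causal.chrom}:{causal.pos} {causal.ref}>{causal.alt}: "
        f"{len(designs)} validated assay(s) "
        f"({sum(d.is_caps for d in designs)} natural CAPS)"
    )
    if designs:
        best = designs[0]
        print(
            f"best: {best.enzyme.name} ({best.enzyme.site}), "
            f"{best.n_mismatches} mismatch(es), cuts the {best.cut_allele} allele "
            f"into {best.fragments[best.cut_allele]}"
        )
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
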