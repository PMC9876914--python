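"""Simulate one recessive and one dominant suppressor screen.

Generates the study-condition BC1F2 screens (115 plants, 35 selected, ~60x
pooled sequencing, ~700 EMS-induced SNPs over ~4800 shared background SNPs)
and writes, per screen, the two pool VCFs and the ground-truth table under
results/screen_{recessive,dominant}/.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common  # noqa: E402

from ssmap import simulate  # noqa: E402


def main():
    for h, label in ((0.0, "recessive"), (1.0, "dominant")):
        genome, mutations, result = common.realized_screen(h)
        outdir = common.screen_dir(h)
        simulate.write_truth_and_vcf(
            result.mut_records,
            result.bg_records,
            mutations,
            result.freq_mut_pool,
            result.freq_bg_pool,
            genome,
            outdir,
        )
        causal = mutations.causal
        idx = next(i for i, m in enumerate(mutations) if m.origin == "causal")
        print(
            f"[{label}] {len(mutations)} segregating sites "
            f"({len(mutations.by_origin('induced', 'causal'))} EMS-induced), "
            f"{len(result.selected)}/{len(result.plants)} plants selected; "
            f"causal {causal.chrom}:{causal.pos} "
            f"pool frequency {result.freq_mut_pool[idx]:.3f} -> {outdir}"
        )


if __name__ == "__main__":
    main()
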