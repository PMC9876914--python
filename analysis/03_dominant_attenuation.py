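"""Dominant versus recessive enrichment of the causal allele.

Replicates the screen 200 times under each dominance model and compares the
causal-locus ΔSNP index.  With recessive action the selected pool is
homozygous and Δ tends to -1; with full dominance heterozygotes are selected
too (2/3 of carriers), the pool allele frequency tends to 2/3, and Δ is
capped near -2/3 - which is why a dominantly segregating suppressor never
produces candidates below -0.8 and blunts bulk-segregant mapping.

Writes results/dominance_attenuation.tsv.
"""
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common  # noqa: E402

from ssmap import experiments  # noqa: E402

N_REPS = 200


def main():
    rows = []
    for h, label in ((0.0, "recessive"), (1.0, "dominant")):
        deltas = experiments.causal_delta_replicates(
            N_REPS, h=h, seed=common.SEED + int(h)
        )
        rows.append(
            {
                "model": label,
                "h": h,
                "n_replicates": N_REPS,
                "mean_delta": round(float(np.mean(deltas)), 4),
                "sd_delta": round(float(np.std(deltas, ddof=1)), 4),
                "analytic_expectation": -1.0 if h == 0 else round(-2 / 3, 4),
                "frac_below_-0.7": round(float(np.mean(deltas <= -0.7)), 3),
            }
        )
        print(
            f"[{label}] causal-locus delta over {N_REPS} screens: "
            f"mean {rows[-1]['mean_delta']} (sd {rows[-1]['sd_delta']}), "
            f"analytic {rows[-1]['analytic_expectation']}, "
            f"flagged at -0.7 in {rows[-1]['frac_below_-0.7']:.0%} of screens"
        )
    common.RESULTS.mkdir(exist_ok=True)
    out = common.RESULTS / "dominance_attenuation.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
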