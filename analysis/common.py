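"""Shared conditions for the numbered analysis drivers.

One master seed; every driver re-derives the same deterministic screen, so
scripts can be run independently and still describe the same experiment.
"""
from pathlib import Path

from ssmap import experiments, simulate
from ssmap.rng import stage_rng

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_genome():
    return experiments.default_genome(seed=SEED)


def study_mutations(genome):
    return experiments.default_mutations(genome, stage_rng(SEED, "mutations"))


def realized_screen(h: float):
    """The deterministic realized screen analysed throughout the drivers."""
    genome = study_genome()
    mutations = study_mutations(genome)
    model = simulate.PhenotypeModel(h=h)
    pool = simulate.PoolSpec()
    result = experiments.run_single_screen(
        genome, mutations, model, pool, seed=stage_rng(SEED, f"screen-h{h:g}")
    )
    return genome, mutations, result


def screen_dir(h: float) -> Path:
    name = "screen_recessive" if h == 0 else "screen_dominant"
    return RESULTS / name
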