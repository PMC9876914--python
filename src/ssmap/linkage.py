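"""Marker-wise recombination-frequency estimation in phenotype-selected pools.

The mapping individuals are segregants selected for the suppressor
phenotype, so the genotype distribution at the trait locus is conditioned on
selection:

* ``selected_recessive`` - only homozygous carriers are selected; every
  other-parent allele at a marker then reflects one recombination event, and
  r is estimated by allele counting: r = (#B alleles) / (2 n).
* ``selected_dominant`` - heterozygotes show the phenotype too, so the trait
  genotype of a selected plant is homozygous with probability 1/3 and
  heterozygous with probability 2/3; r is estimated by maximizing the
  corresponding mixture likelihood of the observed marker genotypes.

Genotype codes: A = mutant-parent homozygote, H = heterozygote,
B = other-parent homozygote, ``-`` = missing (dropped pairwise per marker).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import InputError

__all__ = [
    "MarkerTable",
    "RfEstimate",
    "estimate_rf",
    "rank_markers",
    "segregation_chi2",
    "read_marker_table",
]

_CODES = {"A", "H", "B", "-"}


@dataclass
class MarkerTable:
    """Genotype matrix (individuals x markers) plus marker map positions."""

    genotypes: pd.DataFrame  # values in {A, H, B, -}
    markers: pd.DataFrame  # columns: marker, chrom, pos

    def __post_init__(self):
        bad = set(np.unique(self.genotypes.to_numpy().astype(str))) - _CODES
        if bad:
            raise InputError(f"unknown genotype codes: {sorted(bad)}")
        missing = set(self.genotypes.columns) - set(self.markers["marker"])
        if missing:
            raise InputError(f"markers without map positions: {sorted(missing)}")
        self.markers = self.markers.sort_values(
            ["chrom", "pos"], kind="mergesort"
        ).reset_index(drop=True)

    def calls(self, marker: str) -> np.ndarray:
        if marker not in self.genotypes.columns:
            raise InputError(f"unknown marker {marker!r}")
        calls = self.genotypes[marker].astype(str).to_numpy()
        return calls[calls != "-"]


@dataclass(frozen=True)
class RfEstimate:
    marker: str
    rhat: float  # clamped to [0, 0.5]
    n: int  # informative individuals
    se: float
    unlinked: bool  # raw estimate exceeded 0.5
    model: str


def _genotype_probs(r: float, model: str) -> dict[str, float]:
    """P(marker genotype | selection model, recombination fraction r)."""
    hom = {"A": (1 - r) ** 2, "H": 2 * r * (1 - r), "B": r**2}
    if model == "selected_recessive":
        return hom
    het = {"A": r * (1 - r), "H": (1 - r) ** 2 + r**2, "B": r * (1 - r)}
    return {g: hom[g] / 3 + 2 * het[g] / 3 for g in "AHB"}


def _nll(r: float, counts: dict[str, int], model: str) -> float:
    probs = _genotype_probs(r, model)
    return -sum(
        n * np.log(max(probs[g], 1e-300)) for g, n in counts.items() if n > 0
    )


def estimate_rf(
    table: MarkerTable, marker: str, model: str = "selected_recessive"
) -> RfEstimate:
    """Recombination fraction between a marker and the selected trait locus."""
    if model not in ("selected_recessive", "selected_dominant"):
        raise InputError(f"unknown selection model {model!r}")
    calls = table.calls(marker)
    n = len(calls)
    if n == 0:
        raise InputError(f"marker {marker!r} has no non-missing genotypes")
    counts = {g: int((calls == g).sum()) for g in "AHB"}

    if model == "selected_recessive":
        # every B allele in a homozygous-selected plant is one recombination
        raw = (counts["H"] + 2 * counts["B"]) / (2.0 * n)
        rhat = min(raw, 0.5)
        se = float(np.sqrt(max(rhat * (1 - rhat), 0.0) / (2.0 * n)))
        return RfEstimate(marker, rhat, n, se, raw > 0.5, model)

    res = optimize.minimize_scalar(
        _nll, bounds=(1e-9, 0.5), args=(counts, model), method="bounded",
        options={"xatol": 1e-10},
    )
    raw = float(res.x)
    # one-dimensional observed information by central differences
    h = 1e-5
    lo, hi = max(raw - h, 1e-9), min(raw + h, 0.5)
    info = (_nll(hi, counts, model) - 2 * _nll(raw, counts, model)
            + _nll(lo, counts, model)) / ((hi - raw) * (raw - lo))
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("nan")
    # boundary maximum at 0.5 signals an effectively unlinked marker
    unlinked = raw >= 0.5 - 1e-6
    return RfEstimate(marker, min(raw, 0.5), n, se, unlinked, model)


def rank_markers(
    table: MarkerTable, model: str = "selected_recessive"
) -> pd.DataFrame:
    """All markers sorted by estimated r ascending; ties by (chrom, pos).

    The top marker flags the candidate region for the causal locus.
    """
    if table.genotypes.shape[1] < 2:
        raise InputError("ranking requires at least two markers")
    pos = table.markers.set_index("marker")
    rows = []
    for marker in table.genotypes.columns:
        est = estimate_rf(table, marker, model)
        rows.append(
            {
                "marker": marker,
                "chrom": pos.loc[marker, "chrom"],
                "pos": int(pos.loc[marker, "pos"]),
                "rhat": est.rhat,
                "se": est.se,
                "n": est.n,
                "unlinked": est.unlinked,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["rhat", "chrom", "pos"], kind="mergesort"
    ).reset_index(drop=True)


def segregation_chi2(
    counts: Sequence[int], ratio: Sequence[float] = (1, 2, 1)
) -> tuple[float, int]:
    """Pearson chi-square of observed A/H/B counts against an expected ratio.

    Returns (statistic, degrees of freedom).  Used as a marker-quality check
    in an unselected F2, where the expectation is 1:2:1.
    """
    counts = np.asarray(counts, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    if counts.sum() <= 0:
        raise InputError("total count must be positive")
    if len(counts) != len(ratio):
        raise InputError("counts and ratio must have the same length")
    expected = counts.sum() * ratio / ratio.sum()
    if np.any(expected == 0):
        raise InputError("expected class count of zero")
    chi2, _ = stats.chisquare(counts, expected)
    return float(chi2), len(counts) - 1


def read_marker_table(genotypes_csv, map_csv) -> MarkerTable:
    """Load genotypes (rows = individuals) and a marker map from CSV files."""
    geno = pd.read_csv(genotypes_csv, dtype=str)
    if geno.columns[0].lower() in ("individual", "id", "plant"):
        geno = geno.set_index(geno.columns[0])
    marker_map = pd.read_csv(map_csv)
    required = {"marker", "chrom", "pos"}
    if not required.issubset(marker_map.columns):
        raise InputError(f"marker map needs columns {sorted(required)}")
    return MarkerTable(genotypes=geno.fillna("-"), markers=marker_map)
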