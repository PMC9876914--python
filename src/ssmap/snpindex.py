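"""Bulk-segregant SNP-index statistics for phenotype-selected pools.

The mapping statistic works on two pooled-sequencing variant sets: a pool of
phenotype-selected segregants ("mutant pool") and a pool of the
non-mutagenized parental line ("background pool").  Per biallelic site the
SNP index is the fraction of reads carrying the non-reference base,

    index = alt_depth / (ref_depth + alt_depth),

and the ΔSNP index contrasts the two pools,

    Δ = index_bg - index_mut,

so a SNP that is absent from the background and fixed in the selected pool
scores Δ = -1.  Sites shared with the background pool, low-depth sites,
low-quality sites and multi-allelic sites are filtered before candidate
calling; candidates are sites with Δ at or below a threshold (default -0.7).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import FormatError, UndefinedIndexError

__all__ = [
    "VariantRecord",
    "SnpIndexRecord",
    "read_variants",
    "filter_variants",
    "snp_index",
    "delta_snp_index",
    "build_snpindex_records",
    "call_candidates",
    "records_to_frame",
    "write_snpindex_table",
    "write_plot_data",
    "windowed_delta",
]

#: default candidate threshold on the ΔSNP index
DELTA_THRESHOLD = -0.7


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic site with per-pool reference/non-reference read depths."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    ref_depth: int
    alt_depth: int
    qual: float | None = None
    multiallelic: bool = False
    low_quality: bool = False

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValueError("read depths must be non-negative")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)

    @property
    def depth(self) -> int:
        return self.ref_depth + self.alt_depth


@dataclass(frozen=True)
class SnpIndexRecord:
    """Per-site SNP indices for both pools plus the ΔSNP index.

    ``index_bg`` is ``None`` for sites absent from (or filtered out of) the
    background pool; the Δ computation then takes the background index as 0,
    since a site surviving the shared-SNP filter is background-absent by
    construction.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    ref_depth: int
    alt_depth: int
    index_mut: float
    index_bg: float | None
    delta: float
    filter_status: str  # "PASS" or the single removal reason
    candidate: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)


def read_variants(vcf_path, pool_label: str | None = None) -> list[VariantRecord]:
    """Parse a VCF into :class:`VariantRecord` objects.

    The VCF must carry per-sample allele depths in the ``AD`` FORMAT field
    (first value = reference depth, remainder = alternate depths).  One
    record is produced per row; rows with more than one ALT allele are kept
    but flagged ``multiallelic`` (their first ALT is reported) so the filter
    stage can drop them with an explicit reason.
    """
    try:
        vf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot open VCF {vcf_path}: {exc}") from exc
    with vf:
        if "AD" not in vf.header.formats:
            raise FormatError(
                f"VCF {vcf_path} lacks the AD FORMAT field required for "
                "per-allele read depths"
            )
        samples = list(vf.header.samples)
        if not samples:
            raise FormatError(f"VCF {vcf_path} has no sample column")
        records: list[VariantRecord] = []
        for line_no, rec in enumerate(vf, start=1):
            try:
                if not rec.alts:
                    continue
                ad = rec.samples[samples[0]].get("AD")
                if ad is None or ad[0] is None:
                    raise FormatError(
                        f"row {line_no} ({rec.chrom}:{rec.pos}) has no AD value"
                    )
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=rec.alts[0],
                        ref_depth=int(ad[0]),
                        alt_depth=int(ad[1]) if len(ad) > 1 and ad[1] is not None else 0,
                        qual=rec.qual,
                        multiallelic=len(rec.alts) > 1,
                    )
                )
            except FormatError:
                raise
            except Exception as exc:  # malformed row: report its position
                raise FormatError(
                    f"malformed VCF row {line_no} in {vcf_path}: {exc}"
                ) from exc
    return records


def snp_index(record: VariantRecord) -> float:
    """Fraction of reads supporting the non-reference base at one site."""
    total = record.ref_depth + record.alt_depth
    if total == 0:
        raise UndefinedIndexError(
            f"zero total depth at {record.chrom}:{record.pos}; "
            "the site should have been depth-filtered"
        )
    return record.alt_depth / total


def delta_snp_index(index_bg: float | None, index_mut: float) -> float:
    """ΔSNP index = background index minus mutant-pool index.

    A background-filtered site contributes ``index_bg = 0`` (pass ``None``),
    so a SNP unique to and fixed in the mutant pool scores -1.
    """
    bg = 0.0 if index_bg is None else index_bg
    if not (0.0 <= bg <= 1.0) or not (0.0 <= index_mut <= 1.0):
        raise ValueError("SNP indices must lie in [0, 1]")
    return bg - index_mut


def _background_present(
    bg: VariantRecord | None, min_reads: int, min_freq: float
) -> bool:
    """Is the alternate allele genuinely present in the background pool?

    A handful of error reads must not count as presence, so the site needs
    both an absolute read support and a minimum allele frequency.
    """
    if bg is None or bg.depth == 0:
        return False
    return bg.alt_depth >= min_reads and (bg.alt_depth / bg.depth) >= min_freq


def filter_variants(
    mut: Sequence[VariantRecord],
    bg: Sequence[VariantRecord],
    min_depth: int = 10,
    min_qual: float = 20.0,
    bg_presence_reads: int = 2,
    bg_presence_freq: float = 0.1,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Apply the pre-mapping filters to the mutant-pool variants.

    Removes, with exactly one recorded reason per site (checked in a fixed
    precedence so the labelling is order-independent):

    * ``multi-allelic`` - more than one ALT allele,
    * ``low-quality``   - QUAL below ``min_qual`` (or flagged upstream),
    * ``low-depth``     - total depth below ``min_depth``,
    * ``shared-with-background`` - the alternate allele is present in the
      background pool, so the SNP predates the mutagenesis.

    Returns ``(kept, removed)`` where ``removed`` pairs each record with its
    reason.  Filtering is idempotent: running it on ``kept`` again removes
    nothing.
    """
    bg_by_key = {r.key: r for r in bg}
    kept: list[VariantRecord] = []
    removed: list[tuple[VariantRecord, str]] = []
    for rec in mut:
        if rec.multiallelic:
            removed.append((rec, "multi-allelic"))
        elif rec.low_quality or (rec.qual is not None and rec.qual < min_qual):
            removed.append((rec, "low-quality"))
        elif rec.depth < min_depth:
            removed.append((rec, "low-depth"))
        elif _background_present(
            bg_by_key.get(rec.key), bg_presence_reads, bg_presence_freq
        ):
            removed.append((rec, "shared-with-background"))
        else:
            kept.append(rec)
    return kept, removed


def build_snpindex_records(
    mut: Sequence[VariantRecord],
    bg: Sequence[VariantRecord],
    min_depth: int = 10,
    min_qual: float = 20.0,
    threshold: float = DELTA_THRESHOLD,
    bg_presence_reads: int = 2,
    bg_presence_freq: float = 0.1,
) -> list[SnpIndexRecord]:
    """Filter, compute per-site indices, and flag candidates.

    All mutant-pool sites are reported; removed sites carry their removal
    reason in ``filter_status`` and can never be candidates.  For surviving
    sites the background index is ``None`` (background-absent by
    construction) and Δ = -index_mut.
    """
    bg_by_key = {r.key: r for r in bg}
    kept, removed = filter_variants(
        mut, bg, min_depth, min_qual, bg_presence_reads, bg_presence_freq
    )
    status = {rec.key: reason for rec, reason in removed}

    out: list[SnpIndexRecord] = []
    for rec in mut:
        reason = status.get(rec.key, "PASS")
        idx_mut = snp_index(rec) if rec.depth > 0 else float("nan")
        bg_rec = bg_by_key.get(rec.key)
        if reason == "PASS":
            idx_bg = None  # survived the shared filter => background-absent
        else:
            idx_bg = (
                snp_index(bg_rec) if bg_rec is not None and bg_rec.depth > 0 else None
            )
        delta = (
            delta_snp_index(idx_bg, idx_mut) if np.isfinite(idx_mut) else float("nan")
        )
        candidate = reason == "PASS" and delta <= threshold
        out.append(
            SnpIndexRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=rec.alt,
                ref_depth=rec.ref_depth,
                alt_depth=rec.alt_depth,
                index_mut=idx_mut,
                index_bg=idx_bg,
                delta=delta,
                filter_status=reason,
                candidate=candidate,
            )
        )
    return out


def call_candidates(
    records: Sequence[SnpIndexRecord], threshold: float = DELTA_THRESHOLD
) -> list[SnpIndexRecord]:
    """Candidate causal SNPs: passed sites with Δ at or below the threshold.

    Sorted by Δ ascending, ties broken by (chrom, pos) for determinism.
    """
    cands = [
        r for r in records if r.filter_status == "PASS" and r.delta <= threshold
    ]
    return sorted(cands, key=lambda r: (r.delta, r.chrom, r.pos))


def records_to_frame(records: Iterable[SnpIndexRecord]) -> pd.DataFrame:
    """Tabulate SNP-index records (one row per site)."""
    rows = [
        {
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "ref_depth": r.ref_depth,
            "alt_depth": r.alt_depth,
            "index_mut": r.index_mut,
            "index_bg": r.index_bg,
            "delta": r.delta,
            "filter": r.filter_status,
            "candidate": r.candidate,
        }
        for r in records
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "ref_depth",
            "alt_depth",
            "index_mut",
            "index_bg",
            "delta",
            "filter",
            "candidate",
        ],
    )
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_snpindex_table(records: Iterable[SnpIndexRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def write_plot_data(records: Iterable[SnpIndexRecord], outdir) -> list[str]:
    """Per-chromosome (pos, delta, candidate) tables for plotting Δ profiles."""
    import os

    df = records_to_frame(records)
    df = df[df["filter"] == "PASS"]
    written = []
    for chrom, sub in df.groupby("chrom", sort=True):
        path = os.path.join(str(outdir), f"delta_{chrom}.tsv")
        sub[["pos", "delta", "candidate"]].to_csv(path, sep="\t", index=False)
        written.append(path)
    return written


def windowed_delta(
    records: Sequence[SnpIndexRecord], window_bp: int, step_bp: int | None = None
) -> pd.DataFrame:
    """Optional sliding-window mean of Δ along each chromosome.

    The candidate caller works on raw per-SNP values (the default); this
    smoother is provided for visual inspection only.
    """
    step_bp = step_bp or max(window_bp // 2, 1)
    df = records_to_frame(records)
    df = df[df["filter"] == "PASS"]
    rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        delta = sub["delta"].to_numpy()
        if len(pos) == 0:
            continue
        for start in range(1, int(pos.max()) + 1, step_bp):
            mask = (pos >= start) & (pos < start + window_bp)
            if mask.any():
                rows.append(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": start + window_bp - 1,
                        "n_snps": int(mask.sum()),
                        "mean_delta": float(delta[mask].mean()),
                    }
                )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "mean_delta"])
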