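"""Codon-level annotation of candidate SNPs on gene models.

Maps genomic positions onto coding-sequence (CDS) coordinates of a gene
model, classifies substitutions as synonymous / missense / nonsense using
the standard nuclear genetic code, and reports the affected codon and amino
acid.  Coordinates follow GFF3 conventions: 1-based, inclusive.  Only CDS
features are used; anything outside them is classified ``non-coding``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from Bio.Seq import Seq

from .errors import DataIntegrityError, InputError

__all__ = [
    "GeneModel",
    "VariantEffect",
    "map_genomic_to_cds",
    "cds_to_genomic",
    "classify_variant",
    "extract_cds_sequence",
    "read_gene_models",
    "annotate_candidates",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene as an ordered list of CDS segments.

    ``segments`` are (start, end) pairs, 1-based inclusive, stored in
    ascending genomic order; transcript orientation follows ``strand``.
    The total CDS length must be divisible by 3.
    """

    gene_id: str
    chrom: str
    strand: str
    segments: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise InputError(f"strand must be + or -, got {self.strand!r}")
        segs = tuple(sorted((int(a), int(b)) for a, b in self.segments))
        if not segs:
            raise InputError(f"gene {self.gene_id} has no CDS segments")
        for (a, b) in segs:
            if a > b or a < 1:
                raise InputError(f"bad CDS segment ({a}, {b}) in {self.gene_id}")
        for (_, b1), (a2, _) in zip(segs, segs[1:]):
            if a2 <= b1:
                raise InputError(f"overlapping CDS segments in {self.gene_id}")
        object.__setattr__(self, "segments", segs)
        if self.cds_length % 3 != 0:
            raise InputError(
                f"CDS length of {self.gene_id} ({self.cds_length}) "
                "is not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.segments)


@dataclass(frozen=True)
class VariantEffect:
    """Coding consequence of a single-base substitution."""

    gene_id: str
    cds_pos: int  # 1-based position in the coding sequence
    codon_index: int  # 1-based codon / amino-acid number
    pos_in_codon: int  # 1, 2 or 3
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    effect_class: str  # synonymous | missense | nonsense | non-coding


def map_genomic_to_cds(gene: GeneModel, genomic_pos: int) -> int | None:
    """CDS coordinate of a genomic position, or ``None`` if non-coding.

    On the + strand the CDS coordinate is the offset within the concatenated
    segments; on the - strand it is counted from the 3'-most genomic base of
    the segment set (the first coding base of a minus-strand gene).
    """
    if genomic_pos < 1:
        raise InputError("genomic position must be >= 1")
    segments = gene.segments if gene.strand == "+" else gene.segments[::-1]
    offset = 0
    for a, b in segments:
        if a <= genomic_pos <= b:
            if gene.strand == "+":
                return offset + (genomic_pos - a + 1)
            return offset + (b - genomic_pos + 1)
        offset += b - a + 1
    return None


def cds_to_genomic(gene: GeneModel, cds_pos: int) -> int:
    """Inverse of :func:`map_genomic_to_cds` for coding positions."""
    if not 1 <= cds_pos <= gene.cds_length:
        raise InputError(f"CDS position {cds_pos} outside 1..{gene.cds_length}")
    segments = gene.segments if gene.strand == "+" else gene.segments[::-1]
    offset = 0
    for a, b in segments:
        seg_len = b - a + 1
        if cds_pos <= offset + seg_len:
            within = cds_pos - offset
            return a + within - 1 if gene.strand == "+" else b - within + 1
        offset += seg_len
    raise AssertionError("unreachable")


def classify_variant(
    gene: GeneModel,
    cds_pos: int,
    ref: str,
    alt: str,
    cds_seq: str,
) -> VariantEffect:
    """Classify a substitution given in genomic-strand bases.

    ``cds_seq`` is the coding sequence in transcript orientation; for
    minus-strand genes the genomic ``ref``/``alt`` bases are complemented
    before comparison.  The reference base must match the CDS sequence,
    otherwise a :class:`DataIntegrityError` reports both bases.
    """
    cds_seq = str(cds_seq).upper()
    if len(cds_seq) != gene.cds_length:
        raise InputError(
            f"CDS sequence length {len(cds_seq)} does not match the "
            f"gene model ({gene.cds_length})"
        )
    if not 1 <= cds_pos <= gene.cds_length:
        raise InputError(f"CDS position {cds_pos} outside 1..{gene.cds_length}")
    ref, alt = ref.upper(), alt.upper()
    if gene.strand == "-":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    if cds_seq[cds_pos - 1] != ref:
        raise DataIntegrityError(
            f"reference mismatch at CDS position {cds_pos} of {gene.gene_id}: "
            f"sequence has {cds_seq[cds_pos - 1]}, variant claims {ref}"
        )
    codon_index = math.ceil(cds_pos / 3)
    pos_in_codon = (cds_pos - 1) % 3 + 1
    start = (codon_index - 1) * 3
    ref_codon = cds_seq[start : start + 3]
    alt_codon = ref_codon[: pos_in_codon - 1] + alt + ref_codon[pos_in_codon:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        effect = "synonymous"
    elif alt_aa == "*":
        effect = "nonsense"
    else:
        effect = "missense"
    return VariantEffect(
        gene_id=gene.gene_id,
        cds_pos=cds_pos,
        codon_index=codon_index,
        pos_in_codon=pos_in_codon,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        effect_class=effect,
    )


def extract_cds_sequence(gene: GeneModel, chrom_seq: str) -> str:
    """Coding sequence in transcript orientation from a chromosome sequence."""
    parts = [chrom_seq[a - 1 : b].upper() for a, b in gene.segments]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def read_gene_models(gff_path) -> list[GeneModel]:
    """Load single-transcript gene models (CDS features only) from GFF3."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    by_parent: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        parent = cds.attributes.get("Parent", [cds.id or "cds"])[0]
        by_parent.setdefault(parent, []).append(cds)
    genes = []
    for parent, features in sorted(by_parent.items()):
        strands = {f.strand for f in features}
        chroms = {f.seqid for f in features}
        if len(strands) != 1 or len(chroms) != 1:
            raise InputError(f"inconsistent CDS features for {parent}")
        genes.append(
            GeneModel(
                gene_id=parent,
                chrom=chroms.pop(),
                strand=strands.pop(),
                segments=tuple((f.start, f.end) for f in features),
            )
        )
    return genes


def annotate_candidates(
    candidates: Sequence,
    genes: Sequence[GeneModel],
    chrom_seqs: dict[str, str],
) -> pd.DataFrame:
    """Effect table for candidate SNPs (any object with chrom/pos/ref/alt).

    Each candidate is mapped onto the first gene model whose CDS covers it;
    candidates outside every CDS are reported as ``non-coding``.
    """
    rows = []
    for cand in candidates:
        hit = None
        for gene in genes:
            if gene.chrom != cand.chrom:
                continue
            cds_pos = map_genomic_to_cds(gene, cand.pos)
            if cds_pos is not None:
                hit = (gene, cds_pos)
                break
        row = {
            "chrom": cand.chrom,
            "pos": cand.pos,
            "ref": cand.ref,
            "alt": cand.alt,
        }
        if hit is None:
            row.update(
                gene_id=None, cds_pos=None, codon_index=None, pos_in_codon=None,
                ref_codon=None, alt_codon=None, ref_aa=None, alt_aa=None,
                effect="non-coding",
            )
        else:
            gene, cds_pos = hit
            cds_seq = extract_cds_sequence(gene, chrom_seqs[gene.chrom])
            eff = classify_variant(gene, cds_pos, cand.ref, cand.alt, cds_seq)
            row.update(
                gene_id=gene.gene_id, cds_pos=eff.cds_pos,
                codon_index=eff.codon_index, pos_in_codon=eff.pos_in_codon,
                ref_codon=eff.ref_codon, alt_codon=eff.alt_codon,
                ref_aa=eff.ref_aa, alt_aa=eff.alt_aa, effect=eff.effect_class,
            )
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene_id", "cds_pos", "codon_index",
            "pos_in_codon", "ref_codon", "alt_codon", "ref_aa", "alt_aa", "effect",
        ],
    )
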