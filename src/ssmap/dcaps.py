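"""CAPS / dCAPS genotyping-assay design for single-base substitutions.

A CAPS marker exploits a restriction site that one allele completes
naturally; a dCAPS marker engineers such a site by introducing up to two
substitutions into the genotyping primer whose 3' end abuts the SNP, so
that the amplicon of exactly one allele is cut.  Designs are validated by
in-silico digestion of both allelic amplicons.

Conventions: the engineered site must span the SNP base (otherwise
digestion could not discriminate the alleles); primer mismatches are
restricted to the 5' portion of the site window and never touch the
3'-terminal primer base, preserving PCR extension fidelity.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

from .errors import InputError

__all__ = [
    "Enzyme",
    "DcapsCandidate",
    "load_enzymes",
    "iupac_match",
    "in_silico_digest",
    "design_dcaps",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: IUPAC recognition site and top-strand cut offset."""

    name: str
    site: str
    cut_offset: int

    def __post_init__(self):
        site = self.site.upper()
        if len(site) < 4:
            raise InputError(f"{self.name}: recognition site shorter than 4 bp")
        if any(b not in IUPAC for b in site):
            raise InputError(f"{self.name}: site {site!r} is not IUPAC")
        if not 0 <= self.cut_offset <= len(site):
            raise InputError(f"{self.name}: cut offset outside the site")
        object.__setattr__(self, "site", site)

    def __len__(self) -> int:
        return len(self.site)


@dataclass(frozen=True)
class DcapsCandidate:
    """A primer/enzyme pair whose digestion distinguishes the two alleles."""

    enzyme: Enzyme
    primer: str  # engineered primer, 3' end abutting the SNP
    mismatches: tuple[tuple[int, str, str], ...]  # (amplicon pos 1-based, from, to)
    cut_allele: str
    uncut_allele: str
    site_window: tuple[int, int]  # 1-based inclusive window of the engineered site
    fragments: dict[str, tuple[int, ...]]  # allele -> fragment sizes
    amplicons: dict[str, str]  # engineered full amplicon per allele

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatches)

    @property
    def is_caps(self) -> bool:
        return self.n_mismatches == 0


def load_enzymes(path=None) -> list[Enzyme]:
    """Load an enzyme table (packaged ~36 common 4-6-cutters by default)."""
    if path is None:
        source = resources.files("ssmap").joinpath("data/enzymes.tsv")
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    enzymes = []
    header_seen = False
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if not header_seen:
            if fields[0].lower() == "name":
                header_seen = True
                continue
            header_seen = True
        if len(fields) != 3:
            raise InputError(f"bad enzyme table row: {line!r}")
        enzymes.append(Enzyme(fields[0], fields[1], int(fields[2])))
    return enzymes


def iupac_match(base: str, code: str) -> bool:
    """Does a concrete base satisfy an IUPAC code?"""
    return base.upper() in IUPAC[code.upper()]


def _site_regex(site: str) -> str:
    return "".join(b if len(IUPAC[b]) == 1 else f"[{IUPAC[b]}]" for b in site)


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def in_silico_digest(amplicon: str, enzyme: Enzyme) -> tuple[int, ...]:
    """Fragment sizes after complete digestion of a double-stranded amplicon.

    All recognition-site occurrences are located (the reverse-strand pattern
    is scanned too when it differs from the forward one, which only happens
    for non-palindromic sites); each occurrence contributes one cut at its
    top-strand cut position.  Fragment sizes always partition the amplicon
    length exactly.
    """
    amplicon = amplicon.upper()
    if any(b not in "ACGT" for b in amplicon):
        raise InputError("amplicon must contain only A/C/G/T")
    cuts: set[int] = set()
    fwd = _site_regex(enzyme.site)
    for m in re.finditer(f"(?={fwd})", amplicon):
        cuts.add(m.start() + enzyme.cut_offset)
    rev_site = reverse_complement(enzyme.site)
    rev = _site_regex(rev_site)
    if rev != fwd:
        for m in re.finditer(f"(?={rev})", amplicon):
            cuts.add(m.start() + len(enzyme) - enzyme.cut_offset)
    cuts = sorted(c for c in cuts if 0 < c < len(amplicon))
    bounds = [0, *cuts, len(amplicon)]
    return tuple(b - a for a, b in zip(bounds, bounds[1:]))


def _site_spans_snp(amplicon: str, enzyme: Enzyme, window: tuple[int, int]) -> bool:
    """Is the recognition site present exactly at the SNP-spanning window?"""
    a, b = window
    segment = amplicon[a - 1 : b]
    return re.fullmatch(_site_regex(enzyme.site), segment) is not None


def design_dcaps(
    flank5: str,
    alleles: tuple[str, str],
    flank3: str,
    enzymes: Iterable[Enzyme] | None = None,
    max_mismatch: int = 2,
    primer_length: int = 20,
) -> list[DcapsCandidate]:
    """Enumerate CAPS/dCAPS designs discriminating two alleles of a SNP.

    ``flank5`` and ``flank3`` are the sequences on either side of the SNP;
    ``alleles`` are the two single-base variants.  For every enzyme and every
    placement of its recognition site across the SNP, the number of primer
    substitutions needed to complete the site is counted; placements needing
    at most ``max_mismatch`` substitutions, where exactly one allele matches
    the site at the SNP base, become candidates.  Every candidate is verified
    by in-silico digestion of both engineered amplicons.  Results are sorted
    by (mismatch count, enzyme name), so natural CAPS solutions come first.
    Returns an empty list when no enzyme works (not an error).
    """
    flank5, flank3 = flank5.upper(), flank3.upper()
    for seq, label in ((flank5, "flank5"), (flank3, "flank3")):
        if any(b not in "ACGT" for b in seq):
            raise InputError(f"{label} contains non-ACGT characters")
    allele_a, allele_b = (a.upper() for a in alleles)
    if allele_a == allele_b or len(allele_a) != 1 or len(allele_b) != 1:
        raise InputError("alleles must be two distinct single bases")
    if len(flank5) < primer_length:
        raise InputError("flank5 shorter than the primer length")
    if max_mismatch < 0:
        raise InputError("max_mismatch must be non-negative")
    if enzymes is None:
        enzymes = load_enzymes()

    s = len(flank5)  # 0-based index of the SNP in the amplicon
    primer_lo = s - primer_length  # primer occupies [primer_lo, s-1]
    candidates: list[DcapsCandidate] = []
    for enzyme in enzymes:
        L = len(enzyme)
        for j in range(L):  # SNP sits at site position j (0-based)
            w0 = s - j
            if w0 < 0 or w0 + L > s + 1 + len(flank3):
                continue
            # which allele completes the site at the SNP base?
            code = enzyme.site[j]
            a_ok, b_ok = iupac_match(allele_a, code), iupac_match(allele_b, code)
            if a_ok == b_ok:
                continue  # both or neither cut: no discrimination here
            cut_allele, uncut_allele = (
                (allele_a, allele_b) if a_ok else (allele_b, allele_a)
            )
            mismatches: list[tuple[int, str, str]] = []
            feasible = True
            for q in range(w0, w0 + L):
                if q == s:
                    continue
                base = flank5[q] if q < s else flank3[q - s - 1]
                if iupac_match(base, enzyme.site[q - w0]):
                    continue
                # a substitution is only possible inside the primer, 5' of
                # the SNP, and never at the 3'-terminal primer base
                if primer_lo <= q < s - 1:
                    # replace with the first base satisfying the code
                    mismatches.append((q + 1, base, IUPAC[enzyme.site[q - w0]][0]))
                else:
                    feasible = False
                    break
            if not feasible or len(mismatches) > max_mismatch:
                continue

            primer = list(flank5[primer_lo:s])
            for pos1, _, to in mismatches:
                primer[pos1 - 1 - primer_lo] = to
            primer = "".join(primer)
            engineered5 = flank5[:primer_lo] + primer
            amplicons = {
                allele: engineered5 + allele + flank3
                for allele in (allele_a, allele_b)
            }
            window = (w0 + 1, w0 + L)
            # self-check by digestion: the engineered site must be present
            # in the cut allele's amplicon only
            if not _site_spans_snp(amplicons[cut_allele], enzyme, window):
                continue
            if _site_spans_snp(amplicons[uncut_allele], enzyme, window):
                continue
            fragments = {
                allele: in_silico_digest(amp, enzyme)
                for allele, amp in amplicons.items()
            }
            if fragments[cut_allele] == fragments[uncut_allele]:
                continue  # indistinguishable on a gel
            candidates.append(
                DcapsCandidate(
                    enzyme=enzyme,
                    primer=primer,
                    mismatches=tuple(mismatches),
                    cut_allele=cut_allele,
                    uncut_allele=uncut_allele,
                    site_window=window,
                    fragments=fragments,
                    amplicons=amplicons,
                )
            )
    candidates.sort(key=lambda c: (c.n_mismatches, c.enzyme.name, c.site_window))
    return candidates
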