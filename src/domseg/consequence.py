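"""cDNA substitution → codon → amino-acid consequence mapping.

Coordinates use standard CDS numbering: cDNA position 1 is the first base of
the initiation codon, so residue ``r`` spans cDNA positions ``3(r-1)+1`` to
``3r``. Only substitutions within coding sequence are annotated; intronic
and UTR variants are out of scope ("non-coding: not assessed").

Charges at neutral pH: D, E = -1; K, R = +1; all other residues (histidine
included) 0, matching the qualitative charge-reversal framing used for
acidic-to-basic substitutions such as E→K.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

STOP = "*"

#: residue charge at neutral pH
CHARGE = {"D": -1, "E": -1, "K": 1, "R": 1}

#: Implied CDS start of exon 29 (metadata only): feature-relative position 42
#: of the modelled variant together with cDNA position 9772 imply the exon
#: begins at cDNA 9731. Recorded for reference, not asserted anywhere.
EXON29_IMPLIED_CDS_START = 9731

#: Published scores of external trained/database-backed predictors for the
#: modelled E3258K substitution. Metadata only — never recomputed here.
EXTERNAL_TOOL_SCORES = {
    "polyphen2_score": 0.991,
    "sift_score": 0.00,
    "sift_median_conservation": 3.45,
}


class Consequence(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    STOP_LOSS = "stop-loss"


@dataclass(frozen=True)
class CdnaVariant:
    """A single-nucleotide substitution in CDS coordinates."""

    cdna_position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.cdna_position < 1:
            raise ValueError("cDNA position must be >= 1")
        for b in (self.ref_base, self.alt_base):
            if b not in "ACGT":
                raise ValueError(f"bad nucleotide {b!r}")
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt must differ")


@dataclass(frozen=True)
class AaSubstitution:
    residue_number: int
    ref_aa: str
    alt_aa: str
    consequence: Consequence
    charge_delta: int


def cdna_to_codon(cdna_position: int) -> tuple[int, int]:
    """Map a CDS position to (residue number, offset in codon 1..3)."""
    if cdna_position < 1:
        raise ValueError("cDNA position must be >= 1")
    return ((cdna_position - 1) // 3 + 1, (cdna_position - 1) % 3 + 1)


def codon_span(residue_number: int) -> tuple[int, int]:
    """Inverse of :func:`cdna_to_codon`: cDNA positions covered by a residue."""
    return (3 * (residue_number - 1) + 1, 3 * residue_number)


def mutate_codon(codon: str, offset: int, alt: str) -> str:
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"bad codon {codon!r}")
    if offset not in (1, 2, 3):
        raise ValueError(f"codon offset must be 1..3, got {offset}")
    if alt not in "ACGT":
        raise ValueError(f"bad nucleotide {alt!r}")
    pos = offset - 1
    return codon[:pos] + alt + codon[pos + 1:]


def translate_codon(codon: str) -> str:
    """Standard-code translation; ``*`` for a stop codon."""
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"bad codon {codon!r}")
    return str(Seq(codon).translate())


def annotate_substitution(variant: CdnaVariant, codon_ref: str) -> AaSubstitution:
    """Annotate a CDS substitution given the reference codon it falls in.

    ``codon_ref`` must carry ``variant.ref_base`` at the computed offset —
    a mismatch signals a coordinate bug and raises ``ValueError``.
    """
    residue, offset = cdna_to_codon(variant.cdna_position)
    if len(codon_ref) != 3 or any(b not in "ACGT" for b in codon_ref):
        raise ValueError(f"bad codon {codon_ref!r}")
    if codon_ref[offset - 1] != variant.ref_base:
        raise ValueError(
            f"reference codon {codon_ref} carries {codon_ref[offset - 1]} at "
            f"offset {offset}, but the variant states ref {variant.ref_base}"
        )
    codon_alt = mutate_codon(codon_ref, offset, variant.alt_base)
    ref_aa = translate_codon(codon_ref)
    alt_aa = translate_codon(codon_alt)
    if ref_aa == alt_aa:
        cons = Consequence.SYNONYMOUS
    elif alt_aa == STOP:
        cons = Consequence.NONSENSE
    elif ref_aa == STOP:
        cons = Consequence.STOP_LOSS
    else:
        cons = Consequence.MISSENSE
    delta = CHARGE.get(alt_aa, 0) - CHARGE.get(ref_aa, 0)
    return AaSubstitution(residue, ref_aa, alt_aa, cons, delta)


def hgvs_name(sub: AaSubstitution, variant: CdnaVariant) -> tuple[str, str]:
    """(cDNA, protein) HGVS-style names, e.g. ('c.9772G>A', 'p.Glu3258Lys')."""
    cdna = f"c.{variant.cdna_position}{variant.ref_base}>{variant.alt_base}"
    if sub.consequence is Consequence.SYNONYMOUS:
        prot = "p.(=)"
    else:
        ref3 = "Ter" if sub.ref_aa == STOP else seq3(sub.ref_aa)
        alt3 = "Ter" if sub.alt_aa == STOP else seq3(sub.alt_aa)
        prot = f"p.{ref3}{sub.residue_number}{alt3}"
    return (cdna, prot)
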