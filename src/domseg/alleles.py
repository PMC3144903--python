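"""Allele tokens and genotype calls.

The genotype-table dialect uses four allele token forms:

* base strings (``G``, ``GGG``) — literal nucleotide runs;
* run-length tokens (``11C``) — a mononucleotide repeat of stated length,
  used for repeat-length polymorphisms;
* the deletion token ``Del`` — absence of a segment;
* segment-presence tokens (``59bp``) — a segment of stated length present
  but of unrecorded sequence, used only for reference alleles opposite a
  deletion.

Tokens are compared as normalized opaque symbols: two alleles are equal iff
their tokens are equal. Parsing then re-rendering a token is the identity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from functools import total_ordering


class AlleleForm(str, Enum):
    BASES = "bases"
    RUN_LENGTH = "run-length"
    DELETION = "deletion"
    SEGMENT = "segment"


class AlleleParseError(ValueError):
    """Raised for a token outside the allele grammar."""


_RUN_LENGTH_RE = re.compile(r"^([1-9]\d*)([ACGT])$")
_BASES_RE = re.compile(r"^[ACGT]+$")
_SEGMENT_RE = re.compile(r"^([1-9]\d*)bp$")

DELETION_TOKEN = "Del"


@total_ordering
@dataclass(frozen=True)
class Allele:
    """A normalized allele token.

    ``count`` and ``base`` are populated for run-length alleles; ``count``
    alone for segment-presence alleles.
    """

    token: str
    form: AlleleForm
    count: int | None = None
    base: str | None = None

    def __str__(self) -> str:
        return self.token

    def __lt__(self, other: "Allele") -> bool:
        return self.token < other.token

    @property
    def is_deletion(self) -> bool:
        return self.form is AlleleForm.DELETION


def parse_allele(token: str) -> Allele:
    """Parse one allele token into a normalized :class:`Allele`.

    Raises :class:`AlleleParseError` for malformed tokens, naming the token.
    """
    tok = token.strip()
    if not tok:
        raise AlleleParseError("empty allele token")
    if tok == DELETION_TOKEN:
        return Allele(tok, AlleleForm.DELETION)
    m = _RUN_LENGTH_RE.match(tok)
    if m:
        return Allele(tok, AlleleForm.RUN_LENGTH, count=int(m.group(1)), base=m.group(2))
    if _BASES_RE.match(tok):
        return Allele(tok, AlleleForm.BASES)
    m = _SEGMENT_RE.match(tok)
    if m:
        return Allele(tok, AlleleForm.SEGMENT, count=int(m.group(1)))
    raise AlleleParseError(f"malformed allele token: {token!r}")


@dataclass(frozen=True)
class GenotypeCall:
    """An unordered pair of alleles at one site in one sample.

    Equality is order-insensitive: ``G/A`` equals ``A/G``. The constructor
    normalizes by sorting tokens.
    """

    alleles: tuple[Allele, Allele]

    def __post_init__(self) -> None:
        a, b = self.alleles
        if (b.token, ) < (a.token, ):
            object.__setattr__(self, "alleles", (b, a))

    @classmethod
    def of(cls, a: Allele | str, b: Allele | str) -> "GenotypeCall":
        if isinstance(a, str):
            a = parse_allele(a)
        if isinstance(b, str):
            b = parse_allele(b)
        return cls((a, b))

    @classmethod
    def parse(cls, cell: str) -> "GenotypeCall":
        parts = cell.strip().split("/")
        if len(parts) != 2:
            raise AlleleParseError(f"genotype cell must hold two /-separated alleles: {cell!r}")
        return cls.of(parts[0], parts[1])

    @property
    def heterozygous(self) -> bool:
        return self.alleles[0].token != self.alleles[1].token

    @property
    def homozygous(self) -> bool:
        return not self.heterozygous

    def count(self, allele: Allele) -> int:
        return sum(1 for a in self.alleles if a.token == allele.token)

    def carries(self, allele: Allele) -> bool:
        return self.count(allele) > 0

    def tokens(self) -> tuple[str, str]:
        return (self.alleles[0].token, self.alleles[1].token)

    def __str__(self) -> str:
        return f"{self.alleles[0]}/{self.alleles[1]}"
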