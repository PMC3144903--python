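"""Grantham distance, alignment-based GV/GD scoring, and the C0–C65 classifier.

The Grantham distance between residues x and y combines three
physicochemical properties — composition c (atomic weight ratio of
non-carbon side-chain atoms), polarity p, and molecular volume v:

    D(x, y) = rho * sqrt(alpha*(cx-cy)^2 + beta*(px-py)^2 + gamma*(vx-vy)^2)

with alpha = 1.833, beta = 0.1018, gamma = 0.000399 and a scale factor rho
chosen so the mean over all 190 unordered residue pairs is 100. The
conventional published constant rho = 50.723 is the default; it reproduces
the published integer distance matrix and gives D(E, K) = 56.87.
:func:`calibrate_rho` recomputes the mean-100 calibration from the property
table (50.790 — the 0.13% drift traces to rounding of the published
property values) for callers who prefer a self-contained scale.

For an alignment column, Grantham Variation (GV) measures the
physicochemical spread of the residues observed at the position, and
Grantham Deviation (GD) the distance of a variant residue from the
column's property ranges (zero when the variant lies inside the range on
every property). A (GV, GD) pair is graded into seven classes C0 < C15 <
C25 < C35 < C45 < C55 < C65 of increasing predicted severity by the
boundary rule GD >= x + tan(10 deg) * GV^2 for x in {15, 25, 35, 45, 55, 65}.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO

ALPHA, BETA, GAMMA = 1.833, 0.1018, 0.000399

#: Grantham (1974) residue properties: composition, polarity, volume.
GRANTHAM_PROPERTIES: dict[str, tuple[float, float, float]] = {
    "S": (1.42, 9.2, 32.0),
    "R": (0.65, 10.5, 124.0),
    "L": (0.00, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5),
    "T": (0.71, 8.6, 61.0),
    "A": (0.00, 8.1, 31.0),
    "V": (0.00, 5.9, 84.0),
    "G": (0.74, 9.0, 3.0),
    "I": (0.00, 5.2, 111.0),
    "F": (0.00, 5.2, 132.0),
    "Y": (0.20, 6.2, 136.0),
    "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0),
    "Q": (0.89, 10.5, 85.0),
    "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0),
    "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0),
    "M": (0.00, 5.7, 105.0),
    "W": (0.13, 5.4, 170.0),
}

#: Conventional scale factor making the mean pair distance 100.
RHO = 50.723

CLASS_THRESHOLDS = (65, 55, 45, 35, 25, 15)
GAP_CHARS = set("-.")


def _props(aa: str) -> tuple[float, float, float]:
    try:
        return GRANTHAM_PROPERTIES[aa]
    except KeyError:
        raise ValueError(f"not a standard amino acid: {aa!r}") from None


def _scaled(dc: float, dp: float, dv: float, rho: float) -> float:
    return rho * math.sqrt(ALPHA * dc * dc + BETA * dp * dp + GAMMA * dv * dv)


def calibrate_rho() -> float:
    """Scale factor making the mean of all 190 unordered pair distances 100."""
    residues = sorted(GRANTHAM_PROPERTIES)
    total, n = 0.0, 0
    for i, x in enumerate(residues):
        for y in residues[i + 1:]:
            cx, px, vx = _props(x)
            cy, py, vy = _props(y)
            total += _scaled(cx - cy, px - py, vx - vy, 1.0)
            n += 1
    return 100.0 * n / total


def grantham_distance(aa1: str, aa2: str, rho: float = RHO) -> float:
    """Unrounded Grantham distance between two residues."""
    c1, p1, v1 = _props(aa1)
    c2, p2, v2 = _props(aa2)
    return _scaled(c1 - c2, p1 - p2, v1 - v2, rho)


@dataclass(frozen=True)
class AlignmentColumn:
    """Residues observed at one alignment position, gaps removed."""

    residues: tuple[str, ...]
    gap_count: int = 0

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("alignment column has no residues after gap removal")
        for aa in self.residues:
            _props(aa)

    @classmethod
    def from_symbols(cls, symbols: Iterable[str]) -> "AlignmentColumn":
        kept, gaps = [], 0
        for s in symbols:
            s = s.upper()
            if s in GAP_CHARS:
                gaps += 1
            else:
                kept.append(s)
        return cls(tuple(kept), gap_count=gaps)

    def counts(self) -> Counter:
        return Counter(self.residues)


def gv(column: AlignmentColumn, rho: float = RHO) -> float:
    """Grantham Variation: property-range spread of the observed residues.

    Zero iff the column is invariant (a single distinct residue).
    """
    cs, ps, vs = zip(*(_props(aa) for aa in column.residues))
    return _scaled(max(cs) - min(cs), max(ps) - min(ps), max(vs) - min(vs), rho)


def gd(column: AlignmentColumn, variant_aa: str, rho: float = RHO) -> float:
    """Grantham Deviation of a variant residue from the column's ranges.

    Per property the deviation is 0 inside [min, max] of the observed
    residues, else the distance to the nearer bound.
    """
    cv, pv, vv = _props(variant_aa)
    devs = []
    for value, series in (
        (cv, [c for c, _, _ in map(_props, column.residues)]),
        (pv, [p for _, p, _ in map(_props, column.residues)]),
        (vv, [v for _, _, v in map(_props, column.residues)]),
    ):
        lo, hi = min(series), max(series)
        devs.append(0.0 if lo <= value <= hi else min(abs(value - lo), abs(value - hi)))
    return _scaled(devs[0], devs[1], devs[2], rho)


def classify(gv_value: float, gd_value: float) -> str:
    """Seven-class grade for a (GV, GD) pair.

    The boundary for class Cx is GD >= x + tan(10 deg) * GV^2; the label is
    the largest x whose boundary is met, else C0.
    """
    if gv_value < 0 or gd_value < 0:
        raise ValueError("GV and GD must be non-negative")
    curvature = math.tan(math.radians(10.0))
    for x in CLASS_THRESHOLDS:
        if gd_value >= x + curvature * gv_value**2.0:
            return f"C{x}"
    return "C0"


def class_index(label: str) -> int:
    """Numeric threshold index of a class label (C55 -> 55)."""
    return int(label[1:])


@dataclass(frozen=True)
class GvgdScore:
    gv: float
    gd: float
    class_label: str


def score_column(column: AlignmentColumn, variant_aa: str, rho: float = RHO) -> GvgdScore:
    """End-to-end GV/GD scoring and classification for one substitution."""
    g_v = gv(column, rho)
    g_d = gd(column, variant_aa, rho)
    return GvgdScore(g_v, g_d, classify(g_v, g_d))


# -- alignments ------------------------------------------------------------


def read_alignment(path: str | Path) -> list[str]:
    """Read an aligned FASTA or Clustal file into equal-length sequences."""
    path = Path(path)
    last_error: Exception | None = None
    for fmt in ("fasta", "clustal"):
        try:
            aln = AlignIO.read(str(path), fmt)
            return [str(rec.seq).upper() for rec in aln]
        except ValueError as exc:
            last_error = exc
    raise ValueError(f"could not read {path} as aligned FASTA or Clustal: {last_error}")


def column_at(sequences: Sequence[str], position: int) -> AlignmentColumn:
    """1-based alignment column across equal-length sequences."""
    _check_equal_lengths(sequences)
    if not 1 <= position <= len(sequences[0]):
        raise ValueError(f"column {position} outside alignment of length {len(sequences[0])}")
    return AlignmentColumn.from_symbols(seq[position - 1] for seq in sequences)


def _check_equal_lengths(sequences: Sequence[str]) -> None:
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment lengths: {sorted(lengths)}")


def conservation_fraction(
    sequences: Sequence[str], start: int = 1, end: int | None = None
) -> float:
    """Fraction of gap-free columns at which all sequences agree.

    ``start``/``end`` restrict to an inclusive 1-based column window.
    Columns containing a gap in any sequence are excluded from the
    denominator.
    """
    _check_equal_lengths(sequences)
    end = len(sequences[0]) if end is None else end
    total = identical = 0
    for i in range(start - 1, end):
        symbols = {seq[i].upper() for seq in sequences}
        if symbols & GAP_CHARS:
            continue
        total += 1
        if len(symbols) == 1:
            identical += 1
    if total == 0:
        raise ValueError("no gap-free columns in the requested window")
    return identical / total
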