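"""In-silico allelic-discrimination (TaqMan-style) genotyping.

The assay is modelled combinatorially: a PCR amplicon is delimited by exact
matches of the forward primer and the reverse complement of the reverse
primer, and each chromosome is typed by exact containment (either strand)
of one of two probes that differ at the variant base. No thermodynamic,
mismatch-tolerance or fluorescence modelling is attempted — with probes
differing at one interior base, exact matching reproduces allelic
discrimination. A chromosome matching both probes or neither is ambiguous
and yields a no-call, never a guess.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class ProbeSet:
    forward_primer: str
    reverse_primer: str
    wt_probe: str
    mut_probe: str
    wt_allele: str = "G"
    mut_allele: str = "A"

    def __post_init__(self) -> None:
        if not self.forward_primer or not self.reverse_primer:
            raise ValueError("primers must be non-empty")
        if self.wt_probe == self.mut_probe:
            raise ValueError("probes must differ at >= 1 position")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProbeSet":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def default_probeset() -> ProbeSet:
    """The packaged exon-29 G>A assay (published primers and probes)."""
    text = resources.files("domseg.data").joinpath("probes.yaml").read_text()
    return ProbeSet(**yaml.safe_load(text))


class AmbiguousTemplateError(ValueError):
    pass


def _find_all(haystack: str, needle: str) -> list[int]:
    out, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def extract_amplicon(seq: str, probes: ProbeSet) -> str | None:
    """The substring from the forward primer through the reverse complement
    of the reverse primer, inclusive; both template strands are searched.

    Returns ``None`` when either primer site is absent or mis-ordered;
    raises :class:`AmbiguousTemplateError` when several amplicons are
    possible.
    """
    candidates = []
    for template in (seq.upper(), revcomp(seq.upper())):
        fwd_hits = _find_all(template, probes.forward_primer)
        rev_hits = _find_all(template, revcomp(probes.reverse_primer))
        for i in fwd_hits:
            for j in rev_hits:
                end = j + len(probes.reverse_primer)
                if end > i:
                    candidates.append(template[i:end])
    unique = sorted(set(candidates))
    if len(unique) > 1:
        raise AmbiguousTemplateError(
            f"{len(unique)} distinct candidate amplicons on the template"
        )
    return unique[0] if unique else None


class ChromState(str, Enum):
    WT = "wt"
    MUT = "mut"
    AMBIGUOUS = "ambiguous"


class Call(str, Enum):
    WT_WT = "wt/wt"
    WT_MUT = "wt/mut"
    MUT_MUT = "mut/mut"
    NO_CALL = "no-call"


@dataclass(frozen=True)
class AssayCall:
    sample: str
    call: Call


def _probe_hit(chrom: str, probe: str) -> bool:
    chrom = chrom.upper()
    return probe in chrom or revcomp(probe) in chrom


def type_chromosome(chrom: str, probes: ProbeSet) -> ChromState:
    wt = _probe_hit(chrom, probes.wt_probe)
    mut = _probe_hit(chrom, probes.mut_probe)
    if wt and not mut:
        return ChromState.WT
    if mut and not wt:
        return ChromState.MUT
    return ChromState.AMBIGUOUS


def call_genotype(
    chrom_pair: tuple[str, str], probes: ProbeSet, sample: str = ""
) -> AssayCall:
    """Type both chromosomes; any ambiguous chromosome yields a no-call.

    Symmetric in chromosome order and template strand.
    """
    states = sorted(type_chromosome(c, probes).value for c in chrom_pair)
    mapping = {
        ("mut", "wt"): Call.WT_MUT,
        ("wt", "wt"): Call.WT_WT,
        ("mut", "mut"): Call.MUT_MUT,
    }
    call = mapping.get(tuple(states), Call.NO_CALL)
    return AssayCall(sample=sample, call=call)


def read_chromosome_fasta(path: str | Path) -> dict[str, tuple[str, str]]:
    """FASTA with two records per sample named ``<sample>/1``, ``<sample>/2``."""
    chroms: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "/" not in rec.id:
            raise ValueError(f"record {rec.id!r} is not named <sample>/<1|2>")
        sample, idx = rec.id.rsplit("/", 1)
        if idx not in ("1", "2"):
            raise ValueError(f"record {rec.id!r} is not named <sample>/<1|2>")
        chroms.setdefault(sample, {})[idx] = str(rec.seq)
    out = {}
    for sample, pair in chroms.items():
        if set(pair) != {"1", "2"}:
            raise ValueError(f"sample {sample!r} does not have exactly two chromosomes")
        out[sample] = (pair["1"], pair["2"])
    return out


@dataclass
class CosegregationSummary:
    """Status × carrier-state contingency with a concordance fraction.

    Concordance counts affected heterozygous carriers and unaffected
    non-carriers as concordant; no-calls are reported separately and
    excluded from the denominator. ``concordance`` is ``None`` on empty
    input.
    """

    table: pd.DataFrame
    concordance: float | None
    n_no_call: int


def cosegregation_summary(
    calls: Sequence[AssayCall], status: dict[str, str]
) -> CosegregationSummary:
    missing = [c.sample for c in calls if c.sample not in status]
    if missing:
        raise ValueError(f"samples without status: {missing}")
    rows = ["affected", "unaffected"]
    cols = ["carrier het", "carrier hom", "non-carrier", "no-call"]
    counts = pd.DataFrame(0, index=rows, columns=cols)
    concordant = total = no_calls = 0
    for c in calls:
        st = status[c.sample]
        if c.call is Call.NO_CALL:
            counts.loc[st, "no-call"] += 1
            no_calls += 1
            continue
        col = {
            Call.WT_MUT: "carrier het",
            Call.MUT_MUT: "carrier hom",
            Call.WT_WT: "non-carrier",
        }[c.call]
        counts.loc[st, col] += 1
        total += 1
        if (st == "affected" and c.call is Call.WT_MUT) or (
            st == "unaffected" and c.call is Call.WT_WT
        ):
            concordant += 1
    concordance = concordant / total if total else None
    return CosegregationSummary(counts, concordance, no_calls)
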