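"""Dominant-model segregation filtering.

Under a fully penetrant autosomal dominant model with embryonic-lethal
homozygotes, the causal allele must be carried in exactly one copy by every
affected individual and in no copy by any unaffected individual. A site
whose genotype configuration admits such an allele is a CANDIDATE; every
other site is excluded and labelled with one of five descriptive patterns:

P1  all samples homozygous for one shared allele;
P2  all samples carry the identical heterozygous genotype;
P3  exactly one affected heterozygous, all other samples homozygous for a
    shared allele that is NOT a database reference allele;
P4  exactly one unaffected heterozygous, all other samples homozygous for a
    shared allele;
P5  exactly one affected heterozygous, all other samples homozygous for a
    shared allele that IS a database reference allele (i.e. wild type).

Candidacy is decided purely on the genotype configuration; the database
reference alleles are consulted only to separate the descriptive labels P3
and P5.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .alleles import Allele, GenotypeCall, parse_allele
from .variant_table import AFFECTED, UNAFFECTED, VariantSite, VariantTable


class Verdict(str, Enum):
    CANDIDATE = "CANDIDATE"
    P1 = "P1"
    P2 = "P2"
    P3 = "P3"
    P4 = "P4"
    P5 = "P5"
    OTHER = "OTHER"


@dataclass(frozen=True)
class SiteVerdict:
    site: VariantSite
    verdict: Verdict
    candidate_allele: Allele | None = None
    note: str = ""

    def __post_init__(self) -> None:
        assert (self.candidate_allele is not None) == (self.verdict is Verdict.CANDIDATE)


def _check_status(genotypes: Sequence[GenotypeCall], status: Sequence[str]) -> None:
    if len(genotypes) != len(status):
        raise ValueError("one status label required per genotype")
    bad = [s for s in status if s not in (AFFECTED, UNAFFECTED)]
    if bad:
        raise ValueError(f"unknown status labels: {bad}")
    if AFFECTED not in status or UNAFFECTED not in status:
        raise ValueError("need at least one affected and one unaffected sample")


def qualifying_alleles(
    genotypes: Sequence[GenotypeCall], status: Sequence[str]
) -> list[Allele]:
    """All alleles heterozygous in every affected and absent from every unaffected."""
    _check_status(genotypes, status)
    observed: dict[str, Allele] = {}
    for g in genotypes:
        for a in g.alleles:
            observed.setdefault(a.token, a)
    out = []
    for token in sorted(observed):
        a = observed[token]
        ok = all(
            (g.count(a) == 1) if s == AFFECTED else (not g.carries(a))
            for g, s in zip(genotypes, status)
        )
        if ok:
            out.append(a)
    return out


def dominant_candidate(
    genotypes: Sequence[GenotypeCall], status: Sequence[str]
) -> Allele | None:
    """The dominant-model candidate allele at one site, or None.

    If more than one allele qualifies (possible only at sites with three or
    more alleles) the lexicographically smallest is returned; the caller can
    detect the ambiguity via :func:`qualifying_alleles`.
    """
    quals = qualifying_alleles(genotypes, status)
    return quals[0] if quals else None


def classify_exclusion(
    genotypes: Sequence[GenotypeCall],
    status: Sequence[str],
    db_ref: Iterable[Allele] = (),
    site: VariantSite | None = None,
) -> SiteVerdict:
    """Assign CANDIDATE or one of the exclusion-pattern labels to a site."""
    quals = qualifying_alleles(genotypes, status)
    db = {a.token for a in db_ref}
    if site is not None and not db:
        db = {a.token for a in site.db_ref}
    ref_site = site if site is not None else _DUMMY_SITE

    if len(quals) == 1:
        return SiteVerdict(ref_site, Verdict.CANDIDATE, candidate_allele=quals[0])
    if len(quals) > 1:
        return SiteVerdict(ref_site, Verdict.OTHER, note="multiple qualifying alleles")

    homs = [g for g in genotypes if g.homozygous]
    hets = [g for g in genotypes if g.heterozygous]
    het_status = [s for g, s in zip(genotypes, status) if g.heterozygous]
    hom_tokens = {g.alleles[0].token for g in homs}

    if len(homs) == len(genotypes) and len(hom_tokens) == 1:
        return SiteVerdict(ref_site, Verdict.P1)
    if len(hets) == len(genotypes) and len({g.tokens() for g in hets}) == 1:
        return SiteVerdict(ref_site, Verdict.P2)
    if len(hets) == 1 and len(hom_tokens) == 1:
        shared = next(iter(hom_tokens))
        if het_status[0] == AFFECTED:
            # db membership separates "homozygous for the variant" (P3)
            # from "homozygous for wild type" (P5); ambiguous references
            # containing the shared allele resolve to P5.
            verdict = Verdict.P5 if shared in db else Verdict.P3
            return SiteVerdict(ref_site, verdict)
        return SiteVerdict(ref_site, Verdict.P4)
    return SiteVerdict(ref_site, Verdict.OTHER)


_DUMMY_SITE = VariantSite(
    assay_id="__site__", feature="NA", position=(1, 1),
    db_ref=frozenset({parse_allele("A")}),
)


@dataclass
class Prioritization:
    """Ordered verdicts with per-pattern counts; candidates listed first."""

    verdicts: list[SiteVerdict]
    counts: Counter

    @property
    def candidates(self) -> list[SiteVerdict]:
        return [v for v in self.verdicts if v.verdict is Verdict.CANDIDATE]

    @property
    def excluded(self) -> list[SiteVerdict]:
        return [v for v in self.verdicts if v.verdict is not Verdict.CANDIDATE]


def prioritize(table: VariantTable) -> Prioritization:
    """Classify every site; candidate sites first, input order within groups."""
    status = [table.status[s] for s in table.samples]
    verdicts = [
        classify_exclusion(table.column(site), status, site=site)
        for site in table.sites
    ]
    ordered = [v for v in verdicts if v.verdict is Verdict.CANDIDATE] + [
        v for v in verdicts if v.verdict is not Verdict.CANDIDATE
    ]
    return Prioritization(ordered, Counter(v.verdict.value for v in verdicts))
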