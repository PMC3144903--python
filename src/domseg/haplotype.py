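"""Parsimony haplotyping of small unphased genotype matrices.

Phasing here is pure parsimony: find, over all ways of splitting each
sample's genotypes into two chromosome-length allele vectors, an assignment
minimizing the number of *distinct* haplotypes across all chromosomes. No
recombination, mutation or frequency model is used; alleles are opaque
symbols.

Exact search is feasible because sites with the same cross-sample genotype
pattern (up to relabelling of alleles) must phase identically in some
optimum, so the matrix first collapses to its distinct pattern columns —
a handful for closely related samples — and a branch-and-bound walks the
per-sample phase choices of the collapsed matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import product

from .alleles import Allele, parse_allele
from .variant_table import VariantTable


@dataclass(frozen=True)
class Haplotype:
    """An ordered per-site allele vector covering every site of a table."""

    alleles: tuple[Allele, ...]
    label: str = ""

    def render(self) -> str:
        return encode_haplotype(self)

    def __len__(self) -> int:
        return len(self.alleles)

    def tokens(self) -> tuple[str, ...]:
        return tuple(a.token for a in self.alleles)


def encode_haplotype(h: Haplotype) -> str:
    """Dash-joined allele tokens in table site order."""
    return "-".join(a.token for a in h.alleles)


def decode_haplotype(text: str, label: str = "") -> Haplotype:
    if not text:
        return Haplotype(alleles=(), label=label)
    return Haplotype(tuple(parse_allele(t) for t in text.split("-")), label=label)


@dataclass(frozen=True)
class Violation:
    sample: str
    assay_id: str
    site_index: int
    expected: str  # the genotype call
    observed: str  # union of the two haplotype alleles


def check_phasing(
    table: VariantTable, diplotypes: dict[str, tuple[Haplotype, Haplotype]]
) -> list[Violation]:
    """Verify a proposed phasing: at every (sample, site), the unordered pair
    of haplotype alleles must equal the sample's genotype. Returns every
    violation; an empty list means the phasing is consistent."""
    n_sites = len(table.sites)
    for sample, (h1, h2) in diplotypes.items():
        if len(h1) != n_sites or len(h2) != n_sites:
            raise ValueError(
                f"haplotype length mismatch for {sample}: "
                f"{len(h1)}/{len(h2)} vs {n_sites} sites"
            )
    violations: list[Violation] = []
    for sample, (h1, h2) in diplotypes.items():
        for i, site in enumerate(table.sites):
            call = table.genotype(site, sample)
            pair = tuple(sorted((h1.alleles[i].token, h2.alleles[i].token)))
            if pair != call.tokens():
                violations.append(
                    Violation(sample, site.assay_id, i, str(call), "/".join(pair))
                )
    return violations


@dataclass
class PhasingResult:
    haplotypes: list[Haplotype]  # distinct, labelled Hap1..HapK
    diplotypes: dict[str, tuple[Haplotype, Haplotype]]

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)


class PhasingSearchError(RuntimeError):
    pass


def _collapse_columns(table: VariantTable) -> tuple[list[int], list[list[int]]]:
    """Collapse sites by cross-sample genotype pattern up to allele relabelling.

    Returns (representative site index per pattern class, member site indices
    per class). The canonical key maps alleles to integers in order of first
    appearance scanning samples in order (tokens within a call sorted).
    """
    classes: dict[tuple, int] = {}
    reps: list[int] = []
    members: list[list[int]] = []
    for j, site in enumerate(table.sites):
        symbol: dict[str, int] = {}
        key = []
        for sample in table.samples:
            call = table.genotype(site, sample)
            pair = []
            for tok in call.tokens():
                if tok not in symbol:
                    symbol[tok] = len(symbol)
                pair.append(symbol[tok])
            key.append(tuple(pair))
        k = tuple(key)
        if k in classes:
            members[classes[k]].append(j)
        else:
            classes[k] = len(reps)
            reps.append(j)
            members.append([j])
    return reps, members


def _sample_phasings(
    table: VariantTable, sample: str, rep_sites: list[int]
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """All unordered splits of a sample's genotypes over the collapsed sites."""
    calls = [table.genotype(table.sites[j], sample) for j in rep_sites]
    het_idx = [i for i, c in enumerate(calls) if c.heterozygous]
    base = [c.tokens() for c in calls]
    out = []
    # fix the first het site's orientation to halve the enumeration:
    # the pair is unordered, so orientations of later sites are relative.
    n_free = max(len(het_idx) - 1, 0)
    for bits in product((0, 1), repeat=n_free):
        flips = dict(zip(het_idx[1:], bits))
        h1, h2 = [], []
        for i, (a, b) in enumerate(base):
            if i in flips and flips[i]:
                a, b = b, a
            h1.append(a)
            h2.append(b)
        out.append((tuple(h1), tuple(h2)))
    if not out:
        out.append((tuple(a for a, _ in base), tuple(b for _, b in base)))
    return out


def min_parsimony_phase(table: VariantTable, max_het_columns: int = 16) -> PhasingResult:
    """Exact minimum-distinct-haplotype phasing via branch-and-bound.

    Ties among equally parsimonious solutions are broken by the
    lexicographically smallest sorted tuple of rendered haplotypes, then by
    the per-sample assignments, so output is deterministic. ``max_het_columns``
    guards the worst-case search space (2^(h-1) phasings per sample over h
    heterozygous collapsed columns).
    """
    reps, members = _collapse_columns(table)
    # search on the collapsed matrix
    per_sample: list[list[tuple[tuple[str, ...], tuple[str, ...]]]] = []
    for sample in table.samples:
        calls = [table.genotype(table.sites[j], sample) for j in reps]
        n_het = sum(c.heterozygous for c in calls)
        if n_het > max_het_columns:
            raise PhasingSearchError(
                f"sample {sample} has {n_het} heterozygous pattern columns "
                f"(> {max_het_columns}); collapse patterns or raise the threshold"
            )
        per_sample.append(_sample_phasings(table, sample, reps))

    order = sorted(range(len(table.samples)), key=lambda i: len(per_sample[i]))
    best_count: int | None = None
    best_key: tuple | None = None
    best_choice: dict[int, tuple] | None = None

    def dfs(pos: int, used: frozenset, choice: dict[int, tuple]) -> None:
        nonlocal best_count, best_key, best_choice
        if best_count is not None and len(used) > best_count:
            return
        if pos == len(order):
            count = len(used)
            key = (count, tuple(sorted(used)),
                   tuple(choice[i] for i in range(len(table.samples))))
            if best_count is None or count < best_count or (
                count == best_count and key < best_key
            ):
                best_count, best_key, best_choice = count, key, dict(choice)
            return
        i = order[pos]
        for h1, h2 in per_sample[i]:
            choice[i] = (h1, h2)
            dfs(pos + 1, used | {h1, h2}, choice)
        choice.pop(i, None)

    dfs(0, frozenset(), {})
    assert best_choice is not None

    # expand collapsed haplotypes back to full site vectors
    site_of_class: list[int] = [0] * len(table.sites)
    for ci, group in enumerate(members):
        for j in group:
            site_of_class[j] = ci

    def expand(collapsed: tuple[str, ...], sample: str) -> tuple[Allele, ...]:
        alleles: list[Allele] = []
        for j, site in enumerate(table.sites):
            ci = site_of_class[j]
            rep_call = table.genotype(table.sites[reps[ci]], sample)
            call = table.genotype(site, sample)
            # map the representative's chosen token to this member column's
            # corresponding allele via the shared canonical pattern
            rep_tokens = rep_call.tokens()
            own = call.alleles
            chosen = collapsed[ci]
            if chosen == rep_tokens[0]:
                alleles.append(own[0])
            else:
                alleles.append(own[1])
        return tuple(alleles)

    chrom_vectors: dict[str, tuple[tuple[Allele, ...], tuple[Allele, ...]]] = {}
    for i, sample in enumerate(table.samples):
        h1, h2 = best_choice[i]
        chrom_vectors[sample] = (expand(h1, sample), expand(h2, sample))

    distinct: dict[tuple[str, ...], tuple[Allele, ...]] = {}
    usage: dict[tuple[str, ...], int] = {}
    for pair in chrom_vectors.values():
        for vec in pair:
            toks = tuple(a.token for a in vec)
            distinct.setdefault(toks, vec)
            usage[toks] = usage.get(toks, 0) + 1
    # label most frequent first, ties by rendered string
    ordered = sorted(distinct, key=lambda t: (-usage[t], t))
    labelled = {
        toks: Haplotype(distinct[toks], label=f"Hap{i + 1}")
        for i, toks in enumerate(ordered)
    }
    diplotypes = {
        sample: (
            labelled[tuple(a.token for a in v1)],
            labelled[tuple(a.token for a in v2)],
        )
        for sample, (v1, v2) in chrom_vectors.items()
    }
    return PhasingResult(list(labelled.values()), diplotypes)


def load_pkd1_phasing() -> dict[str, tuple[Haplotype, Haplotype]]:
    """The five published haplotypes and per-dog pairs for the packaged table."""
    text = resources.files("domseg.data").joinpath("pkd1_haplotypes.tsv").read_text()
    haps: dict[str, Haplotype] = {}
    assign: dict[str, tuple[str, str]] = {}
    for line in text.splitlines():
        if line.startswith("#assign:"):
            for cell in line[len("#assign:"):].split("\t"):
                cell = cell.strip()
                if cell:
                    sample, pair = cell.split("=")
                    a, b = pair.split("/")
                    assign[sample] = (a, b)
        elif line.strip() and not line.startswith("#"):
            label, vector = line.split("\t")
            haps[label] = decode_haplotype(vector, label=label)
    return {s: (haps[a], haps[b]) for s, (a, b) in assign.items()}
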