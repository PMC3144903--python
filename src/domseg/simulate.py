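"""Synthetic cohorts with the statistical structure the filter assumes.

The generator emulates a fully penetrant autosomal dominant disease in a
closed population: every affected individual is heterozygous for one causal
allele inherited identically by descent on a shared founder chromosome;
unaffected individuals lack it (or, below full penetrance, carry it
heterozygously with probability ``1 - penetrance``); causal homozygotes are
never produced (embryonic lethality). Background polymorphisms are
biallelic, unlinked, and drawn per chromosome under Hardy–Weinberg at
per-site allele frequencies given either as one fixed value or a
Beta(a, b) law. An optional symmetric per-allele genotyping error flips
observed alleles at a stated rate.

Randomness: one master seed; each stage (frequencies, haplotypes, placement,
errors, amplicon sequence) derives its own independent stream from a fixed
stage offset, so adding a stage never perturbs earlier ones. The same seed
reproduces the cohort bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alleles import GenotypeCall, parse_allele
from .assay import ProbeSet, revcomp
from .segregation import Verdict, prioritize
from .variant_table import AFFECTED, UNAFFECTED, VariantSite, VariantTable

_BASES = "ACGT"
_STAGE_FREQ, _STAGE_HAPLO, _STAGE_PLACE, _STAGE_ERROR, _STAGE_SEQ = range(5)


@dataclass(frozen=True)
class CohortSimSpec:
    """Generator parameters.

    ``allele_freq_law`` is either a float (every background site shares that
    alternate-allele frequency) or a ``("beta", a, b)`` triple drawing each
    site's frequency independently. The default Beta(1, 1) (uniform) reflects
    background polymorphisms of unknown frequency.
    """

    n_affected: int = 2
    n_unaffected: int = 2
    n_background_sites: int = 36
    allele_freq_law: float | tuple = ("beta", 1.0, 1.0)
    penetrance: float = 1.0
    causal_on_founder_haplotype: bool = True
    lethal_homozygote: bool = True
    genotyping_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_affected < 1 or self.n_unaffected < 1:
            raise ValueError("need at least one affected and one unaffected individual")
        if self.n_background_sites < 0:
            raise ValueError("n_background_sites must be >= 0")
        if isinstance(self.allele_freq_law, (int, float)):
            if not 0.0 < float(self.allele_freq_law) < 1.0:
                raise ValueError("fixed allele frequency must lie in (0, 1)")
        else:
            kind, a, b = self.allele_freq_law
            if kind != "beta" or a <= 0 or b <= 0:
                raise ValueError("allele_freq_law must be a float or ('beta', a, b)")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must lie in [0, 1]")
        if not 0.0 <= self.genotyping_error_rate < 1.0:
            raise ValueError("genotyping_error_rate must lie in [0, 1)")


@dataclass
class SimTruth:
    """Everything needed to recompute the observables deterministically."""

    causal_assay_id: str
    causal_index: int
    ref_alt: dict[str, tuple[str, str]]  # assay_id -> (ref token, alt token)
    diplotypes: dict[str, tuple[tuple[str, ...], tuple[str, ...]]]  # true, pre-error
    founder_ids: dict[str, tuple[str, str]]
    carriers: set[str] = field(default_factory=set)  # samples truly carrying causal alt

    def causal_tokens(self, sample: str) -> tuple[str, str]:
        h1, h2 = self.diplotypes[sample]
        return (h1[self.causal_index], h2[self.causal_index])


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, seed])


def simulate_cohort(spec: CohortSimSpec) -> tuple[VariantTable, SimTruth]:
    """Draw one cohort; returns the observed genotype table and the truth."""
    n_sites = spec.n_background_sites + 1
    samples = [f"A{i + 1}" for i in range(spec.n_affected)] + [
        f"U{i + 1}" for i in range(spec.n_unaffected)
    ]
    status = {s: (AFFECTED if s.startswith("A") else UNAFFECTED) for s in samples}

    rng_freq = _stage_rng(spec.seed, _STAGE_FREQ)
    if isinstance(spec.allele_freq_law, (int, float)):
        freqs = np.full(spec.n_background_sites, float(spec.allele_freq_law))
    else:
        _, a, b = spec.allele_freq_law
        freqs = rng_freq.beta(a, b, size=spec.n_background_sites)
        freqs = np.clip(freqs, 1e-9, 1 - 1e-9)

    rng_place = _stage_rng(spec.seed, _STAGE_PLACE)
    causal_index = int(rng_place.integers(0, n_sites))

    # per-site ref/alt bases; the causal site mirrors a G>A transition
    site_bases: list[tuple[str, str]] = []
    for _ in range(spec.n_background_sites):
        i = int(rng_place.integers(0, 4))
        j = int(rng_place.integers(0, 3))
        ref = _BASES[i]
        alt = _BASES[(i + 1 + j) % 4]
        site_bases.append((ref, alt))
    site_bases.insert(causal_index, ("G", "A"))
    site_freqs = list(freqs)
    site_freqs.insert(causal_index, float("nan"))  # causal allele is not a population draw

    rng_h = _stage_rng(spec.seed, _STAGE_HAPLO)
    diplotypes: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {}
    founder_ids: dict[str, tuple[str, str]] = {}
    carriers: set[str] = set()
    for s_idx, sample in enumerate(samples):
        affected = status[sample] == AFFECTED
        if affected:
            carrier, causal_chrom = True, 0
        else:
            carrier = bool(rng_h.random() < (1.0 - spec.penetrance))
            causal_chrom = int(rng_h.integers(0, 2)) if carrier else -1
        if carrier:
            carriers.add(sample)
        chroms: list[list[str]] = [[], []]
        for j in range(n_sites):
            ref, alt = site_bases[j]
            if j == causal_index:
                for c in (0, 1):
                    chroms[c].append(alt if c == causal_chrom else ref)
            else:
                p = site_freqs[j]
                for c in (0, 1):
                    chroms[c].append(alt if rng_h.random() < p else ref)
        diplotypes[sample] = (tuple(chroms[0]), tuple(chroms[1]))
        ids = [f"priv-{sample}-1", f"priv-{sample}-2"]
        if affected and spec.causal_on_founder_haplotype:
            ids[0] = "founder"
        elif carrier and causal_chrom >= 0:
            ids[causal_chrom] = f"carrier-{sample}"
        founder_ids[sample] = (ids[0], ids[1])

    # observed genotypes, with optional symmetric per-allele flips
    rng_err = _stage_rng(spec.seed, _STAGE_ERROR)
    sites: list[VariantSite] = []
    genotypes: dict[tuple[str, str], GenotypeCall] = {}
    ref_alt: dict[str, tuple[str, str]] = {}
    causal_assay_id = ""
    for j in range(n_sites):
        ref, alt = site_bases[j]
        if j == causal_index:
            assay_id, feature = "sim-causal", "Causal"
        else:
            assay_id, feature = f"sim{j:05d}", "Background"
        site = VariantSite(
            assay_id=assay_id,
            feature=feature,
            position=(j + 1, j + 1),
            db_ref=frozenset({parse_allele(ref)}),
        )
        sites.append(site)
        ref_alt[assay_id] = (ref, alt)
        if j == causal_index:
            causal_assay_id = assay_id
        for sample in samples:
            h1, h2 = diplotypes[sample]
            observed = []
            for tok in (h1[j], h2[j]):
                if spec.genotyping_error_rate and rng_err.random() < spec.genotyping_error_rate:
                    tok = alt if tok == ref else ref
                observed.append(tok)
            genotypes[(assay_id, sample)] = GenotypeCall.of(observed[0], observed[1])

    table = VariantTable(sites=sites, samples=samples, status=status, genotypes=genotypes)
    truth = SimTruth(
        causal_assay_id=causal_assay_id,
        causal_index=causal_index,
        ref_alt=ref_alt,
        diplotypes=diplotypes,
        founder_ids=founder_ids,
        carriers=carriers,
    )
    return table, truth


# -- analytic oracle and Monte-Carlo helpers -------------------------------


def expected_null_pass_rate(p: float, n_affected: int, n_unaffected: int) -> float:
    """Probability that an unlinked Hardy–Weinberg site's alternate allele
    (frequency ``p``) is heterozygous in all affected and absent from all
    unaffected samples: ``(2p(1-p))^nA * ((1-p)^2)^nU``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("allele frequency must lie in [0, 1]")
    return (2.0 * p * (1.0 - p)) ** n_affected * ((1.0 - p) ** 2) ** n_unaffected


def null_candidate_rate(
    p: float, n_affected: int, n_unaffected: int, n_sites: int, seed: int = 0
) -> float:
    """Monte-Carlo rate at which the dominant filter returns a background
    site's alternate allele as candidate, over ``n_sites`` unlinked sites."""
    spec = CohortSimSpec(
        n_affected=n_affected,
        n_unaffected=n_unaffected,
        n_background_sites=n_sites,
        allele_freq_law=p,
        seed=seed,
    )
    table, truth = simulate_cohort(spec)
    result = prioritize(table)
    hits = sum(
        1
        for v in result.candidates
        if v.site.assay_id != truth.causal_assay_id
        and v.candidate_allele.token == truth.ref_alt[v.site.assay_id][1]
    )
    return hits / n_sites


def causal_recovered(table: VariantTable, truth: SimTruth) -> bool:
    """True iff the filter flags the planted causal site with its alt allele."""
    for v in prioritize(table).candidates:
        if (
            v.site.assay_id == truth.causal_assay_id
            and v.candidate_allele.token == truth.ref_alt[truth.causal_assay_id][1]
        ):
            return True
    return False


# -- amplicon simulation ---------------------------------------------------


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _clean(seq: str, probes: ProbeSet) -> bool:
    """Exactly one primer pair, unambiguous strand, one physical probe hit."""
    fwd, rcrev = probes.forward_primer, revcomp(probes.reverse_primer)
    if seq.count(fwd) != 1 or seq.count(rcrev) != 1:
        return False
    # no primer sites on the opposite strand: keeps the amplicon unambiguous
    if revcomp(fwd) in seq or probes.reverse_primer in seq:
        return False
    probe_hits = sum(
        seq.count(m) + seq.count(revcomp(m))
        for m in (probes.wt_probe, probes.mut_probe)
    )
    return probe_hits == 1


def simulate_amplicons(
    truth: SimTruth,
    probes: ProbeSet,
    flank_len: int = 30,
    seed: int = 0,
    pad_len: int = 8,
) -> list[SeqRecord]:
    """Two template sequences per sample (records ``<sample>/1``, ``/2``),
    embedding the wild-type or mutant probe core between the primers
    according to the sample's true causal diplotype."""
    max_primer = max(len(probes.forward_primer), len(probes.reverse_primer))
    if flank_len < max_primer:
        raise ValueError(f"flank_len must be >= primer length ({max_primer})")
    rng = _stage_rng(seed, _STAGE_SEQ)
    ref, alt = truth.ref_alt[truth.causal_assay_id]
    records = []
    for sample in truth.diplotypes:
        toks = truth.causal_tokens(sample)
        for c, tok in enumerate(toks, start=1):
            core = probes.mut_probe if tok == alt else probes.wt_probe
            for _ in range(100):
                seq = (
                    _random_bases(rng, flank_len)
                    + probes.forward_primer
                    + _random_bases(rng, pad_len)
                    + core
                    + _random_bases(rng, pad_len)
                    + revcomp(probes.reverse_primer)
                    + _random_bases(rng, flank_len)
                )
                if _clean(seq, probes):
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError("could not draw a clean template")
            records.append(SeqRecord(Seq(seq), id=f"{sample}/{c}", description=""))
    return records
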