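from itertools import product

import numpy as np
import pytest
from hypothesis import given, strategies as st

from domseg.haplotype import (
    Haplotype,
    PhasingSearchError,
    check_phasing,
    decode_haplotype,
    encode_haplotype,
    min_parsimony_phase,
)

from conftest import make_table, random_snv_table

A, U = "affected", "unaffected"


def brute_force_min_haplotypes(table, cap=200_000):
    """Independent oracle: enumerate every per-sample split of the raw
    (uncollapsed) genotype matrix and minimise distinct haplotypes."""
    per_sample = []
    for sample in table.samples:
        calls = [table.genotype(s, sample) for s in table.sites]
        het = [i for i, c in enumerate(calls) if c.heterozygous]
        options = []
        for bits in product((0, 1), repeat=max(len(het) - 1, 0)):
            flips = dict(zip(het[1:], bits))
            h1, h2 = [], []
            for i, c in enumerate(calls):
                a, b = c.tokens()
                if flips.get(i):
                    a, b = b, a
                h1.append(a)
                h2.append(b)
            options.append((tuple(h1), tuple(h2)))
        per_sample.append(options)
    n_combos = int(np.prod([len(o) for o in per_sample]))
    assert n_combos <= cap, "enumeration too large for the oracle"
    best = None
    for combo in product(*per_sample):
        haps = set()
        for h1, h2 in combo:
            haps.add(h1)
            haps.add(h2)
        best = len(haps) if best is None else min(best, len(haps))
    return best


class TestEncoding:
    def test_encode_published_haplotype5(self, pkd1_phasing):
        hap5 = pkd1_phasing["Dog1"][0]
        rendered = encode_haplotype(hap5)
        assert rendered.startswith("31A-C-A-G-G-G-10C")
        # exon-29 slot (30th of 37) carries the disease allele A
        assert rendered.split("-")[29] == "A"

    def test_empty_haplotype_renders_empty(self):
        assert encode_haplotype(Haplotype(())) == ""
        assert decode_haplotype("") == Haplotype(())

    @given(
        st.lists(
            st.one_of(
                st.text(alphabet="ACGT", min_size=1, max_size=3),
                st.just("Del"),
                st.tuples(st.integers(1, 30), st.sampled_from("ACGT")).map(
                    lambda t: f"{t[0]}{t[1]}"
                ),
            ),
            max_size=12,
        )
    )
    def test_decode_encode_round_trip(self, tokens):
        h = decode_haplotype("-".join(tokens))
        assert encode_haplotype(h) == "-".join(tokens)
        assert decode_haplotype(encode_haplotype(h)).alleles == h.alleles


class TestCheckPhasing:
    def test_published_assignment_is_consistent(self, pkd1_table, pkd1_phasing):
        labels = {
            s: (p[0].label, p[1].label) for s, p in pkd1_phasing.items()
        }
        assert labels == {
            "Dog1": ("Hap5", "Hap4"),
            "Dog2": ("Hap5", "Hap2"),
            "Dog3": ("Hap1", "Hap2"),
            "Dog4": ("Hap1", "Hap3"),
        }
        assert check_phasing(pkd1_table, pkd1_phasing) == []

    def test_swapping_dog3_breaks_consistency(self, pkd1_table, pkd1_phasing):
        haps = {h.label: h for pair in pkd1_phasing.values() for h in pair}
        swapped = dict(pkd1_phasing)
        swapped["Dog3"] = (haps["Hap4"], haps["Hap2"])
        violations = check_phasing(pkd1_table, swapped)
        assert violations
        assert {v.sample for v in violations} == {"Dog3"}
        # e.g. the 5' UTR repeat site: Hap4/Hap2 give 22A/22A vs genotype 22A/31A
        assert any(v.assay_id == "ss316885484" for v in violations)

    def test_single_site_heterozygote(self):
        t = make_table([["G/A", "G/G"]], [A, U])
        diplos = {
            "S1": (decode_haplotype("G"), decode_haplotype("A")),
            "S2": (decode_haplotype("G"), decode_haplotype("G")),
        }
        assert check_phasing(t, diplos) == []

    def test_length_mismatch_is_an_error(self, pkd1_table):
        bad = {"Dog1": (decode_haplotype("G"), decode_haplotype("A"))}
        with pytest.raises(ValueError, match="length"):
            check_phasing(pkd1_table, bad)


class TestMinParsimonyPhase:
    def test_fixture_needs_exactly_five_haplotypes(self, pkd1_table):
        result = min_parsimony_phase(pkd1_table)
        assert result.n_haplotypes == 5
        assert check_phasing(pkd1_table, result.diplotypes) == []

    def test_affected_dogs_carry_disease_allele_on_one_chromosome(self, pkd1_table):
        result = min_parsimony_phase(pkd1_table)
        exon29 = [s.assay_id for s in pkd1_table.sites].index("ss316885563")
        for dog in ("Dog1", "Dog2"):
            h1, h2 = result.diplotypes[dog]
            carried = [h.alleles[exon29].token for h in (h1, h2)]
            assert sorted(carried) == ["A", "G"]
        for dog in ("Dog3", "Dog4"):
            for h in result.diplotypes[dog]:
                assert h.alleles[exon29].token == "G"

    def test_fully_homozygous_table(self):
        t = make_table(
            [["G/G", "A/A"], ["C/C", "C/C"]], [A, U]
        )
        result = min_parsimony_phase(t)
        assert result.n_haplotypes == 2  # two distinct homozygous vectors
        assert check_phasing(t, result.diplotypes) == []

    def test_two_sample_two_site_shares_the_homozygous_haplotype(self):
        # S1 het at both sites, S2 homozygous A at both: phasing S1 as
        # (A,A)+(G,G) shares the (A,A) haplotype with S2, so the exhaustive
        # minimum is 2 (the (A,G)+(G,A) split would need 3)
        t = make_table([["A/G", "A/A"], ["A/G", "A/A"]], [A, U])
        assert brute_force_min_haplotypes(t) == 2
        result = min_parsimony_phase(t)
        assert result.n_haplotypes == 2
        assert check_phasing(t, result.diplotypes) == []

    def test_deterministic_output(self, pkd1_table):
        r1 = min_parsimony_phase(pkd1_table)
        r2 = min_parsimony_phase(pkd1_table)
        assert [h.render() for h in r1.haplotypes] == [h.render() for h in r2.haplotypes]
        assert {s: (a.label, b.label) for s, (a, b) in r1.diplotypes.items()} == {
            s: (a.label, b.label) for s, (a, b) in r2.diplotypes.items()
        }

    def test_search_space_guard(self):
        rng = np.random.default_rng(0)
        t = random_snv_table(rng, 2, 40)
        # force a tiny threshold so the guard trips
        with pytest.raises(PhasingSearchError, match="collapse"):
            min_parsimony_phase(t, max_het_columns=1)

    def test_matches_exhaustive_oracle_on_random_tables(self):
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 60:
            n_samples = int(rng.integers(2, 5))
            n_sites = int(rng.integers(2, 7))
            t = random_snv_table(rng, n_samples, n_sites)
            het_total = sum(
                table_call.heterozygous
                for s in t.sites
                for table_call in t.column(s)
            )
            if het_total > 10:
                continue
            expected = brute_force_min_haplotypes(t)
            result = min_parsimony_phase(t)
            assert result.n_haplotypes == expected
            assert check_phasing(t, result.diplotypes) == []
            checked += 1

    def test_collapsing_preserves_the_optimum(self):
        """Tables with duplicated pattern columns phase to the same count as
        their collapsed core (identical columns phase identically)."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            t = random_snv_table(rng, 3, 4)
            duplicated_rows = []
            for s in t.sites:
                row = [str(t.genotype(s, smp)) for smp in t.samples]
                duplicated_rows.extend([row, list(row)])
            t_dup = make_table(
                duplicated_rows, [t.status[s] for s in t.samples]
            )
            assert (
                min_parsimony_phase(t_dup).n_haplotypes
                == min_parsimony_phase(t).n_haplotypes
            )
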