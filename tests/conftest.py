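import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from domseg import load_pkd1_variants, load_pkd1_phasing, default_probeset  # noqa: E402
from domseg.alleles import GenotypeCall  # noqa: E402
from domseg.variant_table import VariantSite, VariantTable, parse_allele  # noqa: E402


@pytest.fixture(scope="session")
def pkd1_table():
    return load_pkd1_variants()


@pytest.fixture(scope="session")
def pkd1_phasing():
    return load_pkd1_phasing()


@pytest.fixture(scope="session")
def probes():
    return default_probeset()


def make_table(genotype_rows, statuses, db_refs=None, features=None, positions=None):
    """Build a small VariantTable from token-pair rows.

    genotype_rows: list of per-site lists of 'X/Y' strings, one per sample.
    statuses: list of 'affected'/'unaffected', one per sample.
    """
    n_samples = len(statuses)
    samples = [f"S{i + 1}" for i in range(n_samples)]
    sites, genotypes = [], {}
    for j, row in enumerate(genotype_rows):
        db = db_refs[j] if db_refs else row[0].split("/")[0]
        feature = features[j] if features else "Exon 1"
        pos = positions[j] if positions else (j + 1, j + 1)
        site = VariantSite(
            assay_id=f"site{j + 1}",
            feature=feature,
            position=pos,
            db_ref=frozenset(parse_allele(t) for t in db.split("|")),
        )
        sites.append(site)
        for sample, cell in zip(samples, row):
            genotypes[(site.assay_id, sample)] = GenotypeCall.parse(cell)
    return VariantTable(
        sites=sites,
        samples=samples,
        status=dict(zip(samples, statuses)),
        genotypes=genotypes,
    )


def random_snv_table(rng: np.random.Generator, n_samples: int, n_sites: int):
    """Random biallelic SNV table for property tests."""
    bases = "ACGT"
    rows = []
    for _ in range(n_sites):
        i = int(rng.integers(0, 4))
        ref, alt = bases[i], bases[(i + 1 + int(rng.integers(0, 3))) % 4]
        row = []
        for _ in range(n_samples):
            pair = [ref if rng.random() < 0.5 else alt for _ in range(2)]
            row.append("/".join(pair))
        rows.append(row)
    statuses = ["affected"] + ["unaffected"] * (n_samples - 1)
    return make_table(rows, statuses)
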