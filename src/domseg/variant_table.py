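"""Per-feature variant sites, the site × sample genotype matrix, and I/O.

The native dialect is a tab-separated file with one leading metadata line::

    #status:<TAB>Dog1=affected<TAB>Dog2=affected<TAB>Dog3=unaffected ...
    assay_id<TAB>feature<TAB>position<TAB>db_ref<TAB>Dog1<TAB>...<TAB>DogN
    ss316885563<TAB>Exon 29<TAB>42<TAB>G<TAB>G/A<TAB>G/A<TAB>G/G<TAB>G/G

Positions are 1-based offsets, or inclusive 1-based ranges ``start-end``,
from the 5' end of the named feature (UTR, exon or intron). ``db_ref`` holds
one or two ``|``-separated database reference alleles. Lines starting with
``#`` other than the status line are comments.

A VCF 4.2 export/import is provided for tables whose alleles can be written
as literal nucleotide strings (SNVs, multi-base substitutions, run-length
repeats); the 59-bp deletion has no recorded sequence and is exported with a
placeholder ``N`` run, so VCF round-trips are only lossless for literal
tables.
"""

from __future__ import annotations

import io
import tempfile
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

from .alleles import Allele, AlleleForm, AlleleParseError, GenotypeCall, parse_allele

AFFECTED = "affected"
UNAFFECTED = "unaffected"
_STATUS_LABELS = {AFFECTED, UNAFFECTED}


class TableFormatError(ValueError):
    """Structured parse error for the genotype-table dialect."""


@dataclass(frozen=True)
class VariantSite:
    """One variant locus, located relative to the 5' end of its feature."""

    assay_id: str
    feature: str
    position: tuple[int, int]  # inclusive 1-based (start, end); start == end for a point
    db_ref: frozenset[Allele]

    def __post_init__(self) -> None:
        start, end = self.position
        if start < 1 or end < start:
            raise TableFormatError(
                f"{self.assay_id}: position must be >= 1 with start <= end, got {self.position}"
            )
        if not self.db_ref:
            raise TableFormatError(f"{self.assay_id}: db_ref must be non-empty")

    @property
    def start(self) -> int:
        return self.position[0]

    def position_str(self) -> str:
        start, end = self.position
        return str(start) if start == end else f"{start}-{end}"


def _parse_position(text: str) -> tuple[int, int]:
    tok = text.strip().replace("–", "-")  # tolerate en-dash ranges
    if "-" in tok:
        a, b = tok.split("-", 1)
        return (int(a), int(b))
    p = int(tok)
    return (p, p)


def _parse_db_ref(text: str) -> frozenset[Allele]:
    return frozenset(parse_allele(t) for t in text.split("|") if t.strip())


@dataclass
class VariantTable:
    """Ordered variant sites × ordered samples with affection status."""

    sites: list[VariantSite]
    samples: list[str]
    status: dict[str, str]
    genotypes: dict[tuple[str, str], GenotypeCall] = field(repr=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for site in self.sites:
            if site.assay_id in seen:
                raise TableFormatError(f"duplicate assay_id {site.assay_id}")
            seen.add(site.assay_id)
        for sample in self.samples:
            label = self.status.get(sample)
            if label not in _STATUS_LABELS:
                raise TableFormatError(f"unknown or missing status for sample {sample!r}: {label!r}")
        for site in self.sites:
            for sample in self.samples:
                if (site.assay_id, sample) not in self.genotypes:
                    raise TableFormatError(f"missing genotype for {site.assay_id} / {sample}")

    # -- accessors ---------------------------------------------------------

    def genotype(self, site: VariantSite | str, sample: str) -> GenotypeCall:
        assay_id = site if isinstance(site, str) else site.assay_id
        return self.genotypes[(assay_id, sample)]

    def column(self, site: VariantSite | str) -> list[GenotypeCall]:
        return [self.genotype(site, s) for s in self.samples]

    def site(self, assay_id: str) -> VariantSite:
        for s in self.sites:
            if s.assay_id == assay_id:
                return s
        raise KeyError(assay_id)

    @property
    def affected(self) -> list[str]:
        return [s for s in self.samples if self.status[s] == AFFECTED]

    @property
    def unaffected(self) -> list[str]:
        return [s for s in self.samples if self.status[s] == UNAFFECTED]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantTable):
            return NotImplemented
        return (
            self.sites == other.sites
            and self.samples == other.samples
            and self.status == other.status
            and self.genotypes == other.genotypes
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for site in self.sites:
            row = {
                "assay_id": site.assay_id,
                "feature": site.feature,
                "position": site.position_str(),
                "db_ref": "|".join(sorted(a.token for a in site.db_ref)),
            }
            for sample in self.samples:
                row[sample] = str(self.genotype(site, sample))
            rows.append(row)
        return pd.DataFrame(rows)

    # -- dialect I/O -------------------------------------------------------

    def render(self) -> str:
        out = io.StringIO()
        status_cells = "\t".join(f"{s}={self.status[s]}" for s in self.samples)
        out.write(f"#status:\t{status_cells}\n")
        out.write("\t".join(["assay_id", "feature", "position", "db_ref", *self.samples]) + "\n")
        for site in self.sites:
            cells = [
                site.assay_id,
                site.feature,
                site.position_str(),
                "|".join(sorted(a.token for a in site.db_ref)),
            ]
            cells += [str(self.genotype(site, s)) for s in self.samples]
            out.write("\t".join(cells) + "\n")
        return out.getvalue()

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.render())


def parse_variant_table(text: str) -> VariantTable:
    """Parse the tab-separated dialect into a :class:`VariantTable`."""
    status: dict[str, str] = {}
    header: list[str] | None = None
    sites: list[VariantSite] = []
    genotypes: dict[tuple[str, str], GenotypeCall] = {}
    samples: list[str] = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#status:"):
            body = line[len("#status:"):]
            for cell in body.split("\t"):
                cell = cell.strip()
                if not cell:
                    continue
                if "=" not in cell:
                    raise TableFormatError(f"line {lineno}: bad status cell {cell!r}")
                sample, label = cell.split("=", 1)
                if label not in _STATUS_LABELS:
                    raise TableFormatError(
                        f"line {lineno}: unknown status label {label!r} for sample {sample!r}"
                    )
                status[sample.strip()] = label.strip()
            continue
        if line.startswith("#"):
            continue
        cells = line.split("\t")
        if header is None:
            header = [c.strip() for c in cells]
            if header[:4] != ["assay_id", "feature", "position", "db_ref"]:
                raise TableFormatError(
                    f"line {lineno}: header must start with assay_id/feature/position/db_ref"
                )
            samples = header[4:]
            if not samples:
                raise TableFormatError(f"line {lineno}: no sample columns")
            continue
        if len(cells) != len(header):
            raise TableFormatError(
                f"line {lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        try:
            site = VariantSite(
                assay_id=cells[0].strip(),
                feature=cells[1].strip(),
                position=_parse_position(cells[2]),
                db_ref=_parse_db_ref(cells[3]),
            )
        except (ValueError, AlleleParseError) as exc:
            raise TableFormatError(f"line {lineno}: {exc}") from exc
        for sample, cell in zip(samples, cells[4:]):
            if not cell.strip():
                raise TableFormatError(f"line {lineno}: missing cell for sample {sample!r}")
            try:
                genotypes[(site.assay_id, sample)] = GenotypeCall.parse(cell)
            except AlleleParseError as exc:
                raise TableFormatError(
                    f"line {lineno}, sample {sample!r}: {exc}"
                ) from exc
        sites.append(site)

    if header is None:
        raise TableFormatError("no header row found")
    missing = [s for s in samples if s not in status]
    if missing:
        raise TableFormatError(f"samples without status metadata: {missing}")
    return VariantTable(sites=sites, samples=samples, status=status, genotypes=genotypes)


def load_table(path: str | Path) -> VariantTable:
    return parse_variant_table(Path(path).read_text())


def load_pkd1_variants() -> VariantTable:
    """The packaged 37-site × 4-dog Pkd1 genotype fixture."""
    text = resources.files("domseg.data").joinpath("pkd1_variants.tsv").read_text()
    return parse_variant_table(text)


# -- VCF export / import ---------------------------------------------------


class VcfExportError(ValueError):
    pass


def _literal(allele: Allele, site: VariantSite) -> str:
    """Render an allele as a literal nucleotide string for VCF."""
    if allele.form is AlleleForm.BASES:
        return allele.token
    if allele.form is AlleleForm.RUN_LENGTH:
        return allele.base * allele.count
    if allele.form is AlleleForm.SEGMENT:
        return "N" * allele.count  # sequence unrecorded
    if allele.form is AlleleForm.DELETION:
        span = site.position[1] - site.position[0] + 1
        return "N" * span
    raise VcfExportError(f"allele {allele.token!r} is not representable in VCF")


def export_vcf(table: VariantTable, feature_offsets: Mapping[str, int]) -> str:
    """Write the table as VCF 4.2 text.

    ``feature_offsets`` maps each feature name to the absolute 1-based contig
    position of its first base; record POS is ``offset + (position - 1)``.
    All records are placed on one synthetic contig per feature. Deletions are
    left-anchored per VCF convention (REF carries the deleted bases plus a
    leading anchor, ALT the anchor alone).
    """
    missing = sorted({s.feature for s in table.sites} - set(feature_offsets))
    if missing:
        raise VcfExportError(f"no offset supplied for features: {missing}")

    def contig(feature: str) -> str:
        return feature.replace(" ", "_").replace("'", "p")

    lines = ["##fileformat=VCFv4.2"]
    for feat in dict.fromkeys(s.feature for s in table.sites):
        lines.append(f"##contig=<ID={contig(feat)}>")
    lines.append('##INFO=<ID=FEATURE,Number=1,Type=String,Description="Source feature">')
    lines.append('##INFO=<ID=OFFSET,Number=1,Type=String,Description="1-based offset in feature">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(table.samples))

    for site in table.sites:
        pos = feature_offsets[site.feature] + site.start - 1
        observed: list[Allele] = []
        for sample in table.samples:
            for a in table.genotype(site, sample).alleles:
                if all(a.token != o.token for o in observed):
                    observed.append(a)
        observed.sort(key=lambda a: a.token)
        has_del = any(a.is_deletion for a in observed)
        in_db = [a for a in observed if a in site.db_ref]
        ref_allele = sorted(in_db or site.db_ref)[0]
        alleles = [ref_allele] + [a for a in observed if a.token != ref_allele.token]
        if has_del:
            # left-anchor: prepend an anchor base, deletion ALT = anchor alone
            ref = "N" + _literal(ref_allele, site)
            alts = [("N" + _literal(a, site)) if not a.is_deletion else "N" for a in alleles[1:]]
            pos -= 1
        else:
            ref = _literal(ref_allele, site)
            alts = [_literal(a, site) for a in alleles[1:]]
        index = {a.token: i for i, a in enumerate(alleles)}
        gts = []
        for sample in table.samples:
            call = table.genotype(site, sample)
            i, j = sorted(index[a.token] for a in call.alleles)
            gts.append(f"{i}/{j}")
        lines.append(
            "\t".join(
                [
                    contig(site.feature),
                    str(pos),
                    site.assay_id,
                    ref,
                    ",".join(alts) if alts else ".",
                    ".",
                    ".",
                    f"FEATURE={contig(site.feature)};OFFSET={site.position_str()}",
                    "GT",
                    *gts,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def import_vcf(text: str, feature_offsets: Mapping[str, int] | None = None) -> VariantTable:
    """Read back a VCF produced by :func:`export_vcf` (literal-allele tables).

    Feature and feature-relative position are recovered from the INFO field.
    Every sample is imported with ``affected`` status unless a
    ``##status=`` header line (as written by callers) is present; statuses
    are not part of VCF, so round-trips should re-attach them explicitly.
    """
    with tempfile.NamedTemporaryFile("w", suffix=".vcf", delete=False) as fh:
        fh.write(text)
        path = fh.name
    sites: list[VariantSite] = []
    genotypes: dict[tuple[str, str], GenotypeCall] = {}
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            info = dict(rec.info)
            feature = str(info.get("FEATURE", rec.chrom)).replace("_", " ")
            offset = str(info.get("OFFSET", rec.pos))
            alleles = [parse_allele(rec.ref)] + [parse_allele(a) for a in (rec.alts or [])]
            site = VariantSite(
                assay_id=rec.id or f"{rec.chrom}:{rec.pos}",
                feature=feature,
                position=_parse_position(offset),
                db_ref=frozenset([alleles[0]]),
            )
            sites.append(site)
            for sample in samples:
                idx = rec.samples[sample]["GT"]
                genotypes[(site.assay_id, sample)] = GenotypeCall.of(
                    alleles[idx[0]], alleles[idx[1]]
                )
    status = {s: AFFECTED for s in samples}
    return VariantTable(sites=sites, samples=samples, status=status, genotypes=genotypes)
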