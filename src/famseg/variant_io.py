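"""Readers and writers for every external format the pipeline touches.

Multi-sample VCF (via pysam), the sample-role file, the variant annotation
table (gene symbol + functional class, the shape of an annotator's output),
GMT gene-set files, the gene-location (cytoband) table, and the packaged
TSV fixtures transcribing the study's two printed variant tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pysam

from .model import (
    ALL_ROLES,
    GERMLINE_ROLES,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    TUMOR_ROLES,
    CHILD_F,
    CHILD_M,
    MOTHER,
    FATHER,
    TUMOR_F,
    TUMOR_M,
    ConfigurationError,
    FamilyCohort,
    FormatError,
    GeneSetCollection,
    IntegrityError,
    VariantRecord,
)

AnnotationMap = dict[tuple[str, int, str, str], tuple[frozenset[str], str]]


def _normalize_chrom(chrom: str) -> str:
    """Normalize chromosome names to the chr-prefixed dialect."""
    return chrom if chrom.startswith("chr") else f"chr{chrom}"


# ---------------------------------------------------------------------------
# sample roles
# ---------------------------------------------------------------------------

def read_roles(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``sample_id<TAB>role``.

    Roles must come from the six-role vocabulary (mother, father, child_f,
    child_m, tumor_f, tumor_m); each role may appear at most once.
    """
    roles: dict[str, str] = {}
    seen_roles: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
        sample, role = fields[0].strip(), fields[1].strip()
        if role not in ALL_ROLES:
            raise ConfigurationError(f"{path}:{lineno}: unknown role {role!r}")
        if role in seen_roles:
            raise ConfigurationError(f"{path}:{lineno}: role {role!r} assigned twice")
        seen_roles.add(role)
        roles[sample] = role
    return roles


def write_roles(roles: Mapping[str, str], path: str | Path) -> None:
    lines = [f"{sample}\t{role}" for sample, role in roles.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _recode_gt(gt: tuple[int | None, ...], alt_index: int) -> int:
    """Dosage of one alternate allele in a (possibly multi-allelic) GT call.

    Any missing allele makes the whole call missing; alleles pointing at a
    different alternate count as reference for this split record. Phasing is
    ignored.
    """
    if len(gt) != 2 or any(a is None for a in gt):
        return MISSING
    dosage = sum(1 for a in gt if a == alt_index)
    return (HOM_REF, HET, HOM_ALT)[dosage]


def read_vcf(
    path: str | Path,
    roles_path: str | Path | None = None,
    *,
    roles: Mapping[str, str] | None = None,
    pass_only: bool = False,
) -> FamilyCohort:
    """Read a multi-sample VCF into a :class:`FamilyCohort`.

    Multi-allelic sites are split into one biallelic record per alternate
    allele, recoding genotypes per record. With ``pass_only`` records whose
    FILTER is neither PASS nor missing are dropped.
    """
    if roles is None:
        roles = read_roles(roles_path) if roles_path is not None else {}
    vcf = pysam.VariantFile(str(path))
    if "GT" not in vcf.header.formats:
        raise FormatError(f"{path}: VCF has no GT FORMAT field")
    samples = list(vcf.header.samples)
    missing_samples = set(roles) - set(samples)
    if missing_samples:
        raise ConfigurationError(
            f"role file names samples absent from the VCF: {sorted(missing_samples)}"
        )

    variants: list[VariantRecord] = []
    rows: list[list[int]] = []
    for rec in vcf:
        if pass_only:
            filters = list(rec.filter.keys())
            if filters and filters != ["PASS"]:
                continue
        alts = rec.alts or ()
        gts = [rec.samples[s].get("GT") or (None, None) for s in samples]
        for alt_index, alt in enumerate(alts, start=1):
            if alt is None or alt == "*":
                continue
            variants.append(
                VariantRecord(
                    chrom=_normalize_chrom(rec.chrom),
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    rsid=rec.id,
                )
            )
            rows.append([_recode_gt(gt, alt_index) for gt in gts])
    vcf.close()

    genotypes = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    return FamilyCohort(variants, samples, roles, genotypes)


_DEFAULT_CONTIGS = [f"chr{c}" for c in list(range(1, 23)) + ["X", "Y", "M"]]


def write_vcf(cohort: FamilyCohort, path: str | Path) -> None:
    """Write a cohort back out as an uncompressed VCF v4.2."""
    header = pysam.VariantHeader()
    header.formats.add("GT", 1, "String", "Genotype")
    contigs = list(dict.fromkeys(v.chrom for v in cohort.variants))
    for contig in contigs or _DEFAULT_CONTIGS:
        header.contigs.add(contig)
    for sample in cohort.samples:
        header.add_sample(sample)

    gt_encoding = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, variant in enumerate(cohort.variants):
            rec = out.new_record(
                contig=variant.chrom,
                start=variant.pos - 1,
                alleles=(variant.ref, variant.alt),
                id=variant.rsid,
            )
            for j, sample in enumerate(cohort.samples):
                rec.samples[sample]["GT"] = gt_encoding[int(cohort.genotypes[i, j])]
            out.write(rec)


# ---------------------------------------------------------------------------
# annotation table
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> AnnotationMap:
    """Read a variant annotation TSV into a lookup keyed by variant identity.

    Columns: chrom, pos, ref, alt, gene(s) (comma-separated), func_class.
    A header row is detected and skipped; unknown functional-class strings
    map to "other".
    """
    from .model import FUNC_CLASSES

    mapping: AnnotationMap = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 6:
            raise FormatError(f"{path}:{lineno}: expected 6 tab-separated fields")
        chrom, pos_s, ref, alt, genes_s, func = (f.strip() for f in fields[:6])
        if lineno == 1 and not pos_s.isdigit():
            continue  # header row
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: position {pos_s!r} is not an integer") from exc
        genes = frozenset(g.strip() for g in genes_s.split(",") if g.strip())
        func = func if func in FUNC_CLASSES else "other"
        mapping[(_normalize_chrom(chrom), pos, ref, alt)] = (genes, func)
    return mapping


def write_annotation(cohort: FamilyCohort, path: str | Path) -> None:
    lines = ["chrom\tpos\tref\talt\tgenes\tfunc_class"]
    for v in cohort.variants:
        lines.append(
            f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{','.join(sorted(v.genes))}\t{v.func_class}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def attach_annotation(cohort: FamilyCohort, annotation: AnnotationMap) -> FamilyCohort:
    """Return a cohort whose records carry gene symbols and functional class.

    Variants absent from the annotation keep empty genes and class "other".
    """
    annotated = [
        v.with_annotation(*annotation[v.key]) if v.key in annotation else v
        for v in cohort.variants
    ]
    return FamilyCohort(annotated, cohort.samples, cohort.roles, cohort.genotypes)


# ---------------------------------------------------------------------------
# gene sets and gene locations
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, background: set[str] | frozenset[str]) -> GeneSetCollection:
    """Read a GMT file (name, description, member genes, tab-separated).

    Members are restricted to the background; duplicated members collapse by
    set semantics.
    """
    sets: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected at least 2 tab-separated fields")
        name = fields[0].strip()
        members = frozenset(g.strip() for g in fields[2:] if g.strip())
        sets[name] = members
    return GeneSetCollection(sets=sets, background=frozenset(background))


def read_gene_locations(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a gene-location TSV ``gene<TAB>chromosome<TAB>band``."""
    locations: dict[str, tuple[str, str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
        gene, chrom, band = (f.strip() for f in fields[:3])
        if lineno == 1 and gene.lower() == "gene":
            continue
        locations[gene] = (_normalize_chrom(chrom), band)
    return locations


# ---------------------------------------------------------------------------
# packaged fixtures (transcribed printed variant tables)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureVariant:
    """A fixture record plus its per-role genotype template."""

    record: VariantRecord
    template: Mapping[str, int]


# Recessive germline pattern: children homozygous-alternate, parents
# heterozygous carriers; the children's tumors retain the germline genotype.
RECESSIVE_TEMPLATE: dict[str, int] = {
    MOTHER: HET,
    FATHER: HET,
    CHILD_F: HOM_ALT,
    CHILD_M: HOM_ALT,
    TUMOR_F: HOM_ALT,
    TUMOR_M: HOM_ALT,
}

# Tumor-acquired pattern: absent from every germline sample, heterozygous in
# both tumors.
TUMOR_DENOVO_TEMPLATE: dict[str, int] = {
    MOTHER: HOM_REF,
    FATHER: HOM_REF,
    CHILD_F: HOM_REF,
    CHILD_M: HOM_REF,
    TUMOR_F: HET,
    TUMOR_M: HET,
}


def read_fixture_table(
    path: str | Path,
    template: Mapping[str, int],
    *,
    expect: Mapping[str, object] | None = None,
) -> list[FixtureVariant]:
    """Read a fixture TSV of variants, tagging each with a genotype template.

    ``expect`` (md5 / n_rows) triggers an integrity check against the file.
    """
    path = Path(path)
    text = path.read_text()
    if expect is not None:
        md5 = hashlib.md5(text.encode()).hexdigest()
        if "md5" in expect and md5 != expect["md5"]:
            raise IntegrityError(f"{path}: checksum {md5} != manifest {expect['md5']}")
    rows: list[FixtureVariant] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 7:
            raise FormatError(f"{path}:{lineno}: expected 7 tab-separated fields")
        chrom, pos_s, rsid, ref, alt, gene, func = (f.strip() for f in fields[:7])
        if lineno == 1 and not pos_s.isdigit():
            continue
        record = VariantRecord(
            chrom=_normalize_chrom(chrom),
            pos=int(pos_s),
            ref=ref,
            alt=alt,
            rsid=None if rsid in (".", "NA", "") else rsid,
            genes=frozenset({gene}),
            func_class=func,
        )
        rows.append(FixtureVariant(record=record, template=dict(template)))
    if expect is not None and "n_rows" in expect and len(rows) != expect["n_rows"]:
        raise IntegrityError(f"{path}: {len(rows)} rows != manifest {expect['n_rows']}")
    return rows


def _packaged(name: str) -> Path:
    return Path(str(resources.files("famseg.data").joinpath(name)))


def _manifest() -> dict:
    return json.loads(_packaged("manifest.json").read_text())


def load_recessive_fixture() -> list[FixtureVariant]:
    """The 85 recessive-pattern variants (73 genes) of the study's first printed table."""
    name = "table1_recessive_variants.tsv"
    return read_fixture_table(_packaged(name), RECESSIVE_TEMPLATE, expect=_manifest()[name])


def load_tumor_denovo_fixture() -> list[FixtureVariant]:
    """The 15 tumor-acquired heterozygous variants of the study's second printed table."""
    name = "table2_tumor_denovo_variants.tsv"
    return read_fixture_table(_packaged(name), TUMOR_DENOVO_TEMPLATE, expect=_manifest()[name])
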