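"""I/O layer: VCF reading/splitting/recoding, annotation, GMT, fixtures."""

from __future__ import annotations

import itertools
import json
from pathlib import Path

import pytest

from famseg import (
    ConfigurationError,
    FormatError,
    IntegrityError,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    load_recessive_fixture,
    load_tumor_denovo_fixture,
    read_annotation,
    read_gmt,
    read_roles,
    read_vcf,
    write_vcf,
)
from famseg.simulate import SimulationPlan, simulate_cohort
from famseg.variant_io import RECESSIVE_TEMPLATE, read_fixture_table

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=chr1>\n##contig=<ID=chr17>\n"
)


def write_test_vcf(path: Path, samples: list[str], rows: list[tuple]) -> Path:
    """rows: (chrom, pos, id, ref, alt, filter, [gt strings])"""
    lines = [VCF_HEADER.rstrip("\n")]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for chrom, pos, vid, ref, alt, flt, gts in rows:
        lines.append(
            f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\t{flt}\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_role_file(path: Path, roles: dict[str, str]) -> Path:
    path.write_text("".join(f"{s}\t{r}\n" for s, r in roles.items()))
    return path


def brute_force_recode(gt: str, alt_index: int) -> int:
    """Independent recoder: dosage of one alternate allele in a GT string."""
    alleles = gt.replace("|", "/").split("/")
    if "." in alleles or len(alleles) != 2:
        return MISSING
    return [HOM_REF, HET, HOM_ALT][sum(1 for a in alleles if int(a) == alt_index)]


class TestGenotypeRecoding:
    def test_het_call_is_het(self, tmp_path):
        vcf = write_test_vcf(tmp_path / "a.vcf", ["S1"], [("chr1", 100, ".", "A", "G", ".", ["0/1"])])
        roles = write_role_file(tmp_path / "r.tsv", {"S1": "mother"})
        cohort = read_vcf(vcf, roles)
        assert cohort.genotypes[0, 0] == HET

    def test_triallelic_split_matches_brute_force(self, tmp_path):
        """Splitting an A->C,T site: every GT pair over 3 alleles recodes, on
        each split record, to the dosage of that record's own alternate."""
        gts = ["/".join(p) for p in itertools.product("012.", repeat=2)]
        samples = [f"S{i}" for i in range(len(gts))]
        vcf = write_test_vcf(
            tmp_path / "tri.vcf", samples, [("chr1", 500, ".", "A", "C,T", ".", gts)]
        )
        roles = write_role_file(tmp_path / "r.tsv", {"S0": "mother"})
        cohort = read_vcf(vcf, roles)
        assert [v.alt for v in cohort.variants] == ["C", "T"]
        for rec_idx, alt_index in ((0, 1), (1, 2)):
            for j, gt in enumerate(gts):
                assert cohort.genotypes[rec_idx, j] == brute_force_recode(gt, alt_index), (
                    gt, alt_index)

    def test_phased_and_order_equivalent(self, tmp_path):
        vcf = write_test_vcf(
            tmp_path / "p.vcf", ["A", "B", "C"],
            [("chr1", 10, ".", "A", "G", ".", ["0|1", "1/0", "./1"])],
        )
        cohort = read_vcf(vcf, write_role_file(tmp_path / "r.tsv", {"A": "mother"}))
        assert list(cohort.genotypes[0]) == [HET, HET, MISSING]

    def test_pass_only_drops_filtered_records(self, tmp_path):
        vcf = write_test_vcf(
            tmp_path / "f.vcf", ["S"],
            [("chr1", 1, ".", "A", "G", "PASS", ["0/1"]),
             ("chr1", 2, ".", "A", "G", "LowQual", ["0/1"]),
             ("chr1", 3, ".", "A", "G", ".", ["0/1"])],
        )
        roles = write_role_file(tmp_path / "r.tsv", {"S": "mother"})
        assert read_vcf(vcf, roles, pass_only=True).n_variants == 2
        assert read_vcf(vcf, roles, pass_only=False).n_variants == 3

    def test_printed_tumor_variant_parses_to_its_table_row(self, tmp_path):
        """The TP53 tumor variant keeps chrom/pos/rsid/alleles through the reader."""
        vcf = write_test_vcf(
            tmp_path / "tp53.vcf", ["S"],
            [("chr17", 7577121, "rs121913343", "G", "A", ".", ["0/1"])],
        )
        v = read_vcf(vcf, write_role_file(tmp_path / "r.tsv", {"S": "tumor_f"})).variants[0]
        assert (v.chrom, v.pos, v.rsid, v.ref, v.alt) == ("chr17", 7577121, "rs121913343", "G", "A")


class TestRolesAndErrors:
    def test_role_absent_from_vcf_is_configuration_error(self, tmp_path):
        vcf = write_test_vcf(tmp_path / "a.vcf", ["S1"], [("chr1", 1, ".", "A", "G", ".", ["0/0"])])
        roles = write_role_file(tmp_path / "r.tsv", {"GHOST": "mother"})
        with pytest.raises(ConfigurationError):
            read_vcf(vcf, roles)

    def test_duplicate_role_assignment_rejected(self, tmp_path):
        roles = write_role_file(tmp_path / "r.tsv", {"A": "mother"})
        with open(roles, "a") as fh:
            fh.write("B\tmother\n")
        with pytest.raises(ConfigurationError):
            read_roles(roles)


class TestRoundTrip:
    def test_write_read_preserves_variants_and_genotypes(self, tmp_path):
        cohort, _ = simulate_cohort(SimulationPlan(
            n_recessive=10, n_tumor_hom=2, n_tumor_het=3, n_decoys_per_class=2, seed=11))
        write_vcf(cohort, tmp_path / "rt.vcf")
        back = read_vcf(tmp_path / "rt.vcf", roles=cohort.roles)
        assert [(v.chrom, v.pos, v.ref, v.alt) for v in back.variants] == [
            (v.chrom, v.pos, v.ref, v.alt) for v in cohort.variants
        ]
        assert (back.genotypes == cohort.genotypes).all()


class TestAnnotation:
    def test_rows_parse_to_lookup(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "chrom\tpos\tref\talt\tgenes\tfunc_class\n"
            "chr1\t169498975\tT\tC\tF5\tmissense\n"
            "chr17\t37814080\tG\tA\tSTARD3,ERBB2\tmissense\n"
            "chr1\t100\tA\tG\tX\tweird_class\n"
        )
        ann = read_annotation(path)
        assert ann[("chr1", 169498975, "T", "C")] == (frozenset({"F5"}), "missense")
        assert ann[("chr17", 37814080, "G", "A")][0] == frozenset({"STARD3", "ERBB2"})
        assert ann[("chr1", 100, "A", "G")][1] == "other"

    def test_empty_file_gives_empty_mapping(self, tmp_path):
        (tmp_path / "e.tsv").write_text("")
        assert read_annotation(tmp_path / "e.tsv") == {}

    def test_malformed_row_reports_line_number(self, tmp_path):
        (tmp_path / "bad.tsv").write_text("chr1\t5\tA\n")
        with pytest.raises(FormatError, match=":1"):
            read_annotation(tmp_path / "bad.tsv")


class TestGmt:
    def test_members_restricted_to_background(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("Focal_adhesion\tna\tTNN\tLAMA1\tERBB2\tCOL4A3\n")
        full = read_gmt(path, {"TNN", "LAMA1", "ERBB2", "COL4A3", "F5"})
        assert full.sets["Focal_adhesion"] == frozenset({"TNN", "LAMA1", "ERBB2", "COL4A3"})
        restricted = read_gmt(path, {"TNN", "LAMA1", "ERBB2"})
        assert len(restricted.sets["Focal_adhesion"]) == 3

    def test_duplicate_members_stored_once(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("S\tna\tA\tA\tB\n")
        assert read_gmt(path, {"A", "B"}).sets["S"] == frozenset({"A", "B"})

    def test_short_line_is_parse_error(self, tmp_path):
        (tmp_path / "bad.gmt").write_text("OnlyName\n")
        with pytest.raises(FormatError):
            read_gmt(tmp_path / "bad.gmt", {"A"})


class TestPackagedFixtures:
    def test_recessive_table_has_85_variants_in_73_genes(self):
        fx = load_recessive_fixture()
        assert len(fx) == 85
        assert len({g for f in fx for g in f.record.genes}) == 73
        assert all(f.template["child_f"] == HOM_ALT and f.template["mother"] == HET for f in fx)

    def test_tumor_table_has_15_variants(self):
        fx = load_tumor_denovo_fixture()
        assert len(fx) == 15
        assert all(f.template["child_f"] == HOM_REF and f.template["tumor_f"] == HET for f in fx)
        keys = {(f.record.chrom, f.record.pos) for f in fx}
        assert ("chr17", 7577121) in keys  # the TP53 hotspot row

    def test_empty_table_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("chrom\tpos\trsid\tref\talt\tgene\tfunc_class\n")
        assert read_fixture_table(path, RECESSIVE_TEMPLATE) == []

    def test_manifest_mismatch_is_integrity_error(self, tmp_path):
        from famseg.variant_io import _manifest, _packaged

        name = "table1_recessive_variants.tsv"
        expect = dict(_manifest()[name])
        expect["n_rows"] = 84
        with pytest.raises(IntegrityError):
            read_fixture_table(_packaged(name), RECESSIVE_TEMPLATE, expect=expect)
        expect = dict(_manifest()[name])
        expect["md5"] = "0" * 32
        with pytest.raises(IntegrityError):
            read_fixture_table(_packaged(name), RECESSIVE_TEMPLATE, expect=expect)
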