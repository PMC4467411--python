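"""Shared fixtures: the printed-table VCF bundle and small cohort builders."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pytest

from famseg import (
    ALL_ROLES,
    FamilyCohort,
    VariantRecord,
    attach_annotation,
    load_recessive_fixture,
    load_tumor_denovo_fixture,
    read_annotation,
    read_vcf,
)
from famseg.simulate import (
    DEFAULT_SAMPLES,
    SYNTHETIC_TUMOR_HOM_PLANT,
    SimulationPlan,
    fixture_to_vcf,
)

ROLE_TO_SAMPLE = {role: sample for sample, role in DEFAULT_SAMPLES.items()}


def build_cohort(
    rows: Sequence[tuple[VariantRecord, Mapping[str, int]]],
    roles: Sequence[str] = ALL_ROLES,
) -> FamilyCohort:
    """Build a cohort from (record, role->genotype) pairs.

    Roles absent from a row's mapping default to homozygous reference.
    """
    samples = [ROLE_TO_SAMPLE[r] for r in roles]
    genotypes = np.array(
        [[gts.get(role, 0) for role in roles] for _, gts in rows], dtype=np.int8
    ) if rows else np.empty((0, len(samples)), dtype=np.int8)
    return FamilyCohort(
        [rec for rec, _ in rows],
        samples,
        {s: r for s, r in zip(samples, roles)},
        genotypes,
    )


def make_variant(
    i: int,
    gene: str = "GENE",
    chrom: str = "chr1",
    func_class: str = "missense",
) -> VariantRecord:
    return VariantRecord(
        chrom=chrom, pos=1000 + 10 * i, ref="A", alt="G",
        genes=frozenset({gene}), func_class=func_class,
    )


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory) -> dict[str, Path]:
    """VCF/roles/annotation files of both printed variant tables, the
    synthetic tumor-homozygous plant, and >=100 decoys in every failing
    genotype configuration."""
    out = tmp_path_factory.mktemp("bundle")
    fixtures = (
        load_recessive_fixture()
        + load_tumor_denovo_fixture()
        + [SYNTHETIC_TUMOR_HOM_PLANT]
    )
    plan = SimulationPlan(n_decoys_per_class=10, seed=7)
    return fixture_to_vcf(fixtures, plan, out)


@pytest.fixture(scope="session")
def fixture_cohort(fixture_bundle) -> FamilyCohort:
    """The bundle read back through the VCF/annotation readers."""
    cohort = read_vcf(fixture_bundle["vcf"], fixture_bundle["roles"])
    return attach_annotation(cohort, read_annotation(fixture_bundle["annotation"]))
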