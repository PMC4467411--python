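"""Synthetic family-quad + tumor cohorts with known ground truth.

Generates six-sample cohorts (mother, father, daughter, son, two tumors)
in which each variant is planted with one of the qualifying genotype
templates — recessive (children hom-alt / parents het), tumor newly
homozygous (leukocytes het-or-ref / tumors hom-alt), tumor-acquired
heterozygous (leukocytes hom-ref / tumors het) — or with one of an
exhaustively enumerated list of decoy configurations that must fail every
filter. The decoy list covers, per filter, each way the predicate can
break: a wrong parent, a wrong child, a wrong tumor, a missing call, a
synonymous functional class, and tumor changes confined to one sibling.
Germline decoys are Mendelian-consistent unless labeled de-novo.

A manifest records each variant's intended class, so filter output can be
checked against ground truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    ALL_ROLES,
    CHILD_F,
    CHILD_M,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    MOTHER,
    FATHER,
    TUMOR_F,
    TUMOR_M,
    FamilyCohort,
    VariantRecord,
)
from .variant_io import (
    FixtureVariant,
    write_annotation,
    write_roles,
    write_vcf,
)

# Canonical sample names used in emitted VCFs, in role order.
DEFAULT_SAMPLES: dict[str, str] = {
    "MOTHER": MOTHER,
    "FATHER": FATHER,
    "DAUGHTER": CHILD_F,
    "SON": CHILD_M,
    "TUMOR_DAUGHTER": TUMOR_F,
    "TUMOR_SON": TUMOR_M,
}

CLASS_RECESSIVE = "recessive"
CLASS_TUMOR_HOM = "tumor_newly_homozygous"
CLASS_TUMOR_HET = "tumor_denovo_het"

_R = (MOTHER, FATHER, CHILD_F, CHILD_M, TUMOR_F, TUMOR_M)


def _t(m: int, f: int, cf: int, cm: int, tf: int | None = None, tm: int | None = None) -> dict[str, int]:
    # tumors default to the matching leukocyte genotype
    tf = cf if tf is None else tf
    tm = cm if tm is None else tm
    return dict(zip(_R, (m, f, cf, cm, tf, tm)))


# Qualifying genotype templates, one per planted class.
CLASS_TEMPLATES: dict[str, dict[str, int]] = {
    CLASS_RECESSIVE: _t(HET, HET, HOM_ALT, HOM_ALT),
    CLASS_TUMOR_HOM: _t(HET, HOM_REF, HET, HET, HOM_ALT, HOM_ALT),
    CLASS_TUMOR_HET: _t(HOM_REF, HOM_REF, HOM_REF, HOM_REF, HET, HET),
}

# Decoy configurations. Each entry: (template, functional class or None for
# "drawn"). None of these may pass any filter; the synonymous decoy carries
# the qualifying recessive genotypes and is rejected on class alone.
DECOY_TEMPLATES: dict[str, tuple[dict[str, int], str | None]] = {
    "decoy_parent_hom_ref": (_t(HOM_REF, HET, HET, HET), None),
    "decoy_parent_hom_alt": (_t(HOM_ALT, HET, HOM_ALT, HET), None),
    "decoy_child_het": (_t(HET, HET, HET, HOM_ALT), None),
    "decoy_children_hom_ref": (_t(HET, HET, HOM_REF, HOM_REF), None),
    "decoy_child_missing": (_t(HET, HET, MISSING, HOM_ALT), None),
    "decoy_parent_missing": (_t(MISSING, HET, HOM_ALT, HOM_ALT), None),
    "decoy_synonymous_recessive": (_t(HET, HET, HOM_ALT, HOM_ALT), "synonymous"),
    "decoy_tumor_one_sibling_het": (_t(HOM_REF, HOM_REF, HOM_REF, HOM_REF, HET, HOM_REF), None),
    "decoy_tumor_one_sibling_hom": (_t(HET, HOM_REF, HET, HET, HOM_ALT, HET), None),
    "decoy_tumor_het_child_het": (_t(HET, HOM_REF, HET, HOM_REF, HET, HET), None),
    "decoy_tumor_missing": (_t(HOM_REF, HOM_REF, HOM_REF, HOM_REF, MISSING, HET), None),
    "decoy_tumor_hom_child_hom": (_t(HOM_ALT, HET, HOM_ALT, HOM_ALT, HOM_ALT, HOM_ALT), None),
    "decoy_all_hom_ref": (_t(HOM_REF, HOM_REF, HOM_REF, HOM_REF), None),
    "decoy_all_het": (_t(HET, HET, HET, HET), None),
}


def default_gene_universe(n_genes: int = 60, positions_per_gene: int = 6) -> dict[str, int]:
    """A synthetic gene universe: SIMG01..SIMGnn with a per-gene position budget."""
    return {f"SIMG{i:02d}": positions_per_gene for i in range(1, n_genes + 1)}


@dataclass
class SimulationPlan:
    """Counts and conditions of one simulated cohort.

    Defaults mirror the study's planted classes: 85 recessive variants,
    1 tumor newly-homozygous, 15 tumor-acquired heterozygous, plus 10
    decoys per enumerated failing configuration.
    """

    n_recessive: int = 85
    n_tumor_hom: int = 1
    n_tumor_het: int = 15
    n_decoys_per_class: int = 10
    genes: dict[str, int] = field(default_factory=default_gene_universe)
    fraction_nonsyn: float = 0.8
    indel_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_recessive", "n_tumor_hom", "n_tumor_het", "n_decoys_per_class"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.fraction_nonsyn <= 1:
            raise ValueError("fraction_nonsyn must be in [0, 1]")


_BASES = "ACGT"
_CHROMS = [f"chr{i}" for i in range(1, 23)]


class _GenePlacer:
    """Assigns (gene, chrom, pos) triples; positions unique, >= 2 bp apart."""

    def __init__(self, genes: Mapping[str, int], rng: np.random.Generator) -> None:
        if not genes:
            raise ValueError("gene universe must be non-empty")
        self._order = sorted(genes)
        self._capacity = dict(genes)
        self._rng = rng
        self._next_pos: dict[str, int] = {}
        self._chrom_of = {
            g: _CHROMS[i % len(_CHROMS)] for i, g in enumerate(self._order)
        }
        # disjoint per-gene blocks keep positions unique per chromosome
        self._base_of = {
            g: 1_000_000 + (i // len(_CHROMS)) * 1_000_000 for i, g in enumerate(self._order)
        }
        self._cursor = 0

    def place(self) -> tuple[str, str, int]:
        n = len(self._order)
        for _ in range(n):
            gene = self._order[self._cursor % n]
            self._cursor += 1
            if self._capacity[gene] > 0:
                self._capacity[gene] -= 1
                pos = self._next_pos.get(gene, self._base_of[gene])
                self._next_pos[gene] = pos + int(self._rng.integers(2, 64))
                return gene, self._chrom_of[gene], pos
        raise ValueError("more variants requested than available gene positions")


def _draw_alleles(rng: np.random.Generator, indel: bool) -> tuple[str, str]:
    ref = _BASES[rng.integers(0, 4)]
    if indel:
        return ref + _BASES[rng.integers(0, 4)], ref
    alt = _BASES[rng.integers(0, 4)]
    while alt == ref:
        alt = _BASES[rng.integers(0, 4)]
    return ref, alt


def _draw_func(rng: np.random.Generator, plan: SimulationPlan, forced: str | None, qualifying: bool, indel: bool) -> str:
    if forced is not None:
        return forced
    if qualifying or rng.random() < plan.fraction_nonsyn:
        return "frameshift" if indel else "missense"
    return "synonymous"


def simulate_cohort(
    plan: SimulationPlan, samples: Mapping[str, str] | None = None
) -> tuple[FamilyCohort, pd.DataFrame]:
    """Build a cohort with planted classes and decoys, plus its truth manifest.

    The manifest has one row per variant (chrom, pos, ref, alt, gene,
    label); planted classes always receive a non-synonymous functional
    class, decoys draw theirs unless their class forces one. Identical
    plans and seeds give identical cohorts.
    """
    samples = dict(samples or DEFAULT_SAMPLES)
    rng = np.random.default_rng(plan.seed)
    placer = _GenePlacer(plan.genes, rng)

    requests: list[tuple[str, dict[str, int], str | None, bool]] = []
    for label, count in (
        (CLASS_RECESSIVE, plan.n_recessive),
        (CLASS_TUMOR_HOM, plan.n_tumor_hom),
        (CLASS_TUMOR_HET, plan.n_tumor_het),
    ):
        requests += [(label, CLASS_TEMPLATES[label], None, True)] * count
    for label, (template, forced) in DECOY_TEMPLATES.items():
        requests += [(label, template, forced, False)] * plan.n_decoys_per_class

    role_of = dict(samples)
    sample_list = list(samples)
    rows = []
    for label, template, forced, qualifying in requests:
        gene, chrom, pos = placer.place()
        indel = bool(rng.random() < plan.indel_fraction)
        ref, alt = _draw_alleles(rng, indel)
        func = _draw_func(rng, plan, forced, qualifying, indel)
        record = VariantRecord(
            chrom=chrom, pos=pos, ref=ref, alt=alt,
            genes=frozenset({gene}), func_class=func,
        )
        gts = [template[role_of[s]] for s in sample_list]
        rows.append((record, gts, label))

    chrom_order = {c: i for i, c in enumerate(_CHROMS)}
    rows.sort(key=lambda r: (chrom_order[r[0].chrom], r[0].pos))

    variants = [r[0] for r in rows]
    genotypes = (
        np.array([r[1] for r in rows], dtype=np.int8)
        if rows
        else np.empty((0, len(sample_list)), dtype=np.int8)
    )
    cohort = FamilyCohort(variants, sample_list, role_of, genotypes)
    manifest = pd.DataFrame(
        [
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": sorted(v.genes)[0],
                "func_class": v.func_class,
                "label": label,
            }
            for v, _, label in rows
        ],
        columns=["chrom", "pos", "ref", "alt", "gene", "func_class", "label"],
    )
    return cohort, manifest


# A synthetic stand-in for the one tumor newly-homozygous hit the study
# reports (a frameshift in RAI1): the printed tables do not include its
# coordinates, so this record uses invented chr17 coordinates and carries
# the qualifying genotype pattern (leukocytes het, both tumors hom-alt).
SYNTHETIC_TUMOR_HOM_PLANT = FixtureVariant(
    record=VariantRecord(
        chrom="chr17",
        pos=17_697_000,
        ref="CT",
        alt="C",
        rsid=None,
        genes=frozenset({"RAI1"}),
        func_class="frameshift",
    ),
    template=_t(HET, HOM_REF, HET, HET, HOM_ALT, HOM_ALT),
)


def cohort_from_fixtures(
    fixtures: Sequence[FixtureVariant],
    decoy_plan: SimulationPlan | None = None,
    samples: Mapping[str, str] | None = None,
) -> tuple[FamilyCohort, pd.DataFrame]:
    """Assemble a cohort from fixture records (with their genotype templates),
    interleaved with the decoy classes of ``decoy_plan``.

    Fixture rows are labeled "fixture" in the returned manifest. Decoy
    positions live in reserved high-coordinate blocks and cannot collide
    with fixture coordinates.
    """
    samples = dict(samples or DEFAULT_SAMPLES)
    sample_list = list(samples)
    rows: list[tuple[VariantRecord, list[int], str]] = []
    for fx in fixtures:
        gts = [fx.template.get(samples[s], HOM_REF) for s in sample_list]
        rows.append((fx.record, gts, "fixture"))

    if decoy_plan is not None:
        decoy_only = SimulationPlan(
            n_recessive=0,
            n_tumor_hom=0,
            n_tumor_het=0,
            n_decoys_per_class=decoy_plan.n_decoys_per_class,
            genes={f"DECOY{i:02d}": 12 for i in range(1, 41)},
            fraction_nonsyn=decoy_plan.fraction_nonsyn,
            indel_fraction=decoy_plan.indel_fraction,
            seed=decoy_plan.seed,
        )
        decoys, decoy_manifest = simulate_cohort(decoy_only, samples)
        offset = 500_000_000  # far beyond any printed exome coordinate
        for i, v in enumerate(decoys.variants):
            shifted = VariantRecord(
                chrom=v.chrom, pos=v.pos + offset, ref=v.ref, alt=v.alt,
                rsid=v.rsid, genes=v.genes, func_class=v.func_class,
            )
            rows.append((shifted, list(decoys.genotypes[i, :]), decoy_manifest["label"].iloc[i]))

    chrom_order = {f"chr{i}": i for i in range(1, 23)}
    chrom_order.update({"chrX": 23, "chrY": 24, "chrM": 25})
    rows.sort(key=lambda r: (chrom_order.get(r[0].chrom, 99), r[0].pos))

    variants = [r[0] for r in rows]
    genotypes = (
        np.array([r[1] for r in rows], dtype=np.int8)
        if rows
        else np.empty((0, len(sample_list)), dtype=np.int8)
    )
    cohort = FamilyCohort(variants, sample_list, dict(samples), genotypes)
    manifest = pd.DataFrame(
        [
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "gene": ",".join(sorted(v.genes)), "func_class": v.func_class,
                "label": label,
            }
            for v, _, label in rows
        ],
        columns=["chrom", "pos", "ref", "alt", "gene", "func_class", "label"],
    )
    return cohort, manifest


def write_cohort_files(
    cohort: FamilyCohort, manifest: pd.DataFrame, out_dir: str | Path
) -> dict[str, Path]:
    """Write sim.vcf, roles.tsv, annotation.tsv and truth.tsv for a cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "sim.vcf",
        "roles": out / "roles.tsv",
        "annotation": out / "annotation.tsv",
        "truth": out / "truth.tsv",
    }
    write_vcf(cohort, paths["vcf"])
    write_roles(cohort.roles, paths["roles"])
    write_annotation(cohort, paths["annotation"])
    manifest.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def fixture_to_vcf(
    fixtures: Sequence[FixtureVariant],
    decoy_plan: SimulationPlan | None,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Materialize fixture records (+decoys) as a VCF/roles/annotation bundle."""
    cohort, manifest = cohort_from_fixtures(fixtures, decoy_plan)
    return write_cohort_files(cohort, manifest, out_dir)
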