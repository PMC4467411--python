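"""Genotype-pattern filters over a family-quad cohort.

Three predicates on the joint genotypes of the six samples:

* recessive quad filter — variants homozygous-alternate in both children's
  germlines and heterozygous in both parents (recessive carrier pattern),
  optionally restricted to protein-changing (non-synonymous) variants;
* tumor newly-homozygous filter — heterozygous or reference in the
  children's leukocyte DNA but homozygous-alternate in both tumors
  (loss of the wild-type allele during tumor development);
* tumor de-novo heterozygous filter — absent from the leukocytes of both
  children but heterozygous in both tumors (tumor-acquired variants).

Missing genotypes in any required role disqualify a variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

import numpy as np

from .model import (
    CHILD_F,
    CHILD_M,
    HET,
    HOM_ALT,
    HOM_REF,
    MOTHER,
    FATHER,
    TUMOR_F,
    TUMOR_M,
    FamilyCohort,
    VariantRecord,
)

RECESSIVE = "recessive"
TUMOR_NEWLY_HOMOZYGOUS = "tumor_newly_homozygous"
TUMOR_DENOVO_HET = "tumor_denovo_het"


@dataclass
class FilterResult:
    """Variants passing one filter, with per-gene hit counts.

    ``genes`` is the union of the passing variants' gene sets; a variant
    annotated to k genes contributes to k per-gene counts but once to the
    variant total.
    """

    name: str
    variants: list[VariantRecord] = field(default_factory=list)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for v in self.variants for g in v.genes)

    @property
    def per_gene_counts(self) -> dict[str, int]:
        counts: Counter[str] = Counter()
        for v in self.variants:
            counts.update(v.genes)
        return dict(counts)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def _select(cohort: FamilyCohort, mask: np.ndarray, name: str) -> FilterResult:
    # output order is the input variant order (deterministic)
    passing = [v for v, keep in zip(cohort.variants, mask) if keep]
    return FilterResult(name=name, variants=passing)


def recessive_quad_filter(cohort: FamilyCohort, nonsyn_only: bool = True) -> FilterResult:
    """Variants hom-alt in both children and het in both parents.

    With ``nonsyn_only`` only protein-changing variants (missense,
    frameshift, stop-gain, stop-loss) pass.
    """
    cohort.require_roles((MOTHER, FATHER, CHILD_F, CHILD_M), "recessive quad filter")
    mask = (
        (cohort.role_genotypes(CHILD_F) == HOM_ALT)
        & (cohort.role_genotypes(CHILD_M) == HOM_ALT)
        & (cohort.role_genotypes(MOTHER) == HET)
        & (cohort.role_genotypes(FATHER) == HET)
    )
    if nonsyn_only:
        nonsyn = np.array([v.is_nonsynonymous for v in cohort.variants], dtype=bool)
        mask &= nonsyn
    return _select(cohort, mask, RECESSIVE)


def tumor_newly_homozygous_filter(cohort: FamilyCohort) -> FilterResult:
    """Variants hom-alt in both tumors but het-or-reference in both leukocyte samples."""
    cohort.require_roles((CHILD_F, CHILD_M, TUMOR_F, TUMOR_M), "tumor newly-homozygous filter")
    cf, cm = cohort.role_genotypes(CHILD_F), cohort.role_genotypes(CHILD_M)
    mask = (
        (cohort.role_genotypes(TUMOR_F) == HOM_ALT)
        & (cohort.role_genotypes(TUMOR_M) == HOM_ALT)
        & ((cf == HOM_REF) | (cf == HET))
        & ((cm == HOM_REF) | (cm == HET))
    )
    return _select(cohort, mask, TUMOR_NEWLY_HOMOZYGOUS)


def tumor_denovo_het_filter(cohort: FamilyCohort) -> FilterResult:
    """Variants absent from both children's leukocytes but het in both tumors."""
    cohort.require_roles((CHILD_F, CHILD_M, TUMOR_F, TUMOR_M), "tumor de-novo het filter")
    mask = (
        (cohort.role_genotypes(CHILD_F) == HOM_REF)
        & (cohort.role_genotypes(CHILD_M) == HOM_REF)
        & (cohort.role_genotypes(TUMOR_F) == HET)
        & (cohort.role_genotypes(TUMOR_M) == HET)
    )
    return _select(cohort, mask, TUMOR_DENOVO_HET)


def multi_hit_genes(result: FilterResult, min_hits: int = 2) -> dict[str, int]:
    """Genes hit by at least ``min_hits`` passing variants, with their counts."""
    if min_hits < 1:
        raise ValueError(f"min_hits must be >= 1, got {min_hits}")
    return {g: n for g, n in result.per_gene_counts.items() if n >= min_hits}
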