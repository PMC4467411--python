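"""Core data model for a nuclear-family quad exome cohort.

The cohort layout mirrors a familial tumor study design: four germline
(leukocyte-derived) samples — mother, father and two affected children —
plus one tumor sample per child. Genotypes at biallelic sites are coded
as allele-dosage integers (0 = homozygous reference, 1 = heterozygous,
2 = homozygous alternate) with -1 for missing calls; the dosage code is
also the per-position weight used by the cumulative gene score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

# Genotype codes. The integer value of the three called states is exactly the
# scoring weight (hom_ref=0, het=1, hom_alt=2); missing carries no weight.
HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

GENOTYPE_NAMES: dict[int, str] = {
    HOM_REF: "hom_ref",
    HET: "het",
    HOM_ALT: "hom_alt",
    MISSING: "missing",
}

# Sample roles. child_f / child_m are the daughter's and son's leukocyte DNA;
# tumor_f / tumor_m the matching tumor DNA.
MOTHER = "mother"
FATHER = "father"
CHILD_F = "child_f"
CHILD_M = "child_m"
TUMOR_F = "tumor_f"
TUMOR_M = "tumor_m"

GERMLINE_ROLES: tuple[str, ...] = (MOTHER, FATHER, CHILD_F, CHILD_M)
TUMOR_ROLES: tuple[str, ...] = (TUMOR_F, TUMOR_M)
ALL_ROLES: tuple[str, ...] = GERMLINE_ROLES + TUMOR_ROLES

# Functional classes. The first four are the non-synonymous (protein-changing)
# classes; everything unrecognized maps to "other".
NONSYN_CLASSES: frozenset[str] = frozenset(
    {"missense", "frameshift", "stopgain", "stoploss"}
)
FUNC_CLASSES: frozenset[str] = NONSYN_CLASSES | {"synonymous", "other"}


class FormatError(ValueError):
    """A file does not conform to its expected format."""


class ConfigurationError(ValueError):
    """Inputs are well-formed but inconsistent with what an operation needs."""


class IntegrityError(ValueError):
    """A packaged fixture does not match its manifest."""


_ALLOWED_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant (multi-allelic sites are split upstream).

    Positions are 1-based as in VCF. ``genes`` may hold several symbols when
    the variant is annotated to overlapping genes; ``func_class`` is one of
    ``FUNC_CLASSES``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str | None = None
    genes: frozenset[str] = field(default_factory=frozenset)
    func_class: str = "other"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or not set(allele.upper()) <= _ALLOWED_BASES:
                raise ValueError(f"invalid allele string {allele!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref!r})")
        if self.func_class not in FUNC_CLASSES:
            object.__setattr__(self, "func_class", "other")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Normalized variant identity used for annotation lookups."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_nonsynonymous(self) -> bool:
        return self.func_class in NONSYN_CLASSES

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def with_annotation(self, genes: Iterable[str], func_class: str) -> "VariantRecord":
        return replace(self, genes=frozenset(genes), func_class=func_class)


class FamilyCohort:
    """Genotype matrix (variants x samples) with a sample-to-role map.

    Each of the six roles maps to at most one sample. The four germline roles
    are required by the segregation filters; the tumor roles only by the
    tumor-vs-leukocyte filters.
    """

    def __init__(
        self,
        variants: list[VariantRecord],
        samples: list[str],
        roles: Mapping[str, str],
        genotypes: np.ndarray,
    ) -> None:
        genotypes = np.asarray(genotypes, dtype=np.int8)
        if genotypes.shape != (len(variants), len(samples)):
            raise ValueError(
                f"genotype matrix shape {genotypes.shape} does not match "
                f"{len(variants)} variants x {len(samples)} samples"
            )
        bad = set(np.unique(genotypes)) - {HOM_REF, HET, HOM_ALT, MISSING}
        if bad:
            raise ValueError(f"invalid genotype codes {sorted(bad)}")
        unknown_samples = set(roles) - set(samples)
        if unknown_samples:
            raise ConfigurationError(
                f"role file names samples absent from the cohort: {sorted(unknown_samples)}"
            )
        unknown_roles = set(roles.values()) - set(ALL_ROLES)
        if unknown_roles:
            raise ConfigurationError(f"unknown roles: {sorted(unknown_roles)}")
        seen: dict[str, str] = {}
        for sample, role in roles.items():
            if role in seen:
                raise ConfigurationError(
                    f"role {role!r} assigned to both {seen[role]!r} and {sample!r}"
                )
            seen[role] = sample

        self.variants = list(variants)
        self.samples = list(samples)
        self.roles = dict(roles)
        self.genotypes = genotypes
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        self._role_column = {role: self._sample_index[s] for s, role in self.roles.items()}

    # -- introspection -------------------------------------------------------

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def has_roles(self, roles: Iterable[str]) -> bool:
        return set(roles) <= set(self._role_column)

    def require_roles(self, roles: Iterable[str], context: str) -> None:
        missing = sorted(set(roles) - set(self._role_column))
        if missing:
            raise ConfigurationError(f"{context} requires roles {missing}, not present in cohort")

    def role_genotypes(self, role: str) -> np.ndarray:
        """Genotype column (length n_variants) for one role."""
        if role not in self._role_column:
            raise ConfigurationError(f"role {role!r} not present in cohort")
        return self.genotypes[:, self._role_column[role]]

    def genotype(self, variant_idx: int, role: str) -> int:
        return int(self.role_genotypes(role)[variant_idx])

    def subset(self, indices: Iterable[int]) -> "FamilyCohort":
        idx = list(indices)
        return FamilyCohort(
            [self.variants[i] for i in idx],
            self.samples,
            self.roles,
            self.genotypes[idx, :] if idx else np.empty((0, self.n_samples), dtype=np.int8),
        )


@dataclass
class GeneSetCollection:
    """Named gene sets over a fixed background universe.

    After construction every set is restricted to the background; sets that
    become empty are retained (and listed in ``empty_sets``) so that callers
    can report them rather than silently losing categories.
    """

    sets: dict[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        self.background = frozenset(self.background)
        self.sets = {
            name: frozenset(members) & self.background for name, members in self.sets.items()
        }

    @property
    def empty_sets(self) -> list[str]:
        return sorted(name for name, members in self.sets.items() if not members)

    def non_empty(self) -> dict[str, frozenset[str]]:
        return {name: members for name, members in self.sets.items() if members}

    def __len__(self) -> int:
        return len(self.sets)
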