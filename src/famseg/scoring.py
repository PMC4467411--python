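"""Cumulative per-gene genotype scores and the three-step gene filter.

Each genomic position contributes its allele dosage to the carrying gene:
homozygous wild type 0, heterozygous 1, homozygous alternate 2; a gene's
score for one sample is the sum over its positions. The score is additive
over any partition of a gene's positions, so a child who inherits every
heterozygous variant of both parents (on disjoint parental position sets)
scores exactly the sum of the parents' scores.

The three-step filter keeps genes (1) scoring at least ``min_child_score``
in the children, (2) whose children's mean score is at least
``child_parent_ratio`` times the parents' mean, and (3) whose combined
children's score strictly exceeds the combined parents' score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    CHILD_F,
    CHILD_M,
    GERMLINE_ROLES,
    MISSING,
    MOTHER,
    FATHER,
    ConfigurationError,
    FamilyCohort,
)


@dataclass(frozen=True)
class ScoreConfig:
    """Weights and thresholds of the scoring cascade.

    ``child_rule`` resolves the ambiguity of "a score below 5 in children":
    ``both`` (default, strict) requires each child to reach the threshold,
    ``either`` requires one, ``mean`` the children's average.
    """

    weight_hom_ref: int = 0
    weight_het: int = 1
    weight_hom_alt: int = 2
    min_child_score: int = 5
    child_parent_ratio: float = 1.5
    child_rule: str = "both"

    def __post_init__(self) -> None:
        if self.min_child_score < 0:
            raise ValueError("min_child_score must be >= 0")
        if self.child_parent_ratio <= 0:
            raise ValueError("child_parent_ratio must be > 0")
        if self.child_rule not in ("both", "either", "mean"):
            raise ValueError(f"unknown child_rule {self.child_rule!r}")

    @property
    def weights(self) -> tuple[int, int, int]:
        return (self.weight_hom_ref, self.weight_het, self.weight_hom_alt)


@dataclass
class GeneScoreTable:
    """Per-gene, per-role cumulative scores.

    ``scores``: DataFrame indexed by gene, one column per role.
    ``n_positions``: number of scored positions per gene.
    ``n_missing``: missing genotype calls per gene, summed over scored roles.
    """

    scores: pd.DataFrame
    n_positions: pd.Series
    n_missing: pd.Series

    @property
    def genes(self) -> list[str]:
        return list(self.scores.index)

    @property
    def roles(self) -> list[str]:
        return list(self.scores.columns)

    def to_frame(self) -> pd.DataFrame:
        out = self.scores.copy()
        out.columns = [f"score_{r}" for r in out.columns]
        out["n_positions"] = self.n_positions
        out["n_missing"] = self.n_missing
        out.index.name = "gene"
        return out


def cumulative_scores(
    cohort: FamilyCohort,
    config: ScoreConfig | None = None,
    roles: Iterable[str] | None = None,
    *,
    nonsyn_only: bool = False,
) -> GeneScoreTable:
    """Sum genotype weights per gene and role over all annotated positions.

    Missing genotypes contribute 0 and are tallied in ``n_missing``;
    unannotated variants (no gene symbol) are not scored.
    """
    config = config or ScoreConfig()
    if roles is None:
        role_list = [r for r in (*GERMLINE_ROLES, *("tumor_f", "tumor_m")) if cohort.has_roles([r])]
    else:
        role_list = list(roles)
    if not role_list:
        raise ConfigurationError("cumulative_scores needs at least one role")
    cohort.require_roles(role_list, "cumulative_scores")

    weight_of = dict(zip((0, 1, 2), config.weights))
    scores: dict[str, dict[str, int]] = {}
    n_positions: dict[str, int] = {}
    n_missing: dict[str, int] = {}
    columns = {role: cohort.role_genotypes(role) for role in role_list}
    for i, variant in enumerate(cohort.variants):
        if not variant.genes or (nonsyn_only and not variant.is_nonsynonymous):
            continue
        for gene in variant.genes:
            row = scores.setdefault(gene, {r: 0 for r in role_list})
            n_positions[gene] = n_positions.get(gene, 0) + 1
            for role in role_list:
                code = int(columns[role][i])
                if code == MISSING:
                    n_missing[gene] = n_missing.get(gene, 0) + 1
                else:
                    row[role] += weight_of[code]

    genes = sorted(scores)
    frame = pd.DataFrame(
        [[scores[g][r] for r in role_list] for g in genes],
        index=pd.Index(genes, name="gene"),
        columns=role_list,
        dtype=int,
    )
    return GeneScoreTable(
        scores=frame,
        n_positions=pd.Series({g: n_positions[g] for g in genes}, dtype=int),
        n_missing=pd.Series({g: n_missing.get(g, 0) for g in genes}, dtype=int),
    )


@dataclass(frozen=True)
class RankedGene:
    """One gene surviving the three-step filter."""

    gene: str
    scores: dict[str, int] = field(hash=False)
    ratio: float = 0.0

    @property
    def children_combined(self) -> int:
        return self.scores[CHILD_F] + self.scores[CHILD_M]


def _passes_child_threshold(cf: int, cm: int, config: ScoreConfig) -> bool:
    if config.child_rule == "both":
        return min(cf, cm) >= config.min_child_score
    if config.child_rule == "either":
        return max(cf, cm) >= config.min_child_score
    return (cf + cm) / 2 >= config.min_child_score


def three_step_filter(
    table: GeneScoreTable, config: ScoreConfig | None = None
) -> list[RankedGene]:
    """Apply the three-step gene filter to a germline score table.

    Returns the passing genes sorted by descending combined children's
    score, ties broken alphabetically. ``ratio`` is children's mean over
    parents' mean (infinite when the parents score 0 and the children do
    not).
    """
    config = config or ScoreConfig()
    missing = [r for r in GERMLINE_ROLES if r not in table.roles]
    if missing:
        raise ConfigurationError(f"three_step_filter requires germline roles, missing {missing}")

    kept: list[RankedGene] = []
    for gene, row in table.scores.iterrows():
        cf, cm = int(row[CHILD_F]), int(row[CHILD_M])
        mo, fa = int(row[MOTHER]), int(row[FATHER])
        if not _passes_child_threshold(cf, cm, config):
            continue
        child_mean, parent_mean = (cf + cm) / 2, (mo + fa) / 2
        if parent_mean == 0:
            if child_mean == 0:
                continue
            ratio = math.inf
        else:
            ratio = child_mean / parent_mean
            if child_mean < config.child_parent_ratio * parent_mean:
                continue
        if not cf + cm > mo + fa:
            continue
        kept.append(RankedGene(gene=gene, scores={r: int(row[r]) for r in table.roles}, ratio=ratio))
    kept.sort(key=lambda r: (-r.children_combined, r.gene))
    return kept


def sibling_contrast(
    table: GeneScoreTable, focus: str = CHILD_F, other: str = CHILD_M
) -> list[tuple[str, int]]:
    """Per-gene score difference ``focus - other``, sorted by descending difference.

    Swapping the roles yields the reverse contrast.
    """
    if focus == other:
        raise ConfigurationError("focus and other roles must differ")
    for role in (focus, other):
        if role not in table.roles:
            raise ConfigurationError(f"role {role!r} not in score table")
    diffs = (table.scores[focus] - table.scores[other]).astype(int)
    return sorted(diffs.items(), key=lambda kv: (-kv[1], kv[0]))
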