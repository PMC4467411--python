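"""Hypergeometric over-representation analysis with BH-FDR adjustment.

Given a query gene list (e.g. the genes surviving a segregation filter),
each gene set (pathway, chromosome, or chromosome band) is tested for
over-representation with the one-sided upper-tail hypergeometric test:
the probability of drawing at least the observed overlap when
``query_size`` genes are drawn without replacement from a background of
``background_size`` genes of which ``set_size`` belong to the set.
Raw p-values are adjusted with the Benjamini–Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model import ConfigurationError, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    background_size: int
    p_raw: float
    p_adj: float
    member_genes: frozenset[str]


def hypergeom_pvalue(overlap: int, set_size: int, query_size: int, background_size: int) -> float:
    """Upper-tail (inclusive) hypergeometric probability P(X >= overlap)."""
    return float(hypergeom.sf(overlap - 1, background_size, set_size, query_size))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, aligned to input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def hypergeom_ora(
    query: set[str] | frozenset[str],
    sets: GeneSetCollection,
    *,
    adjust: bool = True,
) -> list[EnrichmentResult]:
    """Test every non-empty gene set for over-representation of ``query``.

    Query genes outside the background are dropped with a warning. Results
    are sorted by (adjusted p, set name).
    """
    if not sets.background:
        raise ConfigurationError("empty background universe")
    outside = set(query) - set(sets.background)
    if outside:
        logger.warning(
            "%d query gene(s) outside the background were dropped: %s",
            len(outside),
            ", ".join(sorted(outside)[:10]),
        )
    query_in = frozenset(query) & sets.background
    background_size = len(sets.background)
    query_size = len(query_in)

    names, raw, overlaps, members = [], [], [], []
    for name, genes in sorted(sets.non_empty().items()):
        hit = query_in & genes
        names.append(name)
        overlaps.append(len(hit))
        members.append(hit)
        raw.append(hypergeom_pvalue(len(hit), len(genes), query_size, background_size))
    adjusted = bh_adjust(raw) if adjust else list(raw)

    results = [
        EnrichmentResult(
            set_name=name,
            overlap=overlap,
            set_size=len(sets.sets[name]),
            query_size=query_size,
            background_size=background_size,
            p_raw=p,
            p_adj=q,
            member_genes=frozenset(hit),
        )
        for name, overlap, hit, p, q in zip(names, overlaps, members, raw, adjusted)
    ]
    results.sort(key=lambda r: (r.p_adj, r.set_name))
    return results


_BAND_RE = re.compile(r"^[pq][0-9]+(\.[0-9]+)*$")


def band_sets_from_locations(
    locations: Mapping[str, tuple[str, str]]
) -> tuple[GeneSetCollection, GeneSetCollection]:
    """Build positional gene sets from a gene -> (chromosome, band) table.

    Returns two collections over the same background (all located genes):
    one set per chromosome (e.g. ``chr22``) and one per chromosome band
    (e.g. ``chr22.q12.2``), supporting a two-level clustering analysis.
    Genes with a malformed band string contribute to the chromosome level
    only and are skipped at the band level with a warning.
    """
    chrom_sets: dict[str, set[str]] = {}
    band_sets: dict[str, set[str]] = {}
    for gene, (chrom, band) in locations.items():
        chrom_sets.setdefault(chrom, set()).add(gene)
        if not _BAND_RE.match(band):
            logger.warning("gene %s has malformed band %r; skipped at band level", gene, band)
            continue
        band_sets.setdefault(f"{chrom}.{band}", set()).add(gene)
    background = frozenset(locations)
    return (
        GeneSetCollection(sets={k: frozenset(v) for k, v in chrom_sets.items()}, background=background),
        GeneSetCollection(sets={k: frozenset(v) for k, v in band_sets.items()}, background=background),
    )


def filter_by_overlap(
    results: Sequence[EnrichmentResult], min_overlap: int = 3
) -> list[EnrichmentResult]:
    """Keep results backed by at least ``min_overlap`` query genes."""
    return [r for r in results if r.overlap >= min_overlap]
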