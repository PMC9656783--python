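"""Overlap-ratio gene-set enrichment against local annotation sets.

For a studied gene list L and an annotation term T over a background U,
the share ratio is 100*|L∩T|/|L| (how much of the list belongs to the
term) and the intersection ratio is 100*|L∩T|/|T| (how much of the term
is captured by the list).  Significance is the one-sided hypergeometric
upper tail P(X >= |L∩T|), adjusted across tested terms with
Benjamini-Hochberg; the reported significance column is
-log10(adjusted p), the scale on which such tables are printed.
Ratios are kept at full precision internally and rounded to two
decimals only at serialization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .meta import bh_fdr
from .simulate import AnnotationSets

logger = logging.getLogger(__name__)

#: floor for adjusted p before taking -log10, to keep the column finite
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    term_name: str
    category: str
    overlap: int
    list_size: int
    term_size: int
    share: float          # percentage of the list inside the term
    intersection: float   # percentage of the term inside the list
    p: float
    fdr: float
    fdr_neglog10: float


def overlap_ratios(gene_list: set[str], term_members: set[str],
                   background: set[str]) -> tuple[int, float, float]:
    """Overlap count, share %, and intersection % of a list against a term."""
    glist = set(gene_list) & set(background)
    term = set(term_members) & set(background)
    if not glist:
        raise ValueError("gene list empty after background restriction")
    if not term:
        raise ValueError("term empty after background restriction")
    overlap = len(glist & term)
    share = 100.0 * overlap / len(glist)
    intersection = 100.0 * overlap / len(term)
    return overlap, share, intersection


def hypergeom_p(overlap: int, list_size: int, term_size: int,
                background_size: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= overlap)."""
    if not (0 <= overlap <= min(list_size, term_size)):
        raise ValueError("overlap must be in [0, min(list_size, term_size)]")
    if term_size > background_size or list_size > background_size:
        raise ValueError("term and list sizes cannot exceed the background")
    return float(stats.hypergeom.sf(overlap - 1, background_size, term_size, list_size))


def enrich(
    gene_list: set[str],
    sets: AnnotationSets,
    min_term_size: int = 1,
) -> list[EnrichmentRow]:
    """Enrichment of ``gene_list`` against every term in ``sets``.

    Terms of size >= ``min_term_size`` are tested; BH adjustment runs
    across all tested terms; rows are reported for terms with overlap
    >= 1, sorted by -log10(adjusted p) descending (ties by term id).
    Genes outside the background are dropped with a warning.
    """
    background = sets.background
    outside = set(gene_list) - background
    if outside:
        logger.warning("%d list genes outside background dropped: %s",
                       len(outside), sorted(outside)[:10])
    glist = set(gene_list) & background
    if not glist:
        raise ValueError("gene list empty after background restriction")
    tested = [(tid, name, members) for tid, name, members in sets.terms
              if len(members) >= min_term_size]
    if not tested:
        return []
    pvals = []
    stats_rows = []
    for tid, name, members in tested:
        overlap, share, intersection = _ratios_unchecked(glist, members)
        p = hypergeom_p(overlap, len(glist), len(members), len(background))
        pvals.append(p)
        stats_rows.append((tid, name, overlap, len(members), share, intersection, p))
    fdr = bh_fdr(pvals)
    rows = []
    for (tid, name, overlap, tsize, share, intersection, p), q in zip(stats_rows, fdr):
        if overlap < 1:
            continue
        rows.append(EnrichmentRow(
            term_id=tid, term_name=name, category=sets.categories.get(tid, "GO"),
            overlap=overlap, list_size=len(glist), term_size=tsize,
            share=share, intersection=intersection, p=p, fdr=float(q),
            fdr_neglog10=float(-np.log10(max(q, _P_FLOOR))),
        ))
    rows.sort(key=lambda r: (-r.fdr_neglog10, r.term_id))
    return rows


def _ratios_unchecked(glist: set[str], members: set[str]) -> tuple[int, float, float]:
    overlap = len(glist & members)
    return overlap, 100.0 * overlap / len(glist), 100.0 * overlap / len(members)


def rows_to_dataframe(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Serialize rows in printed-table form (ratios rounded to 2 decimals)."""
    df = pd.DataFrame([{
        "term_id": r.term_id, "term_name": r.term_name, "category": r.category,
        "fdr_neglog10": round(r.fdr_neglog10, 1),
        "share_pct": round(r.share, 2), "intersection_pct": round(r.intersection, 2),
        "overlap": r.overlap, "list_size": r.list_size, "term_size": r.term_size,
        "p": r.p, "fdr": r.fdr,
    } for r in rows])
    return df
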