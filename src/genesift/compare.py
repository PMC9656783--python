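"""Comparison of two gene lists by name, locus proximity, shared loci,
and shared enriched terms.

Two nomination strategies (literature frequency and differential
expression) rarely agree by exact name; this module quantifies softer
agreement as well: cross-list gene pairs lying within a distance cutoff
on the same chromosome (strictly less than 1 Mbp by default), fixed-
width chromosomal bins occupied by both lists, and annotation terms
significant in both lists' enrichments.  Distance is start-to-start —
the only well-defined choice for a single-coordinate catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .catalog import GeneCatalog
from .enrichment import EnrichmentRow


@dataclass(frozen=True)
class ProximityPair:
    gene_a: str
    gene_b: str
    chromosome: str
    distance: int

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


@dataclass
class ComparisonReport:
    shared_names: set[str]
    proximity_pairs: list[ProximityPair]
    shared_loci: set[tuple[str, int]]
    shared_terms: dict[str, set[str]] = field(default_factory=dict)

    @property
    def n_proximal_genes_a(self) -> int:
        """Distinct list-A genes appearing in at least one proximity pair."""
        return len({p.gene_a for p in self.proximity_pairs})

    @property
    def n_proximal_genes_b(self) -> int:
        return len({p.gene_b for p in self.proximity_pairs})

    def to_dict(self) -> dict:
        return {
            "shared_names": sorted(self.shared_names),
            "proximity_pairs": [
                {"gene_a": p.gene_a, "gene_b": p.gene_b,
                 "chromosome": p.chromosome, "distance": p.distance}
                for p in self.proximity_pairs
            ],
            "n_proximity_pairs": len(self.proximity_pairs),
            "n_proximal_genes": {"list_a": self.n_proximal_genes_a,
                                 "list_b": self.n_proximal_genes_b},
            "shared_loci": sorted([list(x) for x in self.shared_loci]),
            "shared_terms": {k: sorted(v) for k, v in self.shared_terms.items()},
        }


def intersect_names(list_a, list_b, catalog: GeneCatalog | None = None) -> set[str]:
    """Exact case-sensitive intersection after alias canonicalization."""
    a = set(list_a)
    b = set(list_b)
    if catalog is not None:
        a = catalog.canonicalize(a)
        b = catalog.canonicalize(b)
    return a & b


def _require_entries(symbols, catalog: GeneCatalog) -> None:
    missing = sorted(s for s in symbols if s not in catalog)
    if missing:
        raise KeyError(f"symbols absent from catalog: {missing}")


def proximity_pairs(
    list_a,
    list_b,
    catalog: GeneCatalog,
    max_dist: int = 1_000_000,
    include_shared: bool = True,
) -> list[ProximityPair]:
    """All cross-list same-chromosome pairs with start distance strictly
    below ``max_dist``.

    A gene present in both lists yields a distance-0 self pair unless
    ``include_shared=False``.  Output is sorted by chromosome, then
    distance, then gene names.
    """
    a = sorted(catalog.canonicalize(set(list_a)))
    b = sorted(catalog.canonicalize(set(list_b)))
    _require_entries(a + b, catalog)
    pairs = []
    for ga in a:
        ea = catalog.entry(ga)
        for gb in b:
            if ga == gb and not include_shared:
                continue
            eb = catalog.entry(gb)
            if ea.chromosome != eb.chromosome:
                continue
            d = abs(ea.start - eb.start)
            if d < max_dist:
                pairs.append(ProximityPair(ga, gb, ea.chromosome, d))
    pairs.sort(key=lambda p: (p.chromosome, p.distance, p.gene_a, p.gene_b))
    return pairs


def shared_loci(list_a, list_b, catalog: GeneCatalog,
                bin_size: int = 1_000_000) -> set[tuple[str, int]]:
    """Fixed-width bins ``(chromosome, floor(start/bin_size))`` occupied by
    at least one gene from each list."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    a = catalog.canonicalize(set(list_a))
    b = catalog.canonicalize(set(list_b))
    _require_entries(sorted(a | b), catalog)

    def bins(symbols):
        out = set()
        for s in symbols:
            e = catalog.entry(s)
            out.add((e.chromosome, e.start // bin_size))
        return out

    return bins(a) & bins(b)


def shared_terms(
    enrich_a: list[EnrichmentRow],
    enrich_b: list[EnrichmentRow],
    fdr_max: float = 0.05,
) -> dict[str, set[str]]:
    """Terms significant (adjusted p <= fdr_max) in both enrichments,
    grouped by annotation category.

    Raises if the two enrichments disagree on a term's category — a sign
    they were run against different annotation collections.
    """
    cat_a = {r.term_id: r.category for r in enrich_a}
    cat_b = {r.term_id: r.category for r in enrich_b}
    for tid in set(cat_a) & set(cat_b):
        if cat_a[tid] != cat_b[tid]:
            raise ValueError(
                f"term {tid} categorized differently in the two enrichments "
                f"({cat_a[tid]} vs {cat_b[tid]}); were they run on the same collection?")
    sig_a = {r.term_id for r in enrich_a if r.fdr <= fdr_max}
    sig_b = {r.term_id for r in enrich_b if r.fdr <= fdr_max}
    out: dict[str, set[str]] = {}
    for tid in sig_a & sig_b:
        out.setdefault(cat_a[tid], set()).add(tid)
    return out


def compare_lists(
    list_a,
    list_b,
    catalog: GeneCatalog,
    max_dist: int = 1_000_000,
    bin_size: int = 1_000_000,
    enrich_a: list[EnrichmentRow] | None = None,
    enrich_b: list[EnrichmentRow] | None = None,
    fdr_max: float = 0.05,
) -> ComparisonReport:
    """Full comparison report between two gene lists."""
    terms = shared_terms(enrich_a, enrich_b, fdr_max) if enrich_a and enrich_b else {}
    return ComparisonReport(
        shared_names=intersect_names(list_a, list_b, catalog),
        proximity_pairs=proximity_pairs(list_a, list_b, catalog, max_dist),
        shared_loci=shared_loci(list_a, list_b, catalog, bin_size),
        shared_terms=terms,
    )
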