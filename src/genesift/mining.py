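"""Dictionary-based gene-mention mining over an abstract corpus.

The miner tokenizes each abstract, matches tokens against a gene
catalog (canonical symbols and aliases, case-sensitively), counts each
gene at most once per article, and keeps genes mentioned in strictly
more than a threshold number of articles.  A chromosome distribution
summary over the frequent genes is derived from the catalog.

Matching is exact and token-level: no stemming, no fuzzy matching, no
case folding.  Gene symbols are case-significant, and a dictionary
matcher has no model to back off to, so anything softer manufactures
hits.  The unavoidable residual ambiguity — symbols that are also
English words — is handled by a configurable blacklist.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .catalog import GeneCatalog

# Tokens are alphanumeric runs; hyphens are kept inside tokens so symbols
# like HLA-DRB1 survive tokenization intact.
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:-[A-Za-z0-9]+)*")

#: Gene symbols that double as common English words; matched tokens equal to
#: these are ignored by default.  Configurable per run.
DEFAULT_BLACKLIST: frozenset[str] = frozenset({
    "SET", "CAT", "MET", "REST", "IMPACT", "LARGE", "CELL", "SHE", "WAS",
    "ALL", "CAMP", "MICE", "GC", "UP", "OUT", "FAST", "AIM", "TYPE",
})

#: Minimal default stop set; callers mining real abstracts should supply a
#: fuller stop-phrase list.
DEFAULT_STOP_PHRASES: frozenset[str] = frozenset({
    "the", "of", "and", "a", "to", "in", "is", "was", "that", "for", "on",
    "are", "with", "as", "by", "this", "be", "from", "or", "an", "gene",
    "genes", "were", "which", "at", "not", "but",
})


@dataclass
class MentionIndex:
    """Per-gene article-id sets from one corpus scan."""

    per_gene: dict[str, set[str]]
    n_articles_scanned: int

    def counts(self) -> dict[str, int]:
        return {g: len(a) for g, a in self.per_gene.items()}


@dataclass
class FrequencyTable:
    """Frequent genes and their article counts, sorted by count descending
    (ties lexicographic)."""

    rows: list[tuple[str, int]]
    threshold_used: int

    def symbols(self) -> list[str]:
        return [s for s, _ in self.rows]

    def __len__(self) -> int:
        return len(self.rows)


def normalize_text(text: str, stop_phrases: set[str] | frozenset[str] = frozenset()) -> list[str]:
    """Tokenize ``text`` and apply the redundancy-removal rules.

    Splits on non-alphanumeric boundaries keeping intra-token hyphens,
    drops stop-phrase tokens case-insensitively, and collapses runs of
    consecutive duplicate tokens (case-insensitive comparison, original
    case kept on the surviving token).
    """
    stops = {s.lower() for s in stop_phrases}
    out: list[str] = []
    prev_lower: str | None = None
    for tok in _TOKEN_RE.findall(text):
        low = tok.lower()
        if low in stops:
            continue
        if low == prev_lower:
            continue
        out.append(tok)
        prev_lower = low
    return out


def match_genes(
    tokens: list[str],
    catalog: GeneCatalog,
    blacklist: set[str] | frozenset[str] = DEFAULT_BLACKLIST,
) -> set[str]:
    """Return the canonical symbols matched by ``tokens``.

    A token matches iff it equals a catalog symbol or alias
    case-sensitively and is not blacklisted; alias hits resolve to the
    canonical symbol.
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    amap = catalog.alias_map()
    return {amap[t] for t in tokens if t in amap and t not in blacklist}


def build_index(
    corpus,
    catalog: GeneCatalog,
    stop_phrases: set[str] | frozenset[str] = frozenset(),
    blacklist: set[str] | frozenset[str] = DEFAULT_BLACKLIST,
) -> MentionIndex:
    """Scan a corpus and index which articles mention which genes.

    ``corpus`` is a :class:`~genesift.simulate.SyntheticCorpus` or any
    iterable of ``(article_id, text)`` pairs.  A gene is counted once
    per article regardless of within-article repeats.
    """
    articles = corpus.articles if hasattr(corpus, "articles") else list(corpus)
    per_gene: dict[str, set[str]] = {}
    n = 0
    for rec in articles:
        try:
            article_id, text = rec
        except (TypeError, ValueError) as exc:
            raise IOError(f"unreadable corpus record: {rec!r}") from exc
        n += 1
        hits = match_genes(normalize_text(text, stop_phrases), catalog, blacklist)
        for g in hits:
            per_gene.setdefault(g, set()).add(article_id)
    return MentionIndex(per_gene=per_gene, n_articles_scanned=n)


def filter_frequent(index: MentionIndex, min_articles: int = 50) -> FrequencyTable:
    """Keep genes mentioned in strictly more than ``min_articles`` articles."""
    if min_articles < 0:
        raise ValueError("min_articles must be >= 0")
    rows = [(g, len(a)) for g, a in index.per_gene.items() if len(a) > min_articles]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return FrequencyTable(rows=rows, threshold_used=min_articles)


def chromosome_distribution(table: FrequencyTable, catalog: GeneCatalog) -> dict[str, int]:
    """Count frequent genes per chromosome (all catalog chromosomes reported,
    zeros included)."""
    missing = [s for s, _ in table.rows if s not in catalog]
    if missing:
        raise KeyError(f"symbols absent from catalog: {sorted(missing)}")
    dist = {c: 0 for c in catalog.chromosomes()}
    for sym, _ in table.rows:
        dist[catalog.entry(sym).chromosome] += 1
    return dist
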