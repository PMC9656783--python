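"""Gene catalog: symbols, aliases, and chromosomal coordinates.

The catalog is the shared reference for text mining (the match
dictionary), chromosomal distribution summaries, and locus-proximity
comparisons.  It deliberately carries a single coordinate per gene
(the start position), which makes start-to-start distance the only
well-defined inter-gene distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GeneEntry:
    """One catalog gene: canonical symbol, aliases, and locus."""

    symbol: str
    aliases: tuple[str, ...]
    chromosome: str
    start: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start} for {self.symbol}")


@dataclass
class GeneCatalog:
    """An ordered collection of :class:`GeneEntry` with unique symbols.

    Invariants enforced at construction: symbols are unique, aliases are
    disjoint from the symbol set, and every start position is non-negative.
    """

    entries: list[GeneEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        symbols = [e.symbol for e in self.entries]
        if len(symbols) != len(set(symbols)):
            dupes = sorted({s for s in symbols if symbols.count(s) > 1})
            raise ValueError(f"duplicate symbols in catalog: {dupes}")
        symbol_set = set(symbols)
        for e in self.entries:
            clash = symbol_set.intersection(e.aliases)
            if clash:
                raise ValueError(f"aliases clash with symbols: {sorted(clash)}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbol_set()

    def symbol_set(self) -> set[str]:
        return {e.symbol for e in self.entries}

    def chromosomes(self) -> list[str]:
        """Distinct chromosome labels in catalog order of first appearance."""
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.chromosome, None)
        return list(seen)

    def alias_map(self) -> dict[str, str]:
        """Mapping from every recognisable name (symbol or alias) to the
        canonical symbol."""
        out: dict[str, str] = {}
        for e in self.entries:
            out[e.symbol] = e.symbol
            for a in e.aliases:
                out.setdefault(a, e.symbol)
        return out

    def entry(self, symbol: str) -> GeneEntry:
        for e in self.entries:
            if e.symbol == symbol:
                return e
        raise KeyError(symbol)

    def canonicalize(self, names: set[str] | list[str]) -> set[str]:
        """Resolve aliases to canonical symbols; unknown names pass through."""
        amap = self.alias_map()
        return {amap.get(n, n) for n in names}
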