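"""Synthetic study inputs with recorded ground truth.

Every downstream stage of the pipeline (mining, meta-analysis, network,
enrichment, comparison, biomarker ranking) is exercised on data produced
here, so each generator records exactly what it planted: which articles
mention which gene, which genes are differentially expressed and with
what signed effect, which gene blocks are correlated, which markers are
class-discriminative, and which annotation term is enriched.

Generators are deterministic functions of their arguments and a seed:
equal inputs yield identical outputs.

The corpus model is a bag of decoy sentences drawn from a fixed
common-English vocabulary with gene symbols inserted as standalone
tokens — token-level realism only, which is all a dictionary-based
miner observes.  Expression values are Gaussian on a log2-like scale
around per-gene baselines; an optional negative-binomial count mode
exists for exercising library-size normalization.  Correlated blocks
use a single latent factor per block with loading sqrt(r), so the
expected pairwise correlation within a block equals r.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import GeneCatalog, GeneEntry

# Fixed decoy vocabulary: frequent English words, lower-case, none of which
# collide with the synthetic gene symbols generated below.
COMMON_WORDS: tuple[str, ...] = (
    "the", "of", "and", "a", "to", "in", "is", "was", "that", "for",
    "on", "are", "with", "as", "by", "this", "be", "from", "or", "an",
    "were", "which", "at", "not", "but", "have", "has", "had", "been",
    "their", "its", "also", "can", "may", "more", "these", "such",
    "between", "both", "other", "than", "into", "during", "after",
    "study", "patients", "results", "analysis", "levels", "expression",
    "associated", "increased", "decreased", "significant", "compared",
    "control", "disease", "treatment", "cells", "protein", "role",
    "risk", "clinical", "blood", "glucose", "insulin", "metabolic",
    "chronic", "serum", "plasma", "tissue", "function", "pathway",
    "response", "signaling", "receptor", "factor", "activity", "effect",
    "observed", "higher", "lower", "group", "subjects", "healthy",
    "type", "mellitus", "diabetic", "obesity", "inflammation", "model",
    "data", "findings", "evidence", "potential", "novel", "common",
)


@dataclass
class SyntheticCorpus:
    """Articles plus the planted gene→articles truth.

    ``collisions`` records decoy tokens that deliberately collide with a
    catalog name (planted lower-cased or as-is to probe miner blacklists);
    it maps the colliding string to the article ids where it was planted
    as plain text rather than as a gene mention.
    """

    articles: list[tuple[str, str]]
    truth: dict[str, set[str]]
    collisions: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [a for a, _ in self.articles]
        if len(ids) != len(set(ids)):
            raise ValueError("article ids not unique")
        idset = set(ids)
        for sym, arts in self.truth.items():
            missing = arts - idset
            if missing:
                raise ValueError(f"truth for {sym} cites unknown articles: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.articles)


@dataclass
class ExpressionDataset:
    """A case/control expression matrix with planted structure.

    ``matrix`` is markers × samples; ``labels`` holds one of
    ``{"case", "control"}`` per sample column.  Truth fields record the
    planted differential expression (symbol → signed effect), the
    correlated gene blocks, and the discriminative marker codes.
    """

    dataset_id: str
    platform_id: str
    matrix: pd.DataFrame
    marker_to_gene: dict[str, str]
    labels: pd.Series
    truth_deg: dict[str, float]
    truth_corr_blocks: list[list[str]]
    truth_biomarkers: set[str]

    def __post_init__(self) -> None:
        if len(self.labels) != self.matrix.shape[1]:
            raise ValueError("labels length must equal sample count")
        classes = set(self.labels)
        if not {"case", "control"} <= classes:
            raise ValueError(f"both classes required, got {sorted(classes)}")
        if not np.isfinite(self.matrix.to_numpy()).all():
            raise ValueError("matrix contains non-finite values")

    @property
    def n_case(self) -> int:
        return int((self.labels == "case").sum())

    @property
    def n_control(self) -> int:
        return int((self.labels == "control").sum())


@dataclass
class AnnotationSets:
    """A GMT-style term collection over a background gene universe."""

    terms: list[tuple[str, str, set[str]]]  # (term_id, term_name, members)
    background: set[str]
    categories: dict[str, str] = field(default_factory=dict)  # term_id -> category tag

    def __post_init__(self) -> None:
        ids = [t[0] for t in self.terms]
        if len(ids) != len(set(ids)):
            raise ValueError("term ids not unique")
        for tid, _, members in self.terms:
            if not members:
                raise ValueError(f"term {tid} has no members")
            stray = members - self.background
            if stray:
                raise ValueError(f"term {tid} members outside background: {sorted(stray)[:5]}")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_catalog(n_genes: int, n_chromosomes: int, seed: int) -> GeneCatalog:
    """Generate ``n_genes`` synthetic genes over ``n_chromosomes`` chromosomes.

    Symbols are ``G0001``-style; roughly a third of genes get one alias
    (``<symbol>-ALT``).  Start positions are uniform on [0, 250 Mb); when
    two or more genes exist the first two are forced onto one chromosome
    within 1 Mbp of each other and the last gene far from both, so locus
    proximity logic always has a positive and a negative instance.
    """
    if n_genes < 1 or n_chromosomes < 1:
        raise ValueError("n_genes and n_chromosomes must be positive")
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chromosomes)]
    width = 4 if n_genes < 10000 else len(str(n_genes))
    entries = []
    for i in range(n_genes):
        sym = f"G{i + 1:0{width}d}"
        aliases: tuple[str, ...] = (f"{sym}-ALT",) if rng.random() < 0.3 else ()
        chrom = chroms[int(rng.integers(n_chromosomes))]
        start = int(rng.integers(0, 250_000_000))
        entries.append(GeneEntry(sym, aliases, chrom, start))
    if n_genes >= 2:
        # guarantee one close pair (< 1 Mbp) and, with 3+ genes, a distant one
        base = int(rng.integers(0, 200_000_000))
        e0, e1 = entries[0], entries[1]
        entries[0] = GeneEntry(e0.symbol, e0.aliases, chroms[0], base)
        entries[1] = GeneEntry(e1.symbol, e1.aliases, chroms[0],
                               base + int(rng.integers(1, 900_000)))
        if n_genes >= 3:
            el = entries[-1]
            entries[-1] = GeneEntry(el.symbol, el.aliases, chroms[0],
                                    (base + 50_000_000) % 240_000_000)
    return GeneCatalog(entries)


def generate_corpus(
    catalog: GeneCatalog,
    n_articles: int,
    mention_plan: dict[str, int],
    decoy_vocab_size: int = 60,
    seed: int = 0,
    collision_plan: dict[str, int] | None = None,
) -> SyntheticCorpus:
    """Generate abstracts with a planted per-gene article plan.

    For every symbol in ``mention_plan`` exactly that many distinct
    articles contain the symbol as a standalone token.  ``collision_plan``
    optionally plants strings equal to catalog names as plain decoy text
    (recorded in ``collisions``, not ``truth``) for ambiguity testing.
    """
    if n_articles < 1:
        raise ValueError("n_articles must be positive")
    if decoy_vocab_size < 0:
        raise ValueError("decoy_vocab_size must be non-negative")
    known = catalog.alias_map()
    for sym, cnt in mention_plan.items():
        if sym not in known:
            raise ValueError(f"mention_plan symbol not in catalog: {sym}")
        if cnt < 0 or cnt > n_articles:
            raise ValueError(f"plan count for {sym} must be in [0, {n_articles}], got {cnt}")
    rng = np.random.default_rng(seed)
    vocab = list(COMMON_WORDS[: max(decoy_vocab_size, 1)])
    ids = [f"A{i + 1:06d}" for i in range(n_articles)]

    words_per_article = [list(rng.choice(vocab, size=int(rng.integers(40, 90))))
                         for _ in ids]
    truth: dict[str, set[str]] = {}
    for sym in sorted(mention_plan):
        cnt = mention_plan[sym]
        chosen = sorted(rng.choice(n_articles, size=cnt, replace=False).tolist())
        truth[sym] = {ids[j] for j in chosen}
        for j in chosen:
            # insert once or twice at random positions (dedup is the miner's job)
            for _ in range(int(rng.integers(1, 3))):
                pos = int(rng.integers(0, len(words_per_article[j]) + 1))
                words_per_article[j].insert(pos, sym)
    collisions: dict[str, set[str]] = {}
    for word, cnt in sorted((collision_plan or {}).items()):
        if cnt > n_articles:
            raise ValueError(f"collision count for {word} exceeds n_articles")
        chosen = sorted(rng.choice(n_articles, size=cnt, replace=False).tolist())
        collisions[word] = {ids[j] for j in chosen}
        for j in chosen:
            pos = int(rng.integers(0, len(words_per_article[j]) + 1))
            words_per_article[j].insert(pos, word)
    articles = [(aid, " ".join(words)) for aid, words in zip(ids, words_per_article)]
    return SyntheticCorpus(articles=articles, truth=truth, collisions=collisions)


def generate_expression(
    catalog: GeneCatalog,
    design: list[tuple[str, str, int, int]],
    de_fraction: float = 0.05,
    effect_size: float = 2.5,
    noise_sd: float = 1.0,
    corr_block_spec: list[tuple[int, float]] | None = None,
    seed: int = 0,
    scale: str = "log2",
    markers_per_gene: int = 1,
) -> list[ExpressionDataset]:
    """Generate case/control expression datasets with shared planted truth.

    ``design`` lists ``(dataset_id, platform_id, n_case, n_control)``.
    The same DEG set (a ``de_fraction`` share of the catalog) is planted
    in every dataset with identical signed shift ``±effect_size`` added to
    case means before Gaussian noise of ``noise_sd``.  Correlation blocks
    draw non-DEG genes; within a block each sample shares a latent factor
    with loading sqrt(r), giving expected pairwise correlation r.  Marker
    codes are platform-prefixed so platforms do not share columns; all
    markers of DEG genes are recorded as planted biomarkers.

    ``scale="counts"`` instead emits negative-binomial counts whose means
    follow the same group structure (for library-size normalization).
    """
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must be in [0, 1]")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if scale not in ("log2", "counts"):
        raise ValueError(f"unknown scale: {scale}")
    for did, pid, n_case, n_control in design:
        if n_case < 2 or n_control < 2:
            raise ValueError(f"{did}: need >= 2 samples per class")
    genes = [e.symbol for e in catalog.entries]
    n_genes = len(genes)
    rng = np.random.default_rng(seed)

    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    de_sign = rng.choice([-1.0, 1.0], size=n_de)
    truth_deg = {genes[i]: float(s * effect_size) for i, s in zip(de_idx, de_sign)}

    blocks: list[list[str]] = []
    block_r: list[float] = []
    pool = [i for i in range(n_genes) if genes[i] not in truth_deg]
    for size, r in corr_block_spec or []:
        if size > len(pool):
            raise ValueError(f"correlation block size {size} exceeds available genes")
        take = [pool.pop(int(rng.integers(len(pool)))) for _ in range(size)]
        blocks.append([genes[i] for i in sorted(take)])
        block_r.append(float(r))

    baseline = rng.normal(8.0, 1.0, size=n_genes)  # shared across datasets
    datasets = []
    for did, pid, n_case, n_control in design:
        n = n_case + n_control
        labels = pd.Series(["case"] * n_case + ["control"] * n_control,
                           index=[f"{did}_S{j + 1:03d}" for j in range(n)])
        mean = np.tile(baseline[:, None], (1, n))
        for i, s in zip(de_idx, de_sign):
            mean[i, :n_case] += s * effect_size
        values = mean + rng.normal(0.0, noise_sd, size=(n_genes, n))
        for blk, r in zip(blocks, block_r):
            f = rng.normal(0.0, 1.0, size=n)
            loading = np.sqrt(r)
            for sym in blk:
                i = genes.index(sym)
                eps = rng.normal(0.0, 1.0, size=n)
                values[i] = mean[i] + noise_sd * (loading * f + np.sqrt(1.0 - r) * eps)
        if scale == "counts":
            # NB counts with mean 2^value; dispersion 0.1
            mu = np.power(2.0, np.clip(values, 0.0, 20.0))
            disp = 0.1
            shape = 1.0 / disp
            lam = rng.gamma(shape, mu / shape)
            values = rng.poisson(lam).astype(float)
        marker_rows = {}
        marker_to_gene = {}
        k = 0
        for i, g in enumerate(genes):
            for m in range(markers_per_gene):
                k += 1
                code = f"{pid}_M{k:05d}"
                marker_to_gene[code] = g
                if m == 0:
                    marker_rows[code] = values[i]
                else:
                    marker_rows[code] = values[i] + rng.normal(0.0, noise_sd / 2, size=n)
        matrix = pd.DataFrame.from_dict(marker_rows, orient="index", columns=labels.index)
        biomarkers = {c for c, g in marker_to_gene.items() if g in truth_deg}
        datasets.append(ExpressionDataset(
            dataset_id=did, platform_id=pid, matrix=matrix,
            marker_to_gene=marker_to_gene, labels=labels,
            truth_deg=dict(truth_deg), truth_corr_blocks=[list(b) for b in blocks],
            truth_biomarkers=biomarkers,
        ))
    return datasets


def generate_annotations(
    catalog: GeneCatalog,
    n_terms: int,
    size_range: tuple[int, int],
    enriched_term_spec: tuple[str, list[str]] | None = None,
    seed: int = 0,
    categories: tuple[str, ...] = ("GO",),
) -> AnnotationSets:
    """Generate random annotation terms over the catalog background.

    Term sizes are uniform in ``size_range``.  If ``enriched_term_spec``
    is given, that term is guaranteed to contain the listed genes (padded
    with random background genes up to the requested size range).  Terms
    are assigned category tags cyclically from ``categories``.
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    if n_terms < 1:
        raise ValueError("n_terms must be positive")
    lo, hi = size_range
    if lo < 1 or hi < lo or hi > len(catalog):
        raise ValueError(f"invalid size_range {size_range} for catalog of {len(catalog)}")
    rng = np.random.default_rng(seed)
    background = sorted(catalog.symbol_set())
    terms: list[tuple[str, str, set[str]]] = []
    cats: dict[str, str] = {}
    planted_id = enriched_term_spec[0] if enriched_term_spec else None
    for t in range(n_terms):
        tid = f"T{t + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        members = set(rng.choice(background, size=size, replace=False).tolist())
        name = f"synthetic term {t + 1}"
        if planted_id is not None and tid == planted_id:
            embed = set(enriched_term_spec[1])
            stray = embed - set(background)
            if stray:
                raise ValueError(f"enriched genes outside catalog: {sorted(stray)[:5]}")
            extra = [g for g in background if g not in embed]
            pad = max(size, len(embed)) - len(embed)
            members = embed | set(rng.choice(extra, size=pad, replace=False).tolist())
            name = f"planted enriched term {tid}"
        terms.append((tid, name, members))
        cats[tid] = categories[t % len(categories)]
    if planted_id is not None and planted_id not in {t[0] for t in terms}:
        raise ValueError(f"enriched_term_spec id {planted_id} outside generated range")
    return AnnotationSets(terms=terms, background=set(background), categories=cats)
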