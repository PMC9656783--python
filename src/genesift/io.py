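"""Readers and writers for the pipeline's on-disk formats.

Plain-text formats throughout: corpus as two-column TSV (or MEDLINE-like
``PMID-``/``AB  -`` records), catalog as BED-like TSV with an alias
sidecar, expression as series-matrix-style TSV with a label row,
annotation sets as GMT, gene lists one symbol per line, truth and run
reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .catalog import GeneCatalog, GeneEntry
from .simulate import AnnotationSets, ExpressionDataset, SyntheticCorpus

LABEL_ROW = "!Sample_class"


# -- corpus -----------------------------------------------------------------

def write_corpus_tsv(corpus: SyntheticCorpus, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for aid, text in corpus.articles:
            fh.write(f"{aid}\t{text}\n")


def read_corpus_tsv(path) -> list[tuple[str, str]]:
    articles = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                aid, text = line.split("\t", 1)
            except ValueError as exc:
                raise IOError(f"{path}:{lineno}: expected 'id<TAB>text'") from exc
            articles.append((aid, text))
    return articles


def read_corpus_medline(path) -> list[tuple[str, str]]:
    """Parse a minimal MEDLINE-like file with ``PMID-`` and ``AB  -`` fields;
    continuation lines are indented."""
    articles = []
    pmid = None
    ab_lines: list[str] = []
    in_ab = False

    def flush():
        nonlocal pmid, ab_lines, in_ab
        if pmid is not None:
            articles.append((pmid, " ".join(ab_lines).strip()))
        pmid, ab_lines, in_ab = None, [], False

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("PMID-"):
                flush()
                pmid = line[5:].strip()
            elif line.startswith("AB"):
                in_ab = True
                ab_lines.append(line.split("-", 1)[1].strip())
            elif line.startswith(" ") and in_ab:
                ab_lines.append(line.strip())
            elif line and not line.startswith(" "):
                in_ab = False
    flush()
    return articles


# -- catalog ----------------------------------------------------------------

def write_catalog_bed(catalog: GeneCatalog, bed_path, alias_path=None) -> None:
    with open(bed_path, "w", encoding="utf-8") as fh:
        for e in catalog.entries:
            fh.write(f"{e.chromosome}\t{e.start}\t{e.start + 1}\t{e.symbol}\n")
    if alias_path is not None:
        with open(alias_path, "w", encoding="utf-8") as fh:
            for e in catalog.entries:
                if e.aliases:
                    fh.write(f"{e.symbol}\t{','.join(e.aliases)}\n")


def read_catalog_bed(bed_path, alias_path=None) -> GeneCatalog:
    aliases: dict[str, tuple[str, ...]] = {}
    if alias_path is not None and Path(alias_path).exists():
        with open(alias_path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                sym, al = line.rstrip("\n").split("\t", 1)
                aliases[sym] = tuple(al.split(","))
    entries = []
    with open(bed_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise IOError(f"{bed_path}:{lineno}: expected >= 4 BED columns")
            chrom, start, _end, sym = fields[:4]
            entries.append(GeneEntry(sym, aliases.get(sym, ()), chrom, int(start)))
    return GeneCatalog(entries)


# -- expression -------------------------------------------------------------

def write_expression_tsv(ds: ExpressionDataset, matrix_path, marker_map_path=None) -> None:
    """Series-matrix-style TSV: a ``!Sample_class`` metadata row, then
    marker rows."""
    with open(matrix_path, "w", encoding="utf-8") as fh:
        fh.write("ID_REF\t" + "\t".join(ds.matrix.columns) + "\n")
        fh.write(LABEL_ROW + "\t" + "\t".join(ds.labels.astype(str)) + "\n")
        for marker, row in ds.matrix.iterrows():
            fh.write(marker + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
    if marker_map_path is not None:
        with open(marker_map_path, "w", encoding="utf-8") as fh:
            for m, g in ds.marker_to_gene.items():
                fh.write(f"{m}\t{g}\n")


def read_expression_tsv(matrix_path, marker_map_path=None,
                        dataset_id: str = "", platform_id: str = "") -> ExpressionDataset:
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if LABEL_ROW not in df.index:
        raise IOError(f"{matrix_path}: missing {LABEL_ROW} row")
    labels = df.loc[LABEL_ROW].astype(str)
    matrix = df.drop(index=LABEL_ROW).astype(float)
    marker_to_gene = {}
    if marker_map_path is not None:
        with open(marker_map_path, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    m, g = line.rstrip("\n").split("\t", 1)
                    marker_to_gene[m] = g
    else:
        marker_to_gene = {m: m for m in matrix.index}
    return ExpressionDataset(
        dataset_id=dataset_id or Path(matrix_path).stem,
        platform_id=platform_id or "NA",
        matrix=matrix, marker_to_gene=marker_to_gene, labels=labels,
        truth_deg={}, truth_corr_blocks=[], truth_biomarkers=set(),
    )


# -- annotations ------------------------------------------------------------

def write_gmt(sets: AnnotationSets, path) -> None:
    """GMT: term_id, description (category tag), then member symbols."""
    with open(path, "w", encoding="utf-8") as fh:
        for tid, name, members in sets.terms:
            cat = sets.categories.get(tid, "GO")
            fh.write("\t".join([tid, f"{cat}|{name}"] + sorted(members)) + "\n")


def read_gmt(path, background: set[str] | None = None) -> AnnotationSets:
    terms = []
    cats = {}
    universe: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise IOError(f"{path}:{lineno}: GMT line needs id, description, members")
            tid, desc, members = fields[0], fields[1], set(fields[2:])
            cat, _, name = desc.partition("|")
            if not name:
                cat, name = "GO", desc
            terms.append((tid, name, members))
            cats[tid] = cat
            universe |= members
    bg = background if background is not None else universe
    terms = [(t, n, m & bg) for t, n, m in terms]
    terms = [(t, n, m) for t, n, m in terms if m]
    return AnnotationSets(terms=terms, background=bg, categories=cats)


# -- small helpers ----------------------------------------------------------

def write_gene_list(genes, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(set(genes)):
            fh.write(g + "\n")


def read_gene_list(path) -> set[str]:
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, set):
        return sorted(o)
    if hasattr(o, "item"):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")
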