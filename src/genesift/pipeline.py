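"""End-to-end orchestration: simulate → mine → meta → network → enrich →
compare → ml, from a single configuration.

Every stage writes its outputs plus a ``provenance.json`` carrying the
configuration hash and seed; a rerun with the same configuration reuses
cached stage outputs, and outputs from a different configuration in the
same directory are refused rather than silently mixed.  All writers are
deterministic, so two runs with the same configuration are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import biomarkers, compare, enrichment, io, meta, mining, network, simulate

logger = logging.getLogger(__name__)

STAGES = ("simulate", "mine", "de_meta", "network", "enrich", "compare", "ml")


@dataclass
class RunConfig:
    """All thresholds and generator settings of one pipeline run.

    Threshold defaults are the pipeline's standard operating points: frequent-gene
    cutoff of 50 articles (strict), meta-analysis FDR 0.001 (inclusive),
    network filter |r| >= 0.5 and p <= 0.01, locus window 1 Mbp
    (strict), 70/30 split, 95% CI.
    """

    seed: int = 0
    # synthetic inputs
    n_genes: int = 300
    n_chromosomes: int = 22
    n_articles: int = 400
    n_frequent_genes: int = 12
    decoy_vocab_size: int = 60
    design: list = field(default_factory=lambda: [
        ["DS1", "PLATA", 15, 19], ["DS2", "PLATA", 15, 19], ["DS3", "PLATB", 14, 19],
    ])
    de_fraction: float = 0.05
    effect_size: float = 2.5
    noise_sd: float = 1.0
    corr_blocks: list = field(default_factory=lambda: [[5, 0.9]])
    n_terms: int = 40
    term_size_range: list = field(default_factory=lambda: [10, 60])
    # thresholds
    min_articles: int = 50
    alpha: float = 0.001
    min_datasets: int = 2
    r_min: float = 0.5
    p_max: float = 0.01
    max_dist: int = 1_000_000
    bin_size: int = 1_000_000
    train_frac: float = 0.7
    n_trees: int = 200
    top_k: int = 10
    fdr_max: float = 0.05
    platform_groups: dict = field(default_factory=lambda: {
        "A": ["DS1", "DS2"], "B": ["DS3"],
    })
    algorithms: list = field(default_factory=lambda: list(biomarkers.ALGORITHMS))

    def validate(self) -> None:
        if not 0 <= self.alpha <= 1 or not 0 <= self.p_max <= 1:
            raise ValueError("alpha and p_max must be probabilities")
        if not 0 <= self.r_min <= 1 or not 0 < self.train_frac < 1:
            raise ValueError("r_min in [0,1] and train_frac in (0,1) required")
        if self.min_articles < 0 or self.max_dist <= 0 or self.bin_size <= 0:
            raise ValueError("min_articles >= 0, max_dist and bin_size > 0 required")
        unknown = set(self.algorithms) - set(biomarkers.ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms: {sorted(unknown)}")
        members = [d for ds_list in self.platform_groups.values() for d in ds_list]
        declared = {d[0] for d in self.design}
        if set(members) - declared:
            raise ValueError("platform_groups reference datasets missing from design")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


def _stage_dir(out_dir: Path, stage: str, cfg_hash: str, seed: int) -> tuple[Path, bool]:
    """Return (stage directory, cached?) and refuse foreign provenance."""
    d = out_dir / stage
    prov = d / "provenance.json"
    if prov.exists():
        info = json.loads(prov.read_text())
        if info.get("config_hash") != cfg_hash:
            raise RuntimeError(
                f"stage {stage}: existing outputs belong to config "
                f"{info.get('config_hash')}, current is {cfg_hash}; refusing to mix")
        return d, True
    d.mkdir(parents=True, exist_ok=True)
    return d, False


def _finish_stage(d: Path, stage: str, cfg_hash: str, seed: int) -> None:
    io.write_json({"stage": stage, "config_hash": cfg_hash, "seed": seed},
                  d / "provenance.json")


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run all stages; returns the machine-readable run report."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    seed = config.seed
    report: dict = {"config_hash": cfg_hash, "seed": seed, "stages": {}}

    # -- simulate -----------------------------------------------------------
    d, cached = _stage_dir(out_dir, "simulate", cfg_hash, seed)
    catalog = simulate.generate_catalog(config.n_genes, config.n_chromosomes, seed)
    genes = [e.symbol for e in catalog.entries]
    plan = {}
    rows_per = max(config.min_articles + 1, 1)
    for i in range(min(config.n_frequent_genes, len(genes))):
        plan[genes[i]] = min(config.n_articles, rows_per + i)
    # a few genes planted below the cutoff
    for i in range(config.n_frequent_genes, min(config.n_frequent_genes + 5, len(genes))):
        plan[genes[i]] = max(config.min_articles - (i - config.n_frequent_genes) * 7, 1)
    corpus = simulate.generate_corpus(catalog, config.n_articles, plan,
                                      config.decoy_vocab_size, seed + 1)
    datasets = simulate.generate_expression(
        catalog, [tuple(d_) for d_ in config.design], config.de_fraction,
        config.effect_size, config.noise_sd,
        [tuple(b) for b in config.corr_blocks], seed + 2)
    planted_term_genes = sorted(set(list(plan)[:6]) | set(list(datasets[0].truth_deg)[:6]))
    annotations = simulate.generate_annotations(
        catalog, config.n_terms, tuple(config.term_size_range),
        ("T0001", planted_term_genes), seed + 3,
        categories=("PATHWAY", "GO", "KEGG"))
    if not cached:
        io.write_catalog_bed(catalog, d / "catalog.bed", d / "catalog.aliases.tsv")
        io.write_corpus_tsv(corpus, d / "corpus.tsv")
        for ds in datasets:
            io.write_expression_tsv(ds, d / f"{ds.dataset_id}.matrix.tsv",
                                    d / f"{ds.dataset_id}.markers.tsv")
        io.write_gmt(annotations, d / "annotations.gmt")
        io.write_json({"mention_plan": plan,
                       "truth_deg": datasets[0].truth_deg,
                       "corr_blocks": datasets[0].truth_corr_blocks},
                      d / "truth.json")
        _finish_stage(d, "simulate", cfg_hash, seed)
    report["stages"]["simulate"] = {
        "status": "ok", "cached": cached, "n_genes": len(catalog),
        "n_articles": len(corpus), "n_datasets": len(datasets)}

    # -- mine ---------------------------------------------------------------
    d, cached = _stage_dir(out_dir, "mine", cfg_hash, seed)
    index = mining.build_index(corpus, catalog)
    freq = mining.filter_frequent(index, config.min_articles)
    chrom_dist = mining.chromosome_distribution(freq, catalog)
    if not cached:
        with open(d / "frequency.tsv", "w", encoding="utf-8") as fh:
            for sym, cnt in freq.rows:
                fh.write(f"{sym}\t{cnt}\n")
        with open(d / "chromosomes.tsv", "w", encoding="utf-8") as fh:
            for c in catalog.chromosomes():
                fh.write(f"{c}\t{chrom_dist[c]}\n")
        io.write_json({"n_articles_scanned": index.n_articles_scanned,
                       "min_articles": config.min_articles,
                       "n_frequent": len(freq)}, d / "summary.json")
        _finish_stage(d, "mine", cfg_hash, seed)
    frequent_genes = set(freq.symbols())
    report["stages"]["mine"] = {"status": "ok", "cached": cached,
                                "n_frequent": len(freq)}

    # -- de_meta ------------------------------------------------------------
    d, cached = _stage_dir(out_dir, "de_meta", cfg_hash, seed)
    meta_table = meta.meta_analyze(datasets, min_datasets=config.min_datasets)
    degs = meta.select_degs(meta_table, config.alpha)
    deg_genes = set(degs.index)
    if not cached:
        meta_table.to_csv(d / "meta.tsv", sep="\t", float_format="%.6g")
        degs.to_csv(d / "degs.tsv", sep="\t", float_format="%.6g")
        _finish_stage(d, "de_meta", cfg_hash, seed)
    report["stages"]["de_meta"] = {"status": "ok", "cached": cached,
                                   "n_degs": len(degs)}

    # -- network ------------------------------------------------------------
    d, cached = _stage_dir(out_dir, "network", cfg_hash, seed)
    selected = sorted(deg_genes | set().union(*(
        [set(b) for ds in datasets[:1] for b in ds.truth_corr_blocks] or [set()])))
    nets = {}
    by_id = {ds.dataset_id: ds for ds in datasets}
    for gid in sorted(config.platform_groups):
        blocks = []
        for did in config.platform_groups[gid]:
            ds = by_id[did]
            expr = meta.summarize_markers(ds)
            blocks.append(expr.loc[[g for g in selected if g in expr.index]])
        pooled = pd.concat(blocks, axis=1)
        nets[gid] = network.build_network(pooled, config.r_min, config.p_max, gid)
    if not cached:
        for gid, net in nets.items():
            net.to_dataframe().to_csv(d / f"edges_{gid}.tsv", sep="\t",
                                      index=False, float_format="%.6g")
            with open(d / f"degrees_{gid}.tsv", "w", encoding="utf-8") as fh:
                for g, deg in sorted(net.degrees().items()):
                    fh.write(f"{g}\t{deg}\n")
        _finish_stage(d, "network", cfg_hash, seed)
    report["stages"]["network"] = {
        "status": "ok", "cached": cached,
        "edges": {gid: len(net.edges) for gid, net in nets.items()}}

    # -- enrich -------------------------------------------------------------
    d, cached = _stage_dir(out_dir, "enrich", cfg_hash, seed)
    rows_mined = enrichment.enrich(frequent_genes, annotations)
    rows_deg = enrichment.enrich(deg_genes, annotations) if deg_genes else []
    if not cached:
        enrichment.rows_to_dataframe(rows_mined).to_csv(
            d / "enrichment_mined.tsv", sep="\t", index=False)
        enrichment.rows_to_dataframe(rows_deg).to_csv(
            d / "enrichment_degs.tsv", sep="\t", index=False)
        _finish_stage(d, "enrich", cfg_hash, seed)
    report["stages"]["enrich"] = {"status": "ok", "cached": cached,
                                  "n_terms_mined": len(rows_mined),
                                  "n_terms_degs": len(rows_deg)}

    # -- compare ------------------------------------------------------------
    d, cached = _stage_dir(out_dir, "compare", cfg_hash, seed)
    cmp_report = compare.compare_lists(
        frequent_genes, deg_genes, catalog, config.max_dist, config.bin_size,
        rows_mined, rows_deg, config.fdr_max)
    if not cached:
        io.write_json(cmp_report.to_dict(), d / "comparison.json")
        _finish_stage(d, "compare", cfg_hash, seed)
    report["stages"]["compare"] = {
        "status": "ok", "cached": cached,
        "shared_names": len(cmp_report.shared_names),
        "proximity_pairs": len(cmp_report.proximity_pairs),
        "shared_loci": len(cmp_report.shared_loci)}

    # -- ml -----------------------------------------------------------------
    d, cached = _stage_dir(out_dir, "ml", cfg_hash, seed)
    selected_ml = frequent_genes | deg_genes
    tables = biomarkers.assemble_features(datasets, selected_ml,
                                          config.platform_groups)
    model_reports = []
    for table in tables:
        train, test = biomarkers.split_70_30(table, seed, config.train_frac)
        for algo in config.algorithms:
            model_reports.append(biomarkers.train_and_score(
                train, test, algo, config.n_trees, seed))
    tally = biomarkers.tally_recurrence(model_reports, config.top_k)
    if not cached:
        for rep in model_reports:
            io.write_json({
                "group": rep.group_id, "algorithm": rep.algorithm,
                "accuracy": rep.accuracy, "ci_low": rep.ci_low,
                "ci_high": rep.ci_high, "n_test": rep.n_test,
                "importances": [
                    {"marker": m, "importance": round(v, 4), "gene": g}
                    for m, v, g in rep.importances[:config.top_k]],
            }, d / f"model_{rep.group_id}_{rep.algorithm}.json")
        with open(d / "recurrence.tsv", "w", encoding="utf-8") as fh:
            for m, c in sorted(tally.marker_counts.items(),
                               key=lambda kv: (-kv[1], kv[0])):
                fh.write(f"marker\t{m}\t{c}\n")
            for g, c in sorted(tally.gene_counts.items(),
                               key=lambda kv: (-kv[1], kv[0])):
                fh.write(f"gene\t{g}\t{c}\n")
        _finish_stage(d, "ml", cfg_hash, seed)
    report["stages"]["ml"] = {
        "status": "ok", "cached": cached,
        "accuracies": {f"{r.group_id}:{r.algorithm}": round(r.accuracy, 4)
                       for r in model_reports}}

    report["succeeded"] = [s for s in STAGES if s in report["stages"]]
    # persisted report omits the run-local cache flags so reruns of the same
    # configuration leave byte-identical files
    persisted = json.loads(json.dumps(report))
    for stage_info in persisted["stages"].values():
        stage_info.pop("cached", None)
    io.write_json(persisted, out_dir / "run_report.json")
    return report
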