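"""Cross-dataset differential-expression meta-analysis and TMM factors.

Per dataset, the case-vs-control effect for each gene is Hedges' g
(standardized mean difference with the small-sample correction
J = 1 - 3/(4(n1+n2-2)-1)).  Effects are pooled across datasets with a
DerSimonian-Laird random-effects model (fixed-effects available), the
pooled effect is tested with a two-sided normal z-test, and p-values
are adjusted with Benjamini-Hochberg.  Genes with adjusted p <= alpha
(default 0.001, inclusive) are the differentially expressed set.

TMM (trimmed mean of M-values) normalization factors are computed for
the machine-learning feature path following the published
calcNormFactors recipe: reference sample by upper-quartile proximity
to the mean, per-pair M/A statistics on doubly-trimmed marker sets
(30% on M, 5% on A), precision-weighted mean, and a final rescaling to
geometric mean one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import ExpressionDataset


@dataclass(frozen=True)
class EffectSize:
    """Hedges' g (case minus control) with its sampling variance."""

    g: float
    var_g: float
    n_case: int
    n_control: int


def hedges_g(case, control) -> EffectSize:
    """Standardized mean difference (case - control) with small-sample
    correction.

    g = J * (mean_case - mean_control) / s_pooled with
    J = 1 - 3/(4(n1+n2-2)-1); the sampling variance is
    (n1+n2)/(n1*n2) + g^2/(2(n1+n2)).
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    n1, n2 = len(case), len(control)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    sp2 = ((n1 - 1) * case.var(ddof=1) + (n2 - 1) * control.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ZeroDivisionError("pooled standard deviation is zero")
    j = 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0)
    g = j * (case.mean() - control.mean()) / np.sqrt(sp2)
    var_g = (n1 + n2) / (n1 * n2) + g * g / (2.0 * (n1 + n2))
    return EffectSize(g=float(g), var_g=float(var_g), n_case=n1, n_control=n2)


def dl_pool(effects: list[EffectSize], model: str = "random") -> tuple[float, float, float, float]:
    """Pool effect sizes; returns ``(pooled, tau2, z, p)``.

    ``model="random"`` uses the DerSimonian-Laird moment estimator of the
    between-study variance tau^2 (Q statistic on fixed-effect weights,
    tau2 = max(0, (Q - df)/C)); ``model="fixed"`` forces tau2 = 0.
    """
    if not effects:
        raise ValueError("at least one effect required")
    if model not in ("random", "fixed"):
        raise ValueError(f"unknown model: {model}")
    g = np.array([e.g for e in effects])
    v = np.array([e.var_g for e in effects])
    w = 1.0 / v
    fixed = float((w * g).sum() / w.sum())
    tau2 = 0.0
    if model == "random" and len(effects) > 1:
        q = float((w * (g - fixed) ** 2).sum())
        c = float(w.sum() - (w ** 2).sum() / w.sum())
        tau2 = max(0.0, (q - (len(effects) - 1)) / c) if c > 0 else 0.0
    w_star = 1.0 / (v + tau2)
    pooled = float((w_star * g).sum() / w_star.sum())
    se = float(np.sqrt(1.0 / w_star.sum()))
    z = pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return pooled, tau2, float(z), p


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def summarize_markers(ds: ExpressionDataset, collapse: str = "max_var") -> pd.DataFrame:
    """Collapse marker rows to one row per gene (max-variance marker or
    per-gene mean)."""
    if collapse not in ("max_var", "mean"):
        raise ValueError(f"unknown collapse: {collapse}")
    gene_of = pd.Series(ds.marker_to_gene)
    mat = ds.matrix.loc[gene_of.index.intersection(ds.matrix.index)]
    groups = gene_of.loc[mat.index]
    if collapse == "mean":
        return mat.groupby(groups).mean()
    var = mat.var(axis=1, ddof=1)
    # deterministic: highest variance, marker code as tie-break
    order = pd.DataFrame({"gene": groups, "var": var}).sort_values(
        ["gene", "var"], ascending=[True, False], kind="mergesort")
    pick = order.groupby("gene", sort=True).head(1).index
    out = mat.loc[pick]
    out.index = groups.loc[pick]
    return out.sort_index()


def meta_analyze(
    datasets: list[ExpressionDataset],
    min_datasets: int = 2,
    model: str = "random",
    collapse: str = "max_var",
    log_transform: bool = False,
) -> pd.DataFrame:
    """Per-gene meta-analysis table across datasets.

    Returns a DataFrame indexed by gene with columns ``k`` (datasets
    measured in), ``pooled``, ``tau2``, ``z``, ``p``, ``fdr``.  Genes
    measured in fewer than ``min_datasets`` datasets are excluded.
    ``log_transform`` applies log2(x+1) first (for count-scale input).
    """
    if not datasets:
        raise ValueError("no datasets supplied")
    per_gene: dict[str, list[EffectSize]] = {}
    for ds in datasets:
        expr = summarize_markers(ds, collapse)
        if log_transform:
            expr = np.log2(expr + 1.0)
        case_cols = ds.labels[ds.labels == "case"].index
        ctrl_cols = ds.labels[ds.labels == "control"].index
        case = expr[case_cols].to_numpy()
        ctrl = expr[ctrl_cols].to_numpy()
        for i, gene in enumerate(expr.index):
            try:
                es = hedges_g(case[i], ctrl[i])
            except ZeroDivisionError:
                continue
            per_gene.setdefault(gene, []).append(es)
    rows = []
    for gene in sorted(per_gene):
        effects = per_gene[gene]
        if len(effects) < min_datasets:
            continue
        pooled, tau2, z, p = dl_pool(effects, model=model)
        rows.append((gene, len(effects), pooled, tau2, z, p))
    if not rows:
        return pd.DataFrame(columns=["k", "pooled", "tau2", "z", "p", "fdr"])
    df = pd.DataFrame(rows, columns=["gene", "k", "pooled", "tau2", "z", "p"]).set_index("gene")
    df["fdr"] = bh_fdr(df["p"].to_numpy())
    return df


def select_degs(meta: pd.DataFrame, alpha: float = 0.001) -> pd.DataFrame:
    """Genes with fdr <= alpha (inclusive), ranked by fdr then |pooled|
    descending."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    sel = meta[meta["fdr"] <= alpha].copy()
    sel["abs_pooled"] = sel["pooled"].abs()
    sel = sel.sort_values(["fdr", "abs_pooled"], ascending=[True, False], kind="mergesort")
    return sel.drop(columns="abs_pooled")


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
              trim_m: float, trim_a: float) -> float:
    """TMM factor of one sample against the reference (unscaled, log2)."""
    p_obs = obs / lib_obs
    p_ref = ref / lib_ref
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 0.0
    m = np.log2(p_obs[keep] / p_ref[keep])
    # sum-of-logs (not log-of-product): keeps exact ties between markers
    # with identical count pairs, which the rank-based trim relies on
    a = (np.log2(p_obs[keep]) + np.log2(p_ref[keep])) / 2.0
    # asymptotic (delta-method) precision weights
    w = (lib_obs - obs[keep]) / (lib_obs * obs[keep]) + \
        (lib_ref - ref[keep]) / (lib_ref * ref[keep])
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 0.0
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return float(f) if np.isfinite(f) else 0.0


def tmm_factors(counts, trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors per sample.

    ``counts`` is a markers x samples non-negative matrix.  The reference
    sample is the one whose 75th count-fraction percentile is closest to
    the mean across samples; per-sample log2 ratios against it are doubly
    trimmed (``trim_m`` on M, ``trim_a`` on A) and averaged with
    precision weights.  Returned factors are positive with geometric
    mean one.  Markers with a zero in either member of a pair drop out
    of that pair's M/A set.
    """
    if isinstance(counts, pd.DataFrame):
        mat = counts.to_numpy(dtype=float)
        samples = list(counts.columns)
    else:
        mat = np.asarray(counts, dtype=float)
        samples = list(range(mat.shape[1]))
    if np.any(mat < 0):
        raise ValueError("negative values not allowed")
    lib = mat.sum(axis=0)
    if np.any(lib == 0):
        bad = [samples[j] for j in np.where(lib == 0)[0]]
        raise ValueError(f"all-zero sample(s): {bad}")
    f75 = np.array([np.quantile(mat[:, j] / lib[j], 0.75) for j in range(mat.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    log_f = np.array([
        _tmm_pair(mat[:, j], mat[:, ref], lib[j], lib[ref], trim_m, trim_a)
        for j in range(mat.shape[1])
    ])
    factors = 2.0 ** log_f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=samples, name="tmm_factor")
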