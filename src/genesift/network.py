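"""Thresholded Pearson co-expression networks and hub ranking.

An edge joins two genes when the absolute sample Pearson correlation of
their expression profiles is at least ``r_min`` AND the two-sided
p-value (t-distribution on n-2 df) is at most ``p_max``.  The filter is
applied to |r| so that strong negative correlations are retained; edge
p-values are deliberately not multiplicity-adjusted (the cutoff is a
raw one).  Networks are built per platform group; hubs are the genes
with the most surviving edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationEdge:
    gene_a: str
    gene_b: str
    r: float
    p: float

    def __post_init__(self) -> None:
        if not self.gene_a < self.gene_b:
            raise ValueError("edge endpoints must be in canonical (lexicographic) order")
        if abs(self.r) > 1 + 1e-12:
            raise ValueError(f"|r| > 1: {self.r}")

    @property
    def sign(self) -> str:
        return "positive" if self.r >= 0 else "negative"


@dataclass
class Network:
    nodes: set[str]
    edges: list[CorrelationEdge]
    group_id: str = ""

    def __post_init__(self) -> None:
        pairs = [(e.gene_a, e.gene_b) for e in self.edges]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate edges")
        for e in self.edges:
            if e.gene_a not in self.nodes or e.gene_b not in self.nodes:
                raise ValueError(f"edge endpoint outside node set: {e.gene_a}-{e.gene_b}")

    def degrees(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for e in self.edges:
            deg[e.gene_a] += 1
            deg[e.gene_b] += 1
        return deg

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.gene_a, e.gene_b, e.r, e.p, e.sign) for e in self.edges],
            columns=["gene_a", "gene_b", "r", "p", "sign"],
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for e in self.edges:
            g.add_edge(e.gene_a, e.gene_b, r=e.r, p=e.p, sign=e.sign)
        return g


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r and its two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroDivisionError("zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def build_network(
    expr: pd.DataFrame,
    r_min: float = 0.5,
    p_max: float = 0.01,
    group_id: str = "",
) -> Network:
    """Build the thresholded correlation network of a gene x sample matrix.

    Keeps the edge (a, b) iff ``|r| >= r_min`` and ``p <= p_max``.
    Zero-variance genes cannot be correlated and are skipped (logged);
    they remain in the node set.
    """
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    genes = list(expr.index)
    if len(genes) != len(set(genes)):
        raise ValueError("duplicate gene identifiers in expression matrix")
    mat = expr.to_numpy(dtype=float)
    sd = mat.std(axis=1, ddof=1)
    degenerate = {genes[i] for i in np.where(sd == 0)[0]}
    if degenerate:
        logger.info("skipping %d zero-variance genes: %s",
                    len(degenerate), sorted(degenerate)[:10])
    ok = [i for i in range(len(genes)) if genes[i] not in degenerate]
    edges: list[CorrelationEdge] = []
    if len(ok) >= 2:
        sub = mat[ok]
        n = sub.shape[1]
        rmat = np.corrcoef(sub)
        for ii in range(len(ok)):
            for jj in range(ii + 1, len(ok)):
                r = float(np.clip(rmat[ii, jj], -1.0, 1.0))
                if abs(r) < r_min:
                    continue
                if abs(r) >= 1.0:
                    p = 0.0
                else:
                    t = r * np.sqrt((n - 2) / (1.0 - r * r))
                    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
                if p > p_max:
                    continue
                a, b = sorted((genes[ok[ii]], genes[ok[jj]]))
                edges.append(CorrelationEdge(a, b, r, p))
    return Network(nodes=set(genes), edges=edges, group_id=group_id)


def hub_rank(net: Network, top_k: int) -> list[tuple[str, int]]:
    """Top-``top_k`` genes by edge degree (ties lexicographic); genes with
    zero degree are not listed."""
    if top_k < 1:
        raise ValueError("top_k must be positive")
    deg = [(g, d) for g, d in net.degrees().items() if d > 0]
    deg.sort(key=lambda t: (-t[1], t[0]))
    return deg[:top_k]
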