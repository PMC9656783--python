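"""Tree-ensemble biomarker ranking with local surrogate explanations.

Per platform group, expression of the selected markers is assembled
into a samples x markers feature table (TMM-normalized), split 70/30
stratified by class, and fed to a decision tree, a random forest, and
an extra-trees regressor on a 0/1 label encoding.  Each model reports
test accuracy with a 95% Wilson score interval and impurity-based
importances rescaled to sum to 100 (raw values retained).  Recurrence
tallies count how often each marker — and, through the marker→gene
map, each gene — lands in the top-k importances across
(algorithm x group) runs.  Local explanations fit a weighted ridge
surrogate to the model's predictions on Gaussian perturbations around
one sample, the standard local-surrogate recipe.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor, RandomForestClassifier
from sklearn.linear_model import Ridge
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.proportion import proportion_confint

from .meta import tmm_factors
from .simulate import ExpressionDataset

logger = logging.getLogger(__name__)

ALGORITHMS = ("decision_tree", "random_forest", "extra_trees")


@dataclass
class FeatureTable:
    """Samples x markers matrix with class labels for one platform group."""

    group_id: str
    X: pd.DataFrame               # samples x markers
    y: pd.Series                  # per-sample class label
    marker_to_gene: dict[str, str]

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("missing values in feature table")
        if len(set(self.y)) < 2:
            raise ValueError("both classes must be present")
        if len(self.X.columns) != len(set(self.X.columns)):
            raise ValueError("marker codes not unique")

    @property
    def marker_codes(self) -> list[str]:
        return list(self.X.columns)


@dataclass
class ModelReport:
    group_id: str
    algorithm: str
    accuracy: float
    ci_low: float
    ci_high: float
    n_test: int
    importances: list[tuple[str, float, str]]      # (marker, scaled importance, gene)
    raw_importances: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-12 <= self.accuracy <= self.ci_high + 1e-12):
            raise ValueError("CI must contain the accuracy point estimate")

    def top_markers(self, k: int) -> list[str]:
        return [m for m, _, _ in self.importances[:k]]


@dataclass
class RecurrenceTally:
    marker_counts: dict[str, int]
    gene_counts: dict[str, int]
    n_runs: int
    top_k: int


def assemble_features(
    datasets: list[ExpressionDataset],
    selected_genes: set[str],
    platform_groups: dict[str, list[str]],
    normalize: str | None = "tmm",
) -> list[FeatureTable]:
    """One feature table per platform group.

    Within a group, samples of all member datasets are concatenated and
    the marker set is the intersection of markers (mapping to a selected
    gene) present in every member dataset; markers missing from any
    member are dropped with a log message.  ``normalize="tmm"`` divides
    each sample column by its TMM factor before transposition.
    """
    by_id = {ds.dataset_id: ds for ds in datasets}
    tables = []
    for gid in sorted(platform_groups):
        members = platform_groups[gid]
        if not members:
            raise ValueError(f"group {gid} has no datasets")
        group_ds = [by_id[d] for d in members]
        marker_sets = []
        for ds in group_ds:
            marker_sets.append({m for m in ds.matrix.index
                                if ds.marker_to_gene.get(m) in selected_genes})
        common = set.intersection(*marker_sets)
        dropped = set.union(*marker_sets) - common
        if dropped:
            logger.info("group %s: dropping %d markers absent from some member dataset",
                        gid, len(dropped))
        if not common:
            raise ValueError(f"group {gid}: no shared markers for the selected genes")
        markers = sorted(common)
        blocks = []
        labels = []
        for ds in group_ds:
            sub = ds.matrix.loc[markers]
            if normalize == "tmm":
                nonneg = sub.clip(lower=0.0)
                factors = tmm_factors(nonneg)
                sub = sub.div(factors, axis=1)
            blocks.append(sub)
            labels.append(ds.labels)
        X = pd.concat(blocks, axis=1).T  # samples x markers
        y = pd.concat(labels)
        if len(set(y)) < 2:
            raise ValueError(f"group {gid}: only one class present")
        m2g = {m: g for ds in group_ds for m, g in ds.marker_to_gene.items()
               if m in common}
        tables.append(FeatureTable(group_id=gid, X=X, y=y, marker_to_gene=m2g))
    return tables


def split_70_30(table: FeatureTable, seed: int, train_frac: float = 0.7
                ) -> tuple[FeatureTable, FeatureTable]:
    """Stratified 70/30 split; train size is ceil(train_frac * n) overall
    with per-class counts within one sample of the stratified target."""
    y = table.y
    classes = sorted(set(y))
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples; cannot stratify")
    n = len(y)
    n_train = math.ceil(train_frac * n)
    # largest-remainder allocation of the train budget across classes
    quotas = {c: train_frac * (y == c).sum() for c in classes}
    base = {c: min(int(math.floor(q)), int((y == c).sum()) - 1) for c, q in quotas.items()}
    remaining = n_train - sum(base.values())
    order = sorted(classes, key=lambda c: (-(quotas[c] - math.floor(quotas[c])), c))
    alloc = dict(base)
    i = 0
    while remaining > 0:
        c = order[i % len(order)]
        if alloc[c] < (y == c).sum() - 1:  # keep >= 1 test sample per class
            alloc[c] += 1
            remaining -= 1
        i += 1
    rng = np.random.default_rng(seed)
    train_idx: list = []
    test_idx: list = []
    for c in classes:
        members = list(y.index[y == c])
        perm = rng.permutation(len(members))
        take = alloc[c]
        train_idx += [members[j] for j in perm[:take]]
        test_idx += [members[j] for j in perm[take:]]
    mk = dict(table.marker_to_gene)
    train = FeatureTable(table.group_id, table.X.loc[train_idx], y.loc[train_idx], mk)
    test = FeatureTable(table.group_id, table.X.loc[test_idx], y.loc[test_idx], mk)
    return train, test


def _encode(y: pd.Series) -> np.ndarray:
    classes = sorted(set(y))
    return (y == classes[0]).to_numpy().astype(int)  # first class (e.g. "case") -> 1


def _fit_model(algorithm: str, X: np.ndarray, y01: np.ndarray,
               n_trees: int, seed: int):
    if algorithm == "decision_tree":
        model = DecisionTreeClassifier(random_state=seed)
        model.fit(X, y01)
    elif algorithm == "random_forest":
        model = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        model.fit(X, y01)
    elif algorithm == "extra_trees":
        # regressor on the 0/1 encoding; predictions thresholded at 0.5
        model = ExtraTreesRegressor(n_estimators=n_trees, random_state=seed)
        model.fit(X, y01)
    else:
        raise ValueError(f"unknown algorithm: {algorithm!r} (choose from {ALGORITHMS})")
    return model


def predict01(model, X: np.ndarray) -> np.ndarray:
    """Class predictions on the 0/1 encoding for any supported model."""
    pred = model.predict(X)
    if pred.dtype.kind == "f":
        pred = (pred >= 0.5).astype(int)
    return pred


def model_score(model, X: np.ndarray) -> np.ndarray:
    """Continuous class-1 score used by the local surrogate."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.predict(X)


def train_and_score(
    train: FeatureTable,
    test: FeatureTable,
    algorithm: str,
    n_trees: int = 500,
    seed: int = 0,
) -> ModelReport:
    """Fit one algorithm and report test accuracy (95% Wilson CI) and
    ranked importances rescaled to sum to 100."""
    if len(test.y) == 0:
        raise ValueError("empty test set")
    if list(train.X.columns) != list(test.X.columns):
        raise ValueError("train and test feature columns differ")
    y_train = _encode(train.y)
    y_test = _encode(test.y)
    model = _fit_model(algorithm, train.X.to_numpy(), y_train, n_trees, seed)
    correct = int((predict01(model, test.X.to_numpy()) == y_test).sum())
    acc = correct / len(y_test)
    lo, hi = proportion_confint(correct, len(y_test), alpha=0.05, method="wilson")
    # Wilson bounds can land one ulp inside the point estimate at 0 or 1
    lo, hi = min(float(lo), acc), max(float(hi), acc)
    raw = dict(zip(train.X.columns, model.feature_importances_))
    total = sum(raw.values())
    scale = 100.0 / total if total > 0 else 0.0
    ranked = sorted(raw.items(), key=lambda kv: (-kv[1], kv[0]))
    importances = [(m, v * scale, train.marker_to_gene.get(m, ""))
                   for m, v in ranked]
    return ModelReport(
        group_id=train.group_id, algorithm=algorithm,
        accuracy=acc, ci_low=float(lo), ci_high=float(hi), n_test=len(y_test),
        importances=importances, raw_importances=raw, seed=seed,
    )


def local_explanations(
    model,
    instance: np.ndarray,
    background: FeatureTable,
    n_perturbations: int = 5000,
    kernel_width: float | None = None,
    n_features_out: int = 10,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """Local surrogate explanation of one prediction.

    Draws Gaussian perturbations around ``instance`` scaled by the
    background per-feature SDs, queries the model, and fits a ridge
    regression weighted by exp(-d^2/kw^2) on standardized coordinates
    (d = Euclidean distance in standardized space; kernel width
    defaults to 0.75*sqrt(d_features)).  Returns the
    ``n_features_out`` markers with largest |weight|, signed.
    """
    instance = np.asarray(instance, dtype=float)
    markers = background.marker_codes
    if instance.shape != (len(markers),):
        raise ValueError("instance dimension does not match the background table")
    sds = background.X.std(axis=0, ddof=1).to_numpy()
    usable = sds > 0
    if not usable.all():
        logger.info("excluding %d zero-variance features from the explanation",
                    int((~usable).sum()))
    if not usable.any():
        raise ValueError("all background features have zero variance")
    d_used = int(usable.sum())
    if kernel_width is None:
        kernel_width = 0.75 * np.sqrt(d_used)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(size=(n_perturbations, d_used))
    X_pert = np.tile(instance, (n_perturbations, 1))
    X_pert[:, usable] = instance[usable] + z * sds[usable]
    preds = model_score(model, X_pert)
    dist2 = (z ** 2).sum(axis=1)
    weights = np.exp(-dist2 / kernel_width ** 2)
    ridge = Ridge(alpha=1.0)
    ridge.fit(z, preds, sample_weight=weights)
    coefs = ridge.coef_
    used_markers = [m for m, u in zip(markers, usable) if u]
    ranked = sorted(zip(used_markers, coefs), key=lambda kv: (-abs(kv[1]), kv[0]))
    return [(m, float(w)) for m, w in ranked[:n_features_out]]


def tally_recurrence(reports: list[ModelReport], top_k: int) -> RecurrenceTally:
    """Count appearances of markers (and their genes) in each report's
    top-``top_k`` importance list.

    Gene tallies aggregate marker-level appearances: a gene represented
    by two top-k markers in one report counts twice, mirroring
    marker-level counting.
    """
    if not reports:
        raise ValueError("at least one report required")
    marker_counts: dict[str, int] = {}
    gene_counts: dict[str, int] = {}
    for rep in reports:
        gene_of = {m: g for m, _, g in rep.importances}
        for m in rep.top_markers(top_k):
            marker_counts[m] = marker_counts.get(m, 0) + 1
            g = gene_of.get(m, "")
            if g:
                gene_counts[g] = gene_counts.get(g, 0) + 1
    return RecurrenceTally(marker_counts=marker_counts, gene_counts=gene_counts,
                           n_runs=len(reports), top_k=top_k)
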