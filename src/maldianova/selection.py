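"""Feature selection and decision-tree classification benchmarks.

Three selection strategies feed the same classifier:

* ``anova`` — the plain filter: peaks with the smallest per-peak ANOVA
  p-values for the target factor.
* ``cluster_anova`` — the redundancy-aware filter: cut the correlation
  dendrogram into flat clusters, rank clusters by their node p-value
  and take each top cluster's most significant member, so the selected
  peaks are approximately orthogonal.
* ``aco`` — an ant-colony-optimization wrapper: ants sample feature
  subsets with probability proportional to pheromone^alpha *
  heuristic^beta (heuristic = −log10 p), subsets are scored by internal
  cross-validation error of the decision tree, and pheromone is
  evaporated then reinforced along the iteration-best subset.

Performance is reported as pooled confusion matrices from stratified
10-fold cross-validation, with a permutation p-value obtained by
scoring randomly drawn feature sets of the same size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "FeatureSet", "ClassificationReport", "AcoConfig", "select_top_anova",
    "select_cluster_representatives", "aco_select", "train_decision_tree",
    "cross_validate", "permutation_pvalue",
]


@dataclass
class FeatureSet:
    method: str                       # anova | cluster_anova | aco
    peaks: list[float]                # peak m/z identifiers
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.peaks)) != len(self.peaks):
            raise ValueError("duplicate peaks in feature set")

    @property
    def size(self) -> int:
        return len(self.peaks)


@dataclass
class ClassificationReport:
    labels: list[str]
    confusion: np.ndarray             # true x predicted counts
    cv_error: float
    folds: int
    seed: int
    permutation_p: float | None = None

    def __post_init__(self) -> None:
        total = int(self.confusion.sum())
        correct = int(np.trace(self.confusion))
        if abs(self.cv_error - (1.0 - correct / total)) > 1e-9:
            raise ValueError("cv_error inconsistent with confusion matrix")


@dataclass
class AcoConfig:
    """Ant-colony wrapper settings.  Counts follow the reference runs
    (200 ants, 100 iterations); the remaining internals are package
    defaults chosen for reproducibility."""

    n_ants: int = 200
    n_iterations: int = 100
    evaporation: float = 0.1
    pheromone_floor: float = 0.01
    pheromone_ceiling: float = 10.0
    alpha: float = 1.0                # pheromone weight
    beta: float = 1.0                 # heuristic weight
    internal_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_ants, self.n_iterations, self.internal_folds) < 1:
            raise ValueError("counts must be positive")
        if not 0.0 < self.evaporation < 1.0:
            raise ValueError("evaporation must be in (0, 1)")
        if self.pheromone_floor <= 0 or self.pheromone_ceiling <= self.pheromone_floor:
            raise ValueError("invalid pheromone bounds")


def select_top_anova(anova_table: pd.DataFrame, factor: str,
                     n: int) -> FeatureSet:
    """The n peaks with the smallest p for ``factor``; ties by lower m/z."""
    if n <= 0:
        raise ValueError("n must be positive")
    col = f"p_{factor}"
    if col not in anova_table.columns:
        raise KeyError(f"no column {col!r} in ANOVA table")
    if n > len(anova_table):
        raise ValueError("n exceeds the number of peaks")
    order = anova_table[col].reset_index().sort_values(
        [col, "peak_mz"], kind="mergesort")
    picked = order["peak_mz"].head(n).tolist()
    return FeatureSet("anova", picked,
                      {"factor": factor,
                       "p_values": order[col].head(n).tolist()})


def select_cluster_representatives(
    tree,
    anova_table: pd.DataFrame,
    factor: str,
    n: int,
    cut_distance: float = 0.3,
) -> FeatureSet:
    """One representative peak from each of the n most significant clusters.

    The dendrogram is cut at ``cut_distance`` into flat clusters; each
    cluster is scored by the node p-value of the smallest subtree node
    containing exactly its members (a singleton uses the leaf p).
    From each of the n best clusters the member with the smallest
    individual p is chosen, so representatives are pairwise from
    distinct clusters.
    """
    from maldianova.redundancy import cut_tree

    if n < 1:
        raise ValueError("n must be >= 1")
    col = f"p_{factor}"
    flat = cut_tree(tree, cut_distance)
    clusters: dict[int, list] = {}
    for leaf, lab in flat.items():
        clusters.setdefault(lab, []).append(leaf)

    # locate, per flat cluster, the tree node holding exactly its members
    member_index = {leaf: i for i, leaf in enumerate(tree.leaf_ids)}
    node_by_members = {tuple(tree.members(node)): node
                       for node in tree.all_nodes()}
    scored = []
    for lab, leaves in clusters.items():
        key = tuple(sorted(member_index[l] for l in leaves))
        node = node_by_members.get(key)
        if node is not None and col in tree.nodes.get(node, {}):
            score = tree.nodes[node][col]
        else:                         # fall back to best member p
            score = float(anova_table.loc[leaves, col].min())
        scored.append((score, min(leaves), lab, leaves))
    scored.sort()
    if len(scored) < n:
        warnings.warn(f"only {len(scored)} clusters at cut distance "
                      f"{cut_distance}; returning all", stacklevel=2)
    picked, cluster_of = [], {}
    for score, _, lab, leaves in scored[:n]:
        sub = anova_table.loc[leaves, col].reset_index().sort_values(
            [col, "peak_mz"], kind="mergesort")
        rep = float(sub["peak_mz"].iloc[0])
        picked.append(rep)
        cluster_of[rep] = lab
    return FeatureSet("cluster_anova", picked,
                      {"factor": factor, "cut_distance": cut_distance,
                       "cluster_of": cluster_of})


def train_decision_tree(matrix: pd.DataFrame, labels: pd.Series,
                        features: list, max_depth: int = 5,
                        min_samples_leaf: int = 5) -> DecisionTreeClassifier:
    """CART-style tree (Gini, axis-aligned splits) on selected peaks only.

    ``matrix`` is peaks x samples; depth and leaf size are capped to
    keep the classifier honest on small sample counts.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need >= 2 classes")
    X = matrix.loc[features].T.to_numpy()
    clf = DecisionTreeClassifier(criterion="gini", max_depth=max_depth,
                                 min_samples_leaf=min_samples_leaf,
                                 random_state=0)
    clf.fit(X, y)
    return clf


def cross_validate(matrix: pd.DataFrame, labels: pd.Series, features: list,
                   folds: int = 10, seed: int = 0, max_depth: int = 5,
                   min_samples_leaf: int = 5) -> ClassificationReport:
    """Stratified k-fold CV; out-of-fold predictions pooled into one
    confusion matrix, error = misclassified / total."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = np.asarray(labels).astype(str)
    classes = sorted(np.unique(y))
    min_class = min(np.bincount(pd.Categorical(y, classes).codes))
    if min_class < folds:
        warnings.warn(f"reducing folds {folds} -> {min_class} "
                      "(smallest class)", stacklevel=2)
        folds = max(2, int(min_class))
    X = matrix.loc[features].T.to_numpy()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=object)
    for tr, te in skf.split(X, y):
        clf = DecisionTreeClassifier(criterion="gini", max_depth=max_depth,
                                     min_samples_leaf=min_samples_leaf,
                                     random_state=0)
        clf.fit(X[tr], y[tr])
        pred[te] = clf.predict(X[te])
    cm = confusion_matrix(y, pred.astype(str), labels=classes)
    err = 1.0 - np.trace(cm) / cm.sum()
    return ClassificationReport(classes, cm, float(err), folds, seed)


def _subset_error(matrix, y, features, folds, seed, cache):
    key = frozenset(features)
    if key not in cache:
        cache[key] = cross_validate(matrix, y, list(features),
                                    folds=folds, seed=seed).cv_error
    return cache[key]


def aco_select(matrix: pd.DataFrame, labels: pd.Series, n_features: int,
               anova_table: pd.DataFrame, factor: str = "diet",
               config: AcoConfig | None = None) -> FeatureSet:
    """Ant-colony-optimization wrapper selection.

    Each ant draws ``n_features`` distinct peaks with probability
    proportional to ``pheromone^alpha * heuristic^beta``; the heuristic
    is the peak's −log10 p for ``factor``.  Fitness is the internal
    stratified-CV error of the decision tree on the subset; after each
    iteration pheromone evaporates and the iteration-best subset is
    reinforced by ``1 − error``.  Deterministic for a fixed seed.
    """
    config = config or AcoConfig()
    peaks = list(matrix.index)
    if n_features > len(peaks):
        raise ValueError("n_features exceeds the number of peaks")
    col = f"p_{factor}"
    pvals = anova_table[col].reindex(peaks).fillna(1.0).to_numpy()
    heuristic = np.maximum(-np.log10(np.maximum(pvals, 1e-300)), 1e-3)
    rng = np.random.default_rng(config.seed)
    pher = np.ones(len(peaks))
    cache: dict[frozenset, float] = {}
    best_subset, best_err = None, np.inf
    trace = []
    for _ in range(config.n_iterations):
        weights = (pher ** config.alpha) * (heuristic ** config.beta)
        prob = weights / weights.sum()
        iter_best, iter_err = None, np.inf
        for _ant in range(config.n_ants):
            idx = rng.choice(len(peaks), size=n_features, replace=False,
                             p=prob)
            subset = tuple(sorted(idx))
            err = _subset_error(matrix, labels, [peaks[i] for i in subset],
                                config.internal_folds, config.seed, cache)
            if err < iter_err:
                iter_best, iter_err = subset, err
        pher *= (1.0 - config.evaporation)
        for i in iter_best:
            pher[i] += (1.0 - iter_err)
        np.clip(pher, config.pheromone_floor, config.pheromone_ceiling,
                out=pher)
        if iter_err < best_err:
            best_subset, best_err = iter_best, iter_err
        trace.append(float(iter_err))
    picked = sorted(peaks[i] for i in best_subset)
    return FeatureSet("aco", picked,
                      {"factor": factor, "fitness": float(best_err),
                       "trace": trace, "seed": config.seed})


def permutation_pvalue(matrix: pd.DataFrame, labels: pd.Series,
                       featureset: FeatureSet, n_random: int = 1000,
                       folds: int = 10, seed: int = 0) -> float:
    """How often a random same-size feature set classifies at least as well.

    Random sets are scored with the same folds; the add-one pseudo-count
    bounds the p-value below by 1/(n_random + 1).
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    if featureset.size > len(matrix):
        raise ValueError("feature set larger than the peak count")
    observed = cross_validate(matrix, labels, featureset.peaks,
                              folds=folds, seed=seed).cv_error
    rng = np.random.default_rng(seed)
    peaks = list(matrix.index)
    wins = 0
    for _ in range(n_random):
        idx = rng.choice(len(peaks), size=featureset.size, replace=False)
        err = cross_validate(matrix, labels, [peaks[i] for i in idx],
                             folds=folds, seed=seed).cv_error
        if err <= observed:
            wins += 1
    return (wins + 1) / (n_random + 1)
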