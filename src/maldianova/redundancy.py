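"""Redundancy exploitation: correlation clustering with node p-values.

Peptides derived from one parent protein produce several correlated
peaks.  Average-linkage (UPGMA) hierarchical clustering on the
1 − Pearson-correlation distance between intensity profiles groups such
peaks; each dendrogram node is then annotated with the mean pairwise
correlation of its members and four ANOVA p-values computed on the
point-wise mean of the members' z-transformed profiles.  The annotated
tree fuses similarity with significance in one picture.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import TreeNode

from maldianova.anova import factorial_anova

__all__ = [
    "ClusterTree", "z_transform", "correlation_distance", "average_linkage",
    "node_pvalues", "mean_node_correlation", "build_annotated_tree",
    "export_dendrogram", "cut_tree",
]

P_COLUMNS = ("p_diet", "p_genotype", "p_week", "p_interaction")


def z_transform(profile: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, sample sd 1 (ddof = 1).

    Profiles live on peak-specific absolute scales, so they must be
    standardized before they can be averaged within a node.
    """
    x = np.asarray(profile, dtype=float)
    sd = x.std(ddof=1)
    if sd <= 0:
        raise ValueError("constant profile cannot be z-transformed")
    return (x - x.mean()) / sd


def correlation_distance(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise distance 1 − ρ between peak profiles (rows).

    Constant profiles have undefined correlation and are excluded with a
    warning.  The result is symmetric with zero diagonal, values in
    [0, 2] (2 means perfect anti-correlation).
    """
    sds = profiles.std(axis=1, ddof=1)
    constant = sds[sds <= 0].index.tolist()
    if constant:
        warnings.warn(f"dropping {len(constant)} constant profile(s)",
                      stacklevel=2)
        profiles = profiles.drop(index=constant)
    if len(profiles) < 2:
        raise ValueError("need >= 2 non-constant profiles")
    rho = np.corrcoef(profiles.to_numpy())
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


@dataclass
class ClusterTree:
    """Average-linkage merge tree over peak profiles.

    Wraps a scipy linkage matrix.  Node ids follow scipy convention:
    0..n-1 are leaves, n+i is the cluster created at merge i.  Node
    annotations (members, height, mean correlation, p-values) live in
    ``nodes``, filled by :func:`mean_node_correlation` /
    :func:`node_pvalues`.
    """

    linkage: np.ndarray
    leaf_ids: list            # peak identifiers (m/z), leaf order
    nodes: dict[int, dict] = field(default_factory=dict)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def members(self, node: int) -> list[int]:
        """Leaf indices under a node id."""
        n = self.n_leaves
        if node < n:
            return [node]
        stack, out = [node], []
        while stack:
            k = stack.pop()
            if k < n:
                out.append(k)
            else:
                a, b = self.linkage[k - n, 0], self.linkage[k - n, 1]
                stack.extend((int(a), int(b)))
        return sorted(out)

    def height(self, node: int) -> float:
        n = self.n_leaves
        return 0.0 if node < n else float(self.linkage[node - n, 2])

    def internal_nodes(self) -> list[int]:
        n = self.n_leaves
        return [n + i for i in range(len(self.linkage))]

    def all_nodes(self) -> list[int]:
        return list(range(self.n_leaves)) + self.internal_nodes()


def average_linkage(dist: pd.DataFrame) -> ClusterTree:
    """UPGMA agglomeration of a (peaks x peaks) distance matrix.

    Ties between merge candidates are resolved by scipy's deterministic
    ordering, so the tree is reproducible for identical input.
    """
    if len(dist) < 2:
        raise ValueError("need >= 2 items to cluster")
    condensed = squareform(dist.to_numpy(), checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    return ClusterTree(Z, list(dist.index))


def mean_node_correlation(tree: ClusterTree,
                          profiles: pd.DataFrame) -> dict[int, float]:
    """Mean pairwise Pearson ρ among each node's member profiles.

    Leaves (and any single-member node) are defined as 1.
    """
    rho = np.corrcoef(profiles.loc[tree.leaf_ids].to_numpy())
    out: dict[int, float] = {}
    for node in tree.all_nodes():
        mem = tree.members(node)
        if len(mem) < 2:
            out[node] = 1.0
        else:
            sub = rho[np.ix_(mem, mem)]
            iu = np.triu_indices(len(mem), k=1)
            out[node] = float(sub[iu].mean())
        tree.nodes.setdefault(node, {})["mean_correlation"] = out[node]
    return out


def node_pvalues(tree: ClusterTree, profiles: pd.DataFrame,
                 sample_sheet: pd.DataFrame,
                 week_categorical: bool = True) -> ClusterTree:
    """Annotate every node with four factorial-ANOVA p-values.

    A node's test statistic is computed from the point-wise mean of its
    members' z-transformed profiles; a leaf uses its own profile (the
    F-test is invariant under the affine z-transform, so leaf p-values
    equal the per-peak ANOVA table entries).  Nodes whose members are
    all constant get p = 1 with a flag.
    """
    sheet = sample_sheet.drop_duplicates("sample_id").set_index("sample_id")
    prof = profiles.loc[tree.leaf_ids]
    factors = sheet.loc[list(prof.columns), ["genotype", "diet", "week"]].copy()
    factors["week"] = factors["week"].astype(str if week_categorical else float)

    zrows = np.full(prof.shape, np.nan)
    ok = np.zeros(len(prof), dtype=bool)
    raw = prof.to_numpy()
    for i in range(len(prof)):
        sd = raw[i].std(ddof=1)
        if sd > 0:
            zrows[i] = (raw[i] - raw[i].mean()) / sd
            ok[i] = True

    for node in tree.all_nodes():
        mem = tree.members(node)
        info = tree.nodes.setdefault(node, {})
        info["members"] = [tree.leaf_ids[i] for i in mem]
        info["height"] = tree.height(node)
        usable = [i for i in mem if ok[i]]
        if not usable:
            for c in P_COLUMNS:
                info[c] = 1.0
            info["flag"] = "degenerate:all-constant"
            continue
        # single-member nodes use the raw profile (the F-test is affine
        # invariant, so this matches the per-peak table bit for bit)
        if len(usable) == 1:
            mean_profile = raw[usable[0]]
        else:
            mean_profile = zrows[usable].mean(axis=0)
        res = factorial_anova(mean_profile, factors)
        for c in P_COLUMNS:
            info[c] = res[c]
        if res.get("flags"):
            info["flag"] = res["flags"]
    return tree


def build_annotated_tree(profiles: pd.DataFrame,
                         sample_sheet: pd.DataFrame) -> ClusterTree:
    """Distance -> UPGMA -> correlations -> node p-values, in one call."""
    d = correlation_distance(profiles)
    tree = average_linkage(d)
    mean_node_correlation(tree, profiles.loc[d.index])
    node_pvalues(tree, profiles.loc[d.index], sample_sheet)
    return tree


def cut_tree(tree: ClusterTree, cut_distance: float) -> dict:
    """Flat clusters at a merge-height threshold: leaf id -> cluster label."""
    labels = hierarchy.fcluster(tree.linkage, t=cut_distance,
                                criterion="distance")
    return {leaf: int(lab) for leaf, lab in zip(tree.leaf_ids, labels)}


def export_dendrogram(tree: ClusterTree) -> tuple[str, dict]:
    """Newick string plus a JSON-ready annotation side-table.

    Internal nodes are named ``n<i>``; the side-table maps each node
    name (leaves use their peak id) to members, height, mean correlation
    and −log10 p per factor, each factor carrying its own scale so the
    four colour scales of the dendrogram glyphs stay independent.
    """
    n = tree.n_leaves
    names = {}
    for node in tree.all_nodes():
        names[node] = (str(tree.leaf_ids[node]) if node < n else f"n{node - n}")

    def newick(node: int) -> str:
        if node < n:
            return names[node]
        a, b = int(tree.linkage[node - n, 0]), int(tree.linkage[node - n, 1])
        ha, hb = tree.height(node) - tree.height(a), tree.height(node) - tree.height(b)
        return (f"({newick(a)}:{max(ha, 0.0):.6g},"
                f"{newick(b)}:{max(hb, 0.0):.6g}){names[node]}")

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * n + 100))
    try:
        nwk = newick(2 * n - 2) + ";"
    finally:
        sys.setrecursionlimit(old)

    side: dict[str, dict] = {}
    for node in tree.all_nodes():
        info = tree.nodes.get(node, {})
        entry = {
            "members": [str(m) for m in
                        info.get("members",
                                 [tree.leaf_ids[i] for i in tree.members(node)])],
            "height": tree.height(node),
            "mean_correlation": info.get("mean_correlation"),
        }
        for c in P_COLUMNS:
            if c in info:
                entry[c] = info[c]
                entry[f"neglog10_{c}"] = float(-np.log10(max(info[c], 1e-300)))
        side[names[node]] = entry
    # per-factor colour scale bounds (independent scales, as in the
    # four-box node glyphs)
    scales = {}
    for c in P_COLUMNS:
        vals = [v[f"neglog10_{c}"] for v in side.values() if f"neglog10_{c}" in v]
        if vals:
            scales[c] = {"min": float(min(vals)), "max": float(max(vals))}
    side["_scales"] = scales
    return nwk, side


def parse_newick(text: str) -> TreeNode:
    """Round-trip helper: parse an exported Newick string."""
    import io
    return TreeNode.read(io.StringIO(text))
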