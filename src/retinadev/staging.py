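"""Sample staging: hierarchical clustering, Moran eigenvectors, windows.

Developmental windows are read off an unsupervised ordination of the
samples: Euclidean distances on the quantile-normalised log layer are
clustered with median-linkage agglomeration, the resulting ultrametric
tree is converted to a leaf-proximity matrix (reciprocal patristic
distance), and Moran eigenvectors (MEs) are obtained by
eigen-decomposing the double-centred proximity matrix. ME score columns
are centred to mean zero with unit variance (denominator n) and are
mutually uncorrelated; sign rules on the leading MEs ("ME1 low", "ME2
high", ...) then partition the samples into developmental windows.

The median-linkage dialect here applies the Lance-Williams update
d(k, i+j) = d(k,i)/2 + d(k,j)/2 - d(i,j)/4 to the distances as given
(the hclust convention); ``squared=True`` gives the textbook WPGMC
variant operating on squared Euclidean distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import PreconditionError, ValidationError
from .preprocess import SampleMeta

__all__ = [
    "LinkageTree",
    "MoranBasis",
    "WindowRule",
    "pairwise_distances",
    "median_linkage",
    "tree_to_proximity",
    "moran_eigenvectors",
    "assign_windows",
    "derive_window_rules",
    "cut_tree",
]


# ---------------------------------------------------------------------------
# distances and clustering
# ---------------------------------------------------------------------------

def pairwise_distances(layer: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distances between samples (columns of the layer)."""
    x = layer.to_numpy(dtype=float).T
    if x.shape[0] < 2:
        raise PreconditionError("pairwise_distances: need >=2 samples")
    if np.isnan(x).any():
        raise ValidationError("pairwise_distances: NaN in layer")
    d = squareform(pdist(x, metric="euclidean"))
    return pd.DataFrame(d, index=layer.columns, columns=layer.columns)


@dataclass
class LinkageTree:
    """Agglomerative merge tree over samples.

    Nodes 0..n-1 are leaves (in ``leaf_ids`` order); merge i creates node
    n+i. ``merges`` rows are (node_a, node_b, height, size).
    """

    leaf_ids: list
    merges: list  # list of (int, int, float, int)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValidationError("LinkageTree: need n-1 merges for n leaves")

    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges], dtype=float)

    def leaf_sets(self) -> list:
        """Leaf index set under every node (leaves then internal, merge order)."""
        sets = [frozenset([i]) for i in range(self.n_leaves)]
        for a, b, _h, _s in self.merges:
            sets.append(sets[a] | sets[b])
        return sets

    def cophenetic(self) -> pd.DataFrame:
        """Patristic leaf-to-leaf distances: 2 x merge height of the MRCA."""
        n = self.n_leaves
        sets = [frozenset([i]) for i in range(n)]
        d = np.zeros((n, n))
        for a, b, h, _s in self.merges:
            sa, sb = sets[a], sets[b]
            for i in sa:
                for j in sb:
                    d[i, j] = d[j, i] = 2.0 * h
            sets.append(sa | sb)
        return pd.DataFrame(d, index=self.leaf_ids, columns=self.leaf_ids)

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights.

        Node height equals its merge height; a child branch length is the
        parent height minus the child height (may be negative where the
        merge sequence inverts, as median linkage permits).
        """
        n = self.n_leaves
        height = [0.0] * n + [m[2] for m in self.merges]
        label: list = [str(x) for x in self.leaf_ids]
        for k, (a, b, h, _s) in enumerate(self.merges):
            la = f"{label[a]}:{h - height[a]:.10g}"
            lb = f"{label[b]}:{h - height[b]:.10g}"
            label.append(f"({la},{lb})")
        return label[-1] + ";"


def median_linkage(d: pd.DataFrame, squared: bool = False) -> LinkageTree:
    """Median-agglomeration hierarchical clustering of a distance matrix.

    Nearest active pair merges each step; ties broken by the smallest
    (representative leaf id) pair. With ``squared=True`` the
    Lance-Williams update runs on squared distances and merge heights are
    square roots (WPGMC).
    """
    a = d.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValidationError("median_linkage: distance matrix not square")
    if not np.allclose(a, a.T, atol=1e-8):
        raise ValidationError("median_linkage: distance matrix not symmetric")
    n = a.shape[0]
    if n < 2:
        raise PreconditionError("median_linkage: need >=2 samples")

    work = a.astype(float) ** 2 if squared else a.astype(float).copy()
    np.fill_diagonal(work, np.inf)
    active = {i: i for i in range(n)}  # node id -> matrix row
    rep = {i: i for i in range(n)}  # node id -> smallest leaf index (tie-break)
    size = {i: 1 for i in range(n)}
    merges = []
    for step in range(n - 1):
        nodes = sorted(active, key=lambda u: rep[u])
        best = None
        for u, v in combinations(nodes, 2):
            duv = work[active[u], active[v]]
            key = (duv, rep[u], rep[v])
            if best is None or key < best[0]:
                best = (key, u, v)
        (duv, _, _), u, v = best
        height = float(np.sqrt(duv)) if squared else float(duv)
        new = n + step
        ru, rv = active[u], active[v]
        for w in nodes:
            if w in (u, v):
                continue
            rw = active[w]
            upd = 0.5 * work[rw, ru] + 0.5 * work[rw, rv] - 0.25 * duv
            work[rw, ru] = work[ru, rw] = upd
        work[rv, :] = np.inf
        work[:, rv] = np.inf
        merges.append((u, v, height, size[u] + size[v]))
        size[new] = size[u] + size[v]
        rep[new] = min(rep[u], rep[v])
        active[new] = ru
        del active[u], active[v]
    return LinkageTree(leaf_ids=list(d.index), merges=merges)


def cut_tree(tree: LinkageTree, k: int) -> pd.Series:
    """Cut into k clusters by undoing the k-1 highest merges.

    Merge heights are first monotonised by a running maximum over each
    node's children (median linkage permits inversions), so the undone
    merge set is always an upward-closed crown of the tree.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValidationError(f"cut_tree: k={k} outside [1, {n}]")
    eff = [0.0] * (2 * n - 1)
    for step, (a, b, h, _s) in enumerate(tree.merges):
        eff[n + step] = max(h, eff[a], eff[b])
    order = sorted(range(n - 1), key=lambda t: (eff[n + t], t))
    undone = set(order[n - k:])

    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step, (a, b, _h, _s) in enumerate(tree.merges):
        if step not in undone:
            parent[find(a)] = parent[find(b)] = n + step
    roots = [find(i) for i in range(n)]
    _, labels = np.unique(roots, return_inverse=True)
    return pd.Series(labels, index=tree.leaf_ids, name="cluster")


# ---------------------------------------------------------------------------
# Moran eigenvectors
# ---------------------------------------------------------------------------

def tree_to_proximity(tree: LinkageTree, row_normalize: bool = False) -> pd.DataFrame:
    """Leaf proximity matrix a_ij = 1 / patristic distance, zero diagonal."""
    d = tree.cophenetic().to_numpy()
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    if (d[off] <= 0).any():
        raise ValidationError(
            "tree_to_proximity: zero patristic distance between distinct leaves; "
            "jitter or merge duplicate samples upstream"
        )
    a = np.zeros_like(d)
    a[off] = 1.0 / d[off]
    if row_normalize:
        a = a / a.sum(axis=1, keepdims=True)
        a = 0.5 * (a + a.T)
    return pd.DataFrame(a, index=tree.leaf_ids, columns=tree.leaf_ids)


@dataclass
class MoranBasis:
    """Moran eigenvector scores: samples x components ME1..MEk.

    Columns have mean 0, variance 1 (denominator n) and are pairwise
    uncorrelated; eigenvalues are in descending order.
    """

    scores: pd.DataFrame
    eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def components(self) -> list:
        return list(self.scores.columns)

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]


def moran_eigenvectors(
    a: pd.DataFrame,
    tol: float = 1e-9,
    top_k: int | None = None,
    var_denominator: str = "n",
) -> MoranBasis:
    """Moran eigenvector basis from a symmetric proximity matrix.

    The proximity matrix is double-centred, C = H A H with
    H = I - 11'/n, and eigen-decomposed; eigenvectors whose |eigenvalue|
    exceeds ``tol`` (relative to the largest) are kept, ordered by
    eigenvalue descending, sign-fixed (first nonzero loading positive)
    and rescaled to mean 0, variance 1.
    """
    x = a.to_numpy(dtype=float)
    n = x.shape[0]
    if n < 3:
        raise PreconditionError("moran_eigenvectors: need >=3 samples")
    asym = np.abs(x - x.T).max()
    scale = max(np.abs(x).max(), 1.0)
    if asym > 1e-6 * scale:
        raise ValidationError("moran_eigenvectors: proximity matrix not symmetric")
    x = 0.5 * (x + x.T)

    h = np.eye(n) - np.full((n, n), 1.0 / n)
    c = h @ x @ h
    c = 0.5 * (c + c.T)
    evals, evecs = np.linalg.eigh(c)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    keep = np.abs(evals) > tol * max(np.abs(evals).max(), 1e-300)
    evals, evecs = evals[keep], evecs[:, keep]
    if top_k is not None:
        evals, evecs = evals[:top_k], evecs[:, :top_k]

    # deterministic orientation and within-degenerate-block ordering
    for j in range(evecs.shape[1]):
        col = evecs[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            evecs[:, j] = -col
    j = 0
    block_tol = 1e-9 * max(np.abs(evals).max() if evals.size else 1.0, 1.0)
    while j < len(evals):
        j2 = j + 1
        while j2 < len(evals) and abs(evals[j2] - evals[j]) <= block_tol:
            j2 += 1
        if j2 - j > 1:
            sub = evecs[:, j:j2]
            sub_order = np.argsort(-sub[0, :], kind="stable")
            evecs[:, j:j2] = sub[:, sub_order]
        j = j2

    ddof = 0 if var_denominator == "n" else 1
    scores = evecs - evecs.mean(axis=0, keepdims=True)
    sd = scores.std(axis=0, ddof=ddof)
    if (sd == 0).any():
        raise ValidationError("moran_eigenvectors: degenerate (constant) eigenvector")
    scores = scores / sd
    names = [f"ME{i + 1}" for i in range(scores.shape[1])]
    return MoranBasis(
        scores=pd.DataFrame(scores, index=a.index, columns=names),
        eigenvalues=evals,
    )


# ---------------------------------------------------------------------------
# window assignment
# ---------------------------------------------------------------------------

@dataclass
class WindowRule:
    """Ordered sign rules: (label, [(component, 'low'|'high'), ...]).

    Rules are evaluated in precedence order; a sample takes the label of
    the first rule whose every condition it satisfies ('low' means score
    < 0, 'high' means score >= 0). An empty condition list matches every
    remaining sample (catch-all).
    """

    rules: list  # list of (label, list[(str, str)])

    def __post_init__(self) -> None:
        for label, conds in self.rules:
            for comp, sign in conds:
                if sign not in ("low", "high"):
                    raise ValidationError(
                        f"WindowRule {label!r}: sign must be 'low' or 'high', got {sign!r}"
                    )


def assign_windows(basis: MoranBasis, rules: WindowRule) -> pd.Series:
    """Label every sample by the first matching sign rule."""
    for label, conds in rules.rules:
        for comp, _sign in conds:
            if comp not in basis.scores.columns:
                raise ValidationError(
                    f"assign_windows: rule {label!r} references unknown component {comp!r}"
                )
    labels = pd.Series(index=basis.scores.index, dtype=object)
    for label, conds in rules.rules:
        unassigned = labels.isna()
        match = pd.Series(True, index=basis.scores.index)
        for comp, sign in conds:
            s = basis.scores[comp]
            match &= (s < 0) if sign == "low" else (s >= 0)
        labels[unassigned & match] = label
    if labels.isna().any():
        bad = labels.index[labels.isna()].tolist()
        detail = basis.scores.loc[bad].round(3).to_dict("index")
        raise ValidationError(f"assign_windows: unmatched samples {detail}")
    labels.name = "window"
    return labels


def derive_window_rules(
    tree: LinkageTree,
    basis: MoranBasis,
    n_windows: int,
    meta: SampleMeta | None = None,
    max_components: int = 8,
    max_conditions: int = 3,
) -> WindowRule:
    """Construct ordered sign rules that reproduce a k-way tree partition.

    The tree is cut into ``n_windows`` clusters; for each cluster, in a
    greedy precedence order, the conjunction of up to ``max_conditions``
    ME sign conditions best matching the cluster among still-unassigned
    samples (by Jaccard index) is recorded; the final cluster becomes the
    catch-all rule. If ``meta`` is given, windows are named W1..Wk in
    order of their mean stage index, else by cluster id.
    """
    clusters = cut_tree(tree, n_windows)
    scores = basis.scores
    comps = basis.components[: min(max_components, len(basis.components))]
    sign_sets = {}
    for comp in comps:
        s = scores[comp]
        sign_sets[(comp, "low")] = frozenset(s.index[s < 0])
        sign_sets[(comp, "high")] = frozenset(s.index[s >= 0])

    if meta is not None:
        mean_stage = meta.stage_index.reindex(clusters.index).groupby(clusters).mean()
        cluster_order = list(mean_stage.sort_values().index)
        names = {c: f"W{i + 1}" for i, c in enumerate(cluster_order)}
    else:
        names = {c: f"W{c + 1}" for c in clusters.unique()}

    remaining = set(scores.index)
    todo = sorted(clusters.unique(), key=lambda c: names[c])
    rules: list = []
    while len(todo) > 1:
        best = None  # (jaccard, -n_conds, cluster, conds)
        for c in todo:
            target = frozenset(clusters.index[clusters == c]) & frozenset(remaining)
            if not target:
                continue
            for r in range(1, max_conditions + 1):
                for conds in combinations(sorted(sign_sets), r):
                    sel = frozenset(remaining)
                    for cond in conds:
                        sel &= sign_sets[cond]
                    if not sel:
                        continue
                    jac = len(sel & target) / len(sel | target)
                    key = (jac, -r)
                    if best is None or key > best[0]:
                        best = (key, c, list(conds))
        if best is None:
            break
        _, c, conds = best
        rules.append((names[c], conds))
        sel = frozenset(remaining)
        for cond in conds:
            sel &= sign_sets[cond]
        remaining -= sel
        todo.remove(c)
    rules.append((names[todo[0]], []))  # catch-all
    return WindowRule(rules=rules)
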