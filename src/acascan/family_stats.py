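"""Family summaries, Welch's t-test, NJ trees and Newick export.

The associated-vs-solo contrast mirrors the field's presentation: per family,
protein length and identity-to-reference are summarised per group (mean with
95% t-based confidence interval) and compared by an unpaired unequal-variance
(Welch) t-test; hits must exceed 40% coverage of the reference (strict
inequality). Family relatedness uses neighbor joining on 1 - pairwise
identity; NJ is exact on additive matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genomic_context import AssociationRecord
from .homology import HomologHit, pairwise_identity


@dataclass(frozen=True)
class GroupStats:
    n: int
    mean: float
    ci95_half_width: float


@dataclass
class FamilySummary:
    family: str
    n_associated: int
    n_solo: int
    length_stats: dict[str, GroupStats]
    identity_stats: dict[str, GroupStats]
    t_test_length: tuple[float, float, float] | None  # (t, df, p)
    t_test_identity: tuple[float, float, float] | None


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t statistic, Welch-Satterthwaite df, 2-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    diff = x.mean() - y.mean()
    if se2 == 0.0:
        if diff == 0.0:
            raise ValueError("degenerate: both variances zero and equal means")
        return (np.inf if diff > 0 else -np.inf, float(nx + ny - 2), 0.0)
    t = diff / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _group_stats(values: list[float]) -> GroupStats:
    arr = np.asarray(values, dtype=float)
    n = len(arr)
    if n == 0:
        return GroupStats(0, float("nan"), float("nan"))
    if n == 1:
        return GroupStats(1, float(arr[0]), float("nan"))
    hw = float(stats.t.ppf(0.975, n - 1) * arr.std(ddof=1) / np.sqrt(n))
    return GroupStats(n, float(arr.mean()), hw)


def summarize_family(
    hits: list[HomologHit],
    records: list[AssociationRecord],
    min_coverage: float = 0.4,
    include_proximal: bool = False,
) -> FamilySummary:
    """Associated-vs-solo contrast for one family's hits.

    Hits with coverage <= min_coverage are excluded (the ">40%" filter is a
    strict inequality); proximal records are excluded from the two-group
    contrast by default. Welch tests are reported only when both groups have
    n >= 2 and the inputs are non-degenerate.
    """
    if not hits:
        raise ValueError("empty family: no hits to summarise")
    family = hits[0].family_name
    label_of = {r.aca_hit.cds_id: r.label for r in records}
    groups: dict[str, list[HomologHit]] = {"associated": [], "solo": []}
    for h in sorted(hits, key=lambda h: h.cds_id):
        if h.family_name != family or h.coverage <= min_coverage:
            continue
        label = label_of.get(h.cds_id)
        if label == "acr_associated" or (include_proximal and label == "proximal"):
            groups["associated"].append(h)
        elif label == "solo":
            groups["solo"].append(h)

    def metric_stats(metric) -> dict[str, GroupStats]:
        return {g: _group_stats([metric(h) for h in hs]) for g, hs in groups.items()}

    def metric_test(metric) -> tuple[float, float, float] | None:
        a = [metric(h) for h in groups["associated"]]
        s = [metric(h) for h in groups["solo"]]
        if len(a) < 2 or len(s) < 2:
            return None
        try:
            return welch_t_test(a, s)
        except ValueError:
            return None

    length = lambda h: float(h.protein_length)
    ident = lambda h: h.identity_to_reference
    return FamilySummary(
        family=family,
        n_associated=len(groups["associated"]),
        n_solo=len(groups["solo"]),
        length_stats=metric_stats(length),
        identity_stats=metric_stats(ident),
        t_test_length=metric_test(length),
        t_test_identity=metric_test(ident),
    )


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if np.any(self.values < 0):
            raise ValueError("negative distances")
        if np.abs(self.values - self.values.T).max() > 1e-12:
            raise ValueError("asymmetric distance matrix")
        if np.abs(np.diag(self.values)).max() != 0.0:
            raise ValueError("nonzero diagonal")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "  " + "  ".join(f"{v:.9f}" for v in row) + "\n")


def distances_from_identity(seqs: dict[str, str]) -> DistanceMatrix:
    """d(i, j) = 1 - global-alignment identity; symmetric by construction."""
    labels = sorted(seqs)
    if len(labels) < 2:
        raise ValueError("need at least two sequences")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident, _ = pairwise_identity(seqs[labels[i]], seqs[labels[j]])
            d[i, j] = d[j, i] = max(0.0, 1.0 - ident)
    return DistanceMatrix(labels, d)


@dataclass
class TreeNode:
    """Node of an unrooted tree; the root is a placeholder trifurcation."""

    name: str = ""
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return [n for child, _ in self.children for n in child.leaf_names()]


@dataclass
class PhyloTree:
    root: TreeNode
    negative_lengths_clamped: bool = False

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()


def nj_tree(d: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; exact on additive matrices.

    Q ties are broken by the smallest (sorted) pair of subtree labels, where a
    subtree's label is its lexicographically smallest leaf. Negative branch
    length estimates are clamped to zero and flagged.
    """
    n = len(d.labels)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    clamped = False

    def cl(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    if n == 2:
        half = d.values[0, 1] / 2.0
        root = TreeNode(
            children=[(TreeNode(d.labels[0]), half), (TreeNode(d.labels[1]), half)]
        )
        return PhyloTree(root, clamped)

    nodes: list[TreeNode] = [TreeNode(lab) for lab in d.labels]
    keys: list[str] = list(d.labels)  # smallest leaf label per active subtree
    D = d.values.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                tie = tuple(sorted((keys[i], keys[j])))
                cand = (q, tie, i, j)
                if best is None or cand < best:
                    best = cand
        _, _, i, j = best
        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        new = TreeNode(children=[(nodes[i], cl(li)), (nodes[j], cl(lj))])
        # grow matrix with the merged node's distances
        k_new = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[k_new, k] = D[k, k_new] = (D[i, k] + D[j, k] - D[i, j]) / 2.0
        nodes.append(new)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [k_new]
    if len(active) == 3:
        i, j, k = active
        li = cl((D[i, j] + D[i, k] - D[j, k]) / 2.0)
        lj = cl((D[i, j] + D[j, k] - D[i, k]) / 2.0)
        lk = cl((D[i, k] + D[j, k] - D[i, j]) / 2.0)
        root = TreeNode(children=[(nodes[i], li), (nodes[j], lj), (nodes[k], lk)])
    else:  # exactly two active nodes remain (n was 3 originally handled above)
        i, j = active
        root = TreeNode(children=[(nodes[i], cl(D[i, j] / 2)), (nodes[j], cl(D[i, j] / 2))])
    return PhyloTree(root, clamped)


def _newick_label(name: str) -> str:
    if any(c in name for c in " \t()[]':;,"):
        return "'" + name.replace("'", "''") + "'"
    return name


def _newick_node(node: TreeNode) -> str:
    if node.is_leaf:
        return _newick_label(node.name)
    inner = ",".join(
        f"{_newick_node(child)}:{bl:.12g}" for child, bl in node.children
    )
    return f"({inner})"


def write_newick(tree: PhyloTree) -> str:
    """Newick text with branch lengths; round-trips through standard readers."""
    return _newick_node(tree.root) + ";"


def tree_path_distances(tree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix (for additivity round-trip checks)."""
    import networkx as nx

    g = nx.Graph()
    counter = [0]

    def walk(node: TreeNode) -> str:
        if node.is_leaf:
            return node.name
        counter[0] += 1
        me = f"__internal_{counter[0]}"
        for child, bl in node.children:
            g.add_edge(me, walk(child), weight=bl)
        return me

    walk(tree.root)
    leaves = sorted(tree.leaf_names())
    lengths = dict(nx.all_pairs_dijkstra_path_length(g))
    vals = np.array([[0.0 if a == b else lengths[a][b] for b in leaves] for a in leaves])
    vals = (vals + vals.T) / 2.0  # shed float asymmetry from path summation
    return DistanceMatrix(leaves, vals)
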