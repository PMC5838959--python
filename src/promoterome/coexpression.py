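"""Co-expression clustering with multiscale-bootstrap support values.

Expression profiles are clustered by average linkage (UPGMA) on a
1 - Pearson-correlation distance.  Clade support is assessed by the
multiscale bootstrap: sample columns are resampled with replacement at a
grid of scales, per-clade recovery frequencies BP_rho are recorded, and
the approximately unbiased (AU) p-value is obtained from the weighted
least-squares fit of -Phi^{-1}(BP_rho) to d*sqrt(rho) + c/sqrt(rho),
au = 1 - Phi(d - c).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm


@dataclass
class ClusterNode:
    """Internal node of the merge tree; leaves are label strings."""

    left: "ClusterNode | str"
    right: "ClusterNode | str"
    height: float
    leaves: frozenset[str]
    bp: float | None = None
    au: float | None = None


@dataclass
class ClusterTree:
    root: ClusterNode
    labels: list[str]
    nodes: list[ClusterNode] = field(default_factory=list)  # merge order

    def clades(self) -> list[frozenset[str]]:
        return [n.leaves for n in self.nodes]

    def heights(self) -> list[float]:
        return [n.height for n in self.nodes]

    def leaf_order(self) -> list[str]:
        order: list[str] = []

        def walk(node):
            if isinstance(node, str):
                order.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return order

    def cut(self, k: int) -> dict[str, int]:
        """Cut into k groups by undoing the k-1 highest merges."""
        if not 1 <= k <= len(self.labels):
            raise ValueError("k out of range")
        removed = {id(n) for n in
                   sorted(self.nodes, key=lambda n: -n.height)[: k - 1]}
        groups: dict[str, int] = {}
        next_gid = [0]

        def walk(node, gid):
            if isinstance(node, str):
                groups[node] = gid
                return
            if id(node) in removed:
                walk(node.left, gid)
                next_gid[0] += 1
                walk(node.right, next_gid[0])
            else:
                walk(node.left, gid)
                walk(node.right, gid)

        walk(self.root, 0)
        return groups

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node, parent_height) -> str:
            if isinstance(node, str):
                return f"{node}:{parent_height:.6g}"
            label = ""
            if with_support and node.bp is not None:
                au = node.au if node.au is not None else float("nan")
                label = f"'au={au:.3f}|bp={node.bp:.3f}'"
            blen = parent_height - node.height
            inner = f"({fmt(node.left, node.height)},{fmt(node.right, node.height)})"
            return f"{inner}{label}:{blen:.6g}"

        root = self.root
        inner = f"({fmt(root.left, root.height)},{fmt(root.right, root.height)})"
        label = ""
        if with_support and root.bp is not None:
            au = root.au if root.au is not None else float("nan")
            label = f"'au={au:.3f}|bp={root.bp:.3f}'"
        return f"{inner}{label};"


def pearson_matrix(
    values: pd.DataFrame, rows: list[str] | None = None
) -> pd.DataFrame:
    """Pearson correlation between expression rows; constant rows get
    r = 0 against everything (with a warning) and 1 on the diagonal."""
    if rows is not None:
        values = values.loc[list(rows)]
    mat = values.to_numpy(dtype=float)
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sd = mat.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s): correlation set to 0",
            stacklevel=2,
        )
    centered = mat - mat.mean(axis=1, keepdims=True)
    denom = np.sqrt((centered * centered).sum(axis=1))
    denom[denom == 0] = 1.0
    normed = centered / denom[:, None]
    corr = normed @ normed.T
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(corr, index=values.index, columns=values.index)


def average_linkage_tree(corr: pd.DataFrame) -> ClusterTree:
    """UPGMA on 1 - r distances with a deterministic tie-break.

    Ties in the minimum distance resolve to the pair whose sorted
    (lexicographically smallest member of each cluster) pair is smallest.
    """
    labels = [str(c) for c in corr.index]
    n = len(labels)
    dist = 1.0 - corr.to_numpy(dtype=float)
    clusters: dict[int, ClusterNode | str] = {i: labels[i] for i in range(n)}
    leafsets = {i: frozenset([labels[i]]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    mins = {i: labels[i] for i in range(n)}  # lexicographic representative
    d: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = dist[i, j]

    nodes: list[ClusterNode] = []
    next_id = n
    active = set(range(n))
    while len(active) > 1:
        best = None
        for (i, j), dij in d.items():
            key = (dij, tuple(sorted((mins[i], mins[j]))))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        height = d[(i, j)] / 1.0
        node = ClusterNode(clusters[i], clusters[j], height,
                           leafsets[i] | leafsets[j])
        nodes.append(node)
        nid = next_id
        next_id += 1
        # Lance-Williams average-linkage update
        for k in active:
            if k in (i, j):
                continue
            dik = d[tuple(sorted((i, k)))]
            djk = d[tuple(sorted((j, k)))]
            dnew = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            d[(min(k, nid), max(k, nid))] = dnew
        for key in [key for key in d if i in key or j in key]:
            del d[key]
        active.discard(i)
        active.discard(j)
        active.add(nid)
        clusters[nid] = node
        leafsets[nid] = node.leaves
        sizes[nid] = sizes[i] + sizes[j]
        mins[nid] = min(mins[i], mins[j])
    root = clusters[active.pop()]
    if isinstance(root, str):  # single leaf
        raise ValueError("cannot build a tree from a single row")
    return ClusterTree(root, labels, nodes)


def _build_tree_from_values(values: pd.DataFrame) -> ClusterTree:
    return average_linkage_tree(pearson_matrix(values))


DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 1))


def multiscale_bootstrap(
    values: pd.DataFrame,
    rows: list[str] | None = None,
    nboot: int = 1000,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    rng: np.random.Generator | int | None = None,
) -> ClusterTree:
    """Average-linkage tree with BP and AU support per internal node.

    For each scale rho, ``ceil(rho * n_samples)`` columns are resampled
    with replacement ``nboot`` times and per-clade recovery frequencies
    recorded; clade identity is the leaf set.  AU comes from the WLS fit
    of z(rho) = -Phi^{-1}(BP_rho) to d*sqrt(rho) + c/sqrt(rho) with
    weights nboot * phi(z)^2 / (BP (1 - BP)); scales with BP in {0, 1} are
    dropped, and clades recovered never/always get au = bp = 0/1 without a
    fit.
    """
    if nboot < 100:
        raise ValueError("nboot must be >= 100")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if rows is not None:
        values = values.loc[list(rows)]
    sd = values.to_numpy().std(axis=1)
    if (sd == 0).any():
        warnings.warn("dropping constant rows from clustering", stacklevel=2)
        values = values.loc[sd > 0]
    n_samples = values.shape[1]
    tree = _build_tree_from_values(values)
    clades = tree.clades()
    counts = {c: np.zeros(len(scales)) for c in clades}

    cols = values.to_numpy()
    index = values.index
    for si, rho in enumerate(scales):
        m = int(np.ceil(rho * n_samples))
        if m < 3:
            raise ValueError(f"scale {rho}: resample size {m} < 3")
        for _ in range(nboot):
            pick = rng.integers(0, n_samples, size=m)
            boot = pd.DataFrame(cols[:, pick], index=index)
            try:
                boot_tree = _build_tree_from_values(boot)
            except ValueError:
                continue
            found = set(boot_tree.clades())
            for c in clades:
                if c in found:
                    counts[c][si] += 1

    rho_arr = np.asarray(scales, dtype=float)
    one = int(np.argmin(np.abs(rho_arr - 1.0)))
    for node in tree.nodes:
        bp_all = counts[node.leaves] / nboot
        node.bp = float(bp_all[one])
        usable = (bp_all > 0) & (bp_all < 1)
        if not usable.any():
            node.au = 1.0 if bp_all.mean() >= 0.5 else 0.0
            node.bp = float(bp_all[one])
            continue
        if usable.sum() < 2:
            node.au = float(bp_all[one])
            continue
        bp = bp_all[usable]
        r = rho_arr[usable]
        z = -norm.ppf(bp)
        w = nboot * norm.pdf(z) ** 2 / (bp * (1 - bp))
        X = np.column_stack([np.sqrt(r), 1 / np.sqrt(r)])
        WX = X * w[:, None]
        try:
            coef = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            node.au = float(bp_all[one])
            continue
        d_hat, c_hat = coef
        node.au = float(np.clip(1 - norm.cdf(d_hat - c_hat), 0.0, 1.0))
    return tree


def correlation_heatmap_order(
    values: pd.DataFrame,
    rfx_rows: list[str],
    target_rows: list[str],
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Cross-correlation matrix (family rows x target rows) with leaf
    orders from average-linkage trees built on each axis."""
    corr_all = pearson_matrix(values, list(rfx_rows) + list(target_rows))
    cross = corr_all.loc[list(rfx_rows), list(target_rows)]
    row_order = average_linkage_tree(
        corr_all.loc[list(rfx_rows), list(rfx_rows)]
    ).leaf_order()
    col_order = average_linkage_tree(
        corr_all.loc[list(target_rows), list(target_rows)]
    ).leaf_order()
    return row_order, col_order, cross.loc[row_order, col_order]
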