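"""Distance-based trees on binary marker matrices and hybridization
diagnostics.

Dominant-marker phylogenetics works from band-sharing similarities:

* ``link``  — band-sharing (Dice) similarity s = 2a / (2a + b + c), the
  distance measure offered for dominant markers in TREECON-style software,
  here implemented as d = 1 - s;
* ``jaccard`` — s = a / (a + b + c), d = 1 - s;
* ``p_distance`` — simple mismatch proportion (b + c) / L;

with a = shared presences and b, c = one-sided presences for a pair of
individuals.  Trees come from neighbor-joining; clade robustness from
bootstrapping loci (columns), never individuals.  Three tree-based
hybridization diagnostics are built on the bootstrap sample: leaf
stability (quartet consistency per taxon), lineage movement (attachment
frequencies of a query group relative to a reference group), and the
homoplasy-excess taxon-removal test, in which removing a hybrid increases
bootstrap support of clades containing its parents.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BinaryMarkerMatrix

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "BootstrapSet",
    "BootstrapResult",
    "binary_distance",
    "nj_tree",
    "tree_bipartitions",
    "bootstrap_support",
    "leaf_stability",
    "lineage_movement",
    "homoplasy_excess_scan",
]


@dataclass
class DistanceMatrix:
    ids: list[str]
    data: np.ndarray
    method: str = "link"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("non-symmetric distance matrix")
        if np.diag(self.data).any():
            raise ValueError("non-zero diagonal")
        if (self.data < 0).any():
            raise ValueError("negative distances")


class TreeNode:
    """Minimal tree node: leaves carry ``name``, internal nodes may carry
    a bootstrap ``support``; ``length`` is the branch to the parent."""

    __slots__ = ("name", "children", "length", "support")

    def __init__(self, name=None, children=None, length=None, support=None):
        self.name = name
        self.children = children or []
        self.length = length
        self.support = support

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def __repr__(self) -> str:  # pragma: no cover
        from .io import write_newick

        return write_newick(self)


def binary_distance(m: BinaryMarkerMatrix, method: str = "link") -> DistanceMatrix:
    """Pairwise distance matrix from a presence/absence matrix.

    Raises if a pair shares no scored band at all (a + b + c = 0) under the
    similarity-based methods, where the coefficient is undefined.
    """
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = m.data.astype(float)
    a = X @ X.T  # shared presences
    s = X.sum(axis=1)
    b = s[:, None] - a
    c = s[None, :] - a
    union = a + b + c
    if method in ("link", "jaccard"):
        off = ~np.eye(len(X), dtype=bool)
        if (union[off] == 0).any():
            i, j = np.argwhere((union == 0) & off)[0]
            raise ValueError(
                f"pair ({m.sample_ids[i]!r}, {m.sample_ids[j]!r}) shares no present "
                f"band; {method} distance undefined"
            )
    if method == "jaccard":
        with np.errstate(invalid="ignore"):
            d = 1.0 - a / union
    elif method == "link":
        with np.errstate(invalid="ignore"):
            d = 1.0 - 2.0 * a / (2.0 * a + b + c)
    elif method == "p_distance":
        d = (b + c) / m.n_loci
    else:
        raise ValueError(f"unknown method {method!r}")
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry
    return DistanceMatrix(ids=list(m.sample_ids), data=d, method=method)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q-criterion resolve to the smallest (i, j) index pair.
    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling branch, preserving the pair's summed length.  The returned
    tree is unrooted, represented with a trifurcating root.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    d = dm.data.copy()
    nodes = [TreeNode(name=i) for i in dm.ids]
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        rowsum = sub.sum(axis=1)
        q = (r - 2) * sub - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(q, np.inf)
        flat = np.argmin(q)  # first minimum in row-major order: smallest (i, j)
        ai, aj = divmod(flat, r)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        vi = 0.5 * sub[ai, aj] + (rowsum[ai] - rowsum[aj]) / (2 * (r - 2))
        vj = sub[ai, aj] - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        nodes[i].length = max(vi, 0.0)
        nodes[j].length = max(vj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        d = np.vstack([d, new_row])
        new_col = np.append(new_row, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        k = len(nodes) - 1
        active = [x for x in active if x not in (i, j)] + [k]

    a, b, c = active
    va = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    vb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    vc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for node, v in ((nodes[a], va), (nodes[b], vb), (nodes[c], vc)):
        node.length = max(v, 0.0)
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


def tree_path_lengths(tree: TreeNode) -> pd.DataFrame:
    """Leaf-to-leaf path-length matrix (for additivity checks)."""
    leaves = tree.leaf_names()
    dist = {name: {} for name in leaves}

    def walk(node) -> dict[str, float]:
        if not node.children:
            return {node.name: 0.0}
        below: list[dict[str, float]] = [walk(c) for c in node.children]
        for c, dmap in zip(node.children, below):
            for k in dmap:
                dmap[k] += c.length or 0.0
        for d1, d2 in itertools.combinations(below, 2):
            for x, dx in d1.items():
                for y, dy in d2.items():
                    dist[x][y] = dist[y][x] = dx + dy
        merged = {}
        for dmap in below:
            merged.update(dmap)
        return merged

    walk(tree)
    out = pd.DataFrame(0.0, index=leaves, columns=leaves)
    for x in leaves:
        for y in leaves:
            if x != y:
                out.loc[x, y] = dist[x][y]
    return out


# ---------------------------------------------------------------------------
# bipartitions and bootstrap


def tree_bipartitions(tree: TreeNode, taxa: frozenset | None = None) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, each canonicalised as
    the side not containing the lexicographically smallest taxon."""
    if taxa is None:
        taxa = frozenset(tree.leaf_names())
    ref = min(taxa)
    out: set[frozenset] = set()

    def walk(node) -> frozenset:
        if not node.children:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if 2 <= len(below) <= len(taxa) - 2:
            side = taxa - below if ref in below else below
            out.add(side)
        return below

    walk(tree)
    return out


@dataclass
class BootstrapSet:
    taxa: list[str]
    trees: list[TreeNode]
    bipartitions: list[set] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.bipartitions is None:
            t = frozenset(self.taxa)
            self.bipartitions = [tree_bipartitions(tr, t) for tr in self.trees]


@dataclass
class BootstrapResult:
    tree: TreeNode  # original-matrix NJ tree, support-annotated
    supports: dict  # bipartition -> % of replicates
    bootstrap: BootstrapSet


def bootstrap_support(
    m: BinaryMarkerMatrix,
    n_reps: int,
    method: str = "link",
    seed: int | None = None,
) -> BootstrapResult:
    """Locus bootstrap of the NJ tree.

    Columns are resampled with replacement per replicate; support of a
    clade is the percentage of replicate trees containing its bipartition.
    The original tree's internal nodes are annotated in place.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    base = nj_tree(binary_distance(m, method))
    taxa = frozenset(m.sample_ids)

    trees = []
    for _ in range(n_reps):
        cols = rng.integers(m.n_loci, size=m.n_loci)
        mb = m.subset_loci(cols)
        try:
            trees.append(nj_tree(binary_distance(mb, method)))
        except ValueError as err:
            raise ValueError(f"bootstrap replicate failed: {err}") from err
    bs = BootstrapSet(taxa=list(m.sample_ids), trees=trees)

    counts: dict[frozenset, int] = {}
    for bip_set in bs.bipartitions:
        for b in bip_set:
            counts[b] = counts.get(b, 0) + 1
    supports = {b: 100.0 * c / n_reps for b, c in counts.items()}

    ref = min(taxa)

    def annotate(node) -> frozenset:
        if not node.children:
            return frozenset([node.name])
        below = frozenset().union(*(annotate(c) for c in node.children))
        if 2 <= len(below) <= len(taxa) - 2:
            side = taxa - below if ref in below else below
            node.support = round(supports.get(side, 0.0), 1)
        return below

    annotate(base)
    return BootstrapResult(tree=base, supports=supports, bootstrap=bs)


# ---------------------------------------------------------------------------
# leaf stability


def _quartet_resolutions(bip_arrays: np.ndarray, quartet: tuple[int, int, int, int]):
    """Resolution (0, 1, 2 for ab|cd, ac|bd, ad|bc) or -1 if unresolved,
    given the tree's bipartitions as a boolean matrix (n_bip x n_taxa)."""
    a, b, c, d = quartet
    sub = bip_arrays[:, [a, b, c, d]]
    inside = sub.sum(axis=1)
    for row in sub[inside == 2]:
        if row[0] and row[1]:
            return 0
        if row[0] and row[2]:
            return 1
        if row[0] and row[3]:
            return 2
        if row[2] and row[3]:
            return 0
        if row[1] and row[3]:
            return 1
        if row[1] and row[2]:
            return 2
    return -1


def leaf_stability(bs: BootstrapSet) -> dict[str, float]:
    """Quartet-based leaf-stability index per taxon.

    For every quartet containing the taxon, take the frequency of its most
    common resolution across the bootstrap trees; LS is the mean of those
    maxima.  LS = 1 iff every quartet involving the taxon is resolved the
    same way in all trees.
    """
    taxa = bs.taxa
    n = len(taxa)
    if n < 4:
        raise ValueError("leaf stability needs at least 4 taxa")
    if len(bs.trees) < 2:
        raise ValueError("need at least 2 trees")
    index = {t: i for i, t in enumerate(taxa)}

    bip_mats = []
    for bip_set in bs.bipartitions:
        mat = np.zeros((len(bip_set), n), dtype=bool)
        for r, side in enumerate(bip_set):
            for t in side:
                mat[r, index[t]] = True
        bip_mats.append(mat)

    quartets = list(itertools.combinations(range(n), 4))
    max_freq = np.zeros(len(quartets))
    n_trees = len(bs.trees)
    for qi, q in enumerate(quartets):
        counts = np.zeros(3)
        for mat in bip_mats:
            r = _quartet_resolutions(mat, q)
            if r >= 0:
                counts[r] += 1
        max_freq[qi] = counts.max() / n_trees

    ls = {}
    for ti, t in enumerate(taxa):
        member = [qi for qi, q in enumerate(quartets) if ti in q]
        ls[t] = float(max_freq[member].mean())
    return ls


# ---------------------------------------------------------------------------
# lineage movement


@dataclass
class LineageMovement:
    outside_pct: float
    inside_pct: float
    dispersed_pct: float
    #: sister-group composition -> % of replicates (query monophyletic only)
    attachments: dict


def lineage_movement(
    bs: BootstrapSet, query: set[str], reference: set[str]
) -> LineageMovement:
    """Attachment frequencies of a query group across bootstrap trees.

    In each tree where the query is monophyletic (appears as a bipartition
    side), the query "attaches inside" the reference when some bipartition
    side S satisfies query < S <= query | reference — i.e. its local
    neighbourhood lies within the reference group — and "outside"
    otherwise.  Trees where the query is not monophyletic count as
    "dispersed" and are reported separately.  The sister composition
    (smallest side properly containing the query, minus the query) is
    tabulated per tree as the per-alternative breakdown.
    """
    query = frozenset(query)
    reference = frozenset(reference)
    taxa = frozenset(bs.taxa)
    if not query or not query < taxa:
        raise ValueError("query must be a proper subset of the taxa")
    if query & reference:
        raise ValueError("query and reference must be disjoint")
    qr = query | reference

    n_out = n_in = n_disp = 0
    attach: dict[frozenset, int] = {}
    for bip_set in bs.bipartitions:
        sides = set()
        for side in bip_set:
            sides.add(side)
            sides.add(taxa - side)
        # leaf "sides" for completeness when query is a single taxon
        for t in taxa:
            sides.add(frozenset([t]))
        if query not in sides:
            n_disp += 1
            continue
        supersets = [s for s in sides if query < s]
        inside = any(s <= qr for s in supersets)
        if inside:
            n_in += 1
        else:
            n_out += 1
        if supersets:
            smallest = min(supersets, key=lambda s: (len(s), sorted(s)))
            sister = smallest - query
            attach[sister] = attach.get(sister, 0) + 1

    n_trees = len(bs.bipartitions)
    return LineageMovement(
        outside_pct=100.0 * n_out / n_trees,
        inside_pct=100.0 * n_in / n_trees,
        dispersed_pct=100.0 * n_disp / n_trees,
        attachments={k: 100.0 * v / n_trees for k, v in attach.items()},
    )


# ---------------------------------------------------------------------------
# homoplasy-excess removal experiments


def homoplasy_excess_scan(
    m: BinaryMarkerMatrix,
    removal_sets: dict[str, set[str]],
    n_reps: int = 1000,
    method: str = "link",
    seed: int | None = None,
    full_result: BootstrapResult | None = None,
    extra_clades: dict[str, set[str]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Taxon-removal bootstrap experiments.

    For each named removal set, recompute bootstrap supports on the reduced
    matrix and report the support change for every clade of the full-matrix
    tree plus any ``extra_clades`` of interest (e.g. species monophyly not
    realised in the full tree).  ``support_before`` counts the clade as a
    plain bipartition of the full bootstrap trees — so a hybrid nesting
    inside the clade destroys its monophyly — while ``support_after``
    counts the clade restricted to the retained taxa in the reduced-matrix
    bootstrap.  A hybrid's conflicting signal therefore shows up as a
    support increase upon its removal.  Clades that become trivial after
    removal are reported with NA deltas rather than dropped.
    """
    rng = np.random.default_rng(seed)
    if full_result is None:
        full_result = bootstrap_support(
            m, n_reps, method, seed=int(rng.integers(2**31))
        )
    all_taxa = frozenset(m.sample_ids)
    ref_full = min(all_taxa)

    def canon_full(side: frozenset) -> frozenset:
        return all_taxa - side if ref_full in side else side

    tracked: dict[str, frozenset] = {
        "|".join(sorted(b)): b for b in tree_bipartitions(full_result.tree)
    }
    for label, clade in (extra_clades or {}).items():
        tracked[label] = canon_full(frozenset(clade))

    full_counts: dict[frozenset, int] = {}
    for bip_set in full_result.bootstrap.bipartitions:
        for b in bip_set:
            full_counts[b] = full_counts.get(b, 0) + 1

    out: dict[str, pd.DataFrame] = {}
    for name, removed in removal_sets.items():
        removed = frozenset(removed)
        retained = all_taxa - removed
        if len(retained) < 4:
            raise ValueError(f"removal set {name!r} leaves fewer than 4 taxa")
        keep_ix = [i for i, s in enumerate(m.sample_ids) if s in retained]
        reduced = m.subset_samples(keep_ix)
        red_result = bootstrap_support(
            reduced, n_reps, method, seed=int(rng.integers(2**31))
        )

        ref = min(retained)

        def restrict(side: frozenset) -> frozenset | None:
            side = side & retained
            if not (2 <= len(side) <= len(retained) - 2):
                return None
            return retained - side if ref in side else side

        red_counts: dict[frozenset, int] = {}
        for bip_set in red_result.bootstrap.bipartitions:
            for b in bip_set:
                red_counts[b] = red_counts.get(b, 0) + 1

        rows = []
        n_full = len(full_result.bootstrap.trees)
        n_red = len(red_result.bootstrap.trees)
        for label, clade in sorted(tracked.items()):
            rclade = restrict(clade)
            if rclade is None:
                rows.append((label, np.nan, np.nan, np.nan))
                continue
            before = 100.0 * full_counts.get(clade, 0) / n_full
            after = 100.0 * red_counts.get(rclade, 0) / n_red
            rows.append((label, before, after, after - before))
        out[name] = pd.DataFrame(
            rows, columns=["clade", "support_before", "support_after", "delta"]
        )
    return out
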