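"""Haplotype collapsing and median-joining networks.

Aligned mtDNA sequences are collapsed into haplotypes (identical after
masking, with the alignment gap either treated as a fifth character state
or as missing data) and connected into a median-joining network: the
union of all minimum spanning trees over the haplotypes, augmented with
inferred intermediate sequences ("median vectors", unsampled or extinct
haplotypes) wherever a quasi-median of three connected haplotypes
shortens the network.  With the default epsilon = 0 this is the classic
parsimony-oriented construction for intraspecific data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import SequenceAlignment

__all__ = ["HaplotypeSet", "collapse_haplotypes", "median_joining_network"]


@dataclass
class HaplotypeSet:
    """Collapsed haplotypes, ordered by descending frequency."""

    sequences: list[str]  # post-mask representative per haplotype
    members: list[list[str]]  # sample ids per haplotype
    species: dict | None = None  # optional sample id -> species label
    frequencies: list[int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.frequencies is None:
            self.frequencies = [len(m) for m in self.members]

    @property
    def n_haplotypes(self) -> int:
        return len(self.sequences)

    @property
    def n_samples(self) -> int:
        return int(sum(self.frequencies))

    def modal_frequency_pct(self) -> float:
        """Share of individuals carrying the most common haplotype, in %."""
        return 100.0 * max(self.frequencies) / self.n_samples

    def per_species_table(self) -> pd.DataFrame:
        """Haplotype x species frequency table (requires species labels)."""
        if self.species is None:
            raise ValueError("no species labels attached")
        labels = sorted(set(self.species.values()))
        rows = []
        for h, mem in enumerate(self.members):
            counts = {sp: 0 for sp in labels}
            for sid in mem:
                counts[self.species[sid]] += 1
            rows.append({"haplotype": f"H{h + 1}", **counts})
        return pd.DataFrame(rows).set_index("haplotype")


def _identical(a: str, b: str, gap_mode: str) -> bool:
    if gap_mode == "fifth_state":
        # gap is an ordinary character; N is missing
        return all(x == y or "N" in (x, y) for x, y in zip(a, b))
    if gap_mode == "missing":
        return all(x == y or x in "-N" or y in "-N" for x, y in zip(a, b))
    raise ValueError(f"unknown gap_mode {gap_mode!r}")


def collapse_haplotypes(
    aln: SequenceAlignment,
    gap_mode: str = "fifth_state",
    species: dict | None = None,
) -> HaplotypeSet:
    """Group sequences that are identical at all unmasked sites.

    ``fifth_state`` (the conventional default for control-region data)
    compares the gap like any other character; ``missing`` ignores sites
    that are gapped or N in either sequence.  Because missing data makes
    identity non-transitive, groups are formed by transitive closure of
    pairwise identity.  Haplotypes are ordered by descending frequency,
    ties broken by first occurrence in the alignment.
    """
    if aln.n_sequences == 0:
        raise ValueError("empty alignment")
    keep = ~aln.mask
    seqs = ["".join(np.array(list(s))[keep]) for s in aln.sequences]

    n = len(seqs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if find(i) != find(j) and _identical(seqs[i], seqs[j], gap_mode):
                parent[find(j)] = find(i)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), g[0]))

    return HaplotypeSet(
        sequences=[seqs[g[0]] for g in ordered],
        members=[[aln.sample_ids[i] for i in g] for g in ordered],
        species=species,
    )


# ---------------------------------------------------------------------------
# median-joining network


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _msn_edges(nodes: list[str], epsilon: int = 0) -> list[tuple[int, int, int]]:
    """Epsilon-relaxed minimum spanning network over the node sequences.

    Returns (i, j, weight) for every edge whose weight is within
    ``epsilon`` of the smallest weight that connects the two clusters it
    joins; at epsilon = 0 the result is the union of all minimum spanning
    trees.  Tie-breaking is by (weight, i, j), making the construction
    deterministic for a fixed node order.
    """
    n = len(nodes)
    pairs = sorted(
        ((_hamming(nodes[i], nodes[j]), i, j) for i in range(n) for j in range(i + 1, n))
    )
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    edges: list[tuple[int, int, int]] = []
    k = 0
    while k < len(pairs):
        w = pairs[k][0]
        # all candidate edges whose weight lies within epsilon above w are
        # judged against the component structure *before* merging them
        level = []
        while k < len(pairs) and pairs[k][0] <= w + epsilon:
            level.append(pairs[k])
            k += 1
        feasible = [(wi, i, j) for wi, i, j in level if find(i) != find(j)]
        for wi, i, j in feasible:
            edges.append((i, j, wi))
        for _, i, j in feasible:
            parent[find(j)] = find(i)
        if len({find(i) for i in range(n)}) == 1:
            break
    return edges


def _quasi_medians(u: str, v: str, w: str, cap: int = 729) -> list[str]:
    """Quasi-medians of a triple: majority state per position; positions
    where all three differ expand to all three states (capped)."""
    options = []
    count = 1
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            options.append((a,))
        elif b == c:
            options.append((b,))
        else:
            options.append((a, b, c))
            count *= 3
            if count > cap:
                return []
    return ["".join(p) for p in itertools.product(*options)]


def median_joining_network(
    hs: HaplotypeSet, epsilon: int = 0, max_rounds: int = 20
) -> nx.Graph:
    """Median-joining network of a haplotype set.

    Iterates: build the epsilon-relaxed minimum spanning network; for
    every triple of nodes connected through a shared neighbour, add any
    quasi-median sequences not yet present; prune inferred ("median")
    nodes whose degree falls below 3; stop at a fixpoint.  The result is a
    :class:`networkx.Graph` whose nodes carry ``sequence``, ``observed``,
    ``members`` and ``frequency`` attributes and whose edges carry the
    mutational-step ``weight``.
    """
    if hs.n_haplotypes == 0:
        raise ValueError("empty haplotype set")
    observed = list(hs.sequences)
    nodes = list(observed)

    for _ in range(max_rounds):
        edges = _msn_edges(nodes, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
        for i, j, _w in edges:
            adj[i].add(j)
            adj[j].add(i)

        new: list[str] = []
        seen = set(nodes)
        for u in range(len(nodes)):
            for v, w in itertools.combinations(sorted(adj[u]), 2):
                for m in _quasi_medians(nodes[u], nodes[v], nodes[w]):
                    if m not in seen:
                        seen.add(m)
                        new.append(m)
        if not new:
            break
        nodes.extend(new)

    # prune inferred nodes of degree < 3, recomputing the MSN afterwards
    while True:
        edges = _msn_edges(nodes, epsilon)
        degree = {i: 0 for i in range(len(nodes))}
        for i, j, _w in edges:
            degree[i] += 1
            degree[j] += 1
        drop = [
            i
            for i in range(len(nodes))
            if nodes[i] not in observed and degree[i] < 3
        ]
        if not drop:
            break
        nodes = [s for i, s in enumerate(nodes) if i not in set(drop)]

    g = nx.Graph()
    obs_index = {s: h for h, s in enumerate(observed)}
    for i, s in enumerate(nodes):
        if s in obs_index:
            h = obs_index[s]
            g.add_node(
                i,
                sequence=s,
                observed=True,
                label=f"H{h + 1}",
                members=list(hs.members[h]),
                frequency=hs.frequencies[h],
            )
        else:
            g.add_node(
                i, sequence=s, observed=False, label=f"mv{i}", members=[], frequency=0
            )
    for i, j, w in _msn_edges(nodes, epsilon):
        g.add_edge(i, j, weight=w)
    return g


def network_edge_table(g: nx.Graph) -> pd.DataFrame:
    rows = [
        (g.nodes[i]["label"], g.nodes[j]["label"], d["weight"])
        for i, j, d in g.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["node_a", "node_b", "steps"])


def write_network_gml(g: nx.Graph, path) -> None:
    """GML export for network viewers (member lists joined to strings)."""
    h = g.copy()
    for n in h.nodes:
        h.nodes[n]["members"] = ",".join(h.nodes[n]["members"])
        h.nodes[n]["observed"] = int(h.nodes[n]["observed"])
    nx.write_gml(h, str(path))
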