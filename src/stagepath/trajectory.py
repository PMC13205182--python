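"""Compare inferred event orderings and validate them against progression trees.

Two linear orderings are compared by rank statistics (Kendall tau,
Spearman rho over event positions) and by their longest common
subsequence.  A linear ordering is validated against a tree-shaped
progression model by the concordance rate: the fraction of event pairs
whose order in the sequence agrees with the tree's ancestor-descendant
relations.  The tree builder shipped here is a deliberately simplified
Suppes-style oracle — candidate edges must satisfy temporal priority
(the parent is more frequent) and probability raising (the child is more
likely given the parent), and a maximum-weight arborescence is extracted
with pointwise-mutual-information edge weights.  It serves as an
independent cross-check of linear sequences, not as a reimplementation
of any published progression-inference package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np

from .ebm import EventOrdering
from .features import BinaryMutationMatrix

__all__ = [
    "ProgressionTree",
    "rank_correlations",
    "lcs",
    "suppes_tree",
    "concordance_rate",
]

ROOT = "__ROOT__"


@dataclass
class ProgressionTree:
    """Rooted arborescence over event names with a synthetic root."""

    graph: nx.DiGraph
    root: str = ROOT

    def __post_init__(self) -> None:
        if self.root not in self.graph:
            raise ValueError("root missing from graph")
        for node in self.graph.nodes:
            indeg = self.graph.in_degree(node)
            if node == self.root:
                if indeg != 0:
                    raise ValueError("root must have no parent")
            elif indeg != 1:
                raise ValueError(f"node {node!r} must have exactly one parent")
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("progression tree must be acyclic")

    @property
    def events(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if n != self.root)

    def parent_of(self, event: str) -> str:
        return next(iter(self.graph.predecessors(event)))

    def ancestor_pairs(self) -> set[tuple[str, str]]:
        """Ordered (ancestor, descendant) event pairs, synthetic root excluded."""
        pairs = set()
        for a in self.events:
            for b in nx.descendants(self.graph, a):
                if b != self.root:
                    pairs.add((a, b))
        return pairs

    def to_edge_frame(self):
        import pandas as pd

        rows = [
            (u, v, d.get("weight", float("nan")))
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["parent", "child", "weight"])

    def to_edge_tsv(self, path: str | Path) -> None:
        self.to_edge_frame().to_csv(path, sep="\t", index=False)

    def to_newick(self) -> str:
        def render(node: str) -> str:
            children = sorted(self.graph.successors(node))
            label = "ROOT" if node == self.root else node
            if not children:
                return label
            return "(" + ",".join(render(c) for c in children) + ")" + label

        return render(self.root) + ";"


def _positions(order: EventOrdering) -> dict[str, int]:
    return {e: i for i, e in enumerate(order.events)}


def rank_correlations(
    order_a: EventOrdering, order_b: EventOrdering
) -> tuple[float, float]:
    """Kendall tau and Spearman rho between two orderings' event positions.

    Orderings are tie-free permutations, so the closed forms are exact:
    tau from the discordant-pair count, rho from the squared position
    differences (both agree with the generic rank statistics).
    """
    if set(order_a.events) != set(order_b.events):
        raise ValueError("orderings must cover the same event set")
    pos_b = _positions(order_b)
    xb = [pos_b[e] for e in order_a.events]
    n = len(xb)
    discordant = sum(
        1 for i in range(n) for j in range(i + 1, n) if xb[i] > xb[j]
    )
    tau = 1.0 - 4.0 * discordant / (n * (n - 1))
    d2 = sum((i - b) ** 2 for i, b in enumerate(xb))
    rho = 1.0 - 6.0 * d2 / (n * (n * n - 1))
    return float(tau), float(rho)


def lcs(order_a, order_b) -> tuple[list[str], int]:
    """Longest common subsequence of two duplicate-free sequences.

    Returns one witness and its length; the witness is the
    lexicographically smallest (by positions in ``order_a``) among the
    maximum-length common subsequences.
    """
    a = list(order_a.events) if isinstance(order_a, EventOrdering) else list(order_a)
    b = list(order_b.events) if isinstance(order_b, EventOrdering) else list(order_b)
    for name, seq in (("first", a), ("second", b)):
        if len(set(seq)) != len(seq):
            raise ValueError(f"duplicate events in {name} sequence")
    na, nb = len(a), len(b)
    # dp[i][j] = LCS length of a[i:], b[j:] (plain lists: fast at small N)
    dp = [[0] * (nb + 1) for _ in range(na + 1)]
    for i in range(na - 1, -1, -1):
        row, nxt = dp[i], dp[i + 1]
        ai = a[i]
        for j in range(nb - 1, -1, -1):
            if ai == b[j]:
                row[j] = 1 + nxt[j + 1]
            else:
                down, right = nxt[j], row[j + 1]
                row[j] = down if down >= right else right
    # Greedy reconstruction preferring the earliest usable position in a.
    witness: list[str] = []
    i = j = 0
    while dp[i][j] > 0:
        if a[i] == b[j] and dp[i][j] == 1 + dp[i + 1][j + 1]:
            witness.append(a[i])
            i += 1
            j += 1
        elif dp[i + 1][j] >= dp[i][j + 1]:
            i += 1
        else:
            j += 1
    return witness, int(dp[0][0])


def suppes_tree(matrix: BinaryMutationMatrix) -> ProgressionTree:
    """Simplified Suppes-style progression tree from a binary event matrix.

    Candidate edge a -> b requires temporal priority P(a) > P(b) and
    probability raising P(b|a) > P(b|not a); candidate edges are weighted
    by pointwise mutual information log P(a,b)/(P(a)P(b)) and the
    maximum-weight arborescence from a synthetic root attached to every
    event is returned.  Constant (all-zero / all-one) event columns are
    dropped with a warning.  Deterministic: ties are broken by event name.
    """
    values = matrix.values.astype(float)
    names = matrix.event_names
    freq = values.mean(axis=0)
    usable = [i for i, f in enumerate(freq) if 0.0 < f < 1.0]
    dropped = [names[i] for i in range(len(names)) if i not in usable]
    if dropped:
        warnings.warn(f"dropping constant event columns: {dropped}")
    if len(usable) < 2:
        raise ValueError("need at least two non-constant events")

    g = nx.DiGraph()
    g.add_node(ROOT)
    order = {names[i]: k for k, i in enumerate(sorted(usable, key=lambda i: names[i]))}
    for i in usable:
        g.add_node(names[i])
        # root edges carry weight 0: any probability-raising edge (PMI > 0)
        # is preferred; the tiny name-keyed offset makes ties deterministic
        g.add_edge(ROOT, names[i], weight=-1e-9 * order[names[i]])
    n = values.shape[0]
    for i in usable:
        for j in usable:
            if i == j or freq[i] <= freq[j]:
                continue  # temporal priority fails
            both = float((values[:, i] * values[:, j]).mean())
            p_b_given_a = both / freq[i]
            not_a = 1.0 - freq[i]
            p_b_given_not_a = (freq[j] - both) / not_a if not_a > 0 else 0.0
            if p_b_given_a <= p_b_given_not_a or both == 0.0:
                continue  # probability raising fails
            pmi = math.log(both / (freq[i] * freq[j]))
            g.add_edge(
                names[i],
                names[j],
                weight=pmi - 1e-9 * order[names[i]],
            )
    arb = nx.algorithms.tree.branchings.maximum_spanning_arborescence(
        g, attr="weight", preserve_attrs=True
    )
    return ProgressionTree(arb)


def concordance_rate(
    sequence: EventOrdering, tree: ProgressionTree, mode: str = "all-pairs"
) -> float:
    """Fraction of event pairs whose sequence order matches the tree.

    An ordered ancestor->descendant pair (a, b) of the tree matches when a
    precedes b in the sequence.  ``all-pairs`` divides by C(N, 2), counting
    tree-incomparable pairs as non-matching; ``comparable-only`` divides by
    the number of ancestor-related pairs.
    """
    if mode not in ("all-pairs", "comparable-only"):
        raise ValueError(f"unknown mode {mode!r}")
    events = set(sequence.events)
    if set(tree.events) != events:
        raise ValueError("event sets of sequence and tree differ")
    pos = _positions(sequence)
    pairs = tree.ancestor_pairs()
    matches = sum(1 for a, b in pairs if pos[a] < pos[b])
    if mode == "all-pairs":
        total = len(list(combinations(events, 2)))
        return matches / total
    if not pairs:
        warnings.warn("tree has no comparable pairs; concordance undefined")
        return float("nan")
    return matches / len(pairs)
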