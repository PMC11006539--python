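"""Shared fixtures and random-structure helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from phylopop.tree import GeneTree, Node


def random_unrooted_tree(rng: np.random.Generator, labels, length_low=0.01, length_high=0.3) -> GeneTree:
    """Random unrooted topology (trifurcating root) with U(low, high) lengths."""
    active = [Node(lbl, float(rng.uniform(length_low, length_high))) for lbl in labels]
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        parent = Node(length=float(rng.uniform(length_low, length_high)))
        parent.add_child(active[i])
        parent.add_child(active[j])
        active = [n for k, n in enumerate(active) if k not in (i, j)] + [parent]
    root = Node()
    for n in active:
        root.add_child(n)
    return GeneTree(root)


def tip_path_distances(tree: GeneTree):
    """True additive tip-to-tip distances (labels, matrix) from a tree."""
    tips = tree.tips()
    paths = {}
    for tip in tips:
        path = {}
        node, acc = tip, 0.0
        while node.parent is not None:
            acc += node.length
            node = node.parent
            path[id(node)] = acc
        paths[id(tip)] = (path, tip)
    labels = [t.label for t in tips]
    n = len(tips)
    d = np.zeros((n, n))
    for i in range(n):
        pi, _ = paths[id(tips[i])]
        for j in range(i + 1, n):
            pj, _ = paths[id(tips[j])]
            best = min(pi[k] + pj[k] for k in pi.keys() & pj.keys())
            d[i, j] = d[j, i] = best
    return labels, d


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
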