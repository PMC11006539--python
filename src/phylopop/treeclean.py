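"""Homolog gene-tree hygiene: long-branch tip removal and deep-branch splitting.

A terminal branch is treated as suspect (misassembly, contamination, hidden
paralogy) when it is both long in relative terms — at least ``relative_cutoff``
subs/site AND at least ``sister_factor`` times its sister branch — or long in
absolute terms (>= ``absolute_cutoff`` subs/site).  Deep internal branches
(> ``deep_cutoff`` subs/site) with at least ``min_side_taxa`` distinct taxa on
both sides indicate distinct gene families glued into one cluster; such trees
are split on the branch and the parts treated as separate homologs.

All removal decisions within one sweep are made against the input tree
(no cascading); cascading happens only across rounds, of which the default
is two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .tree import GeneTree, Node, taxon_of

__all__ = ["CleanParams", "CleanReport", "trim_long_tips", "split_deep_branches", "clean_round", "clean_trees"]


@dataclass
class CleanParams:
    relative_cutoff: float = 0.02
    sister_factor: float = 10.0
    absolute_cutoff: float = 0.03
    deep_cutoff: float = 0.2
    min_side_taxa: int = 4
    rounds: int = 2

    def __post_init__(self):
        if min(self.relative_cutoff, self.sister_factor, self.absolute_cutoff, self.deep_cutoff) <= 0:
            raise ValueError("cutoffs must be positive")
        if self.relative_cutoff > self.absolute_cutoff:
            raise ValueError("relative_cutoff must not exceed absolute_cutoff")
        if self.min_side_taxa < 1 or self.rounds < 1:
            raise ValueError("min_side_taxa and rounds must be >= 1")


@dataclass
class CleanReport:
    """Per-round accounting of tip removals and tree splits.

    ``per_sample`` maps sample id -> (tips_before, tips_removed, removal_rate)
    where removal_rate = removed / before.
    """

    round_index: int
    per_sample: dict = field(default_factory=dict)
    trees_split: int = 0
    trees_discarded: int = 0

    def to_rows(self):
        for sample in sorted(self.per_sample):
            before, removed, rate = self.per_sample[sample]
            yield sample, before, removed, rate, self.round_index


def _sister_length(tip: Node) -> float:
    """Sister branch length of a tip.

    The minimum terminal branch among the other tips attached to the same
    internal node; when every sibling subtree is internal, the minimum
    sibling edge length itself.
    """
    siblings = [c for c in tip.parent.children if c is not tip]
    tip_sibs = [c.length for c in siblings if c.is_tip]
    if tip_sibs:
        return min(tip_sibs)
    return min(c.length for c in siblings)


def trim_long_tips(t: GeneTree, p: CleanParams):
    """Remove long terminal branches; returns (tree-or-None, removed tip labels).

    A tip goes iff (length >= relative_cutoff and length >= sister_factor x
    sister) or length >= absolute_cutoff, all judged on the input tree in a
    single sweep.  Returns None for the tree when removal would leave fewer
    than 2 tips (the tree is discarded).
    """
    if t.n_tips < 3:
        raise ValueError("trim_long_tips requires a tree with >= 3 tips")
    doomed = []
    for tip in t.tips():
        ln = tip.length
        sister = _sister_length(tip)
        relative_hit = ln >= p.relative_cutoff and ln >= p.sister_factor * sister
        absolute_hit = ln >= p.absolute_cutoff
        if relative_hit or absolute_hit:
            doomed.append(tip)
    removed = [tip.label for tip in doomed]
    if t.n_tips - len(doomed) < 2:
        return None, removed
    out = t
    out.remove_tip_nodes(doomed)
    return out, removed


def _subtree_taxa(node: Node) -> set[str]:
    return {taxon_of(n.label) for n in node.preorder() if n.is_tip}


def split_deep_branches(t: GeneTree, p: CleanParams) -> list[GeneTree]:
    """Cut internal branches > deep_cutoff with >= min_side_taxa taxa per side.

    Edges are processed longest-first and candidates re-evaluated on the
    resulting components; branch lengths are retained (degree-2 merges sum).
    """
    all_taxa_tips = [(n, taxon_of(n.label)) for n in t.root.preorder() if n.is_tip]
    candidates = []
    for node in t.internal_nodes():
        if node.length > p.deep_cutoff:
            inside = _subtree_taxa(node)
            inside_tips = {id(x) for x in node.preorder() if x.is_tip}
            outside = {tax for n, tax in all_taxa_tips if id(n) not in inside_tips}
            if len(inside) >= p.min_side_taxa and len(outside) >= p.min_side_taxa:
                labels = sorted(x.label for x in node.preorder() if x.is_tip)
                candidates.append((-node.length, labels, node))
    if not candidates:
        return [t]
    candidates.sort(key=lambda c: (c[0], c[1]))
    node = candidates[0][2]
    parent = node.parent
    parent.detach_child(node)
    node.length = 0.0
    part_a = GeneTree(node)
    part_a.suppress_degree_two()
    part_b = t
    part_b.suppress_degree_two()
    return split_deep_branches(part_a, p) + split_deep_branches(part_b, p)


def clean_round(trees, p: CleanParams, round_index: int = 1):
    """One trim + split sweep over a batch of trees; returns (trees, report)."""
    report = CleanReport(round_index=round_index)
    before: dict[str, int] = {}
    removed_by: dict[str, int] = {}
    for t in trees:
        for lbl in t.tip_labels():
            tax = taxon_of(lbl)
            before[tax] = before.get(tax, 0) + 1
    survivors = []
    for t in trees:
        if t.n_tips < 3:  # too small to judge sisters; pass through
            survivors.append(t)
            continue
        trimmed, removed = trim_long_tips(t, p)
        for lbl in removed:
            tax = taxon_of(lbl)
            removed_by[tax] = removed_by.get(tax, 0) + 1
        if trimmed is None:
            report.trees_discarded += 1
            continue
        parts = split_deep_branches(trimmed, p)
        if len(parts) > 1:
            report.trees_split += 1
        survivors.extend(parts)
    for tax, n_before in before.items():
        n_removed = removed_by.get(tax, 0)
        rate = n_removed / n_before if n_before else 0.0
        report.per_sample[tax] = (n_before, n_removed, rate)
    return survivors, report


def clean_trees(trees, p: CleanParams):
    """Run ``p.rounds`` clean rounds; returns (trees, [report per round])."""
    reports = []
    current = list(trees)
    for r in range(1, p.rounds + 1):
        current, rep = clean_round(current, p, round_index=r)
        reports.append(rep)
    return current, reports
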