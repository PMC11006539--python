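"""Maximum-inclusion orthology: greedy extraction of duplicate-free subtrees.

From a cleaned homolog tree, the method repeatedly (1) trims long terminal
branches with the same relative/absolute cutoffs used for tree cleaning,
(2) scores every subtree obtainable by cutting one edge in either direction
(plus the whole tree) and keeps those in which no taxon appears twice, and
(3) emits the duplicate-free subtree covering the most distinct taxa,
deleting its tips from the working tree, until no subtree with at least
``min_taxa`` taxa remains.  Ties are broken by smaller total branch length,
then by the lexicographically smallest sorted tip-label list, so the output
is deterministic and oracle-testable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alnstats import Alignment, clean_columns
from .tree import GeneTree, Node, taxon_of
from .treeclean import CleanParams, trim_long_tips

__all__ = ["MIParams", "max_inclusion", "extract_ortholog_alignment"]


@dataclass
class MIParams:
    relative_cutoff: float = 0.02
    absolute_cutoff: float = 0.03
    min_taxa: int = 10
    sister_factor: float = 10.0
    #: re-run the long-branch trim before every extraction (True) or only
    #: once per input tree (False)
    retrim_each_iteration: bool = True

    def __post_init__(self):
        if self.min_taxa < 2:
            raise ValueError("min_taxa must be >= 2")

    def clean_params(self) -> CleanParams:
        return CleanParams(
            relative_cutoff=self.relative_cutoff,
            sister_factor=self.sister_factor,
            absolute_cutoff=self.absolute_cutoff,
        )


def _tips_under(node: Node) -> list[Node]:
    return [n for n in node.preorder() if n.is_tip]


def _edge_sum(node: Node) -> float:
    """Sum of branch lengths strictly inside the subtree rooted at ``node``."""
    return sum(n.length for n in node.preorder()) - node.length


def _candidates(t: GeneTree):
    """Duplicate-free candidate subtrees: (n_taxa, length, labels, kind, node).

    Candidates are each side of each edge plus the whole tree; a candidate
    qualifies when no taxon occurs twice among its tips.
    """
    all_tips = t.tips()
    total_len = t.total_length()
    out = []

    def consider(tips, length, kind, node):
        taxa = [taxon_of(x.label) for x in tips]
        if len(set(taxa)) != len(taxa):
            return
        labels = sorted(x.label for x in tips)
        out.append((len(taxa), round(length, 12), labels, kind, node))

    consider(all_tips, total_len, "full", None)
    for node in t.root.preorder():
        if node.parent is None:
            continue
        inside = _tips_under(node)
        inside_ids = {id(x) for x in inside}
        outside = [x for x in all_tips if id(x) not in inside_ids]
        sub_len = _edge_sum(node)
        if len(inside) >= 1:
            consider(inside, sub_len, "subtree", node)
        if len(outside) >= 1:
            consider(outside, total_len - sub_len - node.length, "complement", node)
    return out


def _extract(t: GeneTree, kind: str, node: Node | None) -> GeneTree:
    if kind == "full":
        return t.copy()
    if kind == "subtree":
        clone = node.copy()
        clone.length = 0.0
        clone.parent = None
        sub = GeneTree(clone)
        sub.suppress_degree_two()
        return sub
    # complement: copy the tree and delete the subtree's tips
    doomed_labels_ids = {id(x) for x in _tips_under(node)}
    # map by traversal order: copy preserves order, so pair original/copy tips
    clone = t.copy()
    orig_tips = t.tips()
    clone_tips = clone.tips()
    doomed = [ct for ot, ct in zip(orig_tips, clone_tips) if id(ot) in doomed_labels_ids]
    clone.remove_tip_nodes(doomed)
    return clone


def max_inclusion(t: GeneTree, p: MIParams) -> list[GeneTree]:
    """Extract orthologs from a homolog tree by maximum inclusion."""
    work = t.copy()
    orthologs: list[GeneTree] = []
    cp = p.clean_params()
    trimmed_once = False
    while work is not None and work.n_tips >= 2:
        if (p.retrim_each_iteration or not trimmed_once) and work.n_tips >= 3:
            work, _ = trim_long_tips(work, cp)
            trimmed_once = True
            if work is None:
                break
        if len(work.taxa()) < p.min_taxa:
            break
        cands = _candidates(work)
        if not cands:
            break
        cands.sort(key=lambda c: (-c[0], c[1], c[2]))
        n_taxa, _, labels, kind, node = cands[0]
        if n_taxa < p.min_taxa:
            break
        orthologs.append(_extract(work, kind, node))
        if kind == "full":
            break
        inside = _tips_under(node)
        inside_ids = {id(x) for x in inside}
        if kind == "subtree":
            emitted_nodes = inside
        else:
            emitted_nodes = [x for x in work.tips() if id(x) not in inside_ids]
        if work.n_tips - len(emitted_nodes) < 2:
            break
        work.remove_tip_nodes(emitted_nodes)
    return orthologs


def extract_ortholog_alignment(homolog_aln: Alignment, ortholog: GeneTree, occupancy: float = 0.10) -> Alignment:
    """Subset the homolog alignment to the ortholog tips and re-clean columns.

    Rows are renamed to the bare taxon (copy suffix dropped); a tip missing
    from the alignment raises KeyError naming it.
    """
    rows = {}
    for label in ortholog.tip_labels():
        if label not in homolog_aln.rows:
            raise KeyError(f"ortholog tip {label!r} missing from the homolog alignment")
        rows[taxon_of(label)] = homolog_aln.rows[label]
    return clean_columns(Alignment(rows), min_occupancy=occupancy)
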