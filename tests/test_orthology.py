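"""Maximum-inclusion orthology against a brute-force dendropy oracle."""

import dendropy
import pytest

from phylopop.alnstats import Alignment
from phylopop.orthology import MIParams, extract_ortholog_alignment, max_inclusion
from phylopop.tree import parse_newick

from conftest import random_unrooted_tree

#: cutoffs far above any branch length used here: trimming never fires, so
#: the oracle only has to mirror the greedy subtree-selection loop
NO_TRIM = dict(relative_cutoff=900.0, absolute_cutoff=1000.0)


def oracle_max_inclusion(newick: str, min_taxa: int):
    """Independent greedy maximum-inclusion over dendropy trees.

    Enumerates the whole tree plus both sides of every edge, keeps the
    duplicate-free candidates, and applies the same deterministic tie rules
    (most distinct taxa; smaller total branch length; smallest sorted
    label list).  Returns the list of emitted tip-label sets.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    emitted = []
    while True:
        # normalise a dangling single-child root left by pruning
        while len(tree.seed_node.child_nodes()) == 1:
            child = tree.seed_node.child_nodes()[0]
            if not child.child_nodes():
                break
            tree.seed_node = child
            child.parent_node = None
            child.edge.length = None
        leaves = list(tree.leaf_node_iter())
        if len(leaves) < 2:
            break
        total = sum(nd.edge.length or 0.0 for nd in tree if nd is not tree.seed_node)
        candidates = []

        def consider(leaf_set, length):
            taxa = [lf.taxon.label.split("@")[0] for lf in leaf_set]
            if len(set(taxa)) != len(taxa):
                return
            labels = sorted(lf.taxon.label for lf in leaf_set)
            candidates.append((len(taxa), round(length, 12), labels))

        consider(leaves, total)
        for nd in tree.preorder_node_iter():
            if nd is tree.seed_node:
                continue
            inside = list(nd.leaf_iter())
            inside_len = sum(x.edge.length or 0.0 for x in nd.preorder_iter()) - (nd.edge.length or 0.0)
            outside = [lf for lf in leaves if lf not in inside]
            if inside:
                consider(inside, inside_len)
            if outside:
                consider(outside, total - inside_len - (nd.edge.length or 0.0))
        if not candidates:
            break
        candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
        n_taxa, _, labels = candidates[0]
        if n_taxa < min_taxa:
            break
        emitted.append(labels)
        if len(labels) == len(leaves):
            break
        keep = [lf.taxon for lf in leaves if lf.taxon.label not in set(labels)]
        if len(keep) < 2:
            break
        tree.retain_taxa(keep)
    return emitted


def random_paralog_tree(rng, n_tips, n_dups):
    """Random tree whose labels contain ``n_dups`` duplicated taxa."""
    base = [f"t{i}" for i in range(n_tips - n_dups)]
    labels = [f"{t}@1" for t in base]
    for d in range(n_dups):
        labels.append(f"{base[d % len(base)]}@{2 + d // len(base)}")
    return random_unrooted_tree(rng, labels)


class TestMaxInclusion:
    def test_duplicate_free_tree_emitted_whole(self, rng):
        labels = [chr(ord("a") + i) for i in range(12)]
        t = random_unrooted_tree(rng, labels)
        orths = max_inclusion(t, MIParams(min_taxa=10, **NO_TRIM))
        assert len(orths) == 1
        assert sorted(orths[0].tip_labels()) == sorted(labels)

    def test_largest_duplicate_free_side_wins(self):
        # the complement of A@2's subtree covers four distinct taxa and
        # beats both three-taxon clades
        t = parse_newick("((A@1:0.1,B@1:0.1):0.1,(A@2:0.1,(C:0.1,D:0.1):0.1):0.1);")
        orths = max_inclusion(t, MIParams(min_taxa=3, **NO_TRIM))
        assert sorted(orths[0].tip_labels()) == ["A@1", "B@1", "C", "D"]

    def test_min_taxa_threshold_blocks_small_trees(self, rng):
        t = random_unrooted_tree(rng, [f"x{i}" for i in range(6)])
        assert max_inclusion(t, MIParams(min_taxa=10, **NO_TRIM)) == []

    def test_emitted_orthologs_are_tip_disjoint(self, rng):
        for _ in range(20):
            t = random_paralog_tree(rng, 12, int(rng.integers(0, 5)))
            orths = max_inclusion(t, MIParams(min_taxa=3, **NO_TRIM))
            seen = set()
            for o in orths:
                tips = set(o.tip_labels())
                assert not tips & seen
                seen |= tips
                taxa = [lbl.split("@")[0] for lbl in tips]
                assert len(set(taxa)) == len(taxa)

    def test_agrees_with_brute_force_oracle(self, rng):
        """Greedy MI equals independent brute-force enumeration on 200 trees."""
        mismatches = 0
        for rep in range(200):
            n = int(rng.integers(6, 13))
            t = random_paralog_tree(rng, n, int(rng.integers(0, 5)))
            newick = t.write()
            min_taxa = int(rng.integers(3, 6))
            ours = [sorted(o.tip_labels()) for o in max_inclusion(t, MIParams(min_taxa=min_taxa, **NO_TRIM))]
            theirs = oracle_max_inclusion(newick, min_taxa)
            if ours != theirs:
                mismatches += 1
        assert mismatches == 0

    def test_long_tips_trimmed_before_extraction(self):
        t = parse_newick(
            "((X:0.5,a@1:0.01):0.01,(b@1:0.01,c@1:0.01):0.01,(d@1:0.01,e@1:0.01):0.01);"
        )
        orths = max_inclusion(t, MIParams(min_taxa=4))
        assert len(orths) == 1
        assert "X" not in orths[0].tip_labels()


class TestExtractOrthologAlignment:
    def _aln(self):
        return Alignment(
            {
                "s1@1": "ACGTACGT--",
                "s2@1": "ACGTACGTAC",
                "s3@1": "ACGTAC--AC",
                "s4@1": "----ACGTAC",
            }
        )

    def test_rows_subset_and_renamed_to_taxa(self):
        orth = parse_newick("(s1@1:0.1,s2@1:0.1,s3@1:0.1);")
        out = extract_ortholog_alignment(self._aln(), orth)
        assert sorted(out.rows) == ["s1", "s2", "s3"]

    def test_missing_row_raises_with_tip_name(self):
        orth = parse_newick("(s1@1:0.1,s9@1:0.1,s3@1:0.1);")
        with pytest.raises(KeyError, match="s9@1"):
            extract_ortholog_alignment(self._aln(), orth)

    def test_occupancy_boundary_is_inclusive(self):
        rows = {f"s{i}@1": ("A" if i == 0 else "-") + "C" for i in range(10)}
        aln = Alignment(rows)
        orth = parse_newick("(" + ",".join(f"s{i}@1:0.1" for i in range(10)) + ");")
        out = extract_ortholog_alignment(aln, orth, occupancy=0.10)
        # column 1 is non-gap in exactly 1 of 10 rows: kept at >= 10%
        assert out.length == 2

    def test_all_gap_columns_removed_after_subsetting(self):
        aln = Alignment({"s1@1": "A-G", "s2@1": "A-G", "s3@1": "ACG", "s4@1": "ACG"})
        orth = parse_newick("(s1@1:0.1,s2@1:0.1);")
        out = extract_ortholog_alignment(aln, orth, occupancy=0.10)
        assert out.length == 2
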