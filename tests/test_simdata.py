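"""Simulator determinism, planted-truth separability and distributional checks."""

import numpy as np
import pytest

from phylopop.genofilter import FilterThresholds, apply_site_filters
from phylopop.simdata import (
    FamilySimConfig,
    GenoSimConfig,
    island_layout,
    pure_layers,
    simulate_dataset,
    simulate_family,
    simulate_genotypes,
    simulate_species_tree,
)
from phylopop.tree import taxon_of


class TestSpeciesTree:
    def test_tip_count_and_labels(self):
        cfg = FamilySimConfig(seed=1)
        t = simulate_species_tree(cfg)
        assert t.n_tips == 21
        assert sum(lbl.startswith("Outgroup") for lbl in t.tip_labels()) == 2

    def test_seeded_determinism(self):
        cfg = FamilySimConfig(seed=5)
        assert simulate_species_tree(cfg).write() == simulate_species_tree(cfg).write()

    def test_ingroup_branches_shorter_than_outgroup_stem(self):
        t = simulate_species_tree(FamilySimConfig(seed=2))
        stem = next(
            n for n in t.root.children if not any(x.label and x.label.startswith("Sample") for x in n.preorder())
        )
        assert stem.length == pytest.approx(0.05)
        ingroup = next(c for c in t.root.children if c is not stem)
        assert all(n.length < 0.05 for n in ingroup.preorder() if n is not ingroup)


class TestFamilySimulation:
    def test_no_artifacts_when_probabilities_zero(self):
        cfg = FamilySimConfig(seed=3, dup_prob=0, contaminant_prob=0, mask_prob=0)
        rng = np.random.default_rng(3)
        species = simulate_species_tree(cfg, rng)
        fam = simulate_family(species, cfg, rng)
        assert fam.truth.empty
        assert sorted(taxon_of(l) for l in fam.tree.tip_labels()) == sorted(
            taxon_of(l) for l in species.tip_labels()
        )

    def test_planted_contaminant_exceeds_absolute_cutoff(self):
        cfg = FamilySimConfig(seed=4, contaminant_prob=1.0, dup_prob=0)
        rng = np.random.default_rng(4)
        species = simulate_species_tree(cfg, rng)
        fam = simulate_family(species, cfg, rng)
        (tip_label,) = fam.truth.contaminant_tips
        tip = next(t for t in fam.tree.tips() if t.label == tip_label)
        assert tip.length >= 0.05

    def test_truth_config_guards(self):
        with pytest.raises(ValueError):
            FamilySimConfig(contaminant_length_min=0.02)
        with pytest.raises(ValueError):
            FamilySimConfig(legit_tip_max=0.05)

    def test_jc_mismatch_fraction_matches_closed_form(self):
        """Observed tip-pair divergence tracks p = (3/4)(1 - e^(-4d/3))."""
        cfg = FamilySimConfig(seed=6, dup_prob=0, contaminant_prob=0, mask_prob=0, seq_length=10000)
        rng = np.random.default_rng(6)
        species = simulate_species_tree(cfg, rng)
        fam = simulate_family(species, cfg, rng)
        labels, d = _tip_distances(fam.tree)
        rows = fam.alignment.rows
        checked = 0
        for i in range(0, len(labels), 5):
            for j in range(i + 1, len(labels), 7):
                expected_p = 0.75 * (1 - np.exp(-4 * d[i][j] / 3))
                a, b = rows[labels[i]], rows[labels[j]]
                obs = sum(x != y for x, y in zip(a, b)) / len(a)
                se = np.sqrt(expected_p * (1 - expected_p) / len(a))
                assert abs(obs - expected_p) <= 4 * se + 1e-9
                checked += 1
        assert checked >= 5

    def test_dataset_record_ids_globally_unique(self):
        cfg = FamilySimConfig(seed=8, n_families=6)
        _species, families = simulate_dataset(cfg)
        all_ids = [lbl for fam in families for lbl in fam.alignment.rows]
        assert len(all_ids) == len(set(all_ids))

    def test_dataset_determinism(self):
        cfg = FamilySimConfig(seed=11, n_families=4)
        _s1, f1 = simulate_dataset(cfg)
        _s2, f2 = simulate_dataset(cfg)
        assert [f.tree.write() for f in f1] == [f.tree.write() for f in f2]
        assert [f.alignment.rows for f in f1] == [f.alignment.rows for f in f2]


def _tip_distances(tree):
    tips = tree.tips()
    labels = [t.label for t in tips]
    n = len(tips)
    d = [[0.0] * n for _ in range(n)]
    paths = []
    for tip in tips:
        acc, node, path = 0.0, tip, {}
        while node.parent is not None:
            acc += node.length
            node = node.parent
            path[id(node)] = acc
        paths.append(path)
    for i in range(n):
        for j in range(i + 1, n):
            shared = paths[i].keys() & paths[j].keys()
            d[i][j] = d[j][i] = min(paths[i][k] + paths[j][k] for k in shared)
    return labels, d


class TestGenotypeSimulation:
    def test_admixture_rows_must_sum_to_one(self):
        q = island_layout(19)
        q[0, 0] = 0.5
        with pytest.raises(ValueError):
            GenoSimConfig(layer_assignment=q)

    def test_seeded_determinism(self):
        cfg = GenoSimConfig(seed=13, n_loci=20, snps_per_locus=2)
        s1, t1, _ = simulate_genotypes(cfg)
        s2, t2, _ = simulate_genotypes(cfg)
        assert [(a.site_id, a.genotypes, a.allele_depths) for a in s1] == [
            (b.site_id, b.genotypes, b.allele_depths) for b in s2
        ]
        assert [x.artifact for x in t1.site_truth] == [x.artifact for x in t2.site_truth]

    def test_low_fst_collapses_layer_frequencies(self):
        cfg = GenoSimConfig(
            seed=17, n_loci=400, snps_per_locus=1, fst=0.001, layer_assignment=pure_layers(19, 3),
            p_multiallelic=0, p_lowqual=0, p_lowdepth=0, p_het_ab_skew=0,
            p_hom_ab_noise=0, p_low_maf=0, p_missing=0,
        )
        _sites, truth, _names = simulate_genotypes(cfg)
        spread = np.abs(truth.layer_freqs - truth.layer_freqs.mean(axis=1, keepdims=True)).mean()
        assert spread < 0.02

    def test_zero_artifact_rates_give_fully_clean_vcf(self):
        cfg = GenoSimConfig(
            seed=19, n_loci=50, snps_per_locus=2,
            p_multiallelic=0, p_lowqual=0, p_lowdepth=0, p_het_ab_skew=0,
            p_hom_ab_noise=0, p_low_maf=0, p_missing=0,
        )
        sites, truth, _ = simulate_genotypes(cfg)
        kept, report = apply_site_filters(sites, FilterThresholds())
        assert report.sites_out == report.sites_in == 100
        assert truth.planted_counts() == {c: 0 for c in range(1, 7)}

    def test_planted_rates_within_three_binomial_se(self):
        rates = dict(
            p_multiallelic=0.03, p_lowqual=0.03, p_lowdepth=0.03,
            p_het_ab_skew=0.03, p_hom_ab_noise=0.03, p_low_maf=0.03, p_missing=0.03,
        )
        cfg = GenoSimConfig(seed=23, n_loci=300, snps_per_locus=4, **rates)
        _sites, truth, _ = simulate_genotypes(cfg)
        n = 1200
        tally = {}
        for t in truth.site_truth:
            tally[t.artifact] = tally.get(t.artifact, 0) + 1
        se = np.sqrt(0.03 * 0.97 / n)
        for artifact in ("multiallelic", "lowqual", "lowdepth", "het_ab", "hom_ab", "low_maf", "missing"):
            assert abs(tally.get(artifact, 0) / n - 0.03) <= 3 * se

    def test_planted_low_presence_loci_have_14_samples(self):
        cfg = GenoSimConfig(seed=29, n_loci=60, snps_per_locus=2, p_low_presence=0.3)
        sites, truth, _ = simulate_genotypes(cfg)
        assert truth.low_presence_loci
        for locus in truth.low_presence_loci:
            locus_sites = [s for s in sites if s.locus_id == locus]
            present = set()
            for s in locus_sites:
                present |= {i for i, gt in enumerate(s.genotypes) if gt is not None}
            assert len(present) == 14
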