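"""Criterion-by-criterion filter boundaries, order invariance and VCF round-trips."""

import itertools

import pytest

from phylopop.genofilter import (
    FilterThresholds,
    VariantSite,
    apply_site_filters,
    locus_presence_filter,
    one_snp_per_locus,
    read_vcf,
    site_violations,
    write_vcf,
)

N = 19


def make_site(
    locus="locus_00000",
    pos=1,
    qual=500.0,
    n_het=4,
    alts=("T",),
    dp=30,
    override=None,
    missing=(),
):
    """A clean biallelic site: ``n_het`` 0/1 samples, the rest 0/0."""
    genotypes, depths, ads = [], [], []
    for i in range(N):
        if i in missing:
            genotypes.append(None)
            depths.append(0)
            ads.append(None)
            continue
        if i < n_het:
            genotypes.append((0, 1))
            ads.append((dp - dp // 2, dp // 2))
        else:
            genotypes.append((0, 0))
            ads.append((dp, 0))
        depths.append(dp)
    site = VariantSite(locus, pos, "A", alts, qual, genotypes, depths, ads)
    for idx, (gt, d, ad) in (override or {}).items():
        site.genotypes[idx] = gt
        site.depths[idx] = d
        site.allele_depths[idx] = ad
    return site


TH = FilterThresholds()


class TestCriteria:
    def test_clean_site_passes(self):
        assert site_violations(make_site(), TH) == []

    def test_third_allele_fails_criterion_1(self):
        s = make_site(alts=("T", "G"), override={5: ((0, 2), 30, (15, 0, 15))})
        assert 1 in site_violations(s, TH)

    def test_qual_boundary_is_strict_below_20(self):
        assert 2 in site_violations(make_site(qual=19.9), TH)
        assert 2 not in site_violations(make_site(qual=20.0), TH)

    def test_monomorphic_site_exempt_from_qual(self):
        s = make_site(n_het=0, qual=5.0)
        hits = site_violations(s, TH)
        assert 2 not in hits  # (it still fails MAF, being invariant)

    def test_any_sample_below_depth_10_fails_criterion_3(self):
        s = make_site(override={7: ((0, 0), 9, (9, 0))})
        assert 3 in site_violations(s, TH)
        s = make_site(override={7: ((0, 0), 10, (10, 0))})
        assert 3 not in site_violations(s, TH)

    def test_missing_genotype_counts_as_depth_failure_unless_disabled(self):
        s = make_site(missing=(3,))
        assert 3 in site_violations(s, TH)
        lenient = FilterThresholds(missing_fails_depth=False)
        assert site_violations(s, lenient) == []

    def test_het_allele_balance_bounds(self):
        s = make_site(override={0: ((0, 1), 10, (2, 8))})  # AB 0.8
        assert 4 in site_violations(s, TH)
        s = make_site(override={0: ((0, 1), 10, (8, 2))})  # AB 0.2
        assert 4 in site_violations(s, TH)
        s = make_site(override={0: ((0, 1), 12, (9, 3))})  # AB 0.25: boundary passes
        assert 4 not in site_violations(s, TH)

    def test_hom_minor_read_fraction(self):
        s = make_site(override={10: ((0, 0), 30, (28, 2))})  # 2/30 = 0.067
        assert 5 in site_violations(s, TH)
        s = make_site(override={10: ((1, 1), 30, (2, 28))})  # symmetric for 1/1
        assert 5 in site_violations(s, TH)
        s = make_site(override={10: ((0, 0), 40, (38, 2))})  # 0.05: boundary passes
        assert 5 not in site_violations(s, TH)

    def test_maf_boundary_2_vs_1_of_38_alleles(self):
        assert 6 not in site_violations(make_site(n_het=2), TH)  # 2/38 = 0.0526
        assert 6 in site_violations(make_site(n_het=1), TH)  # 1/38 = 0.0263
        strict = FilterThresholds(maf_strict=True)
        assert 6 in site_violations(make_site(n_het=1), strict)

    def test_missing_ad_for_called_genotype_is_an_error(self):
        s = make_site(override={2: ((0, 1), 30, None)})
        with pytest.raises(ValueError, match="allele depths"):
            site_violations(s, TH)


class TestCascade:
    def _battery(self):
        return [
            make_site(pos=1),
            make_site(pos=11, alts=("T", "G"), override={5: ((1, 2), 30, (0, 15, 15))}),
            make_site(pos=21, qual=10.0),
            make_site(pos=31, override={7: ((0, 0), 5, (5, 0))}),
            make_site(pos=41, override={0: ((0, 1), 10, (1, 9))}),
            make_site(pos=51, override={10: ((0, 0), 30, (27, 3))}),
            make_site(pos=61, n_het=1),
        ]

    def test_first_failure_attribution(self):
        kept, report = apply_site_filters(self._battery(), TH)
        assert len(kept) == 1
        assert report.sites_in == 7 and report.sites_out == 1
        assert {c: n for c, n in report.first_failure.items() if n} == {1: 1, 2: 1, 3: 1, 4: 1, 5: 1, 6: 1}

    def test_kept_set_invariant_to_criterion_order(self):
        sites = self._battery()
        baseline, _ = apply_site_filters(sites, TH)
        for order in itertools.permutations(range(1, 7), 6):
            kept, _ = apply_site_filters(sites, TH, order=order)
            assert [s.pos for s in kept] == [s.pos for s in baseline]

    def test_wrong_sample_count_rejected(self):
        s = make_site()
        s.genotypes.append((0, 0))
        s.depths.append(30)
        s.allele_depths.append((30, 0))
        with pytest.raises(ValueError, match="sample slots"):
            apply_site_filters([s], TH)


class TestPresenceAndThinning:
    def test_locus_presence_boundary(self):
        lenient = FilterThresholds(missing_fails_depth=False)
        loc14 = [make_site(locus="L14", pos=p, missing=tuple(range(5))) for p in (1, 11)]
        loc15 = [make_site(locus="L15", pos=p, missing=tuple(range(4))) for p in (1, 11)]
        kept = locus_presence_filter(loc14 + loc15, lenient)
        assert {s.locus_id for s in kept} == {"L15"}

    def test_empty_input(self):
        assert locus_presence_filter([], TH) == []

    def test_one_snp_per_locus_counts_and_determinism(self):
        sites = [make_site(locus=f"L{i}", pos=p) for i in range(5) for p in (1, 11, 21)]
        picked = one_snp_per_locus(sites, seed=7)
        assert len(picked) == 5
        assert len({s.locus_id for s in picked}) == 5
        again = one_snp_per_locus(sites, seed=7)
        assert [(s.locus_id, s.pos) for s in picked] == [(s.locus_id, s.pos) for s in again]
        different = one_snp_per_locus(sites, seed=8)
        assert isinstance(different, list)  # same structure, possibly other picks

    def test_monomorphic_locus_contributes_nothing(self):
        sites = [make_site(locus="L0", n_het=0)]
        assert one_snp_per_locus(sites, seed=1) == []


class TestVCFRoundTrip:
    def test_write_then_read_reproduces_sites(self, tmp_path):
        multi = make_site(pos=21, alts=("T", "G"), override={5: ((1, 2), 30, (0, 15, 15))})
        multi.allele_depths = [
            ad if ad is None or len(ad) == 3 else (ad[0], ad[1], 0) for ad in multi.allele_depths
        ]
        sites = [make_site(pos=1), make_site(pos=11, missing=(2, 3)), multi]
        names = [f"Sample_{i + 1:02d}" for i in range(N)]
        path = tmp_path / "out.vcf"
        write_vcf(sites, names, path)
        back, names2 = read_vcf(path)
        assert names2 == names
        assert len(back) == len(sites)
        for a, b in zip(sites, back):
            assert (a.locus_id, a.pos, a.ref, a.alts) == (b.locus_id, b.pos, b.ref, b.alts)
            assert a.qual == pytest.approx(b.qual, rel=1e-5)
            assert a.genotypes == b.genotypes
            assert a.depths == b.depths
            assert a.allele_depths == b.allele_depths
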