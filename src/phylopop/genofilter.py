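"""Six-criterion hard-filter cascade for multi-sample genotype calls.

A site is removed when ANY of the following fires (criteria are numbered for
reporting; removal is an OR, so the kept set does not depend on evaluation
order):

1. more than two alleles segregate across the called genotypes;
2. the site is polymorphic but its Phred-scaled quality (QUAL) is < 20;
3. any sample has read depth < 10 (a missing genotype counts as a depth
   failure by default; switchable);
4. any heterozygous sample has allele balance AB < 0.25 or AB > 0.75, where
   AB = alternate reads / total reads;
5. any homozygous sample has a minor-read fraction > 0.05;
6. the minor allele frequency across called genotypes is <= 0.05
   (strict '<' available via ``maf_strict``).

Downstream, loci genotyped in fewer than 15 of the 19 samples are dropped
and one informative SNP is drawn per locus to thin linkage.
"""

from __future__ import annotations

import random
from collections import OrderedDict
from dataclasses import dataclass, field

__all__ = [
    "VariantSite",
    "FilterThresholds",
    "FilterReport",
    "site_violations",
    "apply_site_filters",
    "locus_presence_filter",
    "one_snp_per_locus",
    "write_vcf",
    "read_vcf",
]


@dataclass
class VariantSite:
    """One VCF site with per-sample genotype, depth and allele depths.

    ``genotypes[i]`` is a tuple of allele indices (0 = ref) or None when
    missing; ``allele_depths[i]`` has one read count per allele (ref first).
    """

    locus_id: str
    pos: int
    ref: str
    alts: tuple
    qual: float
    genotypes: list
    depths: list
    allele_depths: list

    def n_samples(self) -> int:
        return len(self.genotypes)

    @property
    def site_id(self) -> str:
        return f"{self.locus_id}:{self.pos}"

    def observed_alleles(self) -> set:
        alleles = set()
        for gt in self.genotypes:
            if gt is not None:
                alleles.update(gt)
        return alleles

    def is_polymorphic(self) -> bool:
        return len(self.observed_alleles()) >= 2

    def minor_allele_frequency(self) -> float:
        counts: dict[int, int] = {}
        total = 0
        for gt in self.genotypes:
            if gt is None:
                continue
            for a in gt:
                counts[a] = counts.get(a, 0) + 1
                total += 1
        if total == 0 or len(counts) < 2:
            return 0.0
        return (total - max(counts.values())) / total


@dataclass
class FilterThresholds:
    max_alleles: int = 2
    min_qual: float = 20.0
    min_depth: int = 10
    het_ab_low: float = 0.25
    het_ab_high: float = 0.75
    hom_ab_max: float = 0.05
    min_maf: float = 0.05
    min_samples_present: int = 15
    n_samples: int = 19
    #: remove at MAF <= min_maf (False) or MAF < min_maf (True)
    maf_strict: bool = False
    #: a missing genotype fails the per-sample depth check
    missing_fails_depth: bool = True

    def __post_init__(self):
        if not 0 < self.het_ab_low < self.het_ab_high < 1:
            raise ValueError("need 0 < het_ab_low < het_ab_high < 1")
        if not self.hom_ab_max < self.het_ab_low:
            raise ValueError("hom_ab_max must be below het_ab_low")


@dataclass
class FilterReport:
    """Cascade accounting: first-failure and independent per-criterion counts."""

    sites_in: int = 0
    sites_out: int = 0
    loci_out: int = 0
    first_failure: dict = field(default_factory=lambda: {c: 0 for c in range(1, 7)})
    independent: dict = field(default_factory=lambda: {c: 0 for c in range(1, 7)})

    def to_rows(self):
        for c in range(1, 7):
            yield c, self.first_failure[c], self.independent[c]


def _require_ad(site: VariantSite, i: int):
    ad = site.allele_depths[i]
    if ad is None:
        raise ValueError(f"site {site.site_id}: sample {i} has a called genotype but no allele depths")
    return ad


def site_violations(site: VariantSite, th: FilterThresholds) -> list:
    """Criteria (1..6) this site violates; empty for a clean site."""
    hits = []
    polymorphic = site.is_polymorphic()
    if len(site.observed_alleles()) > th.max_alleles:
        hits.append(1)
    if polymorphic and site.qual < th.min_qual:
        hits.append(2)
    depth_fail = False
    for i, gt in enumerate(site.genotypes):
        if gt is None:
            if th.missing_fails_depth:
                depth_fail = True
                break
            continue
        if site.depths[i] < th.min_depth:
            depth_fail = True
            break
    if depth_fail:
        hits.append(3)
    het_fail = False
    hom_fail = False
    for i, gt in enumerate(site.genotypes):
        if gt is None:
            continue
        a, b = gt
        ad = _require_ad(site, i)
        total = sum(ad)
        if total == 0:
            continue
        if a != b:
            alt_allele = max(a, b)
            ab = ad[alt_allele] / total if alt_allele < len(ad) else 0.0
            if ab < th.het_ab_low or ab > th.het_ab_high:
                het_fail = True
        else:
            own = ad[a] if a < len(ad) else 0
            if (total - own) / total > th.hom_ab_max:
                hom_fail = True
    if het_fail:
        hits.append(4)
    if hom_fail:
        hits.append(5)
    maf = site.minor_allele_frequency()
    if (maf < th.min_maf) if th.maf_strict else (maf <= th.min_maf):
        hits.append(6)
    return hits


def apply_site_filters(sites, th: FilterThresholds, order=(1, 2, 3, 4, 5, 6)):
    """Run the cascade; returns (kept sites, FilterReport).

    ``order`` only affects first-failure attribution in the report; the
    kept set is an OR over criteria and therefore order-invariant.
    """
    report = FilterReport(sites_in=len(sites))
    kept = []
    for site in sites:
        if site.n_samples() != th.n_samples:
            raise ValueError(
                f"site {site.site_id} has {site.n_samples()} sample slots, expected {th.n_samples}"
            )
        hits = site_violations(site, th)
        if hits:
            for c in hits:
                report.independent[c] += 1
            first = next(c for c in order if c in hits)
            report.first_failure[first] += 1
        else:
            kept.append(site)
    report.sites_out = len(kept)
    report.loci_out = len({s.locus_id for s in kept})
    return kept, report


def locus_presence_filter(sites, th: FilterThresholds):
    """Drop all sites of loci genotyped in < ``min_samples_present`` samples.

    A sample counts as genotyped at a locus when it has a called genotype
    at one or more of the locus's sites.
    """
    present: dict[str, set] = {}
    for s in sites:
        bucket = present.setdefault(s.locus_id, set())
        for i, gt in enumerate(s.genotypes):
            if gt is not None:
                bucket.add(i)
    good = {locus for locus, samp in present.items() if len(samp) >= th.min_samples_present}
    return [s for s in sites if s.locus_id in good]


def _is_informative(site: VariantSite) -> bool:
    """Variable across samples: >= 2 distinct called genotype values."""
    gts = {tuple(sorted(gt)) for gt in site.genotypes if gt is not None}
    return len(gts) >= 2


def one_snp_per_locus(sites, seed: int, require_informative: bool = True):
    """Pick one SNP per locus uniformly at random (deterministic given seed).

    Only informative sites (variable across called genotypes) are eligible
    when ``require_informative``; loci with no eligible site contribute
    nothing.  Locus order follows first appearance in the input.
    """
    by_locus: "OrderedDict[str, list]" = OrderedDict()
    for s in sites:
        by_locus.setdefault(s.locus_id, []).append(s)
    rng = random.Random(seed)
    chosen = []
    for locus, group in by_locus.items():
        eligible = [s for s in group if _is_informative(s)] if require_informative else group
        if eligible:
            chosen.append(eligible[rng.randrange(len(eligible))])
    return chosen


# ---------------------------------------------------------------------------
# VCF 4.2 I/O (GT:DP:AD per sample)
# ---------------------------------------------------------------------------


def write_vcf(sites, sample_names, path) -> None:
    """Write sites as uncompressed VCF 4.2 with GT, DP and AD fields."""
    loci = []
    seen = set()
    for s in sites:
        if s.locus_id not in seen:
            loci.append(s.locus_id)
            seen.add(s.locus_id)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=phylopop\n")
        for locus in loci:
            fh.write(f"##contig=<ID={locus}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_names) + "\n")
        for s in sites:
            alt = ",".join(s.alts) if s.alts else "."
            cols = [s.locus_id, str(s.pos), ".", s.ref, alt, f"{s.qual:.6g}", ".", ".", "GT:DP:AD"]
            for gt, dp, ad in zip(s.genotypes, s.depths, s.allele_depths):
                if gt is None:
                    cols.append("./.:.:.")
                else:
                    g = "/".join(str(a) for a in gt)
                    ad_str = ",".join(str(x) for x in ad)
                    cols.append(f"{g}:{dp}:{ad_str}")
            fh.write("\t".join(cols) + "\n")


def read_vcf(path):
    """Parse a VCF with GT/DP/AD back into (sites, sample_names) via cyvcf2."""
    from cyvcf2 import VCF

    reader = VCF(str(path), gts012=False)
    sample_names = list(reader.samples)
    sites = []
    for v in reader:
        genotypes, depths, allele_depths = [], [], []
        dp = v.format("DP")
        ad = v.format("AD")
        for i, gt in enumerate(v.genotypes):
            a, b = int(gt[0]), int(gt[1])
            if a < 0 or b < 0:
                genotypes.append(None)
                depths.append(0)
                allele_depths.append(None)
                continue
            genotypes.append((a, b))
            dval = int(dp[i][0]) if dp is not None else 0
            depths.append(max(dval, 0))
            if ad is not None:
                row = [int(x) for x in ad[i]]
                allele_depths.append(tuple(max(x, 0) for x in row))
            else:
                allele_depths.append(None)
        sites.append(
            VariantSite(
                locus_id=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                qual=float(v.QUAL) if v.QUAL is not None else 0.0,
                genotypes=genotypes,
                depths=depths,
                allele_depths=allele_depths,
            )
        )
    reader.close()
    return sites, sample_names
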