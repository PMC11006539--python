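"""Synthetic study generator: homolog families with planted artifacts, and
layered-admixture genotypes with planted filter violations.

The generator emulates a transcriptome-based study design of 19 conspecific
ingroup samples plus 2 outgroups: a shallow coalescent-shaped species tree
(ingroup internal branches U(0.001, 0.01) subs/site, outgroups on a 0.05
stem), per-family gene trees carrying optional paralog duplications
(stem >= 0.25 subs/site when a deep split is planted), contaminant tips
(terminal branch >= 0.05 subs/site, well above the 0.03 absolute trimming
cutoff, while legitimate tips stay <= 0.01, below the 0.02 relative cutoff,
so trimming truth is unambiguous), Jukes-Cantor sequence evolution without
indels (rows are born aligned), and terminal masking to create occupancy
variation.

Genotypes follow a three-layer Balding-Nichols admixture model: per SNP an
ancestral frequency p ~ U(0.1, 0.9), layer frequencies
Beta(p(1-Fst)/Fst, (1-p)(1-Fst)/Fst), per-sample frequencies mixed by the
admixture matrix, diploid genotypes Binomial(2, .).  Read depths are
Poisson around ``mean_depth`` and allele depths binomial.  Filter
violations are planted site by site; control draws are conditioned to pass
every criterion, so the planted truth labels are exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genofilter import VariantSite
from .homology import record_id
from .alnstats import Alignment
from .tree import GeneTree, Node, taxon_of

__all__ = [
    "FamilySimConfig",
    "GenoSimConfig",
    "FamilyTruth",
    "GenoTruth",
    "FamilyResult",
    "simulate_species_tree",
    "simulate_family",
    "simulate_dataset",
    "simulate_genotypes",
    "simulate_hwe_matrix",
    "island_layout",
    "pure_layers",
]

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass
class FamilySimConfig:
    n_ingroup: int = 19
    n_outgroup: int = 2
    n_families: int = 30
    dup_prob: float = 0.3
    contaminant_prob: float = 0.2
    contaminant_length_min: float = 0.05
    contaminant_length_max: float = 0.12
    legit_tip_max: float = 0.01
    deep_split_prob: float = 0.5
    deep_length: float = 0.25
    moderate_dup_length: float = 0.1
    seq_length: int = 500
    mask_prob: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for name in ("dup_prob", "contaminant_prob", "deep_split_prob", "mask_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        # keep the planted truth separable from legitimate variation
        if self.contaminant_length_min <= 0.03:
            raise ValueError("contaminant_length_min must exceed the 0.03 absolute cutoff")
        if self.legit_tip_max >= 0.02:
            raise ValueError("legit_tip_max must stay below the 0.02 relative cutoff")


def island_layout(n_samples: int = 19) -> np.ndarray:
    """Default admixture: two pure geographic layers plus two admixed samples.

    With 19 samples: 8 pure layer 0 (NE), 9 pure layer 1 (SW), 2 admixed
    40/60; a third layer column is carried (k=3) but unweighted by default.
    """
    if n_samples < 5:
        raise ValueError("island layout needs >= 5 samples")
    q = np.zeros((n_samples, 3))
    n_admixed = 2
    n_pure = n_samples - n_admixed
    n_ne = n_pure // 2
    q[:n_ne, 0] = 1.0
    q[n_ne:n_pure, 1] = 1.0
    q[n_pure:, 0] = 0.4
    q[n_pure:, 1] = 0.6
    return q


def pure_layers(n_samples: int = 19, n_layers: int = 3) -> np.ndarray:
    """Pure block assignment: samples divided into ``n_layers`` contiguous groups."""
    q = np.zeros((n_samples, n_layers))
    bounds = np.linspace(0, n_samples, n_layers + 1).astype(int)
    for layer in range(n_layers):
        q[bounds[layer] : bounds[layer + 1], layer] = 1.0
    return q


@dataclass
class GenoSimConfig:
    n_samples: int = 19
    n_layers: int = 3
    layer_assignment: np.ndarray | None = None
    fst: float = 0.1
    n_loci: int = 200
    snps_per_locus: int = 5
    mean_depth: float = 30.0
    base_error: float = 0.01
    p_multiallelic: float = 0.02
    p_lowqual: float = 0.02
    p_lowdepth: float = 0.02
    p_het_ab_skew: float = 0.02
    p_hom_ab_noise: float = 0.02
    p_low_maf: float = 0.02
    p_missing: float = 0.02
    p_low_presence: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.layer_assignment is None:
            self.layer_assignment = island_layout(self.n_samples)
        self.layer_assignment = np.asarray(self.layer_assignment, dtype=float)
        if self.layer_assignment.shape != (self.n_samples, self.n_layers):
            raise ValueError("layer_assignment must be n_samples x n_layers")
        if not np.allclose(self.layer_assignment.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("admixture rows must sum to 1")
        if not 0 < self.fst < 1:
            raise ValueError("fst must be in (0, 1)")

    @property
    def artifact_rates(self):
        return {
            "multiallelic": self.p_multiallelic,
            "lowqual": self.p_lowqual,
            "lowdepth": self.p_lowdepth,
            "het_ab": self.p_het_ab_skew,
            "hom_ab": self.p_hom_ab_noise,
            "low_maf": self.p_low_maf,
            "missing": self.p_missing,
        }


#: which filter criterion each planted artifact violates (strict reading:
#: a missing genotype fails the per-sample depth rule)
ARTIFACT_CRITERION = {
    "clean": 0,
    "multiallelic": 1,
    "lowqual": 2,
    "lowdepth": 3,
    "missing": 3,
    "het_ab": 4,
    "hom_ab": 5,
    "low_maf": 6,
    "low_presence": 0,
}


# ---------------------------------------------------------------------------
# species tree and homolog families
# ---------------------------------------------------------------------------


def sample_name(i: int) -> str:
    return f"Sample_{i + 1:02d}"


def simulate_species_tree(cfg: FamilySimConfig, rng: np.random.Generator | None = None) -> GeneTree:
    """Shallow random ingroup topology with outgroups on a longer stem."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    active = [
        Node(sample_name(i), float(rng.uniform(0.001, cfg.legit_tip_max)))
        for i in range(cfg.n_ingroup)
    ]
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        parent = Node(length=float(rng.uniform(0.001, 0.01)))
        parent.add_child(active[i])
        parent.add_child(active[j])
        active = [n for k, n in enumerate(active) if k not in (i, j)] + [parent]
    ingroup = active[0]
    root = Node()
    root.add_child(ingroup)
    if cfg.n_outgroup == 1:
        root.add_child(Node("Outgroup_01", 0.05))
    elif cfg.n_outgroup > 1:
        stem = Node(length=0.05)
        for i in range(cfg.n_outgroup):
            stem.add_child(Node(f"Outgroup_{i + 1:02d}", float(rng.uniform(0.001, 0.01))))
        root.add_child(stem)
    return GeneTree(root)


@dataclass
class DeepEdge:
    clade_labels: frozenset
    n_inside_taxa: int
    n_outside_taxa: int
    expected_split: bool


@dataclass
class FamilyTruth:
    contaminant_tips: set = field(default_factory=set)
    paralog_tips: dict = field(default_factory=dict)  # tip label -> source sample
    deep_edges: list = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not (self.contaminant_tips or self.paralog_tips or self.deep_edges)


@dataclass
class FamilyResult:
    family_id: str
    tree: GeneTree
    alignment: Alignment
    truth: FamilyTruth


def _evolve_sequences(tree: GeneTree, seq_length: int, rng: np.random.Generator) -> dict:
    """Jukes-Cantor evolution along the tree; returns tip label -> int array."""
    seqs: dict[int, np.ndarray] = {id(tree.root): rng.integers(0, 4, size=seq_length)}
    out = {}
    for node in tree.root.preorder():
        if node.parent is None:
            continue
        parent_seq = seqs[id(node.parent)]
        p_diff = 0.75 * (1.0 - np.exp(-4.0 * node.length / 3.0))
        hit = rng.random(seq_length) < p_diff
        child = parent_seq.copy()
        n_hit = int(hit.sum())
        if n_hit:
            child[hit] = (child[hit] + rng.integers(1, 4, size=n_hit)) % 4
        seqs[id(node)] = child
        if node.is_tip:
            out[node.label] = child
    return out


def simulate_family(
    species_tree: GeneTree,
    cfg: FamilySimConfig,
    rng: np.random.Generator,
    copy_counters: dict | None = None,
    family_id: str = "fam_00000",
) -> FamilyResult:
    """One homolog family: gene tree + aligned sequences + planted truth."""
    tree = species_tree.copy()
    truth = FamilyTruth()
    clone_tips: list[Node] = []
    contaminant_node = None

    if rng.random() < cfg.dup_prob:
        candidates = [
            n
            for n in tree.internal_nodes()
            if 2 <= len({taxon_of(t.label) for t in n.preorder() if t.is_tip}) <= 8
        ]
        if candidates:
            target = candidates[int(rng.integers(len(candidates)))]
            clone = target.copy()
            parent = target.parent
            bridge = Node(length=target.length)
            idx = parent.children.index(target)
            parent.children[idx] = bridge
            bridge.parent = parent
            target.length = float(rng.uniform(0.002, 0.008))
            deep = rng.random() < cfg.deep_split_prob
            clone.length = cfg.deep_length if deep else cfg.moderate_dup_length
            bridge.add_child(target)
            bridge.add_child(clone)
            clone_tips = [t for t in clone.preorder() if t.is_tip]
            if deep:
                truth.deep_edges.append(clone)  # placeholder; finalised below

    if rng.random() < cfg.contaminant_prob:
        host = sample_name(int(rng.integers(cfg.n_ingroup)))
        attach_points = [n for n in tree.root.preorder() if n.children]
        attach = attach_points[int(rng.integers(len(attach_points)))]
        contaminant_node = Node(
            host, float(rng.uniform(cfg.contaminant_length_min, cfg.contaminant_length_max))
        )
        attach.add_child(contaminant_node)

    # assign unique record ids (per-sample copy counters, optionally global)
    counters = copy_counters if copy_counters is not None else {}
    for tip in tree.tips():
        sample = taxon_of(tip.label)
        counters[sample] = counters.get(sample, 0) + 1
        tip.label = record_id(sample, counters[sample])

    if contaminant_node is not None:
        truth.contaminant_tips.add(contaminant_node.label)
    for t in clone_tips:
        truth.paralog_tips[t.label] = taxon_of(t.label)

    # finalise deep-edge truth against the post-trim tree (contaminants are
    # removed before splitting, so they do not count toward side taxa)
    finalised = []
    for clone in truth.deep_edges:
        inside_tips = [t for t in clone.preorder() if t.is_tip and t is not contaminant_node]
        inside_taxa = {taxon_of(t.label) for t in inside_tips}
        inside_ids = {id(t) for t in clone.preorder() if t.is_tip}
        outside_taxa = {
            taxon_of(t.label)
            for t in tree.tips()
            if id(t) not in inside_ids and t is not contaminant_node
        }
        finalised.append(
            DeepEdge(
                clade_labels=frozenset(t.label for t in inside_tips),
                n_inside_taxa=len(inside_taxa),
                n_outside_taxa=len(outside_taxa),
                expected_split=len(inside_taxa) >= 4 and len(outside_taxa) >= 4,
            )
        )
    truth.deep_edges = finalised

    encoded = _evolve_sequences(tree, cfg.seq_length, rng)
    rows = {}
    for label in tree.tip_labels():
        seq = _BASES[encoded[label]]
        if rng.random() < cfg.mask_prob:
            frac = float(rng.uniform(0.05, 0.4))
            run = max(1, int(frac * cfg.seq_length))
            if rng.random() < 0.5:
                seq[:run] = "-"
            else:
                seq[len(seq) - run :] = "-"
        rows[label] = "".join(seq)
    return FamilyResult(family_id, tree, Alignment(rows), truth)


def simulate_dataset(cfg: FamilySimConfig):
    """Species tree plus ``n_families`` families with globally unique record ids."""
    rng = np.random.default_rng(cfg.seed)
    species = simulate_species_tree(cfg, rng)
    counters: dict[str, int] = {}
    families = [
        simulate_family(species, cfg, rng, copy_counters=counters, family_id=f"fam_{i:05d}")
        for i in range(cfg.n_families)
    ]
    return species, families


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


@dataclass
class SiteTruth:
    site_id: str
    artifact: str
    criterion: int


@dataclass
class GenoTruth:
    site_truth: list = field(default_factory=list)
    low_presence_loci: set = field(default_factory=set)
    admixture: np.ndarray | None = None
    layer_labels: list = field(default_factory=list)
    layer_freqs: np.ndarray | None = None

    @property
    def clean_site_ids(self) -> set:
        return {t.site_id for t in self.site_truth if t.artifact in ("clean", "low_presence")}

    def planted_counts(self) -> dict:
        counts = {c: 0 for c in range(1, 7)}
        for t in self.site_truth:
            if t.criterion:
                counts[t.criterion] += 1
        return counts


def _draw_depth(rng, mean_depth, minimum=10):
    while True:
        dp = int(rng.poisson(mean_depth))
        if dp >= minimum:
            return dp


def _het_ad(rng, dp, low=0.25, high=0.75):
    while True:
        alt = int(rng.binomial(dp, 0.5))
        if low <= alt / dp <= high:
            return alt


def _hom_minor(rng, dp, err, cap=0.05):
    while True:
        minor = int(rng.binomial(dp, err))
        if minor / dp <= cap:
            return minor


def _genotype_draw(rng, f, artifact, n):
    """Diploid genotypes per sample; conditioned so criterion 6 truth is exact."""
    total = 2 * n
    if artifact == "low_maf":
        g = np.zeros(n, dtype=int)
        g[int(rng.integers(n))] = 1  # one minor allele: MAF 1/(2n) <= 0.05
        return g
    for _ in range(200):
        g = rng.binomial(2, f)
        alt = int(g.sum())
        if min(alt, total - alt) / total > 0.05:
            if artifact == "het_ab" and not (g == 1).any():
                continue
            if artifact == "hom_ab" and not (g != 1).any():
                continue
            return g
    # frequency too extreme for a rejection draw: plant two heterozygotes
    g = np.zeros(n, dtype=int)
    i, j = rng.choice(n, size=2, replace=False)
    g[i] = g[j] = 1
    return g


def simulate_genotypes(cfg: GenoSimConfig):
    """Layered-admixture genotypes as VariantSites with planted violations.

    Returns (sites, truth, sample_names).  Control sites are conditioned to
    pass every filter criterion; each planted site violates its intended
    criterion and every criterion ordered before it.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    q = cfg.layer_assignment
    names = [sample_name(i) for i in range(n)]
    truth = GenoTruth(admixture=q.copy(), layer_labels=[int(np.argmax(row)) for row in q])
    artifact_names = list(cfg.artifact_rates)
    artifact_probs = np.array([cfg.artifact_rates[a] for a in artifact_names])
    p_clean = 1.0 - artifact_probs.sum()
    if p_clean < 0.5:
        raise ValueError("artifact rates must leave a majority of clean sites")
    sites: list[VariantSite] = []
    layer_freqs = []

    for locus_idx in range(cfg.n_loci):
        locus_id = f"locus_{locus_idx:05d}"
        low_presence = rng.random() < cfg.p_low_presence
        absent = None
        if low_presence:
            truth.low_presence_loci.add(locus_id)
            n_absent = n - 14  # leaves 14 present: just below the 15-sample rule
            absent = rng.choice(n, size=n_absent, replace=False)
        for snp_idx in range(cfg.snps_per_locus):
            pos = 1 + 10 * snp_idx
            if low_presence:
                artifact = "low_presence"
            else:
                u = rng.random()
                acc = 0.0
                artifact = "clean"
                for name, pa in zip(artifact_names, artifact_probs):
                    acc += pa
                    if u < acc:
                        artifact = name
                        break
            ref, alt = rng.choice(4, size=2, replace=False)
            ref_b, alt_b = str(_BASES[ref]), str(_BASES[alt])
            p_anc = float(rng.uniform(0.1, 0.9))
            a = p_anc * (1 - cfg.fst) / cfg.fst
            b = (1 - p_anc) * (1 - cfg.fst) / cfg.fst
            p_layers = rng.beta(a, b, size=cfg.n_layers)
            layer_freqs.append(p_layers)
            f = np.clip(q @ p_layers, 0.02, 0.98)
            g = _genotype_draw(rng, f, artifact, n)

            genotypes: list = []
            depths: list = []
            allele_depths: list = []
            for i in range(n):
                dp = _draw_depth(rng, cfg.mean_depth)
                if g[i] == 1:
                    alt_reads = _het_ad(rng, dp)
                    gt = (0, 1)
                elif g[i] == 2:
                    minor = _hom_minor(rng, dp, cfg.base_error)
                    alt_reads = dp - minor
                    gt = (1, 1)
                else:
                    alt_reads = _hom_minor(rng, dp, cfg.base_error)
                    gt = (0, 0)
                genotypes.append(gt)
                depths.append(dp)
                allele_depths.append((dp - alt_reads, alt_reads))
            qual = float(rng.uniform(100.0, 2000.0))
            alts: tuple = (alt_b,)

            if artifact == "multiallelic":
                second = [x for x in range(4) if x not in (ref, alt)][int(rng.integers(2))]
                alts = (alt_b, str(_BASES[second]))
                i = int(rng.integers(n))
                dp = depths[i]
                half = dp // 2
                genotypes[i] = (1, 2) if g[i] >= 1 else (0, 2)
                allele_depths[i] = (0, dp - half, half) if g[i] >= 1 else (dp - half, 0, half)
                allele_depths = [ad if len(ad) == 3 else (ad[0], ad[1], 0) for ad in allele_depths]
            elif artifact == "lowqual":
                qual = float(rng.uniform(2.0, 19.5))
            elif artifact == "lowdepth":
                i = int(rng.integers(n))
                dp = int(rng.integers(1, 10))
                depths[i] = dp
                if genotypes[i] == (0, 1):
                    alt_reads = int(rng.binomial(dp, 0.5))
                    allele_depths[i] = (dp - alt_reads, alt_reads)
                elif genotypes[i] == (1, 1):
                    allele_depths[i] = (0, dp)
                else:
                    allele_depths[i] = (dp, 0)
            elif artifact == "missing":
                for i in rng.choice(n, size=int(rng.integers(1, 4)), replace=False):
                    genotypes[int(i)] = None
                    depths[int(i)] = 0
                    allele_depths[int(i)] = None
            elif artifact == "het_ab":
                hets = [i for i in range(n) if genotypes[i] == (0, 1)]
                i = hets[int(rng.integers(len(hets)))]
                dp = depths[i]
                skew = 0.9 if rng.random() < 0.5 else 0.1
                while True:
                    alt_reads = int(rng.binomial(dp, skew))
                    ab = alt_reads / dp
                    if ab < 0.25 or ab > 0.75:
                        break
                allele_depths[i] = (dp - alt_reads, alt_reads)
            elif artifact == "hom_ab":
                homs = [i for i in range(n) if genotypes[i] in ((0, 0), (1, 1))]
                i = homs[int(rng.integers(len(homs)))]
                dp = depths[i]
                floor = int(np.floor(0.05 * dp)) + 1
                minor = max(int(rng.binomial(dp, 0.15)), floor)
                minor = min(minor, dp)
                if genotypes[i] == (0, 0):
                    allele_depths[i] = (dp - minor, minor)
                else:
                    allele_depths[i] = (minor, dp - minor)
            elif artifact == "low_presence":
                for i in absent:
                    genotypes[int(i)] = None
                    depths[int(i)] = 0
                    allele_depths[int(i)] = None

            site = VariantSite(
                locus_id=locus_id,
                pos=pos,
                ref=ref_b,
                alts=alts,
                qual=qual,
                genotypes=genotypes,
                depths=depths,
                allele_depths=allele_depths,
            )
            sites.append(site)
            truth.site_truth.append(
                SiteTruth(site.site_id, artifact, ARTIFACT_CRITERION[artifact])
            )
    truth.layer_freqs = np.array(layer_freqs)
    return sites, truth, names


def simulate_hwe_matrix(n_samples: int = 19, n_sites: int = 1000, seed: int = 0):
    """Genotypes drawn exactly at Hardy-Weinberg equilibrium (binomial sampling)."""
    from .popstruct import GenotypeMatrix

    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, size=n_sites)
    G = rng.binomial(2, p, size=(n_samples, n_sites)).astype(float)
    return GenotypeMatrix(
        samples=[sample_name(i) for i in range(n_samples)],
        site_ids=[f"hwe_{j:05d}" for j in range(n_sites)],
        G=G,
    ), p
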