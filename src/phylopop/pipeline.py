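"""End-to-end driver: stage functions shared by the CLI and the test suite.

Every stage writes plain-text artifacts (FASTA, newick, VCF, TSV) under an
output directory and returns its in-memory products so stages can be
chained without re-reading files.  ``run_all`` records a machine-readable
manifest (seed, parameters, input/output hashes) whose contents are
byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from . import __version__
from .alnstats import (
    Alignment,
    clean_columns,
    concatenate,
    parsimony_informative_sites,
    partition_text,
    read_fasta,
    tree_length,
    write_fasta,
)
from .config import PipelineConfig, stage_seed
from .genofilter import (
    apply_site_filters,
    locus_presence_filter,
    one_snp_per_locus,
    read_vcf,
    write_vcf,
)
from .homology import (
    SequenceRecord,
    build_similarity_graph,
    filter_clusters,
    markov_cluster,
    parse_record_id,
    reduce_redundancy,
)
from .orthology import extract_ortholog_alignment, max_inclusion
from .popstruct import genotype_matrix_from_sites, het_vs_hwe, pca, standardize
from .simdata import simulate_dataset, simulate_genotypes
from .tree import jc_distance_matrix, neighbor_joining, write_newick_file
from .treeclean import clean_round

__all__ = [
    "stage_simulate",
    "stage_cluster",
    "stage_clean_trees",
    "stage_orthologs",
    "stage_alnstats",
    "stage_filter_vcf",
    "stage_pca",
    "run_all",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_tsv(path: Path, header, rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig, outdir: Path):
    """Generate the synthetic study: families, trees, truth and a VCF."""
    outdir = Path(outdir)
    (outdir / "families").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    species, families = simulate_dataset(cfg.family_sim)
    with open(outdir / "species_tree.nwk", "w") as fh:
        fh.write(species.write() + "\n")
    member_rows, contaminant_rows, paralog_rows, deep_rows = [], [], [], []
    for fam in families:
        write_fasta(fam.alignment, outdir / "families" / f"{fam.family_id}.fasta")
        with open(outdir / "families" / f"{fam.family_id}.nwk", "w") as fh:
            fh.write(fam.tree.write() + "\n")
        for label in fam.alignment.rows:
            member_rows.append((fam.family_id, label))
        for tip in sorted(fam.truth.contaminant_tips):
            contaminant_rows.append((fam.family_id, tip))
        for tip, src in sorted(fam.truth.paralog_tips.items()):
            paralog_rows.append((fam.family_id, tip, src))
        for edge in fam.truth.deep_edges:
            deep_rows.append(
                (
                    fam.family_id,
                    ",".join(sorted(edge.clade_labels)),
                    edge.n_inside_taxa,
                    edge.n_outside_taxa,
                    int(edge.expected_split),
                )
            )
    _write_tsv(outdir / "truth" / "family_members.tsv", ("family", "record"), member_rows)
    _write_tsv(outdir / "truth" / "contaminants.tsv", ("family", "tip"), contaminant_rows)
    _write_tsv(outdir / "truth" / "paralogs.tsv", ("family", "tip", "source_sample"), paralog_rows)
    _write_tsv(
        outdir / "truth" / "deep_edges.tsv",
        ("family", "clade", "n_inside_taxa", "n_outside_taxa", "expected_split"),
        deep_rows,
    )
    sites, geno_truth, sample_names = simulate_genotypes(cfg.geno_sim)
    write_vcf(sites, sample_names, outdir / "genotypes.vcf")
    _write_tsv(
        outdir / "truth" / "site_truth.tsv",
        ("site_id", "artifact", "criterion"),
        [(t.site_id, t.artifact, t.criterion) for t in geno_truth.site_truth],
    )
    _write_tsv(
        outdir / "truth" / "admixture.tsv",
        ("sample",) + tuple(f"layer_{k}" for k in range(cfg.geno_sim.n_layers)),
        [
            (name,) + tuple(f"{v:.6f}" for v in row)
            for name, row in zip(sample_names, cfg.geno_sim.layer_assignment)
        ],
    )
    return {"species": species, "families": families, "sites": sites, "geno_truth": geno_truth, "sample_names": sample_names}


def stage_cluster(cfg: PipelineConfig, fasta_paths, outdir: Path):
    """Redundancy reduction, similarity graph, MCL, minimum-taxon filter."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_sample: dict[str, list[SequenceRecord]] = {}
    seqs: dict[str, str] = {}
    for path in sorted(Path(p) for p in fasta_paths):
        aln = read_fasta(path)
        for rid, seq in aln.rows.items():
            sample, copy = parse_record_id(rid)
            rec = SequenceRecord(sample, copy, seq)
            by_sample.setdefault(sample, []).append(rec)
            seqs[rid] = seq
    reps = []
    for sample in sorted(by_sample):
        reps.extend(reduce_redundancy(by_sample[sample], cfg.redundancy_identity))
    graph = build_similarity_graph(reps, min_identity=cfg.min_identity, k=cfg.kmer)
    raw_clusters, _converged = markov_cluster(graph, inflation=cfg.inflation)
    kept, counts = filter_clusters(raw_clusters, min_taxa=cfg.min_cluster_taxa)
    rows = []
    for hc in kept:
        for rid in sorted(hc.members):
            sample, copy = parse_record_id(rid)
            rows.append((hc.cluster_id, sample, copy))
    _write_tsv(outdir / "clusters.tsv", ("cluster_id", "sample_id", "copy_index"), rows)
    _write_tsv(
        outdir / "graph_edges.tsv",
        ("u", "v", "identity"),
        [(u, v, f"{d['weight']:.6f}") for u, v, d in sorted(graph.edges(data=True))],
    )
    return {"clusters": kept, "counts": counts, "sequences": seqs}


def stage_clean_trees(cfg: PipelineConfig, clusters, sequences, outdir: Path):
    """NJ guide trees per cluster, then the two-round trim/split cleaning."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    items = []  # (cluster_id, tree)
    for hc in clusters:
        members = sorted(hc.members)
        dm = jc_distance_matrix(members, [sequences[m] for m in members], saturation_cap=cfg.saturation_cap)
        items.append((hc.cluster_id, neighbor_joining(dm)))
    reports = []
    for round_index in range(1, cfg.clean.rounds + 1):
        agg_before: dict[str, int] = {}
        agg_removed: dict[str, int] = {}
        split_count = discard_count = 0
        next_items = []
        for cid, tree in items:
            survivors, rep = clean_round([tree], cfg.clean, round_index)
            for sample, (before, removed, _r) in rep.per_sample.items():
                agg_before[sample] = agg_before.get(sample, 0) + before
                agg_removed[sample] = agg_removed.get(sample, 0) + removed
            split_count += rep.trees_split
            discard_count += rep.trees_discarded
            next_items.extend((cid, s) for s in survivors)
        items = next_items
        reports.append(
            {
                "round": round_index,
                "per_sample": {
                    s: (agg_before[s], agg_removed.get(s, 0), agg_removed.get(s, 0) / agg_before[s])
                    for s in sorted(agg_before)
                },
                "trees_split": split_count,
                "trees_discarded": discard_count,
            }
        )
    rows = []
    for rep in reports:
        for sample, (before, removed, rate) in rep["per_sample"].items():
            rows.append((sample, before, removed, f"{rate:.6f}", rep["round"]))
    _write_tsv(outdir / "clean_report.tsv", ("sample_id", "before", "removed", "rate", "round"), rows)
    with open(outdir / "cleaned_trees.nwk", "w") as fh:
        for cid, tree in items:
            fh.write(tree.write() + "\n")
    _write_tsv(
        outdir / "cleaned_tree_index.tsv",
        ("tree_index", "source_cluster", "n_tips"),
        [(i, cid, t.n_tips) for i, (cid, t) in enumerate(items)],
    )
    return {"items": items, "reports": reports}


def stage_orthologs(cfg: PipelineConfig, cleaned_items, sequences, outdir: Path):
    """Maximum-inclusion extraction plus per-ortholog alignments."""
    outdir = Path(outdir)
    (outdir / "orthologs").mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    ortho_alns = []
    counter = 0
    for cid, tree in cleaned_items:
        for orth in max_inclusion(tree, cfg.mi):
            oid = f"orth_{counter:05d}"
            counter += 1
            homolog_aln = Alignment({lbl: sequences[lbl] for lbl in orth.tip_labels()})
            aln = extract_ortholog_alignment(homolog_aln, orth, occupancy=cfg.occupancy)
            write_fasta(aln, outdir / "orthologs" / f"{oid}.fasta")
            manifest_rows.append((oid, cid, len(orth.taxa())))
            ortho_alns.append((oid, aln))
    _write_tsv(outdir / "ortholog_manifest.tsv", ("ortholog_id", "source_cluster", "n_taxa"), manifest_rows)
    return {"orthologs": ortho_alns}


def stage_alnstats(cfg: PipelineConfig, ortho_alns, outdir: Path):
    """Concatenation with partitions plus the alignment/tree summary statistics."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not ortho_alns:
        raise ValueError("no ortholog alignments to summarise")
    supermatrix, partitions = concatenate(ortho_alns)
    supermatrix = clean_columns(supermatrix, cfg.occupancy)
    write_fasta(supermatrix, outdir / "supermatrix.fasta")
    with open(outdir / "partitions.txt", "w") as fh:
        fh.write(partition_text(partitions))
    per_gene = [(gid, a.length, parsimony_informative_sites(a)) for gid, a in ortho_alns]
    _write_tsv(outdir / "gene_stats.tsv", ("gene_id", "length", "parsimony_informative"), per_gene)
    names = list(supermatrix.rows)
    dm = jc_distance_matrix(names, [supermatrix.rows[n] for n in names], saturation_cap=cfg.saturation_cap)
    concat_tree = neighbor_joining(dm)
    write_newick_file([concat_tree], outdir / "concat_tree.nwk")
    stats = {
        "n_genes": len(ortho_alns),
        "supermatrix_length": supermatrix.length,
        "parsimony_informative_total": sum(p for _g, _l, p in per_gene),
        "tree_length": tree_length(concat_tree),
    }
    _write_tsv(
        outdir / "summary_stats.tsv",
        ("statistic", "value"),
        [(k, f"{v:.6f}" if isinstance(v, float) else v) for k, v in stats.items()],
    )
    return {"supermatrix": supermatrix, "partitions": partitions, "stats": stats, "tree": concat_tree}


def stage_filter_vcf(cfg: PipelineConfig, vcf_path, outdir: Path, seed: int | None = None):
    """The six-criterion cascade, locus presence rule and one-SNP-per-locus."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed if seed is None else seed
    sites, sample_names = read_vcf(vcf_path)
    kept, report = apply_site_filters(sites, cfg.thresholds)
    present = locus_presence_filter(kept, cfg.thresholds)
    informative = one_snp_per_locus(present, seed=stage_seed(seed, "one_snp_per_locus"))
    write_vcf(present, sample_names, outdir / "filtered.vcf")
    write_vcf(informative, sample_names, outdir / "informative.vcf")
    _write_tsv(
        outdir / "filter_report.tsv",
        ("criterion", "first_failure_removals", "independent_violations"),
        list(report.to_rows()),
    )
    _write_tsv(
        outdir / "filter_summary.tsv",
        ("statistic", "value"),
        [
            ("sites_in", report.sites_in),
            ("sites_pass_cascade", report.sites_out),
            ("sites_after_presence", len(present)),
            ("loci_after_presence", len({s.locus_id for s in present})),
            ("informative_snps", len(informative)),
        ],
    )
    return {
        "sites": sites,
        "kept": kept,
        "present": present,
        "informative": informative,
        "report": report,
        "sample_names": sample_names,
    }


def stage_pca(cfg: PipelineConfig, sites, sample_names, outdir: Path, k: int = 5):
    """Genotype matrix, EIGENSTRAT standardisation, PCA and the HWE table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gm = genotype_matrix_from_sites(sites, sample_names)
    S, _keep = standardize(gm)
    k = min(k, len(sample_names) - 1, S.shape[1])
    result = pca(S, k)
    header = ("sample",) + tuple(f"PC{i + 1}" for i in range(k))
    rows = [
        (name,) + tuple(f"{result.coordinates[i, j]:.6f}" for j in range(k))
        for i, name in enumerate(sample_names)
    ]
    _write_tsv(outdir / "pca.tsv", header, rows)
    _write_tsv(
        outdir / "pca_explained.tsv",
        ("component", "explained_fraction"),
        [(f"PC{i + 1}", f"{v:.6f}") for i, v in enumerate(result.explained_fraction)],
    )
    hwe = het_vs_hwe(gm)
    hwe.to_csv(outdir / "hwe.tsv", sep="\t", float_format="%.6f")
    return {"matrix": gm, "pca": result, "hwe": hwe}


def run_all(cfg: PipelineConfig, outdir: Path) -> dict:
    """Drive every stage under ``outdir`` and write a reproducibility manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = stage_simulate(cfg, outdir / "sim")
    fasta_paths = sorted((outdir / "sim" / "families").glob("*.fasta"))
    clu = stage_cluster(cfg, fasta_paths, outdir / "cluster")
    cleaned = stage_clean_trees(cfg, clu["clusters"], clu["sequences"], outdir / "clean")
    orths = stage_orthologs(cfg, cleaned["items"], clu["sequences"], outdir / "orthologs")
    stats = stage_alnstats(cfg, orths["orthologs"], outdir / "alnstats")
    filt = stage_filter_vcf(cfg, outdir / "sim" / "genotypes.vcf", outdir / "filter", seed=cfg.seed)
    pca_out = stage_pca(cfg, filt["informative"], filt["sample_names"], outdir / "pca")
    artifacts = sorted(
        str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "package": "phylopop",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "artifacts": {rel: _sha256(outdir / rel) for rel in artifacts},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {
        "sim": sim,
        "cluster": clu,
        "clean": cleaned,
        "orthologs": orths,
        "alnstats": stats,
        "filter": filt,
        "pca": pca_out,
        "manifest": manifest,
    }
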