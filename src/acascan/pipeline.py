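"""End-to-end orchestration: scan -> cluster -> context -> promoters -> motifs -> stats.

The in-memory entry point is :func:`analyze`, which takes genomes, seed
alignments and acr family labels and returns every stage's results plus a
JSON-serialisable report; :func:`run_pipeline` wraps it with file I/O. Every
stochastic stage derives its own sub-seed by hashing (seed, stage name), so
stages are individually reproducible and two runs with the same seed produce
byte-identical reports. Structured counts in/out of every filter are kept in
the report so attrition through the filter cascade is auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import genomic_context as gc
from . import promoter_analysis as pa
from .family_stats import (
    FamilySummary,
    distances_from_identity,
    nj_tree,
    summarize_family,
    write_newick,
)
from .homology import (
    ClusterSet,
    FamilyProfile,
    build_profile,
    calibrate_thresholds,
    greedy_cluster,
    scan_genome,
)
from .records import GenomeRecord, read_genomes
from .synthetic_data import SyntheticConfig, generate_genomes


def stage_seed(seed: int, stage: str) -> int:
    """Stable sub-seed for a named stage, < 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class AnalysisParams:
    flank: int = 5000
    operon_max_gap: int = 55
    promoter_length: int = 400
    promoter_search_window: int = 150
    ir_arm_range: tuple[int, int] = (4, 10)
    ir_spacer_range: tuple[int, int] = (0, 12)
    ir_max_mismatch: int = 1
    motif_widths: tuple[int, ...] = (12, 16, 18, 20)
    motif_mode: str = "zoops"
    motif_restarts: int = 3
    motif_iterations: int = 150
    coverage_filter: float = 0.4
    protein_cluster_threshold: float = 0.8
    nucleotide_cluster_threshold: float = 0.9
    calibration_quantile: float = 0.999
    core_quantile: float = 0.99
    seed: int = 0


@dataclass
class PromoterReport:
    region: pa.PromoterRegion
    core: pa.CorePromoterCall | None
    irs: list[pa.InvertedRepeat]


@dataclass
class AnalysisResult:
    profiles: list[FamilyProfile]
    hits: list
    aca_hits: list
    acr_cds_labels: dict[str, str]
    records: list[gc.AssociationRecord]
    operons_by_contig: dict[str, list[gc.Operon]]
    promoters: dict[str, PromoterReport]  # keyed by aca cds_id
    clusters: ClusterSet | None
    network: gc.AssociationNetwork
    motif: pa.Motif | None
    motif_sites: dict[str, list[tuple[int, str, float]]]
    summaries: dict[str, FamilySummary]
    newick: str | None
    report: dict


def _background_genomes(seed: int, n_cds: int = 60) -> list[GenomeRecord]:
    cfg = SyntheticConfig(
        n_contigs=2,
        contig_length=40_000,
        n_acr_aca_operons=0,
        n_solo_aca=0,
        n_background_cds=n_cds,
        seed=seed,
    )
    genomes, _ = generate_genomes(cfg)
    return genomes


def build_family_profiles(
    alignments: dict[str, list[str]],
    coverage_filter: float,
    seed: int,
    calibration_quantile: float = 0.999,
) -> list[FamilyProfile]:
    """Profiles from seed alignments with empirically calibrated thresholds."""
    profiles = []
    for name in sorted(alignments):
        rows = alignments[name]
        ref = rows[0].replace("-", "").replace(".", "")
        prof = build_profile(rows, family_name=name, reference=ref)
        prof.min_coverage = coverage_filter
        profiles.append(prof)
    background = _background_genomes(stage_seed(seed, "calibration"))
    return calibrate_thresholds(profiles, background, calibration_quantile)


def analyze(
    genomes: list[GenomeRecord],
    alignments: dict[str, list[str]],
    acr_family_labels: dict[str, str],
    params: AnalysisParams = AnalysisParams(),
    profiles: list[FamilyProfile] | None = None,
) -> AnalysisResult:
    """Run the whole analysis in memory.

    ``acr_family_labels`` maps acr family name -> class (known/candidate/
    putative); alignment families absent from it are treated as aca families.
    """
    report: dict = {"params": asdict(params), "seed": params.seed, "stages": {}}

    if profiles is None:
        profiles = build_family_profiles(
            alignments, params.coverage_filter, params.seed, params.calibration_quantile
        )
    report["stages"]["profiles"] = {
        p.family_name: {
            "width": p.width,
            "score_threshold": round(p.score_threshold, 6),
        }
        for p in profiles
    }

    # --- scan ---------------------------------------------------------------
    hits = []
    for genome in genomes:
        hits.extend(scan_genome(profiles, genome))
    acr_families = set(acr_family_labels)
    aca_all = [h for h in hits if h.family_name not in acr_families]
    acr_hits = [h for h in hits if h.family_name in acr_families]
    # one association per CDS: keep the best-scoring aca hit per CDS
    best_by_cds: dict[str, object] = {}
    for h in aca_all:
        if h.cds_id not in best_by_cds or h.score > best_by_cds[h.cds_id].score:
            best_by_cds[h.cds_id] = h
    aca_hits = sorted(best_by_cds.values(), key=lambda h: (-h.score, h.cds_id))
    acr_cds_labels: dict[str, str] = {}
    acr_family_of: dict[str, str] = {}
    for h in sorted(acr_hits, key=lambda h: (-h.score, h.cds_id)):
        if h.cds_id not in acr_cds_labels:
            acr_cds_labels[h.cds_id] = acr_family_labels[h.family_name]
            acr_family_of[h.cds_id] = h.family_name
    report["stages"]["scan"] = {
        "n_hits": len(hits),
        "n_aca_cds": len(aca_hits),
        "n_acr_cds": len(acr_cds_labels),
    }

    # --- cluster (protein-level redundancy reduction) -----------------------
    translations = {
        f.cds_id: f.translation for g in genomes for f in g.features if f.translation
    }
    clusters = None
    if aca_hits:
        clusters = greedy_cluster(
            {h.cds_id: translations[h.cds_id] for h in aca_hits},
            params.protein_cluster_threshold,
        )
        report["stages"]["cluster"] = {
            "n_members": len(clusters.membership),
            "n_representatives": len(clusters.representatives),
        }

    # --- genomic context ----------------------------------------------------
    genome_by_contig = {g.contig_id: g for g in genomes}
    operons_by_contig = {
        g.contig_id: gc.call_operons(
            g.features, params.operon_max_gap, id_prefix=f"{g.contig_id}_op"
        )
        for g in genomes
    }
    records = []
    for h in aca_hits:
        nbhd = gc.extract_neighborhood(genome_by_contig[h.contig_id], h, params.flank)
        records.append(
            gc.classify_association(
                nbhd, operons_by_contig[h.contig_id], acr_cds_labels
            )
        )
    label_counts = {
        lab: sum(1 for r in records if r.label == lab)
        for lab in ("acr_associated", "proximal", "solo")
    }
    report["stages"]["context"] = {
        "n_operons": sum(len(v) for v in operons_by_contig.values()),
        **label_counts,
    }
    network = gc.build_network(records, acr_family_of)
    report["stages"]["network"] = {
        "nodes": sorted(network.nodes),
        "edges": [
            {"a": a, "b": b, "weight": w} for (a, b), w in sorted(network.edges.items())
        ],
    }

    # --- promoters: core elements and inverted repeats ----------------------
    core_thr_rng = np.random.default_rng(stage_seed(params.seed, "core_null"))
    from .synthetic_data import random_dna

    bg_seqs = [random_dna(params.promoter_search_window, 0.5, core_thr_rng) for _ in range(300)]
    core_threshold = pa.calibrate_core_threshold(
        bg_seqs, params.core_quantile, params.promoter_search_window
    )
    report["stages"]["core_threshold_bits"] = round(core_threshold, 6)

    operon_by_id = {
        op.operon_id: op for ops in operons_by_contig.values() for op in ops
    }
    promoters: dict[str, PromoterReport] = {}
    for rec in records:
        op = operon_by_id[rec.operon_id]
        region = pa.extract_promoter(
            genome_by_contig[rec.aca_hit.contig_id], op, params.promoter_length
        )
        if not region.sequence:
            promoters[rec.aca_hit.cds_id] = PromoterReport(region, None, [])
            continue
        core = pa.scan_core_promoter(
            region,
            params.promoter_search_window,
            threshold=core_threshold,
        )
        window = region.sequence[-params.promoter_search_window :]
        offset0 = len(region.sequence) - len(window)
        irs = [
            pa.InvertedRepeat(
                left=(ir.left[0] + offset0, ir.left[1] + offset0),
                right=(ir.right[0] + offset0, ir.right[1] + offset0),
                arm_length=ir.arm_length,
                spacer=ir.spacer,
                mismatches=ir.mismatches,
            )
            for ir in pa.find_inverted_repeats(
                window,
                params.ir_arm_range,
                params.ir_spacer_range,
                params.ir_max_mismatch,
            )
        ]
        irs = pa.classify_promoter_irs(irs, core)
        promoters[rec.aca_hit.cds_id] = PromoterReport(region, core, irs)
    report["stages"]["promoters"] = {
        "n_regions": len(promoters),
        "n_core_significant": sum(
            1 for p in promoters.values() if p.core and p.core.significant
        ),
        "n_with_ir": sum(1 for p in promoters.values() if p.irs),
        "n_ir1": sum(
            1
            for p in promoters.values()
            for ir in p.irs
            if ir.classification == "IR1"
        ),
    }

    # --- motifs over the high-confidence (acr-associated) promoter set ------
    hc_ids = [
        r.aca_hit.cds_id
        for r in records
        if r.label == "acr_associated" and promoters[r.aca_hit.cds_id].region.sequence
    ]
    motif = None
    motif_sites: dict[str, list[tuple[int, str, float]]] = {}
    if len(hc_ids) >= 2:
        # nucleotide-level redundancy reduction of the promoter set (0.9)
        prom_seqs = {cid: promoters[cid].region.sequence for cid in hc_ids}
        nt_clusters = greedy_cluster(prom_seqs, params.nucleotide_cluster_threshold)
        reps = [cid for cid in hc_ids if nt_clusters.membership[cid] == cid]
        report["stages"]["promoter_dedup"] = {
            "n_in": len(hc_ids),
            "n_nonredundant": len(reps),
        }
        usable = [
            (cid, prom_seqs[cid][-params.promoter_search_window :]) for cid in reps
        ]
        min_len = min(len(s) for _, s in usable) if usable else 0
        widths = [w for w in params.motif_widths if w <= min_len]
        if len(usable) >= 2 and widths:
            motif = pa.discover_motif_sweep(
                usable,
                widths=widths,
                mode=params.motif_mode,
                n_restarts=params.motif_restarts,
                iterations=params.motif_iterations,
                seed=stage_seed(params.seed, "gibbs"),
            )
            scan_threshold = 0.7 * float(motif.log_odds.max(axis=1).sum())
            for cid, prep in sorted(promoters.items()):
                if len(prep.region.sequence) >= motif.width:
                    found = pa.scan_motif(motif, prep.region, scan_threshold)
                    if found:
                        motif_sites[cid] = found
            report["stages"]["motif"] = {
                "width": motif.width,
                "consensus": motif.consensus,
                "information_content": round(motif.information_content, 6),
                "n_sites": motif.n_sites,
                "n_promoters_with_site": len(motif_sites),
            }

    # --- family statistics and tree -----------------------------------------
    summaries: dict[str, FamilySummary] = {}
    for fam in sorted({h.family_name for h in aca_hits}):
        fam_hits = [h for h in aca_hits if h.family_name == fam]
        summaries[fam] = summarize_family(fam_hits, records, params.coverage_filter)
    report["stages"]["families"] = {
        fam: {
            "n_associated": s.n_associated,
            "n_solo": s.n_solo,
            "mean_length_associated": _r(s.length_stats["associated"].mean),
            "mean_length_solo": _r(s.length_stats["solo"].mean),
            "mean_identity_associated": _r(s.identity_stats["associated"].mean),
            "mean_identity_solo": _r(s.identity_stats["solo"].mean),
            "p_length": _r(s.t_test_length[2]) if s.t_test_length else None,
            "p_identity": _r(s.t_test_identity[2]) if s.t_test_identity else None,
        }
        for fam, s in summaries.items()
    }
    newick = None
    if clusters is not None and len(clusters.representatives) >= 2:
        rep_seqs = {cid: translations[cid] for cid in clusters.representatives[:40]}
        if len(rep_seqs) >= 2:
            dm = distances_from_identity(rep_seqs)
            newick = write_newick(nj_tree(dm))
            report["stages"]["tree"] = {"n_leaves": len(rep_seqs)}

    # internal consistency of the report
    assert (
        label_counts["acr_associated"] + label_counts["proximal"] + label_counts["solo"]
        == len(records)
    )
    return AnalysisResult(
        profiles=profiles,
        hits=hits,
        aca_hits=aca_hits,
        acr_cds_labels=acr_cds_labels,
        records=records,
        operons_by_contig=operons_by_contig,
        promoters=promoters,
        clusters=clusters,
        network=network,
        motif=motif,
        motif_sites=motif_sites,
        summaries=summaries,
        newick=newick,
        report=report,
    )


def _r(x, nd: int = 6):
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return None
    return round(float(x), nd)


def report_json(report: dict) -> str:
    """Canonical report serialisation (sorted keys, no timestamps)."""
    return json.dumps(report, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# File-based pipeline


@dataclass
class PipelineConfig:
    genomes_fasta: str
    genomes_gff: str
    seed_alignment_dir: str
    acr_labels_path: str
    output_dir: str
    params: AnalysisParams = field(default_factory=AnalysisParams)


def load_alignments(directory: str | Path) -> dict[str, list[str]]:
    """Read seed_<family>.afa aligned FASTA files from a directory."""
    from Bio import SeqIO

    alignments = {}
    for path in sorted(Path(directory).glob("seed_*.afa")):
        name = path.stem.removeprefix("seed_")
        alignments[name] = [str(r.seq) for r in SeqIO.parse(str(path), "fasta")]
    if not alignments:
        raise FileNotFoundError(f"no seed_*.afa alignments under {directory}")
    return alignments


def load_acr_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["family"], df["label"]))


def write_artifacts(result: AnalysisResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "cds_id": h.cds_id,
                "contig": h.contig_id,
                "family": h.family_name,
                "score_bits": h.score,
                "coverage": h.coverage,
                "identity": h.identity_to_reference,
                "protein_length": h.protein_length,
            }
            for h in result.hits
        ]
    ).to_csv(outdir / "hits.tsv", sep="\t", index=False)
    if result.clusters is not None:
        pd.DataFrame(
            sorted(result.clusters.membership.items()),
            columns=["member", "representative"],
        ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "cds_id": r.aca_hit.cds_id,
                "family": r.aca_hit.family_name,
                "label": r.label,
                "acr_class": r.acr_class,
                "linked_acr_ids": ",".join(r.linked_acr_ids),
                "operon_id": r.operon_id,
            }
            for r in result.records
        ]
    ).to_csv(outdir / "associations.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"family_a": a, "family_b": b, "weight": w}
            for (a, b), w in sorted(result.network.edges.items())
        ]
    ).to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
    with open(outdir / "operons.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for contig, ops in sorted(result.operons_by_contig.items()):
            for op in ops:
                s = min(m.start for m in op.members) + 1
                e = max(m.end for m in op.members)
                fh.write(
                    f"{contig}\tacascan\toperon\t{s}\t{e}\t.\t{op.strand}\t.\t"
                    f"ID={op.operon_id}\n"
                )
                for m in op.members:
                    fh.write(
                        f"{contig}\tacascan\tCDS\t{m.start + 1}\t{m.end}\t.\t"
                        f"{m.strand}\t0\tID={m.cds_id};Parent={op.operon_id}\n"
                    )
    core_rows, ir_rows = [], []
    for cid, prep in sorted(result.promoters.items()):
        r = prep.region
        if prep.core:
            c = prep.core
            core_rows.append(
                {
                    "aca_cds": cid,
                    "operon_id": r.operon_id,
                    "contig": r.contig_id,
                    "minus35_pos": c.minus35.position,
                    "minus35": c.minus35.hexamer,
                    "minus10_pos": c.minus10.position,
                    "minus10": c.minus10.hexamer,
                    "spacer": c.spacer,
                    "total_score_bits": c.total_score,
                    "significant": c.significant,
                }
            )
        for ir in prep.irs:
            ir_rows.append(
                {
                    "aca_cds": cid,
                    "operon_id": r.operon_id,
                    "left_start": ir.left[0],
                    "left_end": ir.left[1],
                    "right_start": ir.right[0],
                    "right_end": ir.right[1],
                    "arm": ir.arm_length,
                    "spacer": ir.spacer,
                    "mismatches": ir.mismatches,
                    "classification": ir.classification,
                }
            )
    pd.DataFrame(core_rows).to_csv(outdir / "core_promoters.tsv", sep="\t", index=False)
    pd.DataFrame(ir_rows).to_csv(outdir / "inverted_repeats.tsv", sep="\t", index=False)
    if result.motif is not None:
        pa.write_meme_minimal({"acascan_motif_1": result.motif}, outdir / "motif.meme.txt")
        pd.DataFrame(
            [
                {"aca_cds": cid, "offset": off, "strand": st, "score_bits": sc}
                for cid, found in sorted(result.motif_sites.items())
                for off, st, sc in found
            ]
        ).to_csv(outdir / "motif_sites.tsv", sep="\t", index=False)
    if result.newick is not None:
        (outdir / "aca_tree.nwk").write_text(result.newick + "\n")
    (outdir / "report.json").write_text(report_json(result.report))


def run_pipeline(config: PipelineConfig) -> dict:
    """Load inputs, run the analysis, write all artifacts; returns the report."""
    genomes = read_genomes(config.genomes_fasta, config.genomes_gff)
    alignments = load_alignments(config.seed_alignment_dir)
    acr_labels = load_acr_labels(config.acr_labels_path)
    result = analyze(genomes, alignments, acr_labels, config.params)
    write_artifacts(result, config.output_dir)
    return result.report
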