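"""End-to-end orchestration: extract -> align -> threshold -> cluster ->
characterize (-> associate), with per-stage artifacts and a checksum
manifest.

Every stage writes a plain-text artifact into the run directory; the JSON
manifest records parameters, seeds and SHA-256 checksums, so a rerun with
identical inputs and seeds reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import annotation_io, association_analysis, composition_analysis
from . import igs_extraction, pairwise_alignment, similarity_graph
from . import spectral_clustering

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run; YAML-serializable."""

    genome: str = ""
    operons: Optional[str] = None
    scores: Optional[str] = None  # interaction score table (optional)
    categories: Optional[str] = None  # gene -> category table (optional)
    out_dir: str = "igscluster_run"
    window_length: int = igs_extraction.DEFAULT_WINDOW_LENGTH
    sds_search_len: int = igs_extraction.DEFAULT_SDS_SEARCH_LEN
    alignment_mode: str = "global"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    threshold_method: str = "self_shuffle"  # or 'global_shuffle'
    n_shuffles: int = 10
    n_iterations: int = 3
    k: Optional[int] = None  # None -> eigengap suggestion
    k_max: int = 20
    kmeans_tol: float = 1e-8
    n_init: int = 10
    smoothing_half_window: int = 15
    segment_min_len: int = 6
    score_threshold: int = 700
    n_resamples: int = 1000
    seed: int = 0
    atg_only: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return {k: v for k, v in self.__dict__.items()}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunResult:
    config: RunConfig
    records: list
    result: Optional[spectral_clustering.ClusteringResult]
    spectrum: Optional[spectral_clustering.LaplacianSpectrum]
    manifest: dict[str, Any] = field(default_factory=dict)


def run_full(config: RunConfig) -> RunResult:
    """Execute the five-step workflow and write all stage artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"config": config.to_dict(), "stages": {}}
    rng = np.random.default_rng(config.seed)

    # --- stage 1: extraction -------------------------------------------
    annotation = annotation_io.read_genbank(config.genome, config.atg_only)
    if config.operons:
        tus = annotation_io.read_operon_table(config.operons, annotation)
    else:
        logger.warning("no operon table: every gene becomes a singleton TU")
        tus = [annotation_io.TranscriptionUnit(g.gene_id, (g.gene_id,), g.gene_id)
               for g in annotation.genes]
    igrs = igs_extraction.compute_igrs(annotation, tus)
    rigrs = igs_extraction.compute_rigrs(annotation)
    records, log = igs_extraction.extract_igs_records(
        annotation, tus, config.window_length, config.sds_search_len)
    annotation_io.write_igs_fasta(records, out / "igs.fasta")
    pd.DataFrame([(r.anchor, r.length) for r in igrs]).to_csv(
        out / "igr_lengths.tsv", sep="\t", index=False, header=False)
    pd.DataFrame([(r.anchor, r.length) for r in rigrs]).to_csv(
        out / "rigr_lengths.tsv", sep="\t", index=False, header=False)
    manifest["stages"]["extract"] = {
        "n_tus": log.n_tus, "n_igs": log.n_igs,
        "sds_fraction": log.sds_fraction, "n_skipped": log.n_skipped,
        "rigr_rule_length": igs_extraction.choose_window_length(
            [r.length for r in rigrs]) if rigrs else None,
    }

    # --- stage 2: alignment --------------------------------------------
    params = pairwise_alignment.AlignmentParams(
        mode=config.alignment_mode, gap_open=config.gap_open,
        gap_extend=config.gap_extend)
    sim = pairwise_alignment.similarity_matrix(
        [r.sequence for r in records], [r.tu_id for r in records], params)
    sim.to_tsv(out / "similarity.tsv")

    # --- stage 3: threshold + adjacency --------------------------------
    seqs = [r.sequence for r in records]
    if config.threshold_method == "self_shuffle":
        thr = similarity_graph.estimate_threshold_self(
            seqs, params, config.n_shuffles, rng)
    else:
        thr = similarity_graph.estimate_threshold_global(
            seqs, params, config.n_iterations, rng)
    adj = similarity_graph.build_adjacency(sim, thr.s_star)
    pd.DataFrame([{"method": thr.method, "s_star": thr.s_star,
                   "n_iterations": thr.n_iterations,
                   "seed": config.seed}]).to_csv(
        out / "threshold.tsv", sep="\t", index=False)
    pd.DataFrame(adj.weights, index=adj.ids, columns=adj.ids).to_csv(
        out / "adjacency.tsv", sep="\t")
    manifest["stages"]["threshold"] = {
        "method": thr.method, "s_star": thr.s_star,
        "n_isolated": len(adj.isolated)}

    # --- stage 4: spectral clustering ----------------------------------
    ids, W = adj.connected_submatrix()
    result, spectrum, emb = spectral_clustering.cluster_graph(
        ids, W, k=config.k, k_max=config.k_max, tol=config.kmeans_tol,
        n_init=config.n_init, rng=rng)
    pd.DataFrame({"index": np.arange(1, len(spectrum.eigenvalues) + 1),
                  "eigenvalue": spectrum.eigenvalues}).to_csv(
        out / "spectrum.tsv", sep="\t", index=False)
    labels = {i: int(l) for i, l in zip(result.ids, result.labels)}
    rows = [{"igs_id": i, "cluster": f"C{labels[i]}" if i in labels
             else "unclustered"} for i in adj.ids]
    pd.DataFrame(rows).to_csv(out / "labels.tsv", sep="\t", index=False)
    pd.DataFrame({"igs_id": result.ids,
                  "silhouette": result.silhouettes}).to_csv(
        out / "silhouette.tsv", sep="\t", index=False)
    pd.DataFrame(emb.T, index=result.ids).to_csv(
        out / "embedding.tsv", sep="\t", header=False)
    manifest["stages"]["cluster"] = {
        "suggested_k": spectrum.suggested_k,
        "k_used": int(result.centroids.shape[0]),
        "cluster_sizes": {f"C{c}": int((result.labels == c).sum())
                          for c in sorted(set(result.labels))},
        "silhouette_means": result.cluster_silhouette_means,
        "n_unclustered": len(adj.isolated),
    }

    # --- stage 5: characterization -------------------------------------
    by_id = {r.tu_id: r for r in records}
    profiles = {}
    for c in sorted(set(result.labels)):
        members = [by_id[i] for i in result.members(c)]
        profile = composition_analysis.bca(members)
        smoothed = composition_analysis.smooth_bca(
            profile, config.smoothing_half_window)
        df = profile.to_frame()
        for x in composition_analysis.NUCLEOTIDES:
            df[f"rho_{x}_smoothed"] = smoothed.densities[x]
        df.to_csv(out / f"bca_C{c}.tsv", sep="\t", index=False)
        profiles[c] = profile
    clustered_records = [by_id[i] for i in result.ids]
    seg = composition_analysis.cluster_segment_summary(
        clustered_records, result.labels, config.segment_min_len)
    seg.to_csv(out / "segments.tsv", sep="\t", index=False)

    # --- optional stage 6: association ---------------------------------
    tu_genes = {tu.tu_id: list(tu.member_gene_ids) for tu in tus}
    if config.scores:
        scores = association_analysis.read_score_table(config.scores)
        graph = association_analysis.build_network(
            scores, config.score_threshold)
        igs_to_genes = {r.tu_id: tu_genes[r.tu_id] for r in records}
        net_rows = []
        for c in sorted(set(result.labels)):
            stats = association_analysis.resampling_null(
                graph, igs_to_genes, result.members(c),
                config.n_resamples, rng)
            net_rows.append({"cluster": f"C{c}", **stats.__dict__})
        pd.DataFrame(net_rows).to_csv(out / "network_stats.tsv", sep="\t",
                                      index=False)
        manifest["stages"]["network"] = {
            r["cluster"]: {"z_lcc": r["z_lcc"], "z_link": r["z_link"]}
            for r in net_rows}
    if config.categories:
        cat = association_analysis.read_category_table(config.categories)
        background = association_analysis.category_counts(list(cat), cat)
        enr_frames = []
        for c in sorted(set(result.labels)):
            genes = [g for i in result.members(c) for g in tu_genes[i]]
            counts = association_analysis.category_counts(genes, cat)
            df = association_analysis.binomial_enrichment(counts, background)
            df.insert(0, "cluster", f"C{c}")
            enr_frames.append(df)
        pd.concat(enr_frames, ignore_index=True).to_csv(
            out / "enrichment.tsv", sep="\t", index=False)

    # --- manifest -------------------------------------------------------
    manifest["checksums"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir())
        if p.suffix in (".tsv", ".fasta") and p.is_file()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    with open(out / "run.log", "w") as fh:
        fh.write(f"TUs: {log.n_tus}\nIGSs: {log.n_igs}\n"
                 f"SDS fraction: {log.sds_fraction:.4f}\n"
                 f"skipped: {log.n_skipped}\n"
                 f"threshold ({thr.method}): {thr.s_star:.3f}\n"
                 f"suggested k: {spectrum.suggested_k}\n")
    return RunResult(config, records, result, spectrum, manifest)
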