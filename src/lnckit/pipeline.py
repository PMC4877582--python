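"""End-to-end orchestration: catalog -> DE -> clustering -> targets -> enrichment.

A run is a pure function of (input files, configuration, seed): every stage
writes deterministic TSV/JSON outputs into the configured output directory
and the manifest records row counts and SHA-256 digests of every file, so
re-running with identical inputs is bit-identical (manifest hash equality).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation import AnnotationSet, exonic_overlap, read_gtf
from .catalog import FilterParams, build_catalog, catalog_stats, write_attrition, write_catalog
from .diffexp import call_de, hierarchical_cluster, intersect_common_de
from .expression import compute_fpkm, read_expression, read_two_column_tsv
from .targets import (
    cis_targets,
    hypergeometric_enrichment,
    neighbor_correlation_analysis,
    read_gmt,
    trans_targets,
    write_pairs,
)

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("lnckit")

STAGES = ("catalog", "de", "cluster", "targets", "neighbors", "enrich")

_INPUT_KEYS = (
    "assembled_gtf",
    "coding_gtf",
    "lnc_ref_gtf",
    "counts_tsv",
    "totals_tsv",
    "lengths_tsv",
    "groups_tsv",
)


@dataclass
class RunConfig:
    """Paths and thresholds of one pipeline run.

    The named thresholds carry the field-standard defaults: 200 nt minimum
    lncRNA length, FPKM >= 0.5 in at least one sample, a 100 kb cis window,
    |PCC| > 0.95 for trans pairing and adjusted P < 0.05 significance.
    """

    assembled_gtf: str
    coding_gtf: str
    lnc_ref_gtf: str
    counts_tsv: str
    totals_tsv: str
    lengths_tsv: str
    groups_tsv: str
    outdir: str
    scores_tsv: str | None = None
    gene_sets_gmt: str | None = None
    control_group: str = "control"
    case_groups: tuple[str, str] = ("eosinophilic", "noneosinophilic")
    alpha: float = 0.05
    min_length: int = 200
    min_exons_novel: int = 2
    min_fpkm: float = 0.5
    coding_score_max: float = 0.0
    cis_window: int = 100_000
    trans_pcc_min: float = 0.95
    fold_pseudocount: float = 1.0
    seed: int = 1

    def validate(self) -> None:
        missing = [
            key
            for key in (*_INPUT_KEYS, "scores_tsv", "gene_sets_gmt")
            if getattr(self, key) is not None and not Path(getattr(self, key)).exists()
        ]
        if missing:
            raise FileNotFoundError(
                "missing input files: "
                + ", ".join(f"{k}={getattr(self, k)}" for k in missing)
            )
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.cis_window < 0 or not 0 < self.trans_pcc_min <= 1:
            raise ValueError("cis_window must be >= 0 and trans_pcc_min in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "case_groups" in raw:
            raw["case_groups"] = tuple(raw["case_groups"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["case_groups"] = list(data["case_groups"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _coding_transcript_ids(assembled: AnnotationSet, coding_ref: AnnotationSet) -> set[str]:
    """Assembled transcripts that correspond to protein-coding models."""
    out = {t.transcript_id for t in assembled if t.biotype == "protein_coding"}
    by_chrom: dict[str, list] = {}
    for c in coding_ref:
        by_chrom.setdefault(c.chrom, []).append(c)
    for t in assembled:
        if t.transcript_id in out:
            continue
        for c in by_chrom.get(t.chrom, ()):
            if c.strand == t.strand and not (c.end <= t.start or c.start >= t.end):
                if exonic_overlap(t, c, strand_mode="same") > 0:
                    out.add(t.transcript_id)
                    break
    return out


def run_pipeline(cfg: RunConfig, through: str = "enrich") -> dict:
    """Execute the pipeline up to ``through`` (a stage name or ``"enrich"``).

    Stage order: catalog, de, cluster, targets, neighbors, enrich.  Returns
    the manifest (also written as ``manifest.json``) with per-output row
    counts, file digests and an overall run hash.
    """
    if through not in STAGES:
        raise ValueError(f"unknown stage: {through!r}; expected one of {STAGES}")
    cfg.validate()
    last = STAGES.index(through)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {**asdict(cfg), "case_groups": list(cfg.case_groups)},
                      "stages": {}, "outputs": {}}

    def record(name: str, path: Path, n_rows: int) -> None:
        manifest["outputs"][name] = {
            "path": path.name,
            "rows": int(n_rows),
            "sha256": _sha256(path),
        }

    t0 = time.perf_counter()
    assembled = read_gtf(cfg.assembled_gtf)
    coding_ref = read_gtf(cfg.coding_gtf)
    lnc_ref = read_gtf(cfg.lnc_ref_gtf)
    counts = read_expression(cfg.counts_tsv, cfg.groups_tsv, unit="fragments")
    totals = read_two_column_tsv(cfg.totals_tsv, float)
    lengths = read_two_column_tsv(cfg.lengths_tsv, int)
    scores = (
        read_two_column_tsv(cfg.scores_tsv, float) if cfg.scores_tsv else None
    )
    fpkm = compute_fpkm(counts, lengths, totals)
    log.info("load: %d transcripts, %d samples (%.2fs)",
             len(assembled), len(fpkm.samples), time.perf_counter() - t0)

    # --- catalog ----------------------------------------------------------
    t0 = time.perf_counter()
    params = FilterParams(
        min_length=cfg.min_length,
        min_exons_novel=cfg.min_exons_novel,
        min_fpkm=cfg.min_fpkm,
        coding_score_max=cfg.coding_score_max,
    )
    catalog, attrition = build_catalog(
        assembled, coding_ref, lnc_ref, fpkm, scores=scores, params=params
    )
    write_catalog(catalog, outdir / "catalog.tsv")
    write_attrition(attrition, outdir / "attrition.tsv")
    stats = catalog_stats(catalog, fpkm)
    stats_payload = {
        "n_transcripts": stats.n_transcripts,
        "n_loci": stats.n_loci,
        "mean_length": stats.mean_length,
        "mean_exons": stats.mean_exons,
        "isoforms_per_locus": stats.isoforms_per_locus,
        "class_counts": {f"{nov}:{cls}": n for (nov, cls), n in sorted(stats.class_counts.items())},
        "mean_log10_fpkm_overall": float(stats.mean_log10_fpkm.mean()),
    }
    (outdir / "catalog_stats.json").write_text(
        json.dumps(stats_payload, indent=2, sort_keys=True) + "\n"
    )
    record("catalog", outdir / "catalog.tsv", len(catalog))
    record("attrition", outdir / "attrition.tsv", len(attrition))
    record("catalog_stats", outdir / "catalog_stats.json", 1)
    manifest["stages"]["catalog"] = {"n_lncrna": len(catalog), "attrition": attrition}
    log.info("catalog: %d lncRNAs (%.2fs)", len(catalog), time.perf_counter() - t0)

    lnc_ids = {e.transcript.transcript_id for e in catalog}
    coding_ids = _coding_transcript_ids(assembled, coding_ref)
    locus_of = {t.transcript_id: t.locus_id for t in assembled}

    if last >= STAGES.index("de"):
        t0 = time.perf_counter()
        comparisons = [
            (cfg.case_groups[0], cfg.control_group),
            (cfg.case_groups[1], cfg.control_group),
            (cfg.case_groups[0], cfg.case_groups[1]),
        ]
        de_tables: dict[tuple[str, str], pd.DataFrame] = {}
        de_summary = {}
        for ga, gb in comparisons:
            de = call_de(fpkm, ga, gb, alpha=cfg.alpha, pseudocount=cfg.fold_pseudocount)
            de["is_lncrna"] = de["transcript_id"].isin(lnc_ids)
            de["is_mrna"] = de["transcript_id"].isin(coding_ids)
            name = f"de_{ga}_vs_{gb}.tsv"
            de.to_csv(outdir / name, sep="\t", index=False)
            de_tables[(ga, gb)] = de
            sig = de[de["significant"]]
            de_summary[f"{ga}_vs_{gb}"] = {
                "lncrna": {
                    "total": int((sig["is_lncrna"]).sum()),
                    "up": int((sig["is_lncrna"] & (sig["direction"] == "up")).sum()),
                    "down": int((sig["is_lncrna"] & (sig["direction"] == "down")).sum()),
                },
                "mrna": {
                    "total": int((sig["is_mrna"]).sum()),
                    "up": int((sig["is_mrna"] & (sig["direction"] == "up")).sum()),
                    "down": int((sig["is_mrna"] & (sig["direction"] == "down")).sum()),
                },
            }
            record(name, outdir / name, len(de))
        sig_mrna = [
            de_tables[(g, cfg.control_group)]
            .query("significant and is_mrna")["transcript_id"]
            .tolist()
            for g in cfg.case_groups
        ]
        common = intersect_common_de(sig_mrna[0], sig_mrna[1])
        pd.DataFrame({"transcript_id": common}).to_csv(
            outdir / "common_de_mrna.tsv", sep="\t", index=False
        )
        record("common_de_mrna", outdir / "common_de_mrna.tsv", len(common))
        manifest["stages"]["de"] = {"summary": de_summary, "n_common_mrna": len(common)}
        log.info("de: %s (%.2fs)", {k: v["mrna"]["total"] for k, v in de_summary.items()},
                 time.perf_counter() - t0)

    if last >= STAGES.index("cluster"):
        t0 = time.perf_counter()
        union_sig: list[str] = []
        for tbl in de_tables.values():
            union_sig.extend(tbl.query("significant")["transcript_id"].tolist())
        union_sig = list(dict.fromkeys(union_sig))
        cluster_info = {}
        if len(union_sig) >= 2:
            tree = hierarchical_cluster(fpkm, union_sig)
            (outdir / "clustering_de.nwk").write_text(tree.to_newick() + "\n")
            assignment = tree.cut(3)
            pd.DataFrame(
                {"sample_id": list(assignment), "cluster": list(assignment.values())}
            ).to_csv(outdir / "clusters_k3.tsv", sep="\t", index=False)
            record("clustering_de", outdir / "clustering_de.nwk", 1)
            record("clusters_k3", outdir / "clusters_k3.tsv", len(assignment))
            cluster_info["n_transcripts"] = len(union_sig)
        if len(common) >= 2:
            tree2 = hierarchical_cluster(fpkm, common)
            assignment2 = tree2.cut(2)
            pd.DataFrame(
                {"sample_id": list(assignment2), "cluster": list(assignment2.values())}
            ).to_csv(outdir / "clusters_common_k2.tsv", sep="\t", index=False)
            record("clusters_common_k2", outdir / "clusters_common_k2.tsv", len(assignment2))
        manifest["stages"]["cluster"] = cluster_info
        log.info("cluster: %d DE transcripts (%.2fs)", len(union_sig), time.perf_counter() - t0)

    # gene-level spans and expression for target prediction come from the
    # assembled coding transcripts (their ids carry the expression rows)
    coding_annot = AnnotationSet(t for t in assembled if t.transcript_id in coding_ids)
    if last >= STAGES.index("targets"):
        t0 = time.perf_counter()
        cis = cis_targets(catalog, coding_annot, fpkm, window=cfg.cis_window)
        trans = trans_targets(
            catalog, coding_annot, fpkm, pcc_min=cfg.trans_pcc_min, window=cfg.cis_window
        )
        write_pairs(cis, outdir / "cis_pairs.tsv")
        write_pairs(trans, outdir / "trans_pairs.tsv")
        record("cis_pairs", outdir / "cis_pairs.tsv", len(cis))
        record("trans_pairs", outdir / "trans_pairs.tsv", len(trans))
        manifest["stages"]["targets"] = {"n_cis": len(cis), "n_trans": len(trans)}
        log.info("targets: %d cis, %d trans (%.2fs)", len(cis), len(trans),
                 time.perf_counter() - t0)

    if last >= STAGES.index("neighbors"):
        t0 = time.perf_counter()
        summaries, pvalues = neighbor_correlation_analysis(
            catalog, coding_annot, fpkm, window=cfg.cis_window, seed=cfg.seed
        )
        rows = [
            {"pair_class": s.name, "n_pairs": s.n, "mean_pcc": s.mean_pcc}
            for s in summaries.values()
        ]
        pd.DataFrame(rows).to_csv(outdir / "neighbor_correlation.tsv", sep="\t", index=False)
        (outdir / "neighbor_tests.json").write_text(
            json.dumps(pvalues, indent=2, sort_keys=True) + "\n"
        )
        record("neighbor_correlation", outdir / "neighbor_correlation.tsv", len(rows))
        record("neighbor_tests", outdir / "neighbor_tests.json", len(pvalues))
        manifest["stages"]["neighbors"] = {
            s.name: {"n": s.n, "mean_pcc": s.mean_pcc} for s in summaries.values()
        }
        log.info("neighbors: %s (%.2fs)",
                 {s.name: round(s.mean_pcc, 3) for s in summaries.values()},
                 time.perf_counter() - t0)

    if last >= STAGES.index("enrich") and cfg.gene_sets_gmt:
        t0 = time.perf_counter()
        gene_sets = read_gmt(cfg.gene_sets_gmt)
        expressed = fpkm.values.max(axis=1) >= cfg.min_fpkm
        background = sorted(
            {
                locus_of[t]
                for t in fpkm.transcript_ids
                if t in coding_ids and expressed[t]
            }
        )
        enrich_info = {}
        for label, ids in {
            f"{cfg.case_groups[0]}_vs_{cfg.control_group}": sig_mrna[0],
            f"{cfg.case_groups[1]}_vs_{cfg.control_group}": sig_mrna[1],
            "common": common,
        }.items():
            foreground = sorted({locus_of[t] for t in ids if locus_of[t] in set(background)})
            results = hypergeometric_enrichment(
                foreground, background, gene_sets, alpha=cfg.alpha
            )
            df = pd.DataFrame(
                [
                    {
                        "term_id": r.term_id,
                        "k": r.k,
                        "K": r.K,
                        "n": r.n,
                        "N": r.N,
                        "p_raw": r.p_raw,
                        "q": r.q,
                        "rich_factor": r.rich_factor,
                        "significant": r.significant,
                    }
                    for r in results
                ]
            )
            name = f"enrichment_{label}.tsv"
            df.to_csv(outdir / name, sep="\t", index=False)
            record(name, outdir / name, len(df))
            enrich_info[label] = {
                "n_terms_tested": len(df),
                "n_significant": int(df["significant"].sum()) if len(df) else 0,
            }
        manifest["stages"]["enrich"] = enrich_info
        log.info("enrich: %s (%.2fs)", enrich_info, time.perf_counter() - t0)

    digest = hashlib.sha256(
        json.dumps(manifest["outputs"], sort_keys=True).encode()
    ).hexdigest()
    manifest["run_hash"] = digest
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
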