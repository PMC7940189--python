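"""Pipeline orchestration: gene sets -> sequences -> scan -> CT / GRRF -> report.

Each stage is re-runnable from its file interfaces; ``run_pipeline``
wires them for every requested cluster under one negative-set mode
(``non-ocr``: negatives lack a promoter-TSS peak and contribute fixed
TSS windows; ``ocr``: negatives carry a peak and contribute their OCR
sequence, like positives). Every output file records the configuration
hash; a JSON-lines log captures per-stage counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment, evaluation, gene_sets, scan, sequences
from .forest import ForestConfig

logger = logging.getLogger("motifcircuit")

NEGATIVE_MODES = ("non-ocr", "ocr")


@dataclass
class PipelineConfig:
    de_table: str
    peaks_bed: str
    tss_table: str
    genome_fasta: str
    motif_db: str
    out_dir: str
    clusters: list[str] | None = None
    negative_mode: str = "non-ocr"
    criteria: gene_sets.GeneSetCriteria = field(
        default_factory=gene_sets.GeneSetCriteria
    )
    p_threshold: float = scan.DEFAULT_P_THRESHOLD
    q_threshold: float = scan.DEFAULT_Q_THRESHOLD
    q_mode: str = "keep_le"
    forest: ForestConfig = field(default_factory=ForestConfig)
    gamma_grid: tuple = evaluation.DEFAULT_GAMMA_GRID
    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.negative_mode not in NEGATIVE_MODES:
            raise ValueError(f"negative_mode must be one of {NEGATIVE_MODES}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "criteria" in raw and isinstance(raw["criteria"], dict):
            raw["criteria"] = gene_sets.GeneSetCriteria(**raw["criteria"])
        if "forest" in raw and isinstance(raw["forest"], dict):
            raw["forest"] = ForestConfig(**raw["forest"])
        if "gamma_grid" in raw:
            raw["gamma_grid"] = tuple(raw["gamma_grid"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def validate_inputs(self) -> None:
        for name in ("de_table", "peaks_bed", "tss_table", "genome_fasta", "motif_db"):
            path = Path(getattr(self, name))
            if not path.exists():
                raise FileNotFoundError(f"missing input {name}: {path}")


@dataclass
class ClusterResult:
    cluster: str
    negative_mode: str
    positive_set: gene_sets.GeneSet
    negative_set: gene_sets.GeneSet
    matrix: scan.HitCountMatrix
    ct_table: pd.DataFrame
    ct_top10: list[str]
    report: evaluation.EvaluationReport
    curves: pd.DataFrame
    coverage: dict[str, list[float]]


def _scan_gene_set(
    genome,
    annotated_peaks,
    tss_table,
    gset: gene_sets.GeneSet,
    motifs,
    config: PipelineConfig,
    use_tss_windows: bool,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Extract, scan and BH-adjust one gene set; returns (hits, seq->gene)."""
    if use_tss_windows:
        seqs = sequences.extract_tss_windows(genome, tss_table, gset)
    else:
        seqs = sequences.extract_ocr_sequences(genome, annotated_peaks, gset)
    seq_map = {r.sequence_id: r.gene for r in seqs}
    hits = scan.scan_sequences(
        {r.sequence_id: r.sequence for r in seqs},
        motifs,
        p_threshold=config.p_threshold,
    )
    return scan.assign_qvalues(hits), seq_map


def run_cluster(config: PipelineConfig, cluster: str) -> ClusterResult:
    """Execute all stages for one cluster under one negative-set mode."""
    config.validate_inputs()
    de = gene_sets.read_de_table(config.de_table, cluster)
    if len(de) == 0:
        raise ValueError(f"cluster {cluster}: no DE rows")
    tss_table = gene_sets.read_tss_table(config.tss_table)
    peaks = gene_sets.read_peaks_bed(config.peaks_bed)
    annotated = gene_sets.annotate_promoter_tss(peaks, tss_table)
    logger.info(
        json.dumps({"stage": "annotate", "cluster": cluster,
                    "peaks": len(peaks),
                    "promoter_tss": sum(p.annotation_type == "promoter-TSS"
                                        for p in annotated)})
    )

    pos = gene_sets.select_positive(de, annotated, config.criteria, cluster=cluster)
    neg = gene_sets.select_negative(
        de,
        annotated,
        config.criteria,
        ocr_required=(config.negative_mode == "ocr"),
        cluster=cluster,
    )
    logger.info(
        json.dumps({"stage": "genesets", "cluster": cluster,
                    "positive": len(pos.genes), "negative": len(neg.genes),
                    "mode": config.negative_mode})
    )

    genome = sequences.open_genome(config.genome_fasta)
    motifs = scan.parse_meme(config.motif_db)
    motif_ids = [m.motif_id for m in motifs]

    pos_hits, pos_map = _scan_gene_set(
        genome, annotated, tss_table, pos, motifs, config, use_tss_windows=False
    )
    neg_hits, neg_map = _scan_gene_set(
        genome, annotated, tss_table, neg, motifs, config,
        use_tss_windows=(config.negative_mode == "non-ocr"),
    )
    gene_of_sequence = {**pos_map, **neg_map}
    labels = {g: "positive" for g in pos.genes}
    labels.update({g: neg.label for g in neg.genes})
    all_hits = pd.concat([pos_hits, neg_hits], ignore_index=True)
    matrix = scan.count_hits(
        all_hits,
        gene_of_sequence,
        labels,
        motif_ids,
        q_threshold=config.q_threshold,
        mode=config.q_mode,
    )
    logger.info(
        json.dumps({"stage": "scan", "cluster": cluster,
                    "hits": int(len(all_hits)),
                    "retained": int(matrix.counts.sum())})
    )

    pos_f, neg_f = gene_sets.finalize_gene_sets([pos, neg], matrix)
    kept = pos_f.genes + neg_f.genes
    matrix = matrix.subset_genes(kept)
    logger.info(
        json.dumps({"stage": "finalize", "cluster": cluster,
                    "positive": len(pos_f.genes), "negative": len(neg_f.genes)})
    )

    ct_table = enrichment.enrichment_table(matrix)
    ct_top10 = (
        enrichment.rank_ct(ct_table) if ct_table["tested"].any() else []
    )

    plan = evaluation.stratified_kfold(
        matrix.label_array(), k=config.k, seed=config.seed
    )
    report = evaluation.run_nested_cv(
        matrix, plan, config.gamma_grid, config.forest, cluster=cluster
    )
    logger.info(
        json.dumps({"stage": "grrf", "cluster": cluster,
                    "n_selected": report.n_selected,
                    "mean_test_auroc": report.mean_test_auroc})
    )

    rankings = {}
    if report.grrf_top10:
        rankings["RF"] = report.grrf_top10
    if ct_top10:
        rankings["CT"] = ct_top10
    curves = evaluation.topn_curves(rankings, matrix, plan, config.forest)
    coverage = {
        method: evaluation.coverage_curve(ranking, matrix, pos_f.genes)
        for method, ranking in rankings.items()
    }
    return ClusterResult(
        cluster=cluster,
        negative_mode=config.negative_mode,
        positive_set=pos_f,
        negative_set=neg_f,
        matrix=matrix,
        ct_table=ct_table,
        ct_top10=ct_top10,
        report=report,
        curves=curves,
        coverage=coverage,
    )


def _write_cluster_outputs(
    config: PipelineConfig, result: ClusterResult, out: Path
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    gene_sets.write_gene_sets_tsv([result.positive_set, result.negative_set],
                                  out / "gene_sets.tsv")
    result.matrix.write_tsv(out / "hit_counts.tsv")
    ct = result.ct_table.copy()
    ct["config_hash"] = chash
    ct.to_csv(out / "ct_enrichment.tsv", sep="\t", index=False)
    curves = result.curves.copy()
    curves["config_hash"] = chash
    curves.to_csv(out / "topn_curves.tsv", sep="\t", index=False)
    cov_rows = [
        {"method": m, "N": i + 1, "coverage": c, "config_hash": chash}
        for m, cc in result.coverage.items()
        for i, c in enumerate(cc)
    ]
    pd.DataFrame(cov_rows, columns=["method", "N", "coverage", "config_hash"]).to_csv(
        out / "coverage.tsv", sep="\t", index=False
    )
    grrf_rows = [
        {"motif": m, "importance": v, "config_hash": chash}
        for m, v in sorted(result.report.grrf_importances.items(),
                           key=lambda kv: (-kv[1], kv[0]))
    ]
    pd.DataFrame(grrf_rows, columns=["motif", "importance", "config_hash"]).to_csv(
        out / "grrf_features.tsv", sep="\t", index=False
    )
    payload = json.loads(result.report.to_json())
    payload["config_hash"] = chash
    payload["ct_top10"] = result.ct_top10
    with open(out / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> dict[str, ClusterResult]:
    """Run all stages for every requested cluster; writes the output bundle."""
    config.validate_inputs()
    de = pd.read_csv(config.de_table, sep="\t")
    clusters = config.clusters
    if clusters is None:
        clusters = (
            sorted(de["cluster"].unique()) if "cluster" in de.columns else ["cluster"]
        )
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_root / "pipeline.log.jsonl")
    handler.setLevel(logging.INFO)
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    results: dict[str, ClusterResult] = {}
    try:
        for cluster in clusters:
            result = run_cluster(config, cluster)
            _write_cluster_outputs(
                config, result, out_root / f"{cluster}_{config.negative_mode}"
            )
            results[cluster] = result
    finally:
        logger.removeHandler(handler)
        handler.close()
    return results


def compare_negative_modes(config: PipelineConfig) -> pd.DataFrame:
    """Mean test auROC per cluster for RF and CT under both negative modes.

    The RF value is the nested-CV mean test auROC of the tuned GRRF; the
    CT value is the mean test auROC of a plain forest trained on the CT
    top-10 motifs (the top-N curve at its largest N).
    """
    rows = []
    for mode in NEGATIVE_MODES:
        cfg = dataclasses.replace(config, negative_mode=mode,
                                  out_dir=str(Path(config.out_dir) / mode))
        results = run_pipeline(cfg)
        for cluster, res in results.items():
            rows.append(
                {
                    "cluster": cluster,
                    "mode": mode,
                    "method": "RF",
                    "auroc": res.report.mean_test_auroc,
                }
            )
            ct_curves = res.curves[res.curves["method"] == "CT"]
            if len(ct_curves):
                n_max = ct_curves["N"].max()
                ct_auroc = float(
                    ct_curves.loc[ct_curves["N"] == n_max, "auroc"].mean()
                )
            else:
                ct_auroc = np.nan
            rows.append(
                {"cluster": cluster, "mode": mode, "method": "CT", "auroc": ct_auroc}
            )
    table = pd.DataFrame(rows, columns=["cluster", "mode", "method", "auroc"])
    table.to_csv(Path(config.out_dir) / "negative_mode_comparison.tsv",
                 sep="\t", index=False)
    return table
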