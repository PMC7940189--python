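"""Positive / negative training-set construction for one cell cluster.

Positives are up-regulated cluster markers (fold change >= 1.5, adjusted
p < 0.05, expressed in >= 10% of the cluster's cells) whose promoter
carries an ATAC-seq open-chromatin region (OCR). Two alternative
negative backgrounds are built from non-markers (adjusted p > 0.1,
absolute fold change inside (1/1.5, 1.5)): negative set 1 lacks a
promoter-TSS OCR, negative set 2 has one. Genes with 0.05 <= adj_p <=
0.1 fall in the buffer between the two p-value thresholds and belong to
neither set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 100

DE_COLUMNS = ["gene", "avg_fold_change", "adj_p", "pct_expressed"]
TSS_COLUMNS = ["gene", "chrom", "tss", "strand", "transcript_length", "biotype"]


@dataclass
class PeakRecord:
    """An ATAC-seq peak, optionally annotated with a promoter target."""

    chrom: str
    start: int
    end: int
    name: str = "."
    annotation_type: str = "intergenic"
    target_gene: str = ""
    target_strand: str = "+"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: start >= end")


@dataclass
class GeneSetCriteria:
    min_pct: float = 0.10
    pos_max_adj_p: float = 0.05
    pos_min_fold: float = 1.5
    neg_min_adj_p: float = 0.1
    neg_fold_band: tuple[float, float] = (1.0 / 1.5, 1.5)

    def __post_init__(self) -> None:
        if not self.pos_max_adj_p < self.neg_min_adj_p:
            raise ValueError("positive p cutoff must be below negative p cutoff")
        if not self.pos_min_fold > 1:
            raise ValueError("positive fold threshold must exceed 1")


@dataclass
class GeneSet:
    cluster: str
    label: str  # positive | negative1 | negative2
    genes: list[str]
    criteria: GeneSetCriteria = field(default_factory=GeneSetCriteria)

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative1", "negative2"):
            raise ValueError(f"unknown gene-set label {self.label!r}")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene set contains duplicates")


def read_de_table(path, cluster: str | None = None) -> pd.DataFrame:
    de = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in de.columns]
    if missing:
        raise ValueError(f"DE table missing columns {missing}")
    if cluster is not None and "cluster" in de.columns:
        de = de[de["cluster"] == cluster].reset_index(drop=True)
    if np.any(de["avg_fold_change"] <= 0):
        raise ValueError("avg_fold_change must be positive (linear fold change)")
    for col, lo, hi in (("adj_p", 0, 1), ("pct_expressed", 0, 1)):
        if np.any((de[col] < lo) | (de[col] > hi)):
            raise ValueError(f"{col} outside [{lo}, {hi}]")
    return de


def read_tss_table(path) -> pd.DataFrame:
    tss = pd.read_csv(path, sep="\t")
    missing = [c for c in TSS_COLUMNS if c not in tss.columns]
    if missing:
        raise ValueError(f"TSS table missing columns {missing}")
    bad = set(tss["strand"]) - {"+", "-"}
    if bad:
        raise ValueError(f"TSS strands must be +/-, got {bad}")
    return tss


def read_peaks_bed(path) -> list[PeakRecord]:
    """Read a BED3+ / BED6 peak file (0-based half-open)."""
    peaks: list[PeakRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else "."
            peaks.append(PeakRecord(parts[0], int(parts[1]), int(parts[2]), name))
    return peaks


def write_peaks_bed(peaks: list[PeakRecord], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t+\n")


def representative_tss(tss_table: pd.DataFrame) -> pd.DataFrame:
    """One TSS row per gene: longest protein-coding transcript.

    Genes with no protein-coding transcript fall back to their longest
    transcript of any biotype; remaining ties are broken by transcript
    id when a ``transcript`` column exists, else by TSS position.
    """
    tiebreak = "transcript" if "transcript" in tss_table.columns else "tss"

    def _pick(group: pd.DataFrame) -> pd.Series:
        coding = group[group["biotype"] == "protein_coding"]
        pool = coding if len(coding) else group
        pool = pool.sort_values(
            ["transcript_length", tiebreak], ascending=[False, True]
        )
        return pool.iloc[0]

    reps = tss_table.groupby("gene", sort=True).apply(_pick, include_groups=False)
    reps = reps.reset_index()
    return reps[[c for c in tss_table.columns if c in reps.columns]]


def promoter_window(tss: int, strand: str, upstream: int = PROMOTER_UPSTREAM,
                    downstream: int = PROMOTER_DOWNSTREAM) -> tuple[int, int]:
    """Strand-aware promoter interval, 0-based half-open, endpoint-mirrored."""
    if strand == "+":
        return tss - upstream, tss + downstream
    return tss - downstream, tss + upstream


def annotate_promoter_tss(
    peaks: list[PeakRecord],
    tss_table: pd.DataFrame,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> list[PeakRecord]:
    """Label peaks overlapping a gene's promoter window as promoter-TSS.

    The window is [TSS-1000, TSS+100) on the gene's strand (the HOMER
    convention); when a peak overlaps several windows the gene whose TSS
    is nearest to the peak midpoint wins, ties broken lexicographically.
    """
    reps = representative_tss(tss_table)
    known_contigs = set(tss_table["chrom"])
    by_chrom: dict[str, pd.DataFrame] = {
        c: g.reset_index(drop=True) for c, g in reps.groupby("chrom")
    }
    out: list[PeakRecord] = []
    for peak in peaks:
        if peak.chrom not in known_contigs:
            raise ValueError(f"peak on unknown contig {peak.chrom!r}")
        annotated = PeakRecord(peak.chrom, peak.start, peak.end, peak.name)
        genes = by_chrom.get(peak.chrom)
        best: tuple[float, str, str] | None = None
        if genes is not None:
            mid = (peak.start + peak.end) / 2.0
            for row in genes.itertuples(index=False):
                ws, we = promoter_window(int(row.tss), row.strand, upstream, downstream)
                if peak.start < we and ws < peak.end:
                    cand = (abs(mid - row.tss), row.gene, row.strand)
                    if best is None or cand < best:
                        best = cand
        if best is not None:
            annotated.annotation_type = "promoter-TSS"
            annotated.target_gene = best[1]
            annotated.target_strand = best[2]
        out.append(annotated)
    return out


def _ocr_genes(annotated: list[PeakRecord]) -> set[str]:
    return {
        p.target_gene for p in annotated if p.annotation_type == "promoter-TSS"
    }


def select_positive(
    de: pd.DataFrame,
    annotated: list[PeakRecord],
    criteria: GeneSetCriteria | None = None,
    cluster: str = "cluster",
) -> GeneSet:
    """Up-regulated markers with an open promoter.

    Keeps genes with pct >= 10%, adjusted p < 0.05, fold change >= 1.5
    (the ">= " boundary is inclusive) and at least one promoter-TSS
    peak; output order is lexicographic.
    """
    crit = criteria or GeneSetCriteria()
    ocr = _ocr_genes(annotated)
    mask = (
        (de["pct_expressed"] >= crit.min_pct)
        & (de["adj_p"] < crit.pos_max_adj_p)
        & (de["avg_fold_change"] >= crit.pos_min_fold)
        & de["gene"].isin(ocr)
    )
    genes = sorted(de.loc[mask, "gene"].unique())
    if not genes:
        warnings.warn(f"cluster {cluster}: empty positive set")
    return GeneSet(cluster=cluster, label="positive", genes=genes, criteria=crit)


def select_negative(
    de: pd.DataFrame,
    annotated: list[PeakRecord],
    criteria: GeneSetCriteria | None = None,
    ocr_required: bool = False,
    cluster: str = "cluster",
) -> GeneSet:
    """Non-markers, split by promoter open chromatin.

    Keeps genes with pct >= 10%, adjusted p > 0.1 and absolute fold
    change strictly inside (1/1.5, 1.5); ``ocr_required=False`` keeps
    genes without a promoter-TSS peak (negative set 1),
    ``ocr_required=True`` keeps those with one (negative set 2).
    """
    crit = criteria or GeneSetCriteria()
    lo, hi = crit.neg_fold_band
    ocr = _ocr_genes(annotated)
    mask = (
        (de["pct_expressed"] >= crit.min_pct)
        & (de["adj_p"] > crit.neg_min_adj_p)
        & (de["avg_fold_change"] > lo)
        & (de["avg_fold_change"] < hi)
    )
    has_ocr = de["gene"].isin(ocr)
    mask &= has_ocr if ocr_required else ~has_ocr
    genes = sorted(de.loc[mask, "gene"].unique())
    label = "negative2" if ocr_required else "negative1"
    if not genes:
        warnings.warn(f"cluster {cluster}: empty {label} set")
    return GeneSet(cluster=cluster, label=label, genes=genes, criteria=crit)


def finalize_gene_sets(sets: list[GeneSet], hit_counts) -> list[GeneSet]:
    """Drop genes whose total hit count over all motifs is zero.

    The feature table only carries information for genes with at least
    one retained motif hit on their regulatory sequence.
    """
    frame = hit_counts.to_frame()
    rowsum = frame.sum(axis=1)
    nonzero = set(rowsum.index[rowsum > 0])
    return [
        GeneSet(
            cluster=s.cluster,
            label=s.label,
            genes=[g for g in s.genes if g in nonzero],
            criteria=s.criteria,
        )
        for s in sets
    ]


def write_gene_sets_tsv(sets: list[GeneSet], path) -> None:
    rows = [
        {"gene": g, "label": s.label, "cluster": s.cluster}
        for s in sets
        for g in s.genes
    ]
    pd.DataFrame(rows, columns=["gene", "label", "cluster"]).to_csv(
        path, sep="\t", index=False
    )
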