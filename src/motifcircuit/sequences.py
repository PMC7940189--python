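"""Regulatory sequence extraction.

Positive-set and negative-set-2 genes contribute their open chromatin
region(s) directly; negative-set-1 genes contribute a fixed window of
1,000 bp upstream to 220 bp downstream of the representative TSS. All
coordinates are 0-based half-open (BED convention) and sequences are
returned in gene-strand orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from pyfaidx import Fasta

from .gene_sets import GeneSet, PeakRecord, representative_tss
from .scan import reverse_complement

TSS_UPSTREAM = 1000
TSS_DOWNSTREAM = 220


@dataclass
class RegulatorySequence:
    gene: str
    source: str  # 'ocr' or 'tss_window'
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    truncated: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"{self.gene}: sequence length {len(self.sequence)} != interval "
                f"{self.end - self.start}"
            )

    @property
    def sequence_id(self) -> str:
        return f"{self.gene}|{self.source}|{self.chrom}:{self.start}-{self.end}({self.strand})"


def open_genome(path) -> Fasta:
    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


def _fetch(genome: Fasta, chrom: str, start: int, end: int, strand: str) -> str:
    seq = str(genome[chrom][start:end])
    return reverse_complement(seq) if strand == "-" else seq


def extract_ocr_sequences(
    genome: Fasta,
    peaks: list[PeakRecord],
    gene_set: GeneSet,
) -> list[RegulatorySequence]:
    """One record per (gene, promoter-TSS peak) for genes in the set.

    Genes with multiple peaks yield multiple records; hit counting later
    pools them per gene. Minus-strand genes get the reverse complement
    of the plus-strand slice.
    """
    by_gene: dict[str, list[PeakRecord]] = {}
    for p in peaks:
        if p.annotation_type == "promoter-TSS" and p.target_gene:
            by_gene.setdefault(p.target_gene, []).append(p)
    out: list[RegulatorySequence] = []
    for gene in gene_set.genes:
        gene_peaks = by_gene.get(gene)
        if not gene_peaks:
            raise ValueError(f"gene {gene} has no promoter-TSS peak")
        for p in sorted(gene_peaks, key=lambda q: (q.chrom, q.start, q.end)):
            if p.chrom not in genome:
                raise ValueError(f"peak contig {p.chrom} absent from genome")
            contig_len = len(genome[p.chrom])
            if p.end > contig_len:
                raise ValueError(
                    f"peak {p.chrom}:{p.start}-{p.end} beyond contig end {contig_len}"
                )
            out.append(
                RegulatorySequence(
                    gene=gene,
                    source="ocr",
                    chrom=p.chrom,
                    start=p.start,
                    end=p.end,
                    strand=p.target_strand,
                    sequence=_fetch(genome, p.chrom, p.start, p.end, p.target_strand),
                )
            )
    return out


def extract_tss_window(
    genome: Fasta,
    tss_record,
    upstream: int = TSS_UPSTREAM,
    downstream: int = TSS_DOWNSTREAM,
) -> RegulatorySequence:
    """Strand-aware [TSS-upstream, TSS+downstream) window, 1,220 bp by default.

    On the minus strand the interval endpoints are mirrored
    ([TSS-downstream, TSS+upstream)) and the sequence is reverse
    complemented. Windows are truncated (and flagged) at contig edges.
    """
    chrom = tss_record["chrom"] if isinstance(tss_record, (dict, pd.Series)) else tss_record.chrom
    gene = tss_record["gene"] if isinstance(tss_record, (dict, pd.Series)) else tss_record.gene
    tss = int(tss_record["tss"] if isinstance(tss_record, (dict, pd.Series)) else tss_record.tss)
    strand = tss_record["strand"] if isinstance(tss_record, (dict, pd.Series)) else tss_record.strand
    if chrom not in genome:
        raise ValueError(f"TSS contig {chrom} absent from genome")
    contig_len = len(genome[chrom])
    if strand == "+":
        start, end = tss - upstream, tss + downstream
    else:
        start, end = tss - downstream, tss + upstream
    cstart, cend = max(0, start), min(contig_len, end)
    return RegulatorySequence(
        gene=gene,
        source="tss_window",
        chrom=chrom,
        start=cstart,
        end=cend,
        strand=strand,
        sequence=_fetch(genome, chrom, cstart, cend, strand),
        truncated=(cstart != start or cend != end),
    )


def extract_tss_windows(
    genome: Fasta,
    tss_table: pd.DataFrame,
    gene_set: GeneSet,
    upstream: int = TSS_UPSTREAM,
    downstream: int = TSS_DOWNSTREAM,
) -> list[RegulatorySequence]:
    """TSS windows for every gene in the set (one representative TSS each)."""
    reps = representative_tss(tss_table).set_index("gene")
    out = []
    for gene in gene_set.genes:
        if gene not in reps.index:
            raise ValueError(f"gene {gene} absent from TSS table")
        row = reps.loc[gene]
        out.append(
            extract_tss_window(
                genome,
                {"gene": gene, "chrom": row["chrom"], "tss": row["tss"],
                 "strand": row["strand"]},
                upstream,
                downstream,
            )
        )
    return out


def write_fasta(records: list[RegulatorySequence], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.sequence_id}\n")
            for i in range(0, len(r.sequence), 80):
                fh.write(r.sequence[i : i + 80] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Plain FASTA reader returning id -> sequence (full header as id)."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs
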