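"""Synthetic fixture bundles with the statistical structure the method assumes.

A bundle emulates the three real inputs — a per-cluster differential
expression table, promoter-TSS open chromatin peaks with a genome, and
a motif database — as one self-describing directory: one contig per
gene, a TSS placed so the standard 1,000 bp upstream / 220 bp
downstream window fits, an OCR peak of the same length for positive and
negative-set-2 genes, and motif instances planted preferentially into
positive-set regulatory regions. A truth file records the planted motif
ids, per-site coordinates, and the expected gene sets, enabling both
gene-level and site-level recovery tests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .scan import MotifModel, write_meme

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_PAD = 400  # background padding on each side of the regulatory region
_JITTER = 100  # max shift of the OCR peak relative to the TSS window


@dataclass
class SyntheticConfig:
    n_positive: int = 200
    n_negative1: int = 200
    n_negative2: int = 0
    seq_length: int = 1220  # matches the -1,000/+220 TSS window
    planted_motif_ids: list[str] = field(default_factory=list)
    plant_rate_positive: float = 1.0  # expected instances per positive sequence
    plant_rate_negative: float = 0.0  # same for negative-set-1 windows
    plant_rate_negative2: float | None = None  # negative-set-2 OCRs; None -> rate_negative
    background_order: int = 0  # 0 or 1
    gc_content: float = 0.5
    markov_persistence: float = 0.25  # order-1 stickiness
    include_distractors: bool = True  # per-criterion violating genes
    plant_groups: list[tuple[list[str], float]] | None = None
    cluster: str = "C0"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_positive, self.n_negative1) <= 0 or self.n_negative2 < 0:
            raise ValueError("gene counts must be positive")
        if self.seq_length < 2:
            raise ValueError("seq_length must be >= 2")
        rates = [self.plant_rate_positive, self.plant_rate_negative]
        if self.plant_rate_negative2 is not None:
            rates.append(self.plant_rate_negative2)
        if any(r < 0 for r in rates):
            raise ValueError("plant rates must be >= 0")
        # upper bound inclusive so the all-GC degenerate background is usable
        if not 0.0 < self.gc_content <= 1.0:
            raise ValueError("gc_content must be in (0, 1]")
        if self.background_order not in (0, 1):
            raise ValueError("background_order must be 0 or 1")

    @property
    def upstream(self) -> int:
        return min(1000, self.seq_length - 1)

    @property
    def downstream(self) -> int:
        return self.seq_length - self.upstream

    def base_probs(self) -> np.ndarray:
        gc = self.gc_content
        return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


# ---------------------------------------------------------------------------
# motif database construction


def random_motif(motif_id: str, width: int, rng, concentration: float = 0.8) -> MotifModel:
    """A decoy motif: rows drawn from a symmetric Dirichlet."""
    ppm = rng.dirichlet([concentration] * 4, size=width)
    return MotifModel(motif_id=motif_id, ppm=ppm, nsites=20)


def strong_random_motif(
    motif_id: str, width: int, rng, dominance: float = 0.95
) -> MotifModel:
    """A high-information motif: one dominant base per column."""
    ppm = np.full((width, 4), (1.0 - dominance) / 3.0)
    dominant = rng.integers(0, 4, size=width)
    ppm[np.arange(width), dominant] = dominance
    return MotifModel(motif_id=motif_id, ppm=ppm, nsites=20)


def jitter_motif(motif: MotifModel, motif_id: str, rng, amount: float = 0.08) -> MotifModel:
    """A near-duplicate family variant: mix the PPM with Dirichlet noise."""
    noise = rng.dirichlet([1.0] * 4, size=motif.width)
    ppm = (1.0 - amount) * motif.ppm + amount * noise
    return MotifModel(motif_id=motif_id, ppm=ppm, nsites=motif.nsites)


def make_motif_database(
    n_motifs: int = 100,
    n_strong: int = 5,
    strong_width: int = 8,
    decoy_width_range: tuple[int, int] = (6, 12),
    dominance: float = 0.95,
    family_sizes: list[int] | None = None,
    seed: int = 0,
) -> list[MotifModel]:
    """Strong plantable motifs (PLANT*) plus Dirichlet decoys (DECOY*).

    ``family_sizes`` expands each strong motif into a family of jittered
    near-duplicates (PLANT1a, PLANT1b, ...), used to study redundancy.
    Total database size is ``n_motifs``.
    """
    rng = np.random.default_rng(seed)
    motifs: list[MotifModel] = []
    for i in range(n_strong):
        base = strong_random_motif(f"PLANT{i + 1}", strong_width, rng, dominance)
        motifs.append(base)
        if family_sizes is not None:
            for v in range(family_sizes[i] - 1):
                motifs.append(
                    jitter_motif(base, f"PLANT{i + 1}{chr(ord('b') + v)}", rng)
                )
    n_decoys = n_motifs - len(motifs)
    if n_decoys < 0:
        raise ValueError("n_motifs too small for the requested strong motifs")
    lo, hi = decoy_width_range
    for i in range(n_decoys):
        w = int(rng.integers(lo, hi + 1))
        motifs.append(random_motif(f"DECOY{i + 1:03d}", w, rng))
    return motifs


# ---------------------------------------------------------------------------
# sequence generation and planting


def generate_background_sequence(length: int, config: SyntheticConfig, rng) -> str:
    """Background DNA from the configured model (order 0 or 1 Markov)."""
    return _decode(_background_array(length, config, rng))


def _background_array(length: int, config: SyntheticConfig, rng) -> np.ndarray:
    if length <= 0:
        raise ValueError("length must be positive")
    probs = config.base_probs()
    iid = rng.choice(4, size=length, p=probs)
    if config.background_order == 0:
        return iid.astype(np.int8)
    # order 1: with probability rho repeat the previous base, else draw
    # from the stationary distribution (which is therefore preserved)
    stay = rng.random(length) < config.markov_persistence
    stay[0] = False
    src = np.where(~stay, np.arange(length), 0)
    np.maximum.accumulate(src, out=src)
    return iid[src].astype(np.int8)


def _decode(arr: np.ndarray) -> str:
    return bytes(_BASES[arr]).decode("ascii")


def sample_site(motif: MotifModel, rng) -> str:
    """Draw one binding site column-wise from the motif's PPM."""
    idx = np.array([rng.choice(4, p=row) for row in motif.ppm])
    return _decode(idx.astype(np.int8))


def plant_motif(sequence: str, motif: MotifModel, rng) -> tuple[str, int, str]:
    """Replace a uniformly chosen window with a sampled site.

    The strand is uniform; a minus-strand plant inserts the reverse
    complement of the sampled site. Returns the modified sequence and
    the ground-truth (position, strand).
    """
    from .scan import reverse_complement

    w = motif.width
    if w > len(sequence):
        raise ValueError(
            f"motif {motif.motif_id} (width {w}) wider than sequence ({len(sequence)})"
        )
    pos = int(rng.integers(0, len(sequence) - w + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    site = sample_site(motif, rng)
    inserted = site if strand == "+" else reverse_complement(site)
    new_seq = sequence[:pos] + inserted + sequence[pos + w :]
    return new_seq, pos, strand


# ---------------------------------------------------------------------------
# DE table


def _gene_names(config: SyntheticConfig) -> dict[str, list[str]]:
    names = {
        "positive": [f"POS{i + 1:04d}" for i in range(config.n_positive)],
        "negative1": [f"NEGA{i + 1:04d}" for i in range(config.n_negative1)],
        "negative2": [f"NEGB{i + 1:04d}" for i in range(config.n_negative2)],
    }
    names["distractor"] = (
        ["DIST_FOLD", "DIST_PBUF", "DIST_PCT", "DIST_NOOCR", "DIST_DOWN"]
        if config.include_distractors
        else []
    )
    return names


def generate_de_table(config: SyntheticConfig, rng) -> pd.DataFrame:
    """A DE table straddling the selection thresholds.

    Positives: fold >= 1.5, adj_p < 0.05, pct >= 0.10. Negatives: fold
    strictly inside (1/1.5, 1.5), adj_p > 0.1, pct >= 0.10. Optional
    distractor genes each violate exactly one criterion.
    """
    names = _gene_names(config)
    rows = []

    def add(gene, fold, adj_p, pct):
        rows.append(
            {
                "gene": gene,
                "avg_fold_change": round(float(fold), 6),
                "adj_p": round(float(adj_p), 8),
                "pct_expressed": round(float(pct), 4),
                "cluster": config.cluster,
            }
        )

    for g in names["positive"]:
        add(g, 1.5 + rng.exponential(0.8), rng.uniform(1e-6, 0.049),
            rng.uniform(0.10, 0.9))
    for g in names["negative1"] + names["negative2"]:
        add(g, rng.uniform(1.0 / 1.5 + 0.01, 1.49), rng.uniform(0.101, 1.0),
            rng.uniform(0.10, 0.9))
    if config.include_distractors:
        add("DIST_FOLD", 1.2, 0.01, 0.5)   # DEG-like p but fold below 1.5
        add("DIST_PBUF", 2.0, 0.08, 0.5)   # p in the (0.05, 0.1] buffer zone
        add("DIST_PCT", 2.0, 0.01, 0.05)   # expressed in too few cells
        add("DIST_NOOCR", 2.0, 0.01, 0.5)  # passes DE filters, lacks a peak
        add("DIST_DOWN", 0.5, 0.5, 0.5)    # fold outside the negative band
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundle assembly


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _assign_plant_groups(
    config: SyntheticConfig, positives: list[str]
) -> dict[str, list[str]]:
    """Map positive gene -> motif ids planted in it."""
    if config.plant_groups is None:
        return {g: list(config.planted_motif_ids) for g in positives}
    fracs = np.array([f for _, f in config.plant_groups], dtype=float)
    fracs = fracs / fracs.sum()
    bounds = np.floor(np.cumsum(fracs) * len(positives)).astype(int)
    out: dict[str, list[str]] = {}
    start = 0
    for (motif_ids, _), end in zip(config.plant_groups, bounds):
        for g in positives[start:end]:
            out[g] = list(motif_ids)
        start = end
    for g in positives[start:]:
        out[g] = list(config.plant_groups[-1][0])
    return out


def write_fixture_bundle(
    config: SyntheticConfig, motifs: list[MotifModel], out_dir
) -> dict:
    """Write the full on-disk bundle; returns the manifest.

    Files: genome.fa, tss.tsv, peaks.bed, de.tsv, motifs.meme,
    truth.json, manifest.json. Output is byte-identical for a fixed
    seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    by_id = {m.motif_id: m for m in motifs}
    missing = [m for m in config.planted_motif_ids if m not in by_id]
    if missing:
        raise ValueError(f"planted motif ids not in database: {missing}")

    names = _gene_names(config)
    u, d = config.upstream, config.downstream
    contig_len = config.seq_length + 2 * _PAD
    de = generate_de_table(config, rng)

    plant_map = _assign_plant_groups(config, names["positive"])
    rate2 = (
        config.plant_rate_negative2
        if config.plant_rate_negative2 is not None
        else config.plant_rate_negative
    )

    ordered_genes: list[tuple[str, str]] = (
        [(g, "positive") for g in names["positive"]]
        + [(g, "negative1") for g in names["negative1"]]
        + [(g, "negative2") for g in names["negative2"]]
        + [(g, "distractor") for g in names["distractor"]]
    )

    tss_rows = []
    peak_rows = []
    truth_sites = []
    fasta_path = out / "genome.fa"
    with open(fasta_path, "w") as fa:
        for gi, (gene, role) in enumerate(ordered_genes):
            strand = "+" if gi % 2 == 0 else "-"
            tss = u + _PAD if strand == "+" else d + _PAD
            arr = _background_array(contig_len, config, rng)
            # regulatory region = the TSS window on this contig
            if strand == "+":
                rstart, rend = tss - u, tss + d
            else:
                rstart, rend = tss - d, tss + u
            # peak interval (positives, negative2 and OCR distractors)
            has_peak = role in ("positive", "negative2") or gene in (
                "DIST_FOLD",
                "DIST_PBUF",
                "DIST_PCT",
            )
            if has_peak:
                shift = int(rng.integers(-_JITTER, _JITTER + 1))
                pstart, pend = rstart + shift, rend + shift
                peak_rows.append((gene, pstart, pend))
                signal_lo, signal_hi = pstart, pend
            else:
                signal_lo, signal_hi = rstart, rend
            # plant motifs
            if role == "positive":
                plant_spec = [(m, config.plant_rate_positive) for m in plant_map[gene]]
            elif role == "negative1":
                plant_spec = [
                    (m, config.plant_rate_negative) for m in config.planted_motif_ids
                ]
            elif role == "negative2":
                plant_spec = [(m, rate2) for m in config.planted_motif_ids]
            else:
                plant_spec = []
            seq = _decode(arr)
            for motif_id, rate in plant_spec:
                if rate <= 0:
                    continue
                motif = by_id[motif_id]
                k = int(rng.poisson(rate))
                for _ in range(k):
                    w = motif.width
                    region = seq[signal_lo : signal_hi]
                    planted, pos, pstrand = plant_motif(region, motif, rng)
                    seq = seq[:signal_lo] + planted + seq[signal_hi:]
                    truth_sites.append(
                        {
                            "gene": gene,
                            "chrom": gene,
                            "motif": motif_id,
                            "position": signal_lo + pos,
                            "strand": pstrand,
                            "width": w,
                        }
                    )
            fa.write(f">{gene}\n")
            for i in range(0, len(seq), 80):
                fa.write(seq[i : i + 80] + "\n")
            tss_rows.append(
                {
                    "gene": gene,
                    "chrom": gene,
                    "tss": tss,
                    "strand": strand,
                    "transcript_length": 1500,
                    "biotype": "protein_coding",
                }
            )

    tss_df = pd.DataFrame(tss_rows)
    tss_df.to_csv(out / "tss.tsv", sep="\t", index=False)
    de.to_csv(out / "de.tsv", sep="\t", index=False)
    with open(out / "peaks.bed", "w") as bed:
        for gene, s, e in peak_rows:
            bed.write(f"{gene}\t{s}\t{e}\tpeak_{gene}\t0\t+\n")
        # intergenic decoy peaks on a few contigs, far from any promoter
        for gene, _ in ordered_genes[:3]:
            bed.write(f"{gene}\t{contig_len - 150}\t{contig_len - 50}\t"
                      f"decoy_{gene}\t0\t+\n")
    write_meme(motifs, out / "motifs.meme")

    truth = {
        "planted_motifs": list(config.planted_motif_ids),
        "gene_sets": {
            "positive": names["positive"],
            "negative1": names["negative1"],
            "negative2": names["negative2"],
        },
        "sites": truth_sites,
        "cluster": config.cluster,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)

    cfg = asdict(config)
    files = ["genome.fa", "tss.tsv", "peaks.bed", "de.tsv", "motifs.meme", "truth.json"]
    manifest = {
        "config": cfg,
        "window": {"upstream": u, "downstream": d},
        "contig_length": contig_len,
        "files": {f: _sha256(out / f) for f in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
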