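"""Intron extraction from GFF3 annotation and log2 intron-size histograms.

Coordinates follow GFF3 semantics throughout: 1-based, inclusive. The intron
between consecutive exons is [prev_exon_end + 1, next_exon_start - 1], so
its size is next_start - prev_end - 1. Abutting exons yield no intron (the
case is counted, never emitted). Introns are reported in genomic
orientation: strand never alters coordinates.
"""

from __future__ import annotations

import logging
import os
import tempfile
from collections import Counter
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Transcript",
    "Gene",
    "AnnotationSet",
    "Intron",
    "SizeDistribution",
    "read_annotation",
    "extract_introns",
    "log2_histogram",
    "interval_density",
    "intron_table",
    "distribution_table",
]

TRANSCRIPT_TYPES = {"mRNA", "transcript", "primary_transcript"}


@dataclass
class Transcript:
    id: str
    exons: list[tuple[int, int]]  # genomic (start, end), 1-based inclusive


@dataclass
class Gene:
    id: str
    seqid: str
    strand: str
    transcripts: list[Transcript]


@dataclass
class AnnotationSet:
    """Genes -> transcripts -> exon intervals, plus skipped-record tallies."""

    genes: list[Gene]
    skipped: Counter = field(default_factory=Counter)


@dataclass(frozen=True)
class Intron:
    seqid: str
    start: int  # first intronic base
    end: int    # last intronic base
    strand: str
    transcript_ids: tuple[str, ...]

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass
class SizeDistribution:
    """Log2-binned intron-size histogram normalised to unit mass."""

    bin_width: float
    bin_edges: np.ndarray   # len = n_bins + 1, log2 bp
    densities: np.ndarray   # per-bin probability density
    n: int                  # introns counted

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2


def _sanitize_gff(path: str) -> tuple[str, Counter]:
    """Drop structurally malformed GFF3 lines, counting what was dropped.

    Parsing proper is delegated to gffutils; this pass only removes records
    gffutils cannot be allowed to ingest (bad column count, non-numeric or
    inverted coordinates), per-record rather than fatally.
    """
    skipped: Counter = Counter()
    kept: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                kept.append(line)
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                skipped["malformed_line"] += 1
                continue
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                skipped["malformed_coordinate"] += 1
                continue
            if end < start:
                skipped["malformed_coordinate"] += 1
                continue
            kept.append(line)
    return "".join(kept), skipped


def read_annotation(path: str, dialect: str = "auto") -> AnnotationSet:
    """Read a GFF3 file into genes/transcripts/exons linked by Parent.

    ``dialect`` ({"genbank", "refseq", "auto"}) is accepted for provenance;
    both NCBI flavours link features through ``Parent`` attributes, which is
    the mechanism used here, so ``auto`` needs no inspection beyond the
    attribute keys gffutils resolves. Features lacking a resolvable parent
    chain are skipped and counted; malformed coordinate records are skipped
    per-record. An unreadable file raises.
    """
    if dialect not in {"genbank", "refseq", "auto"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    text, skipped = _sanitize_gff(path)
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[Gene] = []
    linked_exons: set[str] = set()
    for gf in db.features_of_type("gene"):
        transcripts: list[Transcript] = []
        for tf in db.children(gf, level=1):
            if tf.featuretype not in TRANSCRIPT_TYPES:
                continue
            exons = []
            for ef in db.children(tf, featuretype="exon", level=1):
                exons.append((ef.start, ef.end))
                linked_exons.add(ef.id)
            exons.sort()
            transcripts.append(Transcript(id=tf.id, exons=exons))
        genes.append(
            Gene(id=gf.id, seqid=gf.seqid, strand=gf.strand,
                 transcripts=transcripts)
        )
    n_exons = sum(1 for _ in db.features_of_type("exon"))
    orphans = n_exons - len(linked_exons)
    if orphans:
        skipped["unparented_exon"] += orphans
        log.warning("skipped %d exon(s) with no resolvable parent", orphans)
    for key, cnt in skipped.items():
        if key != "unparented_exon":
            log.warning("skipped %d record(s): %s", cnt, key)
    return AnnotationSet(genes=genes, skipped=skipped)


def read_annotation_text(text: str, dialect: str = "auto") -> AnnotationSet:
    """Convenience wrapper over :func:`read_annotation` for in-memory GFF3."""
    with tempfile.NamedTemporaryFile(
        "w", suffix=".gff3", delete=False
    ) as fh:
        fh.write(text)
        tmp = fh.name
    try:
        return read_annotation(tmp, dialect=dialect)
    finally:
        os.unlink(tmp)


def extract_introns(ann: AnnotationSet, dedupe: bool = True) -> list[Intron]:
    """Introns between consecutive exons of each transcript.

    Exons are sorted by start within each transcript; a transcript with
    overlapping exons is skipped (counted). Abutting exons produce no intron
    (counted). With ``dedupe=True`` introns identical in (seqid, start, end,
    strand) are collapsed, pooling their transcript ids.
    """
    raw: dict[tuple[str, int, int, str], list[str]] = {}
    order: list[tuple[str, int, int, str]] = []
    for gene in ann.genes:
        for tr in gene.transcripts:
            exons = sorted(tr.exons)
            if any(
                exons[i][1] >= exons[i + 1][0]
                for i in range(len(exons) - 1)
            ):
                ann.skipped["overlapping_exons"] += 1
                log.warning(
                    "transcript %s skipped: overlapping exons", tr.id
                )
                continue
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                istart, iend = e1 + 1, s2 - 1
                if istart > iend:
                    ann.skipped["abutting_exons"] += 1
                    continue
                key = (gene.seqid, istart, iend, gene.strand)
                if dedupe:
                    if key not in raw:
                        order.append(key)
                    raw.setdefault(key, []).append(tr.id)
                else:
                    order.append(key)
                    raw.setdefault(key, []).append(tr.id)
    introns: list[Intron] = []
    if dedupe:
        for key in order:
            seqid, s, e, strand = key
            introns.append(
                Intron(seqid, s, e, strand, tuple(raw[key]))
            )
    else:
        seen: Counter = Counter()
        for key in order:
            seqid, s, e, strand = key
            tid = raw[key][seen[key]]
            seen[key] += 1
            introns.append(Intron(seqid, s, e, strand, (tid,)))
    return introns


def log2_histogram(
    sizes, bin_width: float = 0.25
) -> SizeDistribution:
    """Histogram of log2 sizes with edges anchored at integer log2 values.

    Bins are half-open [lo, lo + bin_width); densities are normalised so
    sum(density * bin_width) == 1.
    """
    sizes = np.asarray(sizes)
    if sizes.size == 0:
        raise ValueError("empty size list")
    if np.any(sizes < 1):
        raise ValueError("sizes must be >= 1 bp")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x = np.log2(sizes.astype(float))
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.floor(x.max() / bin_width) * bin_width + bin_width
    # anchor the grid at integer log2 values
    lo = np.floor(lo)
    n_bins = int(np.ceil((hi - lo) / bin_width - 1e-9))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    densities = counts / (sizes.size * bin_width)
    return SizeDistribution(
        bin_width=bin_width, bin_edges=edges, densities=densities,
        n=int(sizes.size),
    )


def interval_density(
    dist: SizeDistribution, lo: float, hi: float
) -> float:
    """Mean density over the bins covering [lo, hi).

    The interval must align with the bin grid (no interpolation); bins
    outside the histogram's support contribute zero density.
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    bw = dist.bin_width
    for bound in (lo, hi):
        offset = (bound - dist.bin_edges[0]) / bw
        if abs(offset - round(offset)) > 1e-9:
            raise ValueError(
                f"interval bound {bound} not aligned to the bin grid"
            )
    n_int = int(round((hi - lo) / bw))
    total = 0.0
    for i in range(n_int):
        b = lo + i * bw
        j = int(round((b - dist.bin_edges[0]) / bw))
        if 0 <= j < dist.densities.size:
            total += dist.densities[j]
    return total / n_int


def intron_table(introns: list[Intron]) -> pd.DataFrame:
    """Per-intron TSV-ready table (seqid, start, end, strand, size, n_transcripts)."""
    return pd.DataFrame(
        {
            "seqid": [i.seqid for i in introns],
            "start": [i.start for i in introns],
            "end": [i.end for i in introns],
            "strand": [i.strand for i in introns],
            "size": [i.size for i in introns],
            "n_transcripts": [len(i.transcript_ids) for i in introns],
        }
    )


def distribution_table(dist: SizeDistribution) -> pd.DataFrame:
    """Distribution TSV-ready table (bin_lo_log2, density)."""
    return pd.DataFrame(
        {"bin_lo_log2": dist.bin_edges[:-1], "density": dist.densities}
    )
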