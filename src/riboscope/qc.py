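"""Quality-control battery for ribosome profiling libraries.

Four checks, mirroring standard Ribo-seq practice: 3-nt periodicity of
5'-end positions around start/stop codons (per read length and pooled),
reading-frame occupancy of P-sites, footprint length distributions
(globally or restricted to 5'UTR / CDS / 3'UTR), and classification of
genome-aligned reads into exon / intron / intergenic — the latter two
being the signature of DNA contamination or other non-footprint
fragments.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
from intervaltree import IntervalTree

from .annotation import GenomeAnnotation, TranscriptCatalog
from .density import PsiteOffsetTable, ReadAlignment

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# periodicity
# ---------------------------------------------------------------------------

@dataclass
class PeriodicityProfile:
    """5'-end count histograms around start and stop codons.

    Keys are read lengths plus the pooled key ``"all"``; position 0 is the
    first nucleotide of the start (resp. stop) codon.  When an offset table
    is supplied, the pooled histogram sums only accepted lengths after
    shifting each by its P-site offset, i.e. reads aligned by their
    P-sites.
    """

    window: Tuple[int, int]
    start_counts: Dict[object, np.ndarray] = field(default_factory=dict)
    stop_counts: Dict[object, np.ndarray] = field(default_factory=dict)
    in_frame_fraction: Dict[int, float] = field(default_factory=dict)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.window[0], self.window[1] + 1)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("anchor\tread_length\tposition\tcount\n")
            for anchor, table in (("start", self.start_counts), ("stop", self.stop_counts)):
                for key in sorted(table, key=str):
                    for pos, c in zip(self.positions, table[key]):
                        fh.write(f"{anchor}\t{key}\t{pos}\t{int(c)}\n")


def periodicity_profile(
    alignments: Iterable[ReadAlignment],
    catalog: TranscriptCatalog,
    window: Tuple[int, int] = (-50, 50),
    offsets: Optional[PsiteOffsetTable] = None,
) -> PeriodicityProfile:
    """Histogram 5' ends around start and stop codons, per read length.

    The per-length in-frame fraction is the share of window counts landing
    in the modal frame (positions congruent to the start-anchored mode
    modulo 3).
    """
    lo, hi = window
    n = hi - lo + 1
    prof = PeriodicityProfile(window)
    got_any = False
    for aln in alignments:
        entry = catalog.get(aln.reference)
        if entry is None or aln.strand != "+":
            continue
        got_any = True
        five = aln.position
        for anchor_pos, table in ((entry.cds_start, prof.start_counts),
                                  (entry.cds_end - 3, prof.stop_counts)):
            rel = five - anchor_pos
            if lo <= rel <= hi:
                if aln.length not in table:
                    table[aln.length] = np.zeros(n, dtype=int)
                table[aln.length][rel - lo] += 1
    if not got_any:
        logger.warning("periodicity profile: no usable transcriptome alignments")
        return prof

    for L, counts in prof.start_counts.items():
        total = counts.sum()
        if total == 0:
            continue
        mode = int(np.argmax(counts))
        frame_mask = (np.arange(n) % 3) == (mode % 3)
        prof.in_frame_fraction[L] = float(counts[frame_mask].sum() / total)

    # pooled histogram: P-site aligned when offsets available
    for table in (prof.start_counts, prof.stop_counts):
        pooled = np.zeros(n, dtype=int)
        for L, counts in list(table.items()):
            if offsets is not None:
                if L not in offsets:
                    continue
                shifted = np.zeros(n, dtype=int)
                off = offsets[L]
                src = np.arange(n)
                dst = src + off
                ok = dst < n
                shifted[dst[ok]] = counts[src[ok]]
                pooled += shifted
            else:
                pooled += counts
        table["all"] = pooled
    return prof


# ---------------------------------------------------------------------------
# reading frames
# ---------------------------------------------------------------------------

def frame_density(psites: Iterable[Tuple[str, int]], catalog: TranscriptCatalog) -> np.ndarray:
    """Fraction of CDS P-sites in each reading frame {0, 1, 2}.

    Frame = (P-site nt − CDS start) mod 3; P-sites outside the CDS are
    ignored.  The three fractions sum to 1.
    """
    counts = np.zeros(3)
    for tid, p in psites:
        entry = catalog.get(tid)
        if entry is None or not entry.cds_start <= p < entry.cds_end:
            continue
        counts[(p - entry.cds_start) % 3] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no P-sites inside any CDS; cannot compute frame densities")
    return counts / total


# ---------------------------------------------------------------------------
# length distributions
# ---------------------------------------------------------------------------

def length_distribution(
    alignments: Iterable[ReadAlignment],
    region: str = "all",
    catalog: Optional[TranscriptCatalog] = None,
    offsets: Optional[PsiteOffsetTable] = None,
) -> Counter:
    """Read-length histogram, optionally restricted to a transcript region.

    Region membership is decided by the read's P-site when an offset table
    is given, otherwise by its 5' end.  ``region="all"`` counts every
    alignment and needs no catalog.
    """
    if region not in ("all", "5utr", "cds", "3utr"):
        raise ValueError(f"unknown region {region!r}")
    hist: Counter = Counter()
    for aln in alignments:
        if region == "all":
            hist[aln.length] += 1
            continue
        if catalog is None:
            raise ValueError("region-restricted histogram needs the catalog")
        entry = catalog.get(aln.reference)
        if entry is None or aln.strand != "+":
            continue
        pos = aln.five_prime
        if offsets is not None:
            if aln.length not in offsets:
                continue
            pos += offsets[aln.length]
        if not 0 <= pos < entry.length:
            continue
        in_region = (
            (region == "5utr" and pos < entry.cds_start)
            or (region == "cds" and entry.cds_start <= pos < entry.cds_end)
            or (region == "3utr" and pos >= entry.cds_end)
        )
        if in_region:
            hist[aln.length] += 1
    return hist


# ---------------------------------------------------------------------------
# genomic region contamination
# ---------------------------------------------------------------------------

@dataclass
class RegionStats:
    """Exon/intron/intergenic read counts plus per-region length histograms."""

    counts: Dict[str, int] = field(default_factory=lambda: {"exon": 0, "intron": 0,
                                                            "intergenic": 0})
    length_hists: Dict[str, Counter] = field(default_factory=lambda: {
        "exon": Counter(), "intron": Counter(), "intergenic": Counter()})

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("region\tread_length\tcount\n")
            for region in ("exon", "intron", "intergenic"):
                fh.write(f"{region}\ttotal\t{self.counts[region]}\n")
                for L in sorted(self.length_hists[region]):
                    fh.write(f"{region}\t{L}\t{self.length_hists[region][L]}\n")


def genomic_region_stats(
    genome_alignments: Iterable[ReadAlignment],
    annotation: GenomeAnnotation,
) -> RegionStats:
    """Classify genome-aligned reads as exon, intron or intergenic.

    Classification is by the read's 5'-end nucleotide, giving an exact
    three-way partition: exon if it falls in any annotated exon (union over
    all transcripts, not just the chosen ones), else intron if inside any
    gene body, else intergenic.  Reads on chromosomes missing from the
    annotation count as intergenic with a warning.
    """
    exon_trees: Dict[str, IntervalTree] = {}
    gene_trees: Dict[str, IntervalTree] = {}
    gene_spans: Dict[str, Tuple[str, int, int]] = {}
    for model in annotation.transcripts.values():
        if not model.exons:
            continue
        tree = exon_trees.setdefault(model.chrom, IntervalTree())
        for s, e in model.exons:
            tree.addi(s, e)
        lo, hi = model.exons[0][0], model.exons[-1][1]
        if model.gene_id in gene_spans:
            c, a, b = gene_spans[model.gene_id]
            gene_spans[model.gene_id] = (c, min(a, lo), max(b, hi))
        else:
            gene_spans[model.gene_id] = (model.chrom, lo, hi)
    for chrom, lo, hi in gene_spans.values():
        gene_trees.setdefault(chrom, IntervalTree()).addi(lo, hi)

    stats = RegionStats()
    warned = set()
    for aln in genome_alignments:
        chrom = aln.reference
        pos = aln.five_prime
        if chrom not in exon_trees and chrom not in gene_trees:
            if annotation.chromosomes and chrom not in annotation.chromosomes \
                    and chrom not in warned:
                logger.warning("chromosome %s absent from annotation; reads counted "
                               "intergenic", chrom)
                warned.add(chrom)
            region = "intergenic"
        elif chrom in exon_trees and exon_trees[chrom].overlaps_point(pos):
            region = "exon"
        elif chrom in gene_trees and gene_trees[chrom].overlaps_point(pos):
            region = "intron"
        else:
            region = "intergenic"
        stats.counts[region] += 1
        stats.length_hists[region][aln.length] += 1
    return stats
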