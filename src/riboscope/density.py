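"""P-site resolved ribosome footprint densities.

The core data flow of every downstream analysis: transcriptome-aligned
ribosome-protected fragments (RPFs) are reduced to single-nucleotide P-site
positions using per-read-length offsets calibrated from the 3-nt
periodicity around annotated start codons, then accumulated into
per-transcript density vectors in nucleotide or codon units.

Offset calibration exploits the fact that initiating ribosomes pile up on
the start codon: for each read length the 5'-end positions relative to the
start codon show a sharp mode a fixed distance upstream (typically 12-13
nt), and that distance is the P-site offset.  Lengths whose 5'-end
distribution is not phased (in-frame fraction at the mode below a
threshold) are rejected as non-ribosomal.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np
import pysam

from .annotation import TranscriptCatalog

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadAlignment:
    """A mapped read reduced to what density building needs."""

    read_id: str
    reference: str
    position: int  # leftmost, 0-based
    length: int    # read length in nt
    strand: str    # '+' or '-'
    #: one past the rightmost aligned base; differs from position + length
    #: for spliced (N-containing) genome alignments
    reference_end: int = -1

    @property
    def five_prime(self) -> int:
        """5'-end position of the read on the reference."""
        if self.strand == "+":
            return self.position
        end = self.reference_end if self.reference_end >= 0 else self.position + self.length
        return end - 1


def iter_alignments(path, require_forward: bool = False) -> Iterator[ReadAlignment]:
    """Yield primary alignments from a SAM/BAM file.

    Secondary and supplementary records are dropped (each fragment counts
    once).  ``require_forward`` additionally drops reverse-strand records,
    which on a transcriptome reference are mis-mapped fragments.
    """
    save = pysam.set_verbosity(0)  # silence missing-index chatter
    mode = "r" if str(path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        pysam.set_verbosity(save)
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            strand = "-" if rec.is_reverse else "+"
            if require_forward and strand == "-":
                continue
            length = rec.query_length or rec.infer_query_length() or 0
            if length <= 0:
                continue
            yield ReadAlignment(rec.query_name, rec.reference_name,
                                rec.reference_start, length, strand,
                                rec.reference_end if rec.reference_end is not None
                                else rec.reference_start + length)


# ---------------------------------------------------------------------------
# P-site offsets
# ---------------------------------------------------------------------------

@dataclass
class PsiteOffsetTable:
    """Read length -> distance (nt) from the read 5' end to the P-site."""

    offsets: Dict[int, int]
    in_frame_fraction: Dict[int, float] = field(default_factory=dict)
    rejected: Dict[int, str] = field(default_factory=dict)

    def __contains__(self, length: int) -> bool:
        return length in self.offsets

    def __getitem__(self, length: int) -> int:
        return self.offsets[length]

    @property
    def accepted_lengths(self) -> Tuple[int, ...]:
        return tuple(sorted(self.offsets))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("length\toffset\tin_frame_fraction\taccepted\n")
            lengths = sorted(set(self.offsets) | set(self.rejected))
            for L in lengths:
                if L in self.offsets:
                    fh.write(f"{L}\t{self.offsets[L]}\t"
                             f"{self.in_frame_fraction.get(L, float('nan')):.4f}\tyes\n")
                else:
                    fh.write(f"{L}\tNA\t{self.in_frame_fraction.get(L, float('nan')):.4f}\tno\n")

    @classmethod
    def read_tsv(cls, path) -> "PsiteOffsetTable":
        offsets, frac, rejected = {}, {}, {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                L, off, f, acc = line.rstrip("\n").split("\t")
                L = int(L)
                if f not in ("nan", "NA"):
                    frac[L] = float(f)
                if acc == "yes":
                    offsets[L] = int(off)
                else:
                    rejected[L] = "rejected"
        return cls(offsets, frac, rejected)


def start_codon_meta_counts(
    alignments: Iterable[ReadAlignment],
    catalog: TranscriptCatalog,
    window: Tuple[int, int] = (-50, 50),
) -> Dict[int, Counter]:
    """Per read length, counts of 5' ends at each position relative to the
    start codon (position 0 = first nt of the start codon), pooled over all
    catalog transcripts."""
    lo, hi = window
    tallies: Dict[int, Counter] = {}
    for aln in alignments:
        entry = catalog.get(aln.reference)
        if entry is None or aln.strand != "+":
            continue
        rel = aln.position - entry.cds_start
        if lo <= rel <= hi:
            tallies.setdefault(aln.length, Counter())[rel] += 1
    return tallies


def infer_psite_offsets(
    alignments: Iterable[ReadAlignment],
    catalog: TranscriptCatalog,
    length_range: Tuple[int, int] = (25, 35),
    search_window: Tuple[int, int] = (-18, -6),
    min_in_frame: float = 0.5,
) -> PsiteOffsetTable:
    """Calibrate P-site offsets from 5'-end phasing at start codons.

    For each read length L in ``length_range``, the modal 5'-end position m
    is searched in ``search_window`` upstream of the start codon and the
    offset is -m.  The length is accepted only when the local in-frame
    fraction count(m) / (count(m-1)+count(m)+count(m+1)) reaches
    ``min_in_frame``; unphased lengths (e.g. contaminating fragments with
    random 5' ends) fail this screen.
    """
    tallies = start_codon_meta_counts(alignments, catalog,
                                      window=(search_window[0] - 2, search_window[1] + 2))
    if not any(tallies.values()):
        raise ValueError("no transcriptome alignments near start codons; "
                         "cannot calibrate P-site offsets")
    offsets: Dict[int, int] = {}
    fracs: Dict[int, float] = {}
    rejected: Dict[int, str] = {}
    for L in range(length_range[0], length_range[1] + 1):
        counts = tallies.get(L)
        if not counts:
            continue
        in_window = {pos: n for pos, n in counts.items()
                     if search_window[0] <= pos <= search_window[1]}
        if not in_window:
            rejected[L] = "no 5' ends in search window"
            continue
        # deterministic mode: highest count, then most upstream position
        mode = min(in_window, key=lambda p: (-in_window[p], p))
        local = counts[mode] + counts.get(mode - 1, 0) + counts.get(mode + 1, 0)
        frac = counts[mode] / local
        fracs[L] = frac
        if frac < min_in_frame:
            rejected[L] = f"in-frame fraction {frac:.3f} < {min_in_frame}"
            logger.info("read length %d rejected: %s", L, rejected[L])
            continue
        offsets[L] = -mode
    if not offsets:
        raise ValueError("no read length passed the periodicity screen; "
                         "supply offsets manually")
    return PsiteOffsetTable(offsets, fracs, rejected)


# ---------------------------------------------------------------------------
# P-site assignment
# ---------------------------------------------------------------------------

@dataclass
class AssignmentStats:
    assigned: int = 0
    skipped_unlisted_length: int = 0
    skipped_outside: int = 0

    @property
    def total(self) -> int:
        return self.assigned + self.skipped_unlisted_length + self.skipped_outside


def assign_psites(
    alignments: Iterable[ReadAlignment],
    offsets: PsiteOffsetTable,
    catalog: Optional[TranscriptCatalog] = None,
) -> Tuple[List[Tuple[str, int]], AssignmentStats]:
    """Map each read to its P-site nucleotide: 5' end + offset(length).

    Reads whose length has no calibrated offset, or whose P-site falls
    outside the transcript, are skipped and tallied so that
    assigned + skipped == input reads always holds.
    """
    psites: List[Tuple[str, int]] = []
    stats = AssignmentStats()
    for aln in alignments:
        if aln.length not in offsets:
            stats.skipped_unlisted_length += 1
            continue
        p = aln.five_prime + offsets[aln.length] if aln.strand == "+" else \
            aln.five_prime - offsets[aln.length]
        limit = None
        if catalog is not None:
            entry = catalog.get(aln.reference)
            if entry is None:
                stats.skipped_outside += 1
                continue
            limit = entry.length
        if p < 0 or (limit is not None and p >= limit):
            stats.skipped_outside += 1
            continue
        psites.append((aln.reference, p))
        stats.assigned += 1
    return psites, stats


# ---------------------------------------------------------------------------
# density vectors
# ---------------------------------------------------------------------------

@dataclass
class DensityVector:
    """Per-position P-site density for one transcript."""

    transcript_id: str
    unit: str                      # 'nt' or 'codon'
    values: np.ndarray             # non-negative; raw vectors are integral
    normalization: str = "raw"     # raw | per_mean | rpm

    def copy(self) -> "DensityVector":
        return DensityVector(self.transcript_id, self.unit,
                             self.values.copy(), self.normalization)

    @property
    def total(self) -> float:
        return float(self.values.sum())


class DensitySet:
    """Density vectors for many transcripts plus per-transcript UTR tallies."""

    def __init__(self, vectors: Dict[str, DensityVector], unit: str,
                 library_size: int,
                 utr5_counts: Optional[Dict[str, int]] = None,
                 utr3_counts: Optional[Dict[str, int]] = None,
                 normalization: str = "raw"):
        self.vectors = vectors
        self.unit = unit
        self.library_size = library_size
        self.utr5_counts = utr5_counts or {}
        self.utr3_counts = utr3_counts or {}
        self.normalization = normalization

    def __len__(self):
        return len(self.vectors)

    def __iter__(self):
        return iter(self.vectors.values())

    def __contains__(self, tid):
        return tid in self.vectors

    def __getitem__(self, tid) -> DensityVector:
        return self.vectors[tid]

    def get(self, tid) -> Optional[DensityVector]:
        return self.vectors.get(tid)

    def write_tsv(self, path) -> None:
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            fh.write(f"# unit={self.unit} normalization={self.normalization} "
                     f"library_size={self.library_size}\n")
            fh.write("transcript_id\tutr5_count\tutr3_count\tvalues\n")
            for tid in sorted(self.vectors):
                vals = ",".join(format(v, ".6g") for v in self.vectors[tid].values)
                fh.write(f"{tid}\t{self.utr5_counts.get(tid, 0)}\t"
                         f"{self.utr3_counts.get(tid, 0)}\t{vals}\n")

    @classmethod
    def read_tsv(cls, path) -> "DensitySet":
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            header = fh.readline().lstrip("# ").split()
            meta = dict(kv.split("=") for kv in header)
            fh.readline()
            vectors, u5, u3 = {}, {}, {}
            for line in fh:
                tid, a, b, vals = line.rstrip("\n").split("\t")
                arr = np.array([float(x) for x in vals.split(",")]) if vals else np.array([])
                vectors[tid] = DensityVector(tid, meta["unit"], arr, meta["normalization"])
                u5[tid], u3[tid] = int(a), int(b)
        return cls(vectors, meta["unit"], int(meta["library_size"]), u5, u3,
                   meta["normalization"])


def build_density_vectors(
    psites: Iterable[Tuple[str, int]],
    catalog: TranscriptCatalog,
    unit: str = "codon",
) -> DensitySet:
    """Accumulate P-sites into per-transcript density vectors.

    In codon units a P-site nucleotide inside the CDS lands in codon
    ``(nt - utr5_len) // 3 + 1`` (1-based; the stop codon is the last
    element so counts are conserved), while P-sites in the UTRs go to
    separate per-transcript tallies used by the 5'UTR/CDS ratio analysis.
    In nt units the vector spans the whole transcript.
    """
    if unit not in ("nt", "codon"):
        raise ValueError(f"unknown unit {unit!r}")
    arrays: Dict[str, np.ndarray] = {}
    u5: Dict[str, int] = {}
    u3: Dict[str, int] = {}
    n = 0
    for tid, p in psites:
        entry = catalog.get(tid)
        if entry is None:
            continue
        n += 1
        if tid not in arrays:
            size = entry.length if unit == "nt" else entry.n_codons
            arrays[tid] = np.zeros(size)
            u5[tid] = u3[tid] = 0
        if unit == "nt":
            arrays[tid][p] += 1
        else:
            if p < entry.cds_start:
                u5[tid] += 1
            elif p >= entry.cds_end:
                u3[tid] += 1
            else:
                arrays[tid][(p - entry.cds_start) // 3] += 1
    vectors = {tid: DensityVector(tid, unit, arr) for tid, arr in arrays.items()}
    return DensitySet(vectors, unit, library_size=n, utr5_counts=u5, utr3_counts=u3)


def normalize_density(
    vector: DensityVector,
    mode: str,
    library_size: Optional[int] = None,
    catalog: Optional[TranscriptCatalog] = None,
    trim: int = 0,
) -> DensityVector:
    """Return a normalized copy of a density vector.

    ``per_mean`` divides by the mean CDS value so the transcript-relative
    density averages 1.  The normalizer runs over sense codons only (the
    stop codon is excluded — AA-level analyses have no stop residue, and
    excluding it makes pooled identity means conserve exactly); ``trim``
    additionally excludes the first/last ``trim`` codons (start/stop
    pile-ups would deflate the rest).  The returned vector still covers
    every position.  ``rpm`` scales raw counts to reads per million using
    ``library_size``.
    """
    out = vector.copy()
    if mode == "rpm":
        if not library_size:
            raise ValueError("rpm normalization needs a library size")
        out.values = out.values * (1e6 / library_size)
        out.normalization = "rpm"
        return out
    if mode != "per_mean":
        raise ValueError(f"unknown normalization {mode!r}")
    if vector.unit == "codon":
        cds_vals = vector.values[:-1] if len(vector.values) > 1 else vector.values
    else:
        if catalog is None or vector.transcript_id not in catalog:
            raise ValueError("per_mean on nt vectors needs the catalog for CDS bounds")
        e = catalog[vector.transcript_id]
        cds_vals = vector.values[e.cds_start:e.cds_end]
    core = cds_vals[trim: len(cds_vals) - trim] if trim and len(cds_vals) > 2 * trim else cds_vals
    m = core.mean() if len(core) else 0.0
    if m <= 0:
        raise ZeroDivisionError(
            f"transcript {vector.transcript_id}: no CDS coverage, per-mean undefined")
    if vector.normalization == "per_mean":
        return out  # idempotent: already mean-scaled
    out.values = out.values / m
    out.normalization = "per_mean"
    return out


def normalize_set(densities: DensitySet, mode: str, trim: int = 0,
                  catalog: Optional[TranscriptCatalog] = None) -> DensitySet:
    """Normalize every vector; transcripts with no CDS coverage are dropped
    under per_mean (flagged in the log)."""
    vectors: Dict[str, DensityVector] = {}
    dropped = 0
    for vec in densities:
        try:
            vectors[vec.transcript_id] = normalize_density(
                vec, mode, library_size=densities.library_size,
                catalog=catalog, trim=trim)
        except ZeroDivisionError:
            dropped += 1
    if dropped:
        logger.info("per-mean normalization: %d transcript(s) had no coverage", dropped)
    return DensitySet(vectors, densities.unit, densities.library_size,
                      densities.utr5_counts, densities.utr3_counts, mode)
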