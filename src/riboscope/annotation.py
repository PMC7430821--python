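"""Transcript catalog construction from a genome FASTA and GTF annotation.

Alternative splicing gives most eukaryotic genes several isoforms; to keep
read-to-transcript assignment unambiguous, downstream analyses use a single
representative transcript per protein-coding gene — by default the one with
the greatest spliced length.  This module parses the annotation, picks that
transcript, records the 5'UTR / CDS / 3'UTR partition on the spliced
transcript, and extracts transcript, CDS, UTR and amino-acid sequences.

Coordinate conventions: GTF input is 1-based closed (the format standard);
every internal coordinate is 0-based half-open on the spliced transcript,
5'→3' on the transcript strand.  Codon 1 is the first CDS codon.  The stop
codon counts toward the CDS length but is excluded from the amino-acid
sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import gffutils
from Bio import SeqIO

from .scales import reverse_complement, translate_cds

logger = logging.getLogger(__name__)

Interval = Tuple[int, int]  # 0-based half-open, genomic


@dataclass
class TranscriptModel:
    """One transcript as annotated: genomic exon and CDS intervals."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: List[Interval] = field(default_factory=list)
    cds: List[Interval] = field(default_factory=list)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass
class GenomeAnnotation:
    """Chromosome sequences plus gene/transcript records in genomic coords."""

    chromosomes: Dict[str, str]
    transcripts: Dict[str, TranscriptModel]
    gene_biotypes: Dict[str, str] = field(default_factory=dict)
    gene_names: Dict[str, str] = field(default_factory=dict)

    def transcripts_of_gene(self, gene_id: str) -> List[TranscriptModel]:
        return [t for t in self.transcripts.values() if t.gene_id == gene_id]

    @property
    def gene_ids(self) -> List[str]:
        return sorted({t.gene_id for t in self.transcripts.values()})


@dataclass
class CatalogEntry:
    """The chosen transcript of one gene, with its region partition."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: List[Interval]
    utr5_len: int
    cds_len: int
    utr3_len: int
    transcript_seq: str = ""
    cds_seq: str = ""
    aa_seq: str = ""

    @property
    def length(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len

    @property
    def n_codons(self) -> int:
        """CDS codon count, stop codon included."""
        return self.cds_len // 3

    @property
    def cds_start(self) -> int:
        return self.utr5_len

    @property
    def cds_end(self) -> int:
        return self.utr5_len + self.cds_len

    @property
    def utr5_seq(self) -> str:
        return self.transcript_seq[: self.utr5_len]

    @property
    def utr3_seq(self) -> str:
        return self.transcript_seq[self.cds_end:]


class TranscriptCatalog:
    """Per-gene longest-transcript models, keyed by transcript id."""

    def __init__(self, entries: Sequence[CatalogEntry], skipped: Optional[Dict[str, str]] = None):
        self.entries: Dict[str, CatalogEntry] = {e.transcript_id: e for e in entries}
        #: gene id -> reason, for genes dropped during selection
        self.skipped: Dict[str, str] = dict(skipped or {})

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[CatalogEntry]:
        return iter(self.entries.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.entries

    def get(self, transcript_id: str) -> Optional[CatalogEntry]:
        return self.entries.get(transcript_id)

    def __getitem__(self, transcript_id: str) -> CatalogEntry:
        return self.entries[transcript_id]

    def by_gene(self) -> Dict[str, CatalogEntry]:
        return {e.gene_id: e for e in self}

    def subset(self, gene_ids: Sequence[str]) -> "TranscriptCatalog":
        wanted = set(gene_ids)
        return TranscriptCatalog([e for e in self if e.gene_id in wanted or e.transcript_id in wanted])

    # -- text round trip ----------------------------------------------------

    HEADER = ["gene_id", "transcript_id", "chrom", "strand",
              "transcript_len", "utr5_len", "cds_len", "utr3_len"]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# transcript catalog; coordinates 0-based half-open on the "
                     "spliced transcript; cds_len includes the stop codon\n")
            fh.write("\t".join(self.HEADER) + "\n")
            for e in sorted(self, key=lambda e: e.gene_id):
                fh.write("\t".join(map(str, [e.gene_id, e.transcript_id, e.chrom, e.strand,
                                             e.length, e.utr5_len, e.cds_len, e.utr3_len])) + "\n")

    @classmethod
    def read_tsv(cls, path) -> "TranscriptCatalog":
        entries = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or line.startswith("gene_id"):
                    continue
                g, t, chrom, strand, tl, u5, cl, u3 = line.rstrip("\n").split("\t")
                entries.append(CatalogEntry(g, t, chrom, strand, [], int(u5), int(cl), int(u3)))
        return cls(entries)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def read_fasta(path) -> Dict[str, str]:
    """Chromosome name -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def load_annotation(fasta_path, gtf_path) -> GenomeAnnotation:
    """Parse a genome FASTA and Ensembl-style GTF into a GenomeAnnotation.

    `gene_id` and `transcript_id` attributes are required on exon/CDS
    features; `gene_biotype` is used when present.  Separate `stop_codon`
    features are merged into CDS space so both GTF dialects (stop inside or
    outside the CDS records) give a CDS length divisible by three.
    """
    chromosomes = read_fasta(fasta_path)
    db = gffutils.create_db(
        str(gtf_path), ":memory:",
        disable_infer_genes=True, disable_infer_transcripts=True,
        keep_order=True,
    )
    transcripts: Dict[str, TranscriptModel] = {}
    gene_biotypes: Dict[str, str] = {}
    gene_names: Dict[str, str] = {}

    def _get(feat, key):
        vals = feat.attributes.get(key)
        return vals[0] if vals else None

    for feat in db.all_features():
        ftype = feat.featuretype
        if ftype == "gene":
            gid = _get(feat, "gene_id")
            if gid:
                bt = _get(feat, "gene_biotype") or _get(feat, "gene_type")
                if bt:
                    gene_biotypes[gid] = bt
                name = _get(feat, "gene_name")
                if name:
                    gene_names[gid] = name
            continue
        if ftype not in ("exon", "CDS", "stop_codon"):
            continue
        tid, gid = _get(feat, "transcript_id"), _get(feat, "gene_id")
        if not tid or not gid:
            logger.warning("skipping %s record without gene_id/transcript_id at %s:%s",
                           ftype, feat.seqid, feat.start)
            continue
        model = transcripts.setdefault(
            tid, TranscriptModel(tid, gid, feat.seqid, feat.strand))
        iv = (feat.start - 1, feat.end)  # GTF 1-based closed -> 0-based half-open
        if ftype == "exon":
            model.exons.append(iv)
        else:  # CDS or stop_codon both occupy CDS space
            model.cds.append(iv)

    for model in transcripts.values():
        model.exons = _merge_sorted(model.exons)
        model.cds = _merge_sorted(model.cds)

    return GenomeAnnotation(chromosomes, transcripts, gene_biotypes, gene_names)


def _merge_sorted(ivs: List[Interval]) -> List[Interval]:
    """Sort genomically and merge book-ended/overlapping intervals."""
    out: List[Interval] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# longest-transcript selection
# ---------------------------------------------------------------------------

def _transcript_partition(model: TranscriptModel) -> Optional[Tuple[int, int, int]]:
    """(utr5, cds, utr3) lengths on the spliced transcript, or None if the
    CDS does not sit cleanly inside exon space."""
    exons = model.exons
    if not exons or not model.cds:
        return None
    # genomic -> spliced transcript coordinate of an exonic position
    offset = 0
    exon_offsets = []
    for s, e in exons:
        exon_offsets.append((s, e, offset))
        offset += e - s
    tx_len = offset

    def to_tx(gpos: int) -> Optional[int]:
        for s, e, off in exon_offsets:
            if s <= gpos < e:
                return off + (gpos - s)
        return None

    cds_len = model.cds_length
    gstart = model.cds[0][0] if model.strand == "+" else model.cds[-1][1] - 1
    tpos = to_tx(gstart)
    if tpos is None:
        return None
    utr5 = tpos if model.strand == "+" else tx_len - 1 - tpos
    # verify CDS fully exonic
    covered = sum(min(e, ce) - max(s, cs)
                  for s, e in exons for cs, ce in model.cds
                  if min(e, ce) > max(s, cs))
    if covered != cds_len:
        return None
    utr3 = tx_len - utr5 - cds_len
    if utr3 < 0:
        return None
    return utr5, cds_len, utr3


def select_longest_transcripts(
    annotation: GenomeAnnotation,
    by: str = "transcript",
    coding_biotypes: Tuple[str, ...] = ("protein_coding",),
) -> TranscriptCatalog:
    """One representative transcript per protein-coding gene.

    A gene counts as coding when its biotype is in ``coding_biotypes``, or,
    if the GTF carries no biotype tags, when at least one of its transcripts
    has CDS records.  ``by`` selects the length criterion: spliced
    transcript length (default) or CDS length.  Ties break to the
    lexicographically smallest transcript id so runs are reproducible.
    Transcripts with malformed structure (CDS outside exons, CDS length not
    a multiple of three) are excluded with a warning; genes left with no
    usable transcript are dropped and reported in ``catalog.skipped``.
    """
    if by not in ("transcript", "cds"):
        raise ValueError(f"unknown length criterion {by!r}")
    by_gene: Dict[str, List[TranscriptModel]] = {}
    for model in annotation.transcripts.values():
        by_gene.setdefault(model.gene_id, []).append(model)

    entries: List[CatalogEntry] = []
    skipped: Dict[str, str] = {}
    for gene_id in sorted(by_gene):
        biotype = annotation.gene_biotypes.get(gene_id)
        if biotype is not None and biotype not in coding_biotypes:
            skipped[gene_id] = f"biotype {biotype}"
            continue
        candidates = []
        for model in by_gene[gene_id]:
            if not model.cds:
                logger.warning("transcript %s of gene %s has no CDS records; excluded",
                               model.transcript_id, gene_id)
                continue
            part = _transcript_partition(model)
            if part is None:
                logger.warning("transcript %s: CDS not contained in exon space; excluded",
                               model.transcript_id)
                continue
            if part[1] % 3 != 0:
                logger.warning("transcript %s: CDS length %d not a multiple of 3; excluded",
                               model.transcript_id, part[1])
                continue
            chrom_len = len(annotation.chromosomes.get(model.chrom, ""))
            if annotation.chromosomes and (model.chrom not in annotation.chromosomes
                                           or model.exons[-1][1] > chrom_len):
                logger.warning("transcript %s: exon outside chromosome bounds; excluded",
                               model.transcript_id)
                continue
            candidates.append((model, part))
        if not candidates:
            skipped[gene_id] = "no coding transcript"
            continue
        keyfun = ((lambda mp: (-mp[0].spliced_length, mp[0].transcript_id))
                  if by == "transcript" else
                  (lambda mp: (-mp[1][1], mp[0].transcript_id)))
        model, (u5, cl, u3) = min(candidates, key=keyfun)
        entries.append(CatalogEntry(gene_id, model.transcript_id, model.chrom,
                                    model.strand, list(model.exons), u5, cl, u3))
    if skipped:
        logger.info("dropped %d gene(s) with no usable coding transcript", len(skipped))
    return TranscriptCatalog(entries, skipped)


# ---------------------------------------------------------------------------
# sequence extraction
# ---------------------------------------------------------------------------

def spliced_sequence(chrom_seq: str, exons: Sequence[Interval], strand: str) -> str:
    """Concatenate exon sequences 5'→3' on the transcript strand."""
    seq = "".join(chrom_seq[s:e] for s, e in exons)
    return reverse_complement(seq) if strand == "-" else seq


def extract_sequences(catalog: TranscriptCatalog, annotation: GenomeAnnotation) -> TranscriptCatalog:
    """Fill transcript, CDS and amino-acid sequences in place (and return it).

    The AA sequence follows the standard genetic code with the stop trimmed;
    an internal stop truncates translation with a warning, and codons
    containing N translate to 'X'.
    """
    for entry in catalog:
        chrom_seq = annotation.chromosomes.get(entry.chrom)
        if chrom_seq is None:
            raise KeyError(f"chromosome {entry.chrom!r} missing from genome for "
                           f"transcript {entry.transcript_id}")
        tx = spliced_sequence(chrom_seq, entry.exons, entry.strand)
        if len(tx) != entry.length:
            raise ValueError(f"transcript {entry.transcript_id}: spliced length "
                             f"{len(tx)} != catalog length {entry.length}")
        entry.transcript_seq = tx
        entry.cds_seq = tx[entry.cds_start: entry.cds_end]
        aa = translate_cds(entry.cds_seq)
        if aa.endswith("*"):
            aa = aa[:-1]
        if "*" in aa:
            logger.warning("transcript %s: internal stop codon; AA sequence truncated",
                           entry.transcript_id)
            aa = aa.split("*", 1)[0]
        entry.aa_seq = aa
    return catalog


def extract_utr_sequences(catalog: TranscriptCatalog) -> Dict[str, Tuple[str, str]]:
    """Per-transcript (5'UTR, 3'UTR) sequences; empty strings for length 0."""
    out = {}
    for entry in catalog:
        if not entry.transcript_seq:
            raise ValueError(f"transcript {entry.transcript_id} has no sequence; "
                             "run extract_sequences first")
        out[entry.transcript_id] = (entry.utr5_seq, entry.utr3_seq)
    return out


def attach_transcript_sequences(catalog: TranscriptCatalog, fasta_path) -> TranscriptCatalog:
    """Fill catalog sequences from a spliced-transcript FASTA (keyed by
    transcript id), deriving CDS and AA sequences from the region bounds."""
    seqs = read_fasta(fasta_path)
    for entry in catalog:
        if entry.transcript_id not in seqs:
            raise KeyError(f"transcript {entry.transcript_id} missing from {fasta_path}")
        tx = seqs[entry.transcript_id]
        if len(tx) != entry.length:
            raise ValueError(f"transcript {entry.transcript_id}: FASTA length "
                             f"{len(tx)} != catalog length {entry.length}")
        entry.transcript_seq = tx
        entry.cds_seq = tx[entry.cds_start: entry.cds_end]
        aa = translate_cds(entry.cds_seq)
        entry.aa_seq = aa[:-1] if aa.endswith("*") else aa.split("*", 1)[0]
    return catalog


def transcript_to_genome_blocks(entry: CatalogEntry, tstart: int, tend: int) -> List[Interval]:
    """Map a transcript-coordinate interval [tstart, tend) through the exon
    blocks to genomic intervals, returned in genomic order."""
    if not 0 <= tstart < tend <= entry.length:
        raise ValueError(f"interval [{tstart},{tend}) outside transcript "
                         f"{entry.transcript_id} of length {entry.length}")
    exons = entry.exons if entry.strand == "+" else list(reversed(entry.exons))
    blocks: List[Interval] = []
    off = 0
    for s, e in exons:
        n = e - s
        a, b = max(tstart - off, 0), min(tend - off, n)
        if a < b:
            if entry.strand == "+":
                blocks.append((s + a, s + b))
            else:
                blocks.append((e - b, e - a))
        off += n
    return sorted(blocks)


def transcript_fasta(catalog: TranscriptCatalog, kind: str = "transcript") -> Dict[str, str]:
    """Sequences keyed by transcript id; kind in {transcript, cds, aa, utr5, utr3}."""
    attr = {"transcript": "transcript_seq", "cds": "cds_seq", "aa": "aa_seq",
            "utr5": "utr5_seq", "utr3": "utr3_seq"}[kind]
    return {e.transcript_id: getattr(e, attr) for e in catalog if getattr(e, attr) != ""}
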