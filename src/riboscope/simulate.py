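"""Synthetic ribosome-profiling fixtures with recorded ground truth.

The simulator emits a small random genome (FASTA + GTF), the matching
longest-transcript catalog, and pre-aligned ribosome footprints as SAM
against both the transcriptome and the genome.  Every planted signal —
P-site offsets per read length, early-elongation stalling on a labeled
gene subset, pauses at chosen tri-amino-acid motifs, engagement onset for
selective-profiling IP samples, intron/intergenic contamination — is
recorded in a truth table, so each analysis module can be checked against
a closed-form or direct-tally expectation without any external download.

Reads are drawn codon by codon with probability proportional to the
planted density model, and each read's 5' end is placed at (P-site nt −
offset(length)), which makes offset calibration recover the planted table
by construction.  A 5× pile-up on the start codon mimics the universal
initiation peak of real libraries (and is what makes the calibration mode
unambiguous); it can be switched off for deliberately flat data.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotation import (CatalogEntry, TranscriptCatalog, transcript_to_genome_blocks,
                         write_fasta)
from .scales import GENETIC_CODE, SENSE_CODONS, reverse_complement, translate_cds

_NONSTOP_NONMET = tuple(c for c in SENSE_CODONS if c != "ATG")


@dataclass(frozen=True)
class SimulationScenario:
    """All knobs of one simulated sample and its genome.

    Defaults emulate a typical good-quality yeast-like library: footprints
    peaked at 28–30 nt with offsets 12–13 nt, strong frame-0 phasing, and
    an initiation pile-up at the start codon.
    """

    # genome layout
    n_genes: int = 60
    n_chromosomes: int = 2
    utr5_range: Tuple[int, int] = (30, 80)
    cds_codons_range: Tuple[int, int] = (150, 300)  # incl. start, excl. stop
    utr3_range: Tuple[int, int] = (40, 80)
    exons_range: Tuple[int, int] = (1, 3)
    intron_range: Tuple[int, int] = (60, 200)
    intergenic_gap_range: Tuple[int, int] = (150, 400)
    #: tri-AA motif deliberately written into CDS sequences: (motif, copies per gene)
    planted_motif: Optional[Tuple[str, int]] = None
    #: fraction of genes labeled 'up' in the truth table (stall/classification targets)
    up_gene_fraction: float = 0.0

    # read model
    library_size: int = 50_000
    read_length_probs: Dict[int, float] = field(
        default_factory=lambda: {28: 0.5, 29: 0.3, 30: 0.2})
    offsets: Dict[int, int] = field(default_factory=lambda: {28: 12, 29: 13, 30: 13})
    frame_probs: Tuple[float, float, float] = (1.0, 0.0, 0.0)
    #: extra reads of this length get uniformly random 5' ends (fails periodicity)
    unphased_length: Optional[int] = None
    unphased_fraction: float = 0.0
    #: fraction of reads whose P-site lands uniformly in the 5'UTR
    utr5_read_fraction: float = 0.0
    utr3_read_fraction: float = 0.0

    # density model
    init_peak_multiplier: float = 5.0
    #: (first_k_codons, multiplier) applied to genes labeled 'up'
    stall: Optional[Tuple[int, float]] = None
    #: (tri-AA motif, multiplier) applied at the motif's A-site codon
    motif_pause: Optional[Tuple[str, float]] = None
    #: (codon identity, multiplier) e.g. ("CCA", 4.0)
    codon_boost: Optional[Tuple[str, float]] = None
    #: (onset codon 1-based, multiplier) — IP enrichment from onset onward,
    #: applied to the 'up'-labeled target genes (or every gene if none are
    #: labeled); keeping targets a subset mimics real selective profiling,
    #: where library renormalization leaves non-targets near ratio 1
    engagement: Optional[Tuple[int, float]] = None

    # genome-level contamination (genome SAM only)
    intergenic_fraction: float = 0.0
    intron_fraction: float = 0.0
    contamination_length: int = 19


@dataclass
class TruthTable:
    """Planted ground truth sufficient to recompute every expected output."""

    offsets: Dict[int, int] = field(default_factory=dict)
    unphased_lengths: List[int] = field(default_factory=list)
    gene_labels: Dict[str, str] = field(default_factory=dict)
    #: transcript id -> 1-based codon indices whose density was boosted (motif A-sites)
    motif_sites: Dict[str, List[int]] = field(default_factory=dict)
    engagement_onset: Optional[int] = None
    stall: Optional[Tuple[int, float]] = None
    counts: Dict[str, int] = field(default_factory=dict)
    length_counts: Dict[int, int] = field(default_factory=dict)

    def write_json(self, path) -> None:
        payload = {
            "offsets": self.offsets,
            "unphased_lengths": self.unphased_lengths,
            "gene_labels": self.gene_labels,
            "motif_sites": self.motif_sites,
            "engagement_onset": self.engagement_onset,
            "stall": self.stall,
            "counts": self.counts,
            "length_counts": self.length_counts,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class SimulatedGenome:
    chromosomes: Dict[str, str]
    gtf: str
    catalog: TranscriptCatalog
    truth: TruthTable
    #: per gene: intron genomic intervals of the simulated transcript
    introns: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random sense codons + TAA (no internal stop by construction)."""
    body = rng.integers(0, len(_NONSTOP_NONMET), n_codons - 1)
    return "ATG" + "".join(_NONSTOP_NONMET[i] for i in body) + "TAA"


def _plant_motif(rng: np.random.Generator, cds: str, motif: str, copies: int) -> str:
    """Overwrite `copies` random interior codon triplets with codons for `motif`."""
    aa_to_codon = {}
    for codon, aa in GENETIC_CODE.items():
        if aa != "*":
            aa_to_codon.setdefault(aa, codon)
    motif_nt = "".join(aa_to_codon[a] for a in motif)
    n_codons = len(cds) // 3 - 1  # keep the stop
    positions = rng.choice(np.arange(5, n_codons - len(motif) - 5), size=copies,
                           replace=False)
    cds = list(cds)
    for p in sorted(positions):
        cds[3 * p: 3 * p + 9] = motif_nt
    return "".join(cds)


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------

def make_genome_annotation(scenario: SimulationScenario, seed: int) -> SimulatedGenome:
    """Build a random genome with non-overlapping multi-exon genes on both
    strands, the GTF describing them, and the ground-truth catalog.
    Deterministic given (scenario, seed)."""
    if scenario.n_genes < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    truth = TruthTable(offsets=dict(scenario.offsets))
    if scenario.unphased_length is not None:
        truth.unphased_lengths.append(scenario.unphased_length)

    n_up = int(round(scenario.up_gene_fraction * scenario.n_genes))
    up_ids = set(rng.choice(scenario.n_genes, size=n_up, replace=False).tolist())

    entries: List[CatalogEntry] = []
    gtf_lines: List[str] = []
    chrom_parts: Dict[str, List[str]] = {}
    chrom_cursor: Dict[str, int] = {}
    introns_by_gene: Dict[str, List[Tuple[int, int]]] = {}
    chrom_names = [f"chr{i + 1}" for i in range(scenario.n_chromosomes)]
    for c in chrom_names:
        chrom_parts[c] = []
        chrom_cursor[c] = 0

    for gi in range(scenario.n_genes):
        gene_id, tx_id = f"gene{gi:04d}", f"tx{gi:04d}"
        chrom = chrom_names[gi % scenario.n_chromosomes]
        strand = "+" if rng.random() < 0.5 else "-"
        u5 = int(rng.integers(*scenario.utr5_range))
        n_codons = int(rng.integers(*scenario.cds_codons_range))
        u3 = int(rng.integers(*scenario.utr3_range))
        cds = _random_cds(rng, n_codons)
        if scenario.planted_motif:
            motif, copies = scenario.planted_motif
            cds = _plant_motif(rng, cds, motif, copies)
        tx_seq = _random_seq(rng, u5) + cds + _random_seq(rng, u3)
        tx_len = len(tx_seq)

        # split the exonic sequence into exons with random introns between
        n_exons = int(rng.integers(scenario.exons_range[0], scenario.exons_range[1] + 1))
        n_exons = min(n_exons, max(1, tx_len // 60))
        cuts = sorted(rng.choice(np.arange(30, tx_len - 30), size=n_exons - 1,
                                 replace=False).tolist()) if n_exons > 1 else []
        bounds = [0] + cuts + [tx_len]
        exon_lens_tx = [bounds[i + 1] - bounds[i] for i in range(n_exons)]
        exonic = tx_seq if strand == "+" else reverse_complement(tx_seq)
        exon_lens_genomic = exon_lens_tx if strand == "+" else exon_lens_tx[::-1]

        gap = int(rng.integers(*scenario.intergenic_gap_range))
        chrom_parts[chrom].append(_random_seq(rng, gap))
        gstart = chrom_cursor[chrom] + gap

        exons: List[Tuple[int, int]] = []
        introns: List[Tuple[int, int]] = []
        pos, spliced_off = gstart, 0
        pieces: List[str] = []
        for k, elen in enumerate(exon_lens_genomic):
            pieces.append(exonic[spliced_off: spliced_off + elen])
            exons.append((pos, pos + elen))
            pos += elen
            spliced_off += elen
            if k < len(exon_lens_genomic) - 1:
                ilen = int(rng.integers(*scenario.intron_range))
                pieces.append(_random_seq(rng, ilen))
                introns.append((pos, pos + ilen))
                pos += ilen
        chrom_parts[chrom].append("".join(pieces))
        chrom_cursor[chrom] = pos
        introns_by_gene[gene_id] = introns

        entry = CatalogEntry(gene_id, tx_id, chrom, strand, exons,
                             u5, 3 * (n_codons + 1), u3,
                             transcript_seq=tx_seq, cds_seq=cds,
                             aa_seq=translate_cds(cds)[:-1])
        entries.append(entry)
        truth.gene_labels[gene_id] = "up" if gi in up_ids else "unblocked"
        if scenario.planted_motif:
            motif, _ = scenario.planted_motif
            aa = entry.aa_seq
            sites = [j + len(motif) for j in range(len(aa) - len(motif) + 1)
                     if aa[j:j + len(motif)] == motif]  # 1-based A-site codon
            truth.motif_sites[tx_id] = sites

        gene_start, gene_end = exons[0][0] + 1, exons[-1][1]  # GTF 1-based closed
        attrs = (f'gene_id "{gene_id}"; transcript_id "{tx_id}"; '
                 f'gene_biotype "protein_coding";')
        gattrs = f'gene_id "{gene_id}"; gene_biotype "protein_coding";'
        gtf_lines.append(f"{chrom}\tsim\tgene\t{gene_start}\t{gene_end}\t.\t{strand}\t.\t{gattrs}")
        gtf_lines.append(f"{chrom}\tsim\ttranscript\t{gene_start}\t{gene_end}\t.\t{strand}\t.\t{attrs}")
        for s, e in exons:
            gtf_lines.append(f"{chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}")
        for s, e in transcript_to_genome_blocks(entry, entry.cds_start, entry.cds_end):
            gtf_lines.append(f"{chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\t{attrs}")

    for c in chrom_names:  # trailing intergenic space
        chrom_parts[c].append(_random_seq(rng, 300))
    chromosomes = {c: "".join(chrom_parts[c]) for c in chrom_names}
    catalog = TranscriptCatalog(entries)
    if scenario.engagement:
        truth.engagement_onset = scenario.engagement[0]
    if scenario.stall:
        truth.stall = scenario.stall
    return SimulatedGenome(chromosomes, "\n".join(gtf_lines) + "\n", catalog, truth,
                           introns_by_gene)


# ---------------------------------------------------------------------------
# planted density model
# ---------------------------------------------------------------------------

def planted_codon_weights(entry: CatalogEntry, scenario: SimulationScenario,
                          truth: TruthTable) -> np.ndarray:
    """Relative sampling weight per sense codon (stop codon weight 0)."""
    n = entry.n_codons
    w = np.ones(n)
    w[-1] = 0.0  # stop codon: no elongating P-site planted
    w[0] *= scenario.init_peak_multiplier
    if scenario.stall and truth.gene_labels.get(entry.gene_id) == "up":
        k, mult = scenario.stall
        w[:min(k, n - 1)] *= mult
    if scenario.codon_boost:
        codon, mult = scenario.codon_boost
        for i in range(n - 1):
            if entry.cds_seq[3 * i: 3 * i + 3] == codon:
                w[i] *= mult
    if scenario.motif_pause:
        motif, mult = scenario.motif_pause
        aa = entry.aa_seq
        for j in range(len(aa) - len(motif) + 1):
            if aa[j:j + len(motif)] == motif:
                w[j + len(motif) - 1] *= mult  # A-site codon of the motif
    if scenario.engagement:
        labels = truth.gene_labels
        targeted = (not any(v == "up" for v in labels.values())
                    or labels.get(entry.gene_id) == "up")
        if targeted:
            onset, mult = scenario.engagement
            w[min(onset - 1, n - 1):] *= mult
            w[-1] = 0.0
    return w


# ---------------------------------------------------------------------------
# footprint simulation
# ---------------------------------------------------------------------------

def _sam_header(refs: Sequence[Tuple[str, int]]) -> List[str]:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    lines += [f"@SQ\tSN:{name}\tLN:{length}" for name, length in refs]
    return lines


def simulate_footprints(genome: SimulatedGenome, scenario: SimulationScenario,
                        seed: int) -> Tuple[str, str, TruthTable]:
    """Draw a footprint library from the planted density model.

    Returns (transcriptome SAM, genome SAM, truth) — the same reads appear
    in both files (genome records lifted through the exon blocks, spliced
    with N cigar ops), plus intron/intergenic contamination reads that
    exist only in the genome SAM.  Deterministic given (scenario, seed).
    """
    if len(genome.catalog) == 0:
        raise ValueError("empty catalog")
    rng = np.random.default_rng(seed)
    catalog = genome.catalog
    truth = replace_truth(genome.truth, scenario)

    entries = sorted(catalog, key=lambda e: e.transcript_id)
    weights, owners = [], []
    for e in entries:
        w = planted_codon_weights(e, scenario, truth)
        weights.append(w)
        owners.append(e)
    flat = np.concatenate(weights)
    flat_prob = flat / flat.sum()
    starts = np.cumsum([0] + [len(w) for w in weights])

    n_unphased = int(round(scenario.unphased_fraction * scenario.library_size))
    n_utr5 = int(round(scenario.utr5_read_fraction * scenario.library_size))
    n_utr3 = int(round(scenario.utr3_read_fraction * scenario.library_size))
    n_body = scenario.library_size - n_unphased - n_utr5 - n_utr3

    lengths = sorted(scenario.read_length_probs)
    lprobs = np.array([scenario.read_length_probs[L] for L in lengths], dtype=float)
    lprobs /= lprobs.sum()
    frame_probs = np.array(scenario.frame_probs, dtype=float)
    frame_probs /= frame_probs.sum()

    counts = rng.multinomial(n_body, flat_prob)
    tx_records: List[Tuple[str, int, int, str]] = []  # (tid, five, length, seq)

    def emit(entry: CatalogEntry, psite: int, L: int) -> bool:
        off = scenario.offsets.get(L)
        if off is None:
            return False
        five = psite - off
        if five < 0 or five + L > entry.length:
            return False
        tx_records.append((entry.transcript_id, five, L,
                           entry.transcript_seq[five:five + L]))
        return True

    for flat_idx in np.nonzero(counts)[0]:
        t = int(np.searchsorted(starts, flat_idx, side="right")) - 1
        entry = owners[t]
        codon0 = int(flat_idx - starts[t])
        c = int(counts[flat_idx])
        fr = rng.choice(3, size=c, p=frame_probs)
        ls = rng.choice(lengths, size=c, p=lprobs)
        for f, L in zip(fr, ls):
            psite = entry.cds_start + 3 * codon0 + int(f)
            emit(entry, psite, int(L))

    # UTR reads: P-site uniform in the region
    tx_prob = np.array([w.sum() for w in weights]); tx_prob /= tx_prob.sum()
    for n_reads, region in ((n_utr5, "utr5"), (n_utr3, "utr3")):
        for t in rng.choice(len(entries), size=n_reads, p=tx_prob):
            entry = owners[int(t)]
            L = int(rng.choice(lengths, p=lprobs))
            if region == "utr5":
                lo, hi = scenario.offsets[L], entry.cds_start
            else:
                lo, hi = entry.cds_end, entry.length - (L - scenario.offsets[L])
            if hi <= lo:
                continue
            emit(entry, int(rng.integers(lo, hi)), L)

    # unphased contaminant fragments: uniform 5' ends, own length
    if n_unphased and scenario.unphased_length:
        L = scenario.unphased_length
        for t in rng.choice(len(entries), size=n_unphased, p=tx_prob):
            entry = owners[int(t)]
            five = int(rng.integers(0, entry.length - L))
            tx_records.append((entry.transcript_id, five, L,
                               entry.transcript_seq[five:five + L]))

    tx_records.sort(key=lambda r: (r[0], r[1], r[2]))
    truth.counts["transcriptome_reads"] = len(tx_records)
    truth.counts["exon_reads"] = len(tx_records)
    length_counter = Counter(r[2] for r in tx_records)

    tx_sam = _sam_header([(e.transcript_id, e.length) for e in entries])
    gen_sam = _sam_header([(c, len(genome.chromosomes[c]))
                           for c in sorted(genome.chromosomes)])
    by_tid = {e.transcript_id: e for e in entries}
    for i, (tid, five, L, seq) in enumerate(tx_records):
        qname = f"r{i:07d}"
        tx_sam.append(f"{qname}\t0\t{tid}\t{five + 1}\t255\t{L}M\t*\t0\t0\t{seq}\t*")
        entry = by_tid[tid]
        blocks = transcript_to_genome_blocks(entry, five, five + L)
        cigar = []
        for k, (s, e) in enumerate(blocks):
            if k:
                cigar.append(f"{s - blocks[k - 1][1]}N")
            cigar.append(f"{e - s}M")
        gseq = seq if entry.strand == "+" else reverse_complement(seq)
        flag = 0 if entry.strand == "+" else 16
        gen_sam.append(f"{qname}\t{flag}\t{entry.chrom}\t{blocks[0][0] + 1}\t255\t"
                       f"{''.join(cigar)}\t*\t0\t0\t{gseq}\t*")

    # contamination on the genome only
    n_intergenic = int(round(scenario.intergenic_fraction * scenario.library_size))
    n_intron = int(round(scenario.intron_fraction * scenario.library_size))
    Lc = scenario.contamination_length
    intergenic = _intergenic_intervals(genome)
    introns = [(by_tid[e.transcript_id].chrom, s, iv_e)
               for e in entries for s, iv_e in genome.introns.get(e.gene_id, [])]
    ridx = len(tx_records)
    for n_reads, space, tag in ((n_intergenic, intergenic, "intergenic"),
                                (n_intron, introns, "intron")):
        emitted = 0
        if n_reads and space:
            sizes = np.array([e - s for _, s, e in space], dtype=float)
            ok = sizes > Lc
            space = [iv for iv, good in zip(space, ok) if good]
            sizes = sizes[ok]
            probs = sizes / sizes.sum()
            for j in rng.choice(len(space), size=n_reads, p=probs):
                chrom, s, e = space[int(j)]
                pos = int(rng.integers(s, e - Lc))
                seq = genome.chromosomes[chrom][pos:pos + Lc]
                gen_sam.append(f"r{ridx:07d}\t0\t{chrom}\t{pos + 1}\t255\t{Lc}M\t*\t0\t0\t{seq}\t*")
                ridx += 1
                emitted += 1
                length_counter[Lc] += 1
        truth.counts[f"{tag}_reads"] = emitted
    truth.counts["genome_reads"] = ridx
    truth.length_counts = dict(sorted(length_counter.items()))
    return "\n".join(tx_sam) + "\n", "\n".join(gen_sam) + "\n", truth


def replace_truth(truth: TruthTable, scenario: SimulationScenario) -> TruthTable:
    """Copy the genome truth and stamp sample-level plantings onto it."""
    out = TruthTable(dict(truth.offsets), list(truth.unphased_lengths),
                     dict(truth.gene_labels), {k: list(v) for k, v in truth.motif_sites.items()},
                     truth.engagement_onset, truth.stall, {}, {})
    if scenario.engagement:
        out.engagement_onset = scenario.engagement[0]
    if scenario.stall:
        out.stall = scenario.stall
    if scenario.unphased_length is not None and scenario.unphased_length not in out.unphased_lengths:
        out.unphased_lengths.append(scenario.unphased_length)
    return out


def _intergenic_intervals(genome: SimulatedGenome) -> List[Tuple[str, int, int]]:
    """Complement of gene spans per chromosome."""
    spans: Dict[str, List[Tuple[int, int]]] = {c: [] for c in genome.chromosomes}
    for e in genome.catalog:
        spans[e.chrom].append((e.exons[0][0], e.exons[-1][1]))
    out = []
    for chrom, ivs in spans.items():
        cursor = 0
        for s, e in sorted(ivs):
            if s > cursor:
                out.append((chrom, cursor, s))
            cursor = max(cursor, e)
        clen = len(genome.chromosomes[chrom])
        if clen > cursor:
            out.append((chrom, cursor, clen))
    return out


# ---------------------------------------------------------------------------
# convenience: write a full dataset to disk
# ---------------------------------------------------------------------------

def simulate_to_dir(scenario: SimulationScenario, seed: int, outdir) -> Dict[str, Path]:
    """Generate genome + annotation + one footprint sample and write
    genome.fa, annotation.gtf, catalog.tsv, transcripts.fa, transcriptome.sam,
    genome.sam and truth.json into ``outdir``.  Returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = make_genome_annotation(scenario, seed)
    tx_sam, gen_sam, truth = simulate_footprints(genome, scenario, seed + 1)
    paths = {
        "genome_fasta": outdir / "genome.fa",
        "gtf": outdir / "annotation.gtf",
        "catalog": outdir / "catalog.tsv",
        "transcript_fasta": outdir / "transcripts.fa",
        "transcriptome_sam": outdir / "transcriptome.sam",
        "genome_sam": outdir / "genome.sam",
        "truth": outdir / "truth.json",
    }
    write_fasta(genome.chromosomes, paths["genome_fasta"])
    paths["gtf"].write_text(genome.gtf)
    genome.catalog.write_tsv(paths["catalog"])
    write_fasta({e.transcript_id: e.transcript_seq for e in genome.catalog},
                paths["transcript_fasta"])
    paths["transcriptome_sam"].write_text(tx_sam)
    paths["genome_sam"].write_text(gen_sam)
    truth.write_json(paths["truth"])
    return paths
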