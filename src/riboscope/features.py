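"""Translation-regulatory feature mining over gene sets.

Given P-site codon densities and the transcript catalog, this module asks
*why* ribosomes dwell where they do: occupancy per codon or amino-acid
identity, pausing scores per tri-amino-acid motif (with the ribosome's
E/P/A site selectable as the scored position), density around motif
occurrences, codon and tRNA adaptation indices (global per gene and as
positional profiles), hydropathy/charge profiles of the encoded peptide,
5'UTR/CDS footprint ratios, and the treated-vs-control classification of
genes by early-elongation density change.

Throughout, densities are per-transcript mean-normalized so a value of 1
means "average occupancy for this transcript" and identities are read
from the catalog's CDS sequence; the stop codon carries no residue and is
excluded from all identity-level statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats as sps

from .annotation import TranscriptCatalog
from .density import DensitySet
from .metagene import (MetageneProfile, _profile_from_matrix,
                       covered_normalized_vectors)
from .scales import (CODONS_BY_AA, GENETIC_CODE, SENSE_CODONS,
                     DEFAULT_WOBBLE_PENALTIES, ResidueScale, reverse_complement)

logger = logging.getLogger(__name__)

_SITE_OFFSET = {"E": 0, "P": 1, "A": 2}


# ---------------------------------------------------------------------------
# codon / AA occupancy
# ---------------------------------------------------------------------------

@dataclass
class CodonDensityTable:
    """Mean relative ribosome density per codon and per amino acid."""

    codon_density: Dict[str, float]
    codon_count: Dict[str, int]
    aa_density: Dict[str, float]
    aa_count: Dict[str, int]

    def write_tsv(self, path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("kind\tidentity\tmean_density\tcount\n")
            for c in sorted(self.codon_density):
                fh.write(f"codon\t{c}\t{self.codon_density[c]:.6g}\t{self.codon_count[c]}\n")
            for a in sorted(self.aa_density):
                fh.write(f"aa\t{a}\t{self.aa_density[a]:.6g}\t{self.aa_count[a]}\n")


def density_by_codon_identity(
    densities: DensitySet,
    catalog: TranscriptCatalog,
    gene_set: Optional[Iterable[str]] = None,
    trim: int = 0,
    **filter_kw,
) -> CodonDensityTable:
    """Mean normalized density over every CDS position encoding each codon.

    The amino-acid table is the occurrence-weighted mean over synonymous
    codons, so pooling all identities reproduces the gene-set mean density
    exactly.  Codons never observed in the gene set are absent.
    """
    vectors = covered_normalized_vectors(densities, catalog, gene_set,
                                         trim=trim, **filter_kw)
    codon_sum: Dict[str, float] = {}
    codon_n: Dict[str, int] = {}
    for tid, vals in vectors.items():
        entry = catalog[tid]
        cds = entry.cds_seq
        for i in range(entry.n_codons - 1):  # sense codons only
            codon = cds[3 * i: 3 * i + 3]
            if codon not in GENETIC_CODE or GENETIC_CODE[codon] == "*":
                continue
            codon_sum[codon] = codon_sum.get(codon, 0.0) + vals[i]
            codon_n[codon] = codon_n.get(codon, 0) + 1
    codon_density = {c: codon_sum[c] / codon_n[c] for c in codon_sum}
    aa_sum: Dict[str, float] = {}
    aa_n: Dict[str, int] = {}
    for c, s in codon_sum.items():
        aa = GENETIC_CODE[c]
        aa_sum[aa] = aa_sum.get(aa, 0.0) + s
        aa_n[aa] = aa_n.get(aa, 0) + codon_n[c]
    aa_density = {a: aa_sum[a] / aa_n[a] for a in aa_sum}
    return CodonDensityTable(codon_density, codon_n, aa_density, aa_n)


def codon_density_ratio(
    table_treated: CodonDensityTable,
    table_control: CodonDensityTable,
) -> Tuple[Dict[str, float], Dict[str, float]]:
    """log2(treated / control) per codon and per amino acid.

    Identities absent from either table, or with zero control density, are
    omitted (with a warning for the zero-control case).
    """
    def ratios(t: Mapping[str, float], c: Mapping[str, float]) -> Dict[str, float]:
        out = {}
        for key in sorted(set(t) & set(c)):
            if c[key] <= 0:
                logger.warning("identity %s has zero control density; omitted", key)
                continue
            out[key] = math.log2(t[key] / c[key]) if t[key] > 0 else -math.inf
        return out

    return (ratios(table_treated.codon_density, table_control.codon_density),
            ratios(table_treated.aa_density, table_control.aa_density))


# ---------------------------------------------------------------------------
# tri-AA pausing
# ---------------------------------------------------------------------------

@dataclass
class PausingScoreTable:
    """Mean normalized density per tri-AA motif at the chosen ribosome site."""

    scores: Dict[str, float]
    counts: Dict[str, int]
    n_transcripts: Dict[str, int]
    site: str

    def top(self, n: int = 10) -> List[Tuple[str, float]]:
        return sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))[:n]

    def write_tsv(self, path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("motif\tpausing_score\toccurrences\tn_transcripts\n")
            for m, s in sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0])):
                fh.write(f"{m}\t{s:.6g}\t{self.counts[m]}\t{self.n_transcripts[m]}\n")


def _motif_occurrences(aa_seq: str, motif_len: int = 3):
    for j in range(len(aa_seq) - motif_len + 1):
        yield j, aa_seq[j: j + motif_len]


def pausing_scores(
    densities: DensitySet,
    catalog: TranscriptCatalog,
    gene_set: Optional[Iterable[str]] = None,
    site: str = "A",
    occurrence_floor: int = 10,
    **filter_kw,
) -> PausingScoreTable:
    """Score every tri-AA motif by its mean normalized density.

    An occurrence at AA positions (j, j+1, j+2) is scored by the density
    at the codon that places the motif's E, P or A site at the ribosome's
    decoding position — by default the A site, i.e. codon j+2; ``site`` may
    also be ``"sum"`` to add all three codons.  Motifs with fewer
    occurrences than ``occurrence_floor`` across the gene set are dropped.
    """
    if site not in ("E", "P", "A", "sum"):
        raise ValueError(f"unknown ribosome site {site!r}")
    vectors = covered_normalized_vectors(densities, catalog, gene_set, **filter_kw)
    sums: Dict[str, float] = {}
    counts: Dict[str, int] = {}
    ntx: Dict[str, Set[str]] = {}
    for tid, vals in vectors.items():
        aa = catalog[tid].aa_seq
        for j, motif in _motif_occurrences(aa):
            if site == "sum":
                score = float(vals[j] + vals[j + 1] + vals[j + 2])
            else:
                score = float(vals[j + _SITE_OFFSET[site]])
            sums[motif] = sums.get(motif, 0.0) + score
            counts[motif] = counts.get(motif, 0) + 1
            ntx.setdefault(motif, set()).add(tid)
    scores = {m: sums[m] / counts[m] for m in sums if counts[m] >= occurrence_floor}
    return PausingScoreTable(scores,
                             {m: counts[m] for m in scores},
                             {m: len(ntx[m]) for m in scores},
                             site)


def motif_anchored_density(
    densities: DensitySet,
    catalog: TranscriptCatalog,
    motif: str,
    gene_set: Optional[Iterable[str]] = None,
    window: int = 25,
    site: str = "A",
    ci: bool = True,
    n_boot: int = 1000,
    seed: int = 0,
    **filter_kw,
) -> MetageneProfile:
    """Mean normalized density in ±``window`` codons around each occurrence
    of ``motif``, anchored at the scored-site codon (offset 0)."""
    if site not in _SITE_OFFSET:
        raise ValueError(f"unknown ribosome site {site!r}")
    vectors = covered_normalized_vectors(densities, catalog, gene_set, **filter_kw)
    rows = []
    for tid, vals in vectors.items():
        aa = catalog[tid].aa_seq
        for j, m in _motif_occurrences(aa, len(motif)):
            if m != motif:
                continue
            a = j + min(_SITE_OFFSET[site], len(motif) - 1)
            row = np.full(2 * window + 1, np.nan)
            lo, hi = max(a - window, 0), min(a + window + 1, len(vals))
            row[lo - (a - window): hi - (a - window)] = vals[lo:hi]
            rows.append(row)
    if not rows:
        raise ValueError(f"motif {motif!r} has no occurrence in covered transcripts")
    matrix = np.vstack(rows)
    return _profile_from_matrix(matrix, np.arange(-window, window + 1),
                                motif, "codon", ci, n_boot, seed)


# ---------------------------------------------------------------------------
# adaptation indices
# ---------------------------------------------------------------------------

@dataclass
class AdaptationWeights:
    """Relative adaptiveness w in (0, 1] per sense codon (cAI or tAI)."""

    kind: str                   # 'cai' | 'tai'
    weights: Dict[str, float]
    provenance: str = ""

    def __getitem__(self, codon: str) -> float:
        return self.weights[codon]

    def __contains__(self, codon: str) -> bool:
        return codon in self.weights

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# kind={self.kind} provenance={self.provenance}\n")
            fh.write("codon\tweight\n")
            for c in sorted(self.weights):
                fh.write(f"{c}\t{self.weights[c]:.6g}\n")


def compute_cai_weights(reference_cds: Iterable[str]) -> AdaptationWeights:
    """Relative synonymous-codon adaptiveness from a reference gene set.

    w_c = f_c / max(f) within each synonymous family, from codon counts
    over the reference CDS sequences (stop codons ignored).  Zero-count
    codons take half a count before normalization so weights stay
    positive; single-codon families get w = 1 by construction.
    """
    counts = {c: 0 for c in SENSE_CODONS}
    n_seqs = 0
    for cds in reference_cds:
        n_seqs += 1
        for i in range(0, len(cds) - len(cds) % 3, 3):
            codon = cds[i:i + 3].upper()
            if codon in counts:
                counts[codon] += 1
    if n_seqs == 0:
        raise ValueError("empty reference set")
    weights: Dict[str, float] = {}
    for aa, family in CODONS_BY_AA.items():
        fam = {c: (counts[c] if counts[c] > 0 else 0.5) for c in family}
        top = max(fam.values())
        for c in family:
            weights[c] = fam[c] / top
    return AdaptationWeights("cai", weights, f"reference set of {n_seqs} CDS")


def compute_tai_weights(
    trna_copy_numbers: Mapping[str, float],
    wobble_penalties: Optional[Mapping[Tuple[str, str], float]] = None,
) -> AdaptationWeights:
    """tRNA adaptation weights from gene copy numbers and wobble penalties.

    For each sense codon, every anticodon able to decode it (Watson-Crick
    or a wobble rule pairing the codon's third base with the anticodon's
    first) contributes (1 - s) * tGCN; w = W / max(W), and codons with no
    recognizing tRNA get the geometric mean of the nonzero weights.
    Anticodons are keyed 5'→3'.
    """
    penalties = dict(DEFAULT_WOBBLE_PENALTIES if wobble_penalties is None
                     else wobble_penalties)
    if not any(v > 0 for v in trna_copy_numbers.values()):
        raise ValueError("tRNA copy-number table is empty or all zero")
    absolute: Dict[str, float] = {}
    for codon in SENSE_CODONS:
        W = 0.0
        stem = reverse_complement(codon)[1:]  # anticodon positions 35-36
        for (codon3, wobble_base), s in penalties.items():
            if codon[2] != codon3:
                continue
            anticodon = wobble_base + stem
            W += (1.0 - s) * trna_copy_numbers.get(anticodon, 0.0)
        absolute[codon] = W
    top = max(absolute.values())
    if top <= 0:
        raise ValueError("no codon is recognized by any listed anticodon")
    weights = {c: w / top for c, w in absolute.items()}
    nonzero = [w for w in weights.values() if w > 0]
    gmean = math.exp(sum(math.log(w) for w in nonzero) / len(nonzero))
    weights = {c: (w if w > 0 else gmean) for c, w in weights.items()}
    return AdaptationWeights("tai", weights,
                             f"tGCN table of {len(trna_copy_numbers)} anticodons")


#: single-codon families are uninformative for cAI and conventionally skipped
_CAI_EXCLUDED = frozenset(c for aa, fam in CODONS_BY_AA.items() if len(fam) == 1
                          for c in fam)


def global_adaptation_index(weights: AdaptationWeights, cds: str) -> float:
    """Geometric mean of codon weights over a CDS (stop codon excluded;
    for cAI, single-codon families are excluded as well)."""
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    logs = []
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3].upper()
        if codon not in SENSE_CODONS:
            continue  # stop or ambiguous
        if weights.kind == "cai" and codon in _CAI_EXCLUDED:
            continue
        logs.append(math.log(weights[codon]))
    if len(logs) < 2:
        raise ValueError("fewer than two scorable codons after exclusions")
    return math.exp(sum(logs) / len(logs))


def local_adaptation_profile(
    weights: AdaptationWeights,
    catalog: TranscriptCatalog,
    gene_set: Optional[Iterable[str]] = None,
    n_codons: int = 100,
    ci: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
) -> MetageneProfile:
    """Mean codon weight at positions 1..n_codons from the start codon,
    averaged over the gene set; shorter genes contribute where defined."""
    wanted = set(gene_set) if gene_set is not None else None
    rows = []
    for entry in catalog:
        if wanted is not None and entry.gene_id not in wanted \
                and entry.transcript_id not in wanted:
            continue
        row = np.full(n_codons, np.nan)
        k = min(n_codons, entry.n_codons - 1)
        for i in range(k):
            codon = entry.cds_seq[3 * i: 3 * i + 3]
            if codon in weights:
                row[i] = weights[codon]
        rows.append(row)
    if not rows:
        raise ValueError("empty gene set")
    matrix = np.vstack(rows)
    return _profile_from_matrix(matrix, np.arange(1, n_codons + 1),
                                f"start ({weights.kind})", "codon", ci, n_boot, seed)


# ---------------------------------------------------------------------------
# residue profiles
# ---------------------------------------------------------------------------

def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, NaN-aware, window shrinking at the edges."""
    if window <= 1:
        return values.copy()
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    half = window // 2
    out = np.full_like(values, np.nan, dtype=float)
    for i in range(len(values)):
        seg = values[max(i - half, 0): i + half + 1]
        good = np.isfinite(seg)
        if good.any():
            out[i] = seg[good].mean()
    return out


def residue_profile(
    catalog: TranscriptCatalog,
    gene_set: Optional[Iterable[str]],
    scale: ResidueScale,
    n_codons: int = 100,
    smoothing_window: int = 5,
) -> MetageneProfile:
    """Per-position mean of a residue scale (hydropathy, charge, ...) over
    the encoded peptides of the gene set, then smoothed with a centered
    moving average.  Unknown residues are treated as missing."""
    wanted = set(gene_set) if gene_set is not None else None
    rows = []
    for entry in catalog:
        if wanted is not None and entry.gene_id not in wanted \
                and entry.transcript_id not in wanted:
            continue
        row = np.full(n_codons, np.nan)
        for i, aa in enumerate(entry.aa_seq[:n_codons]):
            v = scale.get(aa)
            if v is not None:
                row[i] = v
        rows.append(row)
    if not rows:
        raise ValueError("empty gene set")
    matrix = np.vstack(rows)
    prof = _profile_from_matrix(matrix, np.arange(1, n_codons + 1),
                                f"start ({scale.name})", "codon",
                                False, 0, 0)
    prof.mean = moving_average(prof.mean, smoothing_window)
    prof.ci_lower = prof.ci_upper = prof.mean
    return prof


# ---------------------------------------------------------------------------
# 5'UTR / CDS ratio
# ---------------------------------------------------------------------------

def rpf_dist(
    densities: DensitySet,
    catalog: TranscriptCatalog,
    gene_set: Optional[Iterable[str]] = None,
    min_cds_reads: int = 16,
) -> Dict[str, float]:
    """Per-gene ratio of 5'UTR to CDS P-site counts (raw counts).

    A proxy inversely related to translation efficiency when matched
    RNA-seq is unavailable.  Genes with fewer than ``min_cds_reads`` CDS
    reads are excluded.
    """
    if densities.normalization != "raw":
        raise ValueError("rpf_dist needs raw counts")
    wanted = set(gene_set) if gene_set is not None else None
    out: Dict[str, float] = {}
    excluded = 0
    for vec in densities:
        entry = catalog.get(vec.transcript_id)
        if entry is None:
            continue
        if wanted is not None and entry.gene_id not in wanted \
                and entry.transcript_id not in wanted:
            continue
        cds_reads = vec.values.sum()
        if cds_reads < min_cds_reads:
            excluded += 1
            continue
        out[entry.gene_id] = densities.utr5_counts.get(vec.transcript_id, 0) / cds_reads
    if excluded:
        logger.info("rpf_dist: %d gene(s) below the CDS read floor", excluded)
    return out


# ---------------------------------------------------------------------------
# gene-set classification and comparison
# ---------------------------------------------------------------------------

def classify_gene_sets(
    dens_treated: DensitySet,
    dens_control: DensitySet,
    catalog: TranscriptCatalog,
    n_codons: int = 100,
    up_threshold: float = 1.5,
    min_control_reads: int = 10,
) -> Dict[str, str]:
    """Split genes by early-elongation density change between two samples.

    Both samples are library-size normalized (reads per million); the
    statistic is the ratio of mean rpm density over codons 1..n_codons
    (treated / control).  Genes at or above ``up_threshold`` are "up",
    at or below its reciprocal "down", otherwise "unblocked".  Genes
    without ``min_control_reads`` raw reads in the control window are
    excluded.
    """
    if up_threshold <= 1:
        raise ValueError("up_threshold must exceed 1")
    labels: Dict[str, str] = {}
    for vec in dens_treated:
        entry = catalog.get(vec.transcript_id)
        ctrl = dens_control.get(vec.transcript_id)
        if entry is None or ctrl is None:
            continue
        k = min(n_codons, len(vec.values))
        raw_ctrl = ctrl.values[:k]
        if dens_control.normalization != "raw":
            raise ValueError("classification expects raw counts (rpm applied internally)")
        if raw_ctrl.sum() < min_control_reads:
            continue
        t = vec.values[:k].mean() * 1e6 / dens_treated.library_size
        c = raw_ctrl.mean() * 1e6 / dens_control.library_size
        if c == 0:
            continue
        r = t / c
        labels[entry.gene_id] = ("up" if r >= up_threshold
                                 else "down" if r <= 1 / up_threshold
                                 else "unblocked")
    return labels


def compare_gene_set_feature(values_a: Sequence[float],
                             values_b: Sequence[float]) -> Tuple[float, float]:
    """Welch two-sample t-test on a per-gene feature (cAI, tAI, ...).

    Returns (t, p).  Two degenerate groups with zero variance and equal
    means give (0, 1) by convention.
    """
    a, b = np.asarray(values_a, dtype=float), np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def read_gene_set(path) -> List[str]:
    """Plain text gene list, one id per line; '#' comments allowed."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split()[0])
    return out


def write_gene_labels(labels: Mapping[str, str], path,
                      header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("gene_id\tlabel\n")
        for g in sorted(labels):
            fh.write(f"{g}\t{labels[g]}\n")


def read_trna_copy_numbers(path) -> Dict[str, float]:
    """TSV of (anticodon, gene copy number)."""
    out: Dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("anticodon"):
                continue
            anticodon, tgcn = line.split("\t")[:2]
            out[anticodon.upper().replace("U", "T")] = float(tgcn)
    return out
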