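"""Metagene analyses: pooled positional density, polarity, anchored profiles.

All three views summarize where ribosomes sit along transcripts after
per-transcript mean normalization, so that highly and lowly expressed
genes contribute equally:

* whole-region profiles interpolate each transcript's codon densities onto
  a fixed number of equal-width bins spanning the CDS;
* polarity scores condense each gene's distribution into a single number
  in [-1, 1] — negative when density leans toward the 5' end, positive
  toward the 3' end;
* anchored profiles average densities at fixed codon (or nt) distances
  from the start or stop codon, with a transcript-level bootstrap giving
  the 95% confidence band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .annotation import TranscriptCatalog
from .density import DensitySet, DensityVector, normalize_density

logger = logging.getLogger(__name__)

#: default coverage filter: per-mean normalization is unstable on sparse data
MIN_CDS_READS = 32
MIN_MEAN_DENSITY = 0.1  # reads per codon
#: codons excluded from the per-mean normalizer at both CDS ends
NORMALIZER_TRIM = 5


@dataclass
class MetageneProfile:
    """Position-indexed mean relative density with a confidence band."""

    anchor: str                  # 'start' | 'stop' | 'whole' | motif name
    positions: np.ndarray        # codon/bin/nt index, signed relative to anchor
    mean: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n: np.ndarray                # transcripts contributing per position
    unit: str = "codon"

    def write_tsv(self, path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("position\tmean\tci_lower\tci_upper\tn\n")
            for p, m, lo, hi, n in zip(self.positions, self.mean,
                                       self.ci_lower, self.ci_upper, self.n):
                fh.write(f"{p}\t{m:.6g}\t{lo:.6g}\t{hi:.6g}\t{int(n)}\n")


@dataclass
class PolarityRecord:
    gene_id: str
    score: float
    cds_reads: int


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def passes_coverage(vector: DensityVector,
                    min_reads: int = MIN_CDS_READS,
                    min_mean: float = MIN_MEAN_DENSITY) -> bool:
    """Raw codon vectors only: enough CDS reads and mean density."""
    total = vector.values.sum()
    return total >= min_reads and total / max(len(vector.values), 1) >= min_mean


def covered_normalized_vectors(
    densities: DensitySet,
    catalog: TranscriptCatalog,
    gene_set: Optional[Iterable[str]] = None,
    min_reads: int = MIN_CDS_READS,
    min_mean: float = MIN_MEAN_DENSITY,
    trim: int = NORMALIZER_TRIM,
) -> Dict[str, np.ndarray]:
    """Per-mean-normalized codon vectors for transcripts passing the
    coverage filter, restricted to ``gene_set`` (gene or transcript ids)."""
    if densities.unit != "codon":
        raise ValueError("metagene analyses need codon-unit densities")
    wanted: Optional[Set[str]] = set(gene_set) if gene_set is not None else None
    out: Dict[str, np.ndarray] = {}
    for vec in densities:
        entry = catalog.get(vec.transcript_id)
        if entry is None:
            continue
        if wanted is not None and entry.gene_id not in wanted \
                and entry.transcript_id not in wanted:
            continue
        if densities.normalization == "raw" and not passes_coverage(vec, min_reads, min_mean):
            continue
        if densities.normalization == "per_mean":
            out[vec.transcript_id] = vec.values
        else:
            try:
                out[vec.transcript_id] = normalize_density(vec, "per_mean", trim=trim).values
            except ZeroDivisionError:
                continue
    return out


def bootstrap_band(matrix: np.ndarray, n_boot: int = 1000, seed: int = 0,
                   level: float = 0.95) -> Tuple[np.ndarray, np.ndarray]:
    """Percentile bootstrap of the per-column nanmean over rows (transcripts)."""
    rng = np.random.default_rng(seed)
    n = matrix.shape[0]
    if n == 0:
        raise ValueError("bootstrap over an empty transcript set")
    stats = np.full((n_boot, matrix.shape[1]), np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        with np.errstate(invalid="ignore"):
            stats[b] = np.nanmean(matrix[idx], axis=0)
    alpha = (1 - level) / 2
    with np.errstate(invalid="ignore"):
        lo = np.nanpercentile(stats, 100 * alpha, axis=0)
        hi = np.nanpercentile(stats, 100 * (1 - alpha), axis=0)
    return lo, hi


def _profile_from_matrix(matrix: np.ndarray, positions: np.ndarray, anchor: str,
                         unit: str, ci: bool, n_boot: int, seed: int) -> MetageneProfile:
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(matrix, axis=0)
    n = np.sum(~np.isnan(matrix), axis=0)
    if ci and matrix.shape[0] > 1:
        lo, hi = bootstrap_band(matrix, n_boot=n_boot, seed=seed)
    else:
        lo = hi = mean.copy()
    return MetageneProfile(anchor, positions, mean, lo, hi, n, unit)


# ---------------------------------------------------------------------------
# whole-region profile
# ---------------------------------------------------------------------------

def bin_codon_density(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Average a codon vector into ``n_bins`` equal-width bins with
    fractional assignment at bin edges (a uniform vector maps to itself)."""
    L = len(values)
    if L == 0:
        return np.full(n_bins, np.nan)
    edges = np.linspace(0, L, n_bins + 1)
    out = np.empty(n_bins)
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        i0, i1 = int(np.floor(lo)), int(np.ceil(hi))
        total = 0.0
        for i in range(i0, min(i1, L)):
            overlap = min(hi, i + 1) - max(lo, i)
            if overlap > 0:
                total += values[i] * overlap
        out[b] = total / (hi - lo)
    return out


def metagene_whole_regions(
    densities: DensitySet,
    catalog: TranscriptCatalog,
    gene_set: Optional[Iterable[str]] = None,
    n_bins: int = 90,
    ci: bool = True,
    n_boot: int = 1000,
    seed: int = 0,
    **filter_kw,
) -> MetageneProfile:
    """Mean relative density across the CDS rescaled to ``n_bins`` bins."""
    vectors = covered_normalized_vectors(densities, catalog, gene_set, **filter_kw)
    if not vectors:
        raise ValueError(
            f"no transcript passes the coverage filter "
            f"(>= {MIN_CDS_READS} CDS reads and mean >= {MIN_MEAN_DENSITY}/codon)")
    matrix = np.vstack([bin_codon_density(v, n_bins) for v in vectors.values()])
    return _profile_from_matrix(matrix, np.arange(1, n_bins + 1), "whole",
                                "bin", ci, n_boot, seed)


# ---------------------------------------------------------------------------
# polarity
# ---------------------------------------------------------------------------

def polarity_score(values: np.ndarray) -> float:
    """Distribution-bias score for one codon density vector.

    p = sum_i d_i w_i / sum_i d_i with w_i = (2i - (L+1)) / (L-1) over CDS
    codons i = 1..L: -1 when all density sits on the first codon, +1 on the
    last, 0 for a uniform distribution.
    """
    L = len(values)
    if L < 2:
        raise ValueError("polarity needs at least two codons")
    total = values.sum()
    if total == 0:
        raise ZeroDivisionError("no density")
    i = np.arange(1, L + 1)
    w = (2 * i - (L + 1)) / (L - 1)
    return float(np.dot(values, w) / total)


def polarity_scores(
    densities: DensitySet,
    catalog: TranscriptCatalog,
    gene_set: Optional[Iterable[str]] = None,
    min_reads: int = MIN_CDS_READS,
    min_mean: float = MIN_MEAN_DENSITY,
) -> List[PolarityRecord]:
    """Per-gene polarity; genes with zero CDS density are excluded (logged)."""
    wanted = set(gene_set) if gene_set is not None else None
    records: List[PolarityRecord] = []
    excluded = 0
    for vec in densities:
        entry = catalog.get(vec.transcript_id)
        if entry is None or len(vec.values) < 2:
            continue
        if wanted is not None and entry.gene_id not in wanted \
                and entry.transcript_id not in wanted:
            continue
        if densities.normalization == "raw" and not passes_coverage(vec, min_reads, min_mean):
            continue
        try:
            p = polarity_score(vec.values)
        except ZeroDivisionError:
            excluded += 1
            continue
        records.append(PolarityRecord(entry.gene_id, p, int(round(vec.values.sum()))))
    if excluded:
        logger.info("polarity: %d gene(s) with zero CDS density excluded", excluded)
    return records


def write_polarity_tsv(records: Sequence[PolarityRecord], path,
                       header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("gene_id\tpolarity\tcds_reads\n")
        for r in sorted(records, key=lambda r: r.gene_id):
            fh.write(f"{r.gene_id}\t{r.score:.6g}\t{r.cds_reads}\n")


# ---------------------------------------------------------------------------
# anchored profiles
# ---------------------------------------------------------------------------

def metagene_anchored(
    densities: DensitySet,
    catalog: TranscriptCatalog,
    gene_set: Optional[Iterable[str]] = None,
    anchor: str = "start",
    mode: str = "cds",
    window: int = 100,
    ci: bool = True,
    n_boot: int = 1000,
    seed: int = 0,
    **filter_kw,
) -> MetageneProfile:
    """Mean relative density at fixed distances from the start/stop codon.

    CDS mode works in codon units: start anchor covers codons 1..window,
    stop anchor covers the last ``window`` codons (positions -window..-1,
    -1 being the codon just before the stop).  UTR mode works in nt units
    and spans the anchor symmetrically (positions -window..window, 0 = the
    anchor codon's first nt), so flanking UTR density is visible.
    Transcripts shorter than the window contribute only where defined.
    """
    if anchor not in ("start", "stop"):
        raise ValueError(f"unknown anchor {anchor!r}")
    if mode not in ("cds", "utr"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "cds":
        vectors = covered_normalized_vectors(densities, catalog, gene_set, **filter_kw)
        if not vectors:
            raise ValueError("no transcript passes the coverage filter")
        rows = []
        for tid, v in vectors.items():
            row = np.full(window, np.nan)
            if anchor == "start":
                k = min(window, len(v))
                row[:k] = v[:k]
            else:
                k = min(window, len(v))
                row[window - k:] = v[len(v) - k:]
            rows.append(row)
        positions = (np.arange(1, window + 1) if anchor == "start"
                     else np.arange(-window, 0))
        matrix = np.vstack(rows)
        if not np.isfinite(matrix).any(axis=0).all():
            raise ValueError("window larger than every contributing transcript")
        return _profile_from_matrix(matrix, positions, anchor, "codon", ci, n_boot, seed)

    # UTR mode: nt units around the anchor
    if densities.unit != "nt":
        raise ValueError("UTR-mode anchored profiles need nt-unit densities")
    wanted = set(gene_set) if gene_set is not None else None
    rows = []
    for vec in densities:
        entry = catalog.get(vec.transcript_id)
        if entry is None:
            continue
        if wanted is not None and entry.gene_id not in wanted \
                and entry.transcript_id not in wanted:
            continue
        cds_nt = vec.values[entry.cds_start:entry.cds_end]
        total = cds_nt.sum()
        if densities.normalization == "raw":
            if total < filter_kw.get("min_reads", MIN_CDS_READS):
                continue
            norm = vec.values / (total / max(len(cds_nt), 1))
        else:
            norm = vec.values
        a = entry.cds_start if anchor == "start" else entry.cds_end - 3
        row = np.full(2 * window + 1, np.nan)
        lo = max(a - window, 0)
        hi = min(a + window + 1, entry.length)
        row[lo - (a - window): hi - (a - window)] = norm[lo:hi]
        rows.append(row)
    if not rows:
        raise ValueError("no transcript passes the coverage filter")
    matrix = np.vstack(rows)
    return _profile_from_matrix(matrix, np.arange(-window, window + 1),
                                anchor, "nt", ci, n_boot, seed)
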