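"""Selective-ribosome-profiling enrichment analysis.

Selective ribosome profiling (SeRP) sequences footprints from ribosomes
co-purified with a factor of interest (the IP sample) alongside a total
translatome sample.  The position-wise ratio of IP over total density
along a transcript reveals where the factor engages the nascent chain: a
flat ratio near 1 means no selective engagement, while a sustained rise
above a threshold (conventionally two-fold) marks the onset codon.  The
same machinery compares any two libraries, selective or not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .density import DensitySet, DensityVector
from .features import moving_average
from .metagene import MetageneProfile, _profile_from_matrix

logger = logging.getLogger(__name__)

#: suppress profiles when the total sample is too sparse to trust a ratio
COVERAGE_FLOOR = 0.2  # raw reads per codon, mean over the CDS


@dataclass
class EnrichmentProfile:
    """Per-codon IP/total density ratio for one transcript."""

    transcript_id: str
    values: np.ndarray
    smoothing_window: int
    pseudocount: float

    def __len__(self):
        return len(self.values)


def mean_replicate_density(density_sets: Sequence[DensitySet]) -> DensitySet:
    """Position-wise arithmetic mean over replicate density sets.

    All replicates must share unit and normalization (use rpm so library
    depth cancels); a transcript contributes wherever it is present, and
    mismatched vector lengths raise an error naming the transcript.
    """
    if not density_sets:
        raise ValueError("need at least one replicate")
    first = density_sets[0]
    for ds in density_sets[1:]:
        if ds.unit != first.unit or ds.normalization != first.normalization:
            raise ValueError("replicates differ in unit or normalization")
    acc: Dict[str, np.ndarray] = {}
    n: Dict[str, int] = {}
    for ds in density_sets:
        for vec in ds:
            if vec.transcript_id in acc:
                if len(vec.values) != len(acc[vec.transcript_id]):
                    raise ValueError(f"transcript {vec.transcript_id}: replicate "
                                     "vectors have mismatched lengths")
                acc[vec.transcript_id] = acc[vec.transcript_id] + vec.values
            else:
                acc[vec.transcript_id] = vec.values.astype(float).copy()
            n[vec.transcript_id] = n.get(vec.transcript_id, 0) + 1
    vectors = {tid: DensityVector(tid, first.unit, acc[tid] / n[tid],
                                  first.normalization)
               for tid in acc}
    lib = int(round(np.mean([ds.library_size for ds in density_sets])))
    return DensitySet(vectors, first.unit, lib, normalization=first.normalization)


def enrichment_ratio(
    ip_density: DensitySet,
    total_density: DensitySet,
    pseudocount: Optional[float] = None,
    smoothing_window: int = 7,
    coverage_floor: float = COVERAGE_FLOOR,
) -> Dict[str, EnrichmentProfile]:
    """Smoothed per-codon ratio of IP over total density per transcript.

    Both sets should be rpm-normalized so sequencing depth cancels.  The
    ratio is (ip + eps) / (total + eps) followed by a centered moving
    average of ``smoothing_window`` codons.  ``pseudocount=None`` picks
    eps = 1 / mean(total) per transcript, which keeps zero-coverage codons
    finite without distorting covered ones.  Transcripts absent from
    either sample, or whose total-sample coverage is below
    ``coverage_floor`` raw reads/codon, are skipped (counted in the log).
    """
    if smoothing_window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    profiles: Dict[str, EnrichmentProfile] = {}
    skipped_absent = skipped_sparse = 0
    rpm_per_read_total = (1e6 / total_density.library_size
                          if total_density.normalization == "rpm" else 1.0)
    for vec in ip_density:
        total_vec = total_density.get(vec.transcript_id)
        if total_vec is None:
            skipped_absent += 1
            continue
        if len(total_vec.values) != len(vec.values):
            raise ValueError(f"transcript {vec.transcript_id}: IP and total vectors "
                             "have mismatched lengths")
        total_mean = float(total_vec.values.mean()) if len(total_vec.values) else 0.0
        raw_mean = total_mean / rpm_per_read_total
        if raw_mean < coverage_floor:
            skipped_sparse += 1
            continue
        eps = pseudocount if pseudocount is not None else 1.0 / total_mean
        ratio = (vec.values + eps) / (total_vec.values + eps)
        smoothed = moving_average(ratio, smoothing_window)
        profiles[vec.transcript_id] = EnrichmentProfile(
            vec.transcript_id, smoothed, smoothing_window, eps)
    if skipped_absent or skipped_sparse:
        logger.info("enrichment: skipped %d transcript(s) absent from the total "
                    "sample and %d below the coverage floor",
                    skipped_absent, skipped_sparse)
    return profiles


def detect_engagement_onset(
    profile: EnrichmentProfile,
    threshold: float = 2.0,
    min_run: int = 5,
) -> Optional[int]:
    """First codon (1-based) where the smoothed ratio stays at or above
    ``threshold`` for at least ``min_run`` consecutive codons; None if the
    ratio never qualifies."""
    above = profile.values >= threshold
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= min_run:
            return i - min_run + 2  # 1-based start of the qualifying run
    return None


def aggregate_enrichment(
    profiles: Mapping[str, EnrichmentProfile],
    gene_set: Optional[Iterable[str]] = None,
    window: int = 100,
    ci: bool = True,
    n_boot: int = 1000,
    seed: int = 0,
) -> MetageneProfile:
    """Start-anchored mean enrichment ratio across transcripts, with a
    transcript-level bootstrap confidence band."""
    wanted = set(gene_set) if gene_set is not None else None
    rows = []
    for tid, prof in sorted(profiles.items()):
        if wanted is not None and tid not in wanted:
            continue
        row = np.full(window, np.nan)
        k = min(window, len(prof.values))
        row[:k] = prof.values[:k]
        rows.append(row)
    if not rows:
        raise ValueError("no enrichment profile matches the gene set")
    matrix = np.vstack(rows)
    return _profile_from_matrix(matrix, np.arange(1, window + 1), "start",
                                "codon", ci, n_boot, seed)


def write_enrichment_tsv(profiles: Mapping[str, EnrichmentProfile], path,
                         header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("transcript_id\tposition\tratio\n")
        for tid in sorted(profiles):
            for i, v in enumerate(profiles[tid].values, start=1):
                fh.write(f"{tid}\t{i}\t{v:.6g}\n")
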