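"""Selective-ribosome-profiling enrichment and engagement onset.

The IP sample is 4x enriched from codon 100 onward on the 30% of genes
that are true targets of the tagged factor.  The per-transcript IP/total
ratio crosses the conventional two-fold threshold at the engagement
onset; non-target genes stay flat.
"""

import tempfile
from dataclasses import replace
from pathlib import Path

import numpy as np

from riboscope import (SimulationScenario, assign_psites,
                       build_density_vectors, detect_engagement_onset,
                       enrichment_ratio, infer_psite_offsets,
                       iter_alignments, make_genome_annotation,
                       normalize_set, simulate_footprints)

workdir = Path(tempfile.mkdtemp())
base = SimulationScenario(n_genes=20, cds_codons_range=(180, 260),
                          library_size=60_000, up_gene_fraction=0.3)
genome = make_genome_annotation(base, seed=51)


def rpm_densities(scenario, seed):
    tx_sam, _, _ = simulate_footprints(genome, scenario, seed)
    sam = workdir / f"lib{seed}.sam"
    sam.write_text(tx_sam)
    alns = list(iter_alignments(sam, require_forward=True))
    offsets = infer_psite_offsets(alns, genome.catalog)
    psites, _ = assign_psites(alns, offsets, genome.catalog)
    return normalize_set(build_density_vectors(psites, genome.catalog,
                                               unit="codon"), "rpm")


total = rpm_densities(base, 52)
ip = rpm_densities(replace(base, engagement=(100, 4.0)), 53)

profiles = enrichment_ratio(ip, total, smoothing_window=7)
targets = {e.transcript_id for e in genome.catalog
           if genome.truth.gene_labels[e.gene_id] == "up"}

onsets = []
print("engagement onsets at the two-fold threshold (planted onset: codon 100):")
for tid in sorted(profiles):
    onset = detect_engagement_onset(profiles[tid], threshold=2.0, min_run=5)
    role = "target" if tid in targets else "non-target"
    if onset is not None:
        onsets.append(onset)
        print(f"  {tid} ({role}): onset at codon {onset}")
print(f"\n{len(onsets)} transcripts crossed the threshold; "
      f"median onset codon {np.median(onsets):.0f}")
print("non-target transcripts never cross it: library renormalization keeps "
      "their ratio near (and below) 1")
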