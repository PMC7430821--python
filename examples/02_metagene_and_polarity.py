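"""Metagene analysis of a planted early-elongation stall.

Every gene in this scenario carries 5x ribosome density over codons
1-100, the signature of an elongation block shortly after initiation.
The start-anchored metagene profile and the polarity-score distribution
both recover it.
"""

import tempfile
from pathlib import Path

import numpy as np

from riboscope import (SimulationScenario, assign_psites,
                       build_density_vectors, infer_psite_offsets,
                       iter_alignments, make_genome_annotation,
                       metagene_anchored, polarity_scores,
                       simulate_footprints)

scenario = SimulationScenario(
    n_genes=30, cds_codons_range=(260, 320), library_size=60_000,
    up_gene_fraction=1.0, stall=(100, 5.0),
)
genome = make_genome_annotation(scenario, seed=21)
tx_sam, _, _ = simulate_footprints(genome, scenario, seed=22)
sam = Path(tempfile.mkdtemp()) / "lib.sam"
sam.write_text(tx_sam)

alns = list(iter_alignments(sam, require_forward=True))
offsets = infer_psite_offsets(alns, genome.catalog)
psites, _ = assign_psites(alns, offsets, genome.catalog)
densities = build_density_vectors(psites, genome.catalog, unit="codon")

profile = metagene_anchored(densities, genome.catalog, anchor="start",
                            window=250, n_boot=300, seed=1)
early = np.nanmean(profile.mean[:100])
late = np.nanmean(profile.mean[150:250])
print(f"mean relative density codons 1-100:   {early:.2f}")
print(f"mean relative density codons 151-250: {late:.2f}")
print(f"early/late ratio: {early / late:.2f} "
      "(~5 expected from the planted 5x stall)")

records = polarity_scores(densities, genome.catalog)
scores = np.array([r.score for r in records])
print(f"\npolarity scores over {len(scores)} genes: "
      f"median {np.median(scores):+.3f} "
      "(negative = density leaning toward the 5' end, as a stall predicts)")
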