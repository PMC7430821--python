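"""Shared fixtures: simulated datasets written once per session."""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import pytest

from riboscope.simulate import (SimulationScenario, make_genome_annotation,
                                simulate_footprints)


class Dataset:
    """A simulated genome plus one or more footprint samples on it."""

    def __init__(self, scenario: SimulationScenario, seed: int, outdir: Path):
        self.scenario = scenario
        self.seed = seed
        self.dir = outdir
        self.genome = make_genome_annotation(scenario, seed)
        self.catalog = self.genome.catalog
        self.samples = {}

    def add_sample(self, name: str, scenario: SimulationScenario, seed: int) -> Path:
        tx_sam, gen_sam, truth = simulate_footprints(self.genome, scenario, seed)
        tx_path = self.dir / f"{name}.tx.sam"
        gen_path = self.dir / f"{name}.genome.sam"
        tx_path.write_text(tx_sam)
        gen_path.write_text(gen_sam)
        self.samples[name] = {"tx": tx_path, "genome": gen_path, "truth": truth,
                              "scenario": scenario}
        return tx_path

    def sample(self, name: str):
        return self.samples[name]


@pytest.fixture(scope="session")
def qc_dataset(tmp_path_factory) -> Dataset:
    """General-purpose library: phased 28-30 nt reads, a 20-nt unphased
    contaminant class, some UTR reads, and genomic contamination."""
    sc = SimulationScenario(
        n_genes=20, library_size=30_000,
        unphased_length=20, unphased_fraction=0.15,
        utr5_read_fraction=0.03, utr3_read_fraction=0.01,
        intergenic_fraction=0.08, intron_fraction=0.03,
    )
    ds = Dataset(sc, seed=11, outdir=tmp_path_factory.mktemp("qc_ds"))
    ds.add_sample("main", sc, seed=12)
    return ds


@pytest.fixture(scope="session")
def stall_dataset(tmp_path_factory) -> Dataset:
    """Every gene carries a 5x density excess over codons 1-100."""
    sc = SimulationScenario(
        n_genes=30, cds_codons_range=(260, 320), library_size=60_000,
        up_gene_fraction=1.0, stall=(100, 5.0),
    )
    ds = Dataset(sc, seed=21, outdir=tmp_path_factory.mktemp("stall_ds"))
    ds.add_sample("stalled", sc, seed=22)
    ds.add_sample("uniform", replace(sc, stall=None, init_peak_multiplier=1.0), seed=23)
    return ds


@pytest.fixture(scope="session")
def classification_dataset(tmp_path_factory) -> Dataset:
    """Control/treated pair: 30% of genes get 2x early density in treated."""
    genome_sc = SimulationScenario(
        n_genes=50, cds_codons_range=(150, 250), library_size=100_000,
        up_gene_fraction=0.3,
    )
    ds = Dataset(genome_sc, seed=31, outdir=tmp_path_factory.mktemp("classify_ds"))
    ds.add_sample("control", genome_sc, seed=32)
    ds.add_sample("treated", replace(genome_sc, stall=(100, 2.0)), seed=33)
    return ds


@pytest.fixture(scope="session")
def motif_dataset(tmp_path_factory) -> Dataset:
    """Poly-proline motifs written into every CDS; treated sample carries a
    10x pause at each PPP A-site codon."""
    genome_sc = SimulationScenario(
        n_genes=30, cds_codons_range=(200, 280), library_size=40_000,
        planted_motif=("PPP", 3),
    )
    ds = Dataset(genome_sc, seed=41, outdir=tmp_path_factory.mktemp("motif_ds"))
    ds.add_sample("control", genome_sc, seed=42)
    ds.add_sample("treated", replace(genome_sc, motif_pause=("PPP", 10.0)), seed=43)
    return ds


@pytest.fixture(scope="session")
def engagement_dataset(tmp_path_factory) -> Dataset:
    """SeRP-style pair: in the IP sample, the 30% of genes labeled 'up' are
    4x enriched from codon 100 onward (the engaged targets)."""
    genome_sc = SimulationScenario(
        n_genes=20, cds_codons_range=(180, 260), library_size=60_000,
        up_gene_fraction=0.3,
    )
    ds = Dataset(genome_sc, seed=51, outdir=tmp_path_factory.mktemp("serp_ds"))
    ds.add_sample("total", genome_sc, seed=52)
    ds.add_sample("ip", replace(genome_sc, engagement=(100, 4.0)), seed=53)
    return ds
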