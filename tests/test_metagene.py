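"""Metagene profiles, polarity scores and their invariants."""

import numpy as np
import pytest

from riboscope.annotation import CatalogEntry, TranscriptCatalog
from riboscope.density import (DensitySet, DensityVector, PsiteOffsetTable,
                               assign_psites,
                               infer_psite_offsets, iter_alignments,
                               build_density_vectors)
from riboscope.metagene import (bin_codon_density, metagene_anchored,
                                metagene_whole_regions, polarity_score,
                                polarity_scores)


def _density_set(vectors, normalization="raw"):
    return DensitySet({v.transcript_id: v for v in vectors}, "codon",
                      library_size=int(sum(v.values.sum() for v in vectors)),
                      normalization=normalization)


def _catalog_for(vectors):
    entries = []
    for v in vectors:
        n = len(v.values)
        entries.append(CatalogEntry(f"g_{v.transcript_id}", v.transcript_id, "c",
                                    "+", [(0, 3 * n + 40)], 20, 3 * n, 20))
    return TranscriptCatalog(entries)


@pytest.fixture(scope="module")
def stalled_densities(stall_dataset):
    alns = list(iter_alignments(stall_dataset.sample("stalled")["tx"],
                                require_forward=True))
    offsets = infer_psite_offsets(alns, stall_dataset.catalog)
    psites, _ = assign_psites(alns, offsets, stall_dataset.catalog)
    return build_density_vectors(psites, stall_dataset.catalog, unit="codon")


class TestPolarity:
    def test_all_mass_on_last_codon_is_one(self):
        assert polarity_score(np.array([0.0, 0, 0, 7.0])) == pytest.approx(1.0)

    def test_all_mass_on_first_codon_is_minus_one(self):
        assert polarity_score(np.array([5.0, 0, 0, 0])) == pytest.approx(-1.0)

    def test_uniform_is_zero(self):
        for L in (2, 5, 17, 100):
            assert polarity_score(np.ones(L)) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_endpoint_example(self):
        # weights (-1, -1/3, 1/3, 1): equal mass at both ends cancels
        assert polarity_score(np.array([1.0, 0, 0, 1.0])) == pytest.approx(0.0)

    def test_reversal_antisymmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            d = rng.poisson(2.0, size=rng.integers(2, 60)).astype(float)
            if d.sum() == 0:
                continue
            assert polarity_score(d[::-1]) == pytest.approx(-polarity_score(d), abs=1e-12)

    def test_bounds_on_simulated_data(self, stall_dataset, stalled_densities):
        records = polarity_scores(stalled_densities, stall_dataset.catalog)
        assert records, "coverage filter removed everything"
        for r in records:
            assert -1.0 <= r.score <= 1.0

    def test_early_stall_shifts_polarity_negative(self, stall_dataset, stalled_densities):
        records = polarity_scores(stalled_densities, stall_dataset.catalog)
        assert np.median([r.score for r in records]) < -0.1


class TestWholeRegions:
    def test_uniform_density_gives_flat_profile(self, stall_dataset):
        alns = list(iter_alignments(stall_dataset.sample("uniform")["tx"],
                                    require_forward=True))
        # a deliberately flat library has no initiation peak to calibrate
        # offsets from, so the planted table is used directly
        truth = stall_dataset.sample("uniform")["truth"]
        offsets = PsiteOffsetTable(dict(truth.offsets))
        psites, _ = assign_psites(alns, offsets, stall_dataset.catalog)
        ds = build_density_vectors(psites, stall_dataset.catalog, unit="codon")
        prof = metagene_whole_regions(ds, stall_dataset.catalog, n_bins=30,
                                      ci=False, trim=0)
        # ~7 reads/codon x 30 transcripts: per-bin SE ~ 0.025, max dev ~ 4 SE
        assert np.allclose(prof.mean, 1.0, atol=0.2)
        assert prof.mean.mean() == pytest.approx(1.0, abs=0.02)

    def test_single_bin_equals_mean_relative_density(self):
        vectors = [DensityVector(f"t{i}", "codon",
                                 np.array([2.0, 1.0, 3.0, 2.0, 0.0])) for i in range(3)]
        ds = _density_set(vectors)
        catalog = _catalog_for(vectors)
        prof = metagene_whole_regions(ds, catalog, n_bins=1, ci=False,
                                      min_reads=0, min_mean=0, trim=0)
        # per-mean normalization over sense codons; the stop codon dilutes
        # the single bin by exactly (L-1)/L
        assert prof.mean[0] == pytest.approx(4 / 5)

    def test_fractional_binning_preserves_mass(self):
        values = np.array([1.0, 5.0, 2.0, 0.5, 3.0, 1.5, 4.0])
        binned = bin_codon_density(values, 3)
        # total mass (value x width) is conserved
        assert binned.sum() * len(values) / 3 == pytest.approx(values.sum())

    def test_stall_scenario_elevates_early_bins(self, stall_dataset, stalled_densities):
        prof = metagene_whole_regions(stalled_densities, stall_dataset.catalog,
                                      n_bins=30, ci=False)
        early = prof.mean[1:9].mean()   # codons ~10-90 of ~290
        late = prof.mean[20:].mean()
        assert early > 2 * late


class TestAnchored:
    def test_uniform_profile_near_one_with_ci(self, stall_dataset):
        alns = list(iter_alignments(stall_dataset.sample("uniform")["tx"],
                                    require_forward=True))
        # a deliberately flat library has no initiation peak to calibrate
        # offsets from, so the planted table is used directly
        truth = stall_dataset.sample("uniform")["truth"]
        offsets = PsiteOffsetTable(dict(truth.offsets))
        psites, _ = assign_psites(alns, offsets, stall_dataset.catalog)
        ds = build_density_vectors(psites, stall_dataset.catalog, unit="codon")
        prof = metagene_anchored(ds, stall_dataset.catalog, anchor="start",
                                 window=80, n_boot=200, seed=4, trim=0)
        # per-position SE ~ 0.07 across 30 transcripts
        assert np.allclose(prof.mean, 1.0, atol=0.3)
        assert prof.mean.mean() == pytest.approx(1.0, abs=0.03)
        inside = (prof.ci_lower <= 1.0) & (1.0 <= prof.ci_upper)
        assert inside.mean() > 0.85

    def test_planted_pause_peaks_at_planted_codon(self):
        rng = np.random.default_rng(9)
        vectors = []
        for i in range(12):
            vals = np.ones(120)
            vals[49] = 10.0  # codon 50
            vals[-1] = 0.0
            vectors.append(DensityVector(f"t{i}", "codon", vals))
        ds = _density_set(vectors)
        prof = metagene_anchored(ds, _catalog_for(vectors), anchor="start",
                                 window=100, ci=False, min_mean=0, trim=0)
        assert int(prof.positions[np.argmax(prof.mean)]) == 50

    def test_uniform_coverage_profile_mean_is_exactly_one(self):
        vectors = [DensityVector(f"t{i}", "codon",
                                 np.concatenate([np.full(60, 3.0), [0.0]]))
                   for i in range(4)]
        ds = _density_set(vectors)
        prof = metagene_anchored(ds, _catalog_for(vectors), anchor="start",
                                 window=60, ci=False, min_mean=0, trim=0)
        assert np.allclose(prof.mean[:-1], 1.0, atol=1e-9)

    def test_stop_anchor_positions_cover_tail(self):
        vectors = [DensityVector("t0", "codon", np.arange(50, dtype=float))]
        ds = _density_set(vectors)
        prof = metagene_anchored(ds, _catalog_for(vectors), anchor="stop",
                                 window=10, ci=False, min_mean=0, trim=0)
        assert prof.positions[0] == -10 and prof.positions[-1] == -1
        assert prof.n.sum() == 10

    def test_gene_set_union_is_average_of_halves(self, stall_dataset, stalled_densities):
        genes = sorted({e.gene_id for e in stall_dataset.catalog})
        half_a, half_b = genes[:15], genes[15:30]
        kw = dict(anchor="start", window=50, ci=False)
        pa = metagene_anchored(stalled_densities, stall_dataset.catalog, half_a, **kw)
        pb = metagene_anchored(stalled_densities, stall_dataset.catalog, half_b, **kw)
        pu = metagene_anchored(stalled_densities, stall_dataset.catalog,
                               half_a + half_b, **kw)
        mask = (pa.n > 0) & (pb.n > 0) & (pa.n == pb.n)
        expected = (pa.mean * pa.n + pb.mean * pb.n) / (pa.n + pb.n)
        assert np.allclose(pu.mean[mask], expected[mask], atol=1e-12)

    def test_bootstrap_width_shrinks_with_transcript_count(self, stall_dataset,
                                                           stalled_densities):
        """Quadrupling the transcript count roughly halves the CI width."""
        genes = sorted({e.gene_id for e in stall_dataset.catalog})
        kw = dict(anchor="start", window=40, n_boot=400, seed=13)
        small = metagene_anchored(stalled_densities, stall_dataset.catalog,
                                  genes[:7], **kw)
        large = metagene_anchored(stalled_densities, stall_dataset.catalog,
                                  genes[:28], **kw)
        w_small = np.nanmean(small.ci_upper - small.ci_lower)
        w_large = np.nanmean(large.ci_upper - large.ci_lower)
        assert w_large / w_small == pytest.approx(0.5, abs=0.15)

    def test_window_larger_than_all_transcripts_raises(self):
        vectors = [DensityVector("t0", "codon", np.ones(10))]
        ds = _density_set(vectors)
        with pytest.raises(ValueError):
            metagene_anchored(ds, _catalog_for(vectors), anchor="start",
                              window=50, ci=False, min_mean=0, trim=0)
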