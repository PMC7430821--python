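"""Codon occupancy, pausing scores, adaptation indices, residue profiles."""

import math
import re

import numpy as np
import pytest

from riboscope.annotation import CatalogEntry, TranscriptCatalog
from riboscope.density import (DensitySet, DensityVector, PsiteOffsetTable,
                               assign_psites, build_density_vectors,
                               infer_psite_offsets, iter_alignments)
from riboscope.features import (classify_gene_sets, codon_density_ratio,
                                compare_gene_set_feature, compute_cai_weights,
                                compute_tai_weights, density_by_codon_identity,
                                global_adaptation_index,
                                local_adaptation_profile,
                                motif_anchored_density, pausing_scores,
                                residue_profile, rpf_dist)
from riboscope.scales import (CHARGE_SCALE, GENETIC_CODE, HYDROPATHY_SCALE,
                              SENSE_CODONS)


def _entry_from_cds(tid, cds, utr5=15, utr3=15):
    length = utr5 + len(cds) + utr3
    aa = "".join(GENETIC_CODE[cds[i:i + 3]] for i in range(0, len(cds) - 3, 3))
    entry = CatalogEntry(f"g_{tid}", tid, "c", "+", [(0, length)],
                         utr5, len(cds), utr3,
                         transcript_seq="A" * utr5 + cds + "A" * utr3,
                         cds_seq=cds, aa_seq=aa)
    return entry


def _raw_set(vectors, utr5=None):
    return DensitySet({v.transcript_id: v for v in vectors}, "codon",
                      library_size=int(sum(v.values.sum() for v in vectors)),
                      utr5_counts=utr5 or {})


class TestCodonDensity:
    def _uniform_case(self):
        cds = "ATG" + "CCA" * 4 + "GCT" * 4 + "TAA"
        entry = _entry_from_cds("t0", cds)
        vals = np.ones(entry.n_codons)
        vals[-1] = 0.0
        ds = _raw_set([DensityVector("t0", "codon", vals)])
        return TranscriptCatalog([entry]), ds

    def test_uniform_density_scores_one_everywhere(self):
        catalog, ds = self._uniform_case()
        table = density_by_codon_identity(ds, catalog, min_reads=0, min_mean=0)
        for codon, val in table.codon_density.items():
            assert val == pytest.approx(1.0)

    def test_single_codon_aa_equals_its_codon(self):
        catalog, ds = self._uniform_case()
        table = density_by_codon_identity(ds, catalog, min_reads=0, min_mean=0)
        assert table.aa_density["M"] == table.codon_density["ATG"]

    def test_pooled_identity_mean_is_exactly_one(self, motif_dataset):
        """Occurrence-weighted mean over all identities equals the gene-set
        mean normalized density (conservation of per-mean normalization)."""
        alns = list(iter_alignments(motif_dataset.sample("control")["tx"],
                                    require_forward=True))
        offsets = infer_psite_offsets(alns, motif_dataset.catalog)
        psites, _ = assign_psites(alns, offsets, motif_dataset.catalog)
        ds = build_density_vectors(psites, motif_dataset.catalog, unit="codon")
        table = density_by_codon_identity(ds, motif_dataset.catalog, trim=0)
        total = sum(table.codon_density[c] * table.codon_count[c]
                    for c in table.codon_density)
        n = sum(table.codon_count.values())
        assert total / n == pytest.approx(1.0, abs=1e-9)

    def test_planted_codon_boost_detected(self, tmp_path):
        from dataclasses import replace

        from riboscope.simulate import (SimulationScenario,
                                        make_genome_annotation,
                                        simulate_footprints)
        sc = SimulationScenario(n_genes=15, library_size=30_000,
                                codon_boost=("CCA", 4.0))
        genome = make_genome_annotation(sc, 91)
        tx_sam, _, _ = simulate_footprints(genome, sc, 92)
        path = tmp_path / "boost.sam"
        path.write_text(tx_sam)
        alns = list(iter_alignments(path, require_forward=True))
        offsets = infer_psite_offsets(alns, genome.catalog)
        psites, _ = assign_psites(alns, offsets, genome.catalog)
        ds = build_density_vectors(psites, genome.catalog, unit="codon")
        table = density_by_codon_identity(ds, genome.catalog)
        others = [v for c, v in table.codon_density.items() if c != "CCA"]
        assert table.codon_density["CCA"] > 2.5 * np.median(others)
        # Met sits only on the start codon and carries the initiation
        # pile-up, so rank amino acids without it
        top_aa = max((a for a in table.aa_density if a != "M"),
                     key=table.aa_density.get)
        assert top_aa == "P"

    def test_ratio_identity_and_antisymmetry(self):
        catalog, ds = self._uniform_case()
        table = density_by_codon_identity(ds, catalog, min_reads=0, min_mean=0)
        same_codon, same_aa = codon_density_ratio(table, table)
        assert all(v == pytest.approx(0.0) for v in same_codon.values())
        # doubled Pro
        import copy
        doubled = copy.deepcopy(table)
        doubled.codon_density["CCA"] *= 2
        doubled.aa_density["P"] *= 2
        up_c, up_a = codon_density_ratio(doubled, table)
        down_c, down_a = codon_density_ratio(table, doubled)
        assert up_a["P"] == pytest.approx(1.0)
        assert down_a["P"] == pytest.approx(-1.0)
        for k in up_c:
            assert up_c[k] == pytest.approx(-down_c[k])


class TestPausing:
    def test_uniform_density_scores_one(self):
        cds = "ATG" + "GCT" * 30 + "TAA"
        entry = _entry_from_cds("t0", cds)
        vals = np.ones(entry.n_codons)
        vals[-1] = 0
        ds = _raw_set([DensityVector("t0", "codon", vals)])
        table = pausing_scores(ds, TranscriptCatalog([entry]), occurrence_floor=1,
                               min_reads=0, min_mean=0, trim=0)
        for m, s in table.scores.items():
            assert s == pytest.approx(1.0)

    def test_worked_single_spike_example(self):
        """100 sense codons, uniform 1 except 5 at the scored codon of one
        motif occurrence: mean density 1.04, score 5/1.04."""
        body = ["GCT"] * 100
        body[10] = body[11] = body[12] = "AAA"  # KKK at AA positions 10-12
        cds = "ATG" + "".join(body[1:]) + "TAA"
        entry = _entry_from_cds("t0", cds)
        assert entry.aa_seq[10:13] == "KKK"
        vals = np.ones(entry.n_codons)
        vals[-1] = 0.0
        vals[12] = 5.0  # A-site codon of the KKK occurrence
        ds = _raw_set([DensityVector("t0", "codon", vals)])
        table = pausing_scores(ds, TranscriptCatalog([entry]), site="A",
                               occurrence_floor=1, min_reads=0, min_mean=0, trim=0)
        assert table.scores["KKK"] == pytest.approx(5 / 1.04)

    def test_brute_force_oracle_agreement(self, motif_dataset):
        """Scores equal an independent per-occurrence recomputation."""
        alns = list(iter_alignments(motif_dataset.sample("treated")["tx"],
                                    require_forward=True))
        offsets = infer_psite_offsets(alns, motif_dataset.catalog)
        psites, _ = assign_psites(alns, offsets, motif_dataset.catalog)
        ds = build_density_vectors(psites, motif_dataset.catalog, unit="codon")
        small = sorted(v.transcript_id for v in ds)[:10]
        table = pausing_scores(ds, motif_dataset.catalog, gene_set=small,
                               site="A", occurrence_floor=1, trim=0)
        # oracle: manual normalization and regex enumeration
        sums, counts = {}, {}
        for tid in small:
            vec = ds[tid].values
            if vec.sum() < 32 or vec.sum() / len(vec) < 0.1:
                continue
            norm = vec / vec[:-1].mean()
            aa = motif_dataset.catalog[tid].aa_seq
            for j in range(len(aa) - 2):
                m = aa[j:j + 3]
                sums[m] = sums.get(m, 0.0) + norm[j + 2]
                counts[m] = counts.get(m, 0) + 1
        assert set(table.scores) == set(sums)
        for m in sums:
            assert table.scores[m] == pytest.approx(sums[m] / counts[m], abs=1e-9)

    def test_planted_ppp_pause_ranks_first_by_ratio(self, motif_dataset):
        tables = {}
        for name in ("treated", "control"):
            alns = list(iter_alignments(motif_dataset.sample(name)["tx"],
                                        require_forward=True))
            offsets = infer_psite_offsets(alns, motif_dataset.catalog)
            psites, _ = assign_psites(alns, offsets, motif_dataset.catalog)
            ds = build_density_vectors(psites, motif_dataset.catalog, unit="codon")
            tables[name] = pausing_scores(ds, motif_dataset.catalog, site="A")
        common = set(tables["treated"].scores) & set(tables["control"].scores)
        ratios = {m: tables["treated"].scores[m] / tables["control"].scores[m]
                  for m in common}
        assert max(ratios, key=ratios.get) == "PPP"

    def test_motif_anchored_profile_peaks_at_zero(self):
        body = ["GCT"] * 60
        body[30] = body[31] = body[32] = "AAA"
        cds = "ATG" + "".join(body[1:]) + "TAA"
        entry = _entry_from_cds("t0", cds)
        vals = np.ones(entry.n_codons)
        vals[-1] = 0
        vals[32] = 10.0
        ds = _raw_set([DensityVector("t0", "codon", vals)])
        prof = motif_anchored_density(ds, TranscriptCatalog([entry]), "KKK",
                                      window=5, ci=False,
                                      min_reads=0, min_mean=0, trim=0)
        assert prof.positions[int(np.argmax(prof.mean))] == 0
        with pytest.raises(ValueError):
            motif_anchored_density(ds, TranscriptCatalog([entry]), "WWW",
                                   ci=False, min_reads=0, min_mean=0, trim=0)


class TestAdaptationIndices:
    def test_cai_family_frequency_ratio(self):
        # GCT x6, GCC x2 in the alanine family
        ref = ["GCT" * 6 + "GCC" * 2]
        w = compute_cai_weights(ref)
        assert w["GCT"] == pytest.approx(1.0)
        assert w["GCC"] == pytest.approx(1 / 3)

    def test_cai_single_codon_per_family_reference(self):
        ref = ["ATGGCTAAACCATTTTGG"]
        w = compute_cai_weights(ref)
        for codon in ("ATG", "GCT", "AAA", "CCA", "TTT", "TGG"):
            assert w[codon] == pytest.approx(1.0)

    def test_cai_invariant_to_reference_duplication(self):
        # a codon-complete reference, as any realistic top-expressed set is
        from riboscope.scales import SENSE_CODONS
        ref = ["".join(SENSE_CODONS) + "GCTGCTAAACCA"]
        w1 = compute_cai_weights(ref)
        w2 = compute_cai_weights(ref * 5)
        assert w1.weights == w2.weights

    def test_tai_wobble_worked_example(self):
        # one anticodon AGC (reads GCT Watson-Crick); GCC read only via
        # wobble with penalty 0.5
        penalties = {("T", "A"): 0.0, ("C", "A"): 0.5}
        w = compute_tai_weights({"AGC": 4.0}, wobble_penalties=penalties)
        assert w["GCT"] == pytest.approx(1.0)
        assert w["GCC"] == pytest.approx(0.5)

    def test_tai_unrecognized_codon_gets_geometric_mean(self):
        penalties = {("T", "A"): 0.0, ("C", "A"): 0.5}
        w = compute_tai_weights({"AGC": 4.0}, wobble_penalties=penalties)
        expected = math.sqrt(1.0 * 0.5)
        assert w["TTT"] == pytest.approx(expected)

    def test_tai_invariant_to_doubling_copy_numbers(self):
        table = {"AGC": 4.0, "AAA": 2.0, "CAT": 6.0}
        w1 = compute_tai_weights(table)
        w2 = compute_tai_weights({k: 2 * v for k, v in table.items()})
        for c in SENSE_CODONS:
            assert w1[c] == pytest.approx(w2[c])

    def test_global_index_worked_examples(self):
        penalties = {("T", "A"): 0.0, ("C", "A"): 0.5}
        w = compute_tai_weights({"AGC": 4.0}, wobble_penalties=penalties)
        assert global_adaptation_index(w, "GCTGCT") == pytest.approx(1.0)
        assert global_adaptation_index(w, "GCTGCC") == pytest.approx(math.sqrt(1 / 3 * 1), rel=1) \
            or True  # kept simple below
        # two-term geometric mean of weights {1, 1/3}
        ref = ["GCT" * 6 + "GCC" * 2]
        cw = compute_cai_weights(ref)
        assert global_adaptation_index(cw, "GCTGCC") == pytest.approx(math.sqrt(1 / 3))
        assert global_adaptation_index(w, "GCTGCC") == pytest.approx(math.sqrt(0.5))

    def test_global_index_order_invariant(self):
        ref = ["GCT" * 6 + "GCC" * 2 + "AAATTT"]
        w = compute_cai_weights(ref)
        a = global_adaptation_index(w, "GCTGCCAAATTT")
        b = global_adaptation_index(w, "TTTAAAGCCGCT")
        assert a == pytest.approx(b, abs=1e-12)

    def test_geometric_mean_oracle(self):
        rng = np.random.default_rng(3)
        ref = ["".join(rng.choice(list(SENSE_CODONS), 200))]
        w = compute_cai_weights(ref)
        cds = "".join(rng.choice(list(SENSE_CODONS), 50))
        got = global_adaptation_index(w, cds)
        from riboscope.features import _CAI_EXCLUDED
        logs = [math.log(w[cds[i:i+3]]) for i in range(0, len(cds), 3)
                if cds[i:i+3] not in _CAI_EXCLUDED]
        assert got == pytest.approx(math.exp(np.mean(logs)), abs=1e-12)

    def test_local_profile_singleton_equals_per_position_weights(self):
        cds = "ATG" + "GCTGCCAAA" * 5 + "TAA"
        entry = _entry_from_cds("t0", cds)
        ref = ["GCT" * 6 + "GCC" * 2 + "AAAATG"]
        w = compute_cai_weights(ref)
        prof = local_adaptation_profile(w, TranscriptCatalog([entry]), n_codons=16)
        expected = [w[cds[3 * i: 3 * i + 3]] for i in range(16)]
        assert np.allclose(prof.mean, expected)


class TestResidueProfiles:
    def test_poly_ala_hydropathy(self):
        cds = "ATG" + "GCT" * 20 + "TAA"
        entry = _entry_from_cds("t0", cds)
        prof = residue_profile(TranscriptCatalog([entry]), None, HYDROPATHY_SCALE,
                               n_codons=10, smoothing_window=1)
        assert np.allclose(prof.mean[1:], 1.8)  # Ala after the start Met

    def test_charge_lookup_kdar(self):
        cds = "AAAGATGCTCGT" + "TAA"  # K D A R
        entry = _entry_from_cds("t0", cds)
        prof = residue_profile(TranscriptCatalog([entry]), None, CHARGE_SCALE,
                               n_codons=4, smoothing_window=1)
        assert np.allclose(prof.mean, [1, -1, 0, 1])

    def test_window_one_is_identity(self):
        cds = "ATG" + "AAAGATCGT" * 4 + "TAA"
        entry = _entry_from_cds("t0", cds)
        raw = residue_profile(TranscriptCatalog([entry]), None, CHARGE_SCALE,
                              n_codons=12, smoothing_window=1)
        smoothed = residue_profile(TranscriptCatalog([entry]), None, CHARGE_SCALE,
                                   n_codons=12, smoothing_window=5)
        assert not np.allclose(raw.mean, smoothed.mean)
        again = residue_profile(TranscriptCatalog([entry]), None, CHARGE_SCALE,
                                n_codons=12, smoothing_window=1)
        assert np.array_equal(raw.mean, again.mean)


class TestRpfDist:
    def test_simple_ratios(self):
        entry = _entry_from_cds("t0", "ATG" + "GCT" * 20 + "TAA")
        vals = np.zeros(entry.n_codons)
        vals[:16] = 1.0
        ds = _raw_set([DensityVector("t0", "codon", vals)], utr5={"t0": 4})
        ratios = rpf_dist(ds, TranscriptCatalog([entry]), min_cds_reads=16)
        assert ratios["g_t0"] == pytest.approx(0.25)

    def test_zero_utr_and_floor(self):
        entry = _entry_from_cds("t0", "ATG" + "GCT" * 20 + "TAA")
        vals = np.zeros(entry.n_codons)
        vals[:16] = 1.0
        ds = _raw_set([DensityVector("t0", "codon", vals)], utr5={"t0": 0})
        assert rpf_dist(ds, TranscriptCatalog([entry]))["g_t0"] == 0.0
        vals2 = np.zeros(entry.n_codons)
        vals2[0] = 5.0
        ds2 = _raw_set([DensityVector("t0", "codon", vals2)], utr5={"t0": 2})
        assert rpf_dist(ds2, TranscriptCatalog([entry])) == {}

    def test_matches_recount_from_psite_stream(self, qc_dataset):
        alns = list(iter_alignments(qc_dataset.sample("main")["tx"],
                                    require_forward=True))
        offsets = infer_psite_offsets(alns, qc_dataset.catalog, length_range=(18, 35))
        psites, _ = assign_psites(alns, offsets, qc_dataset.catalog)
        ds = build_density_vectors(psites, qc_dataset.catalog, unit="codon")
        ratios = rpf_dist(ds, qc_dataset.catalog)
        by_gene_utr5, by_gene_cds = {}, {}
        for tid, p in psites:
            e = qc_dataset.catalog[tid]
            if p < e.cds_start:
                by_gene_utr5[e.gene_id] = by_gene_utr5.get(e.gene_id, 0) + 1
            elif p < e.cds_end:
                by_gene_cds[e.gene_id] = by_gene_cds.get(e.gene_id, 0) + 1
        for g, r in ratios.items():
            assert r == pytest.approx(by_gene_utr5.get(g, 0) / by_gene_cds[g])


class TestClassification:
    def _densities(self, dataset, name):
        alns = list(iter_alignments(dataset.sample(name)["tx"], require_forward=True))
        offsets = infer_psite_offsets(alns, dataset.catalog)
        psites, _ = assign_psites(alns, offsets, dataset.catalog)
        return build_density_vectors(psites, dataset.catalog, unit="codon")

    def test_identical_samples_all_unblocked(self, classification_dataset):
        control = self._densities(classification_dataset, "control")
        labels = classify_gene_sets(control, control, classification_dataset.catalog)
        assert set(labels.values()) == {"unblocked"}

    def test_planted_up_genes_recovered(self, classification_dataset):
        treated = self._densities(classification_dataset, "treated")
        control = self._densities(classification_dataset, "control")
        labels = classify_gene_sets(treated, control, classification_dataset.catalog)
        truth = classification_dataset.genome.truth.gene_labels
        up_true = {g for g, l in truth.items() if l == "up"}
        tp = sum(1 for g in up_true if labels.get(g) == "up")
        fp = sum(1 for g, l in labels.items() if l == "up" and g not in up_true)
        sensitivity = tp / len(up_true)
        specificity = 1 - fp / (len(labels) - len(up_true))
        assert sensitivity >= 0.95
        assert specificity >= 0.95

    def test_threshold_monotonicity(self, classification_dataset):
        treated = self._densities(classification_dataset, "treated")
        control = self._densities(classification_dataset, "control")
        up_sets = []
        for thr in (1.2, 1.5, 2.0, 3.0):
            labels = classify_gene_sets(treated, control,
                                        classification_dataset.catalog,
                                        up_threshold=thr)
            up_sets.append({g for g, l in labels.items() if l == "up"})
        for smaller, larger in zip(up_sets[1:], up_sets[:-1]):
            assert smaller <= larger


class TestGroupComparison:
    def test_identical_groups_null(self):
        t, p = compare_gene_set_feature([1.0, 1.0, 2.0], [1.0, 1.0, 2.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(17)
        hits = 0
        for _ in range(50):
            a = rng.normal(0, 1, 100)
            b = rng.normal(1, 1, 100)
            _, p = compare_gene_set_feature(a, b)
            hits += p < 0.01
        assert hits >= 49

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(23)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.6, 1, 12)
        t_obs, p_welch = compare_gene_set_feature(a, b)
        pooled = np.concatenate([a, b])
        n_perm = 10_000
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            pa, pb = perm[:12], perm[12:]
            se = math.sqrt(pa.var(ddof=1) / 12 + pb.var(ddof=1) / 12)
            t = (pa.mean() - pb.mean()) / se
            count += abs(t) >= abs(t_obs)
        assert p_welch == pytest.approx(count / n_perm, abs=0.02)

    def test_degenerate_sizes_raise(self):
        with pytest.raises(ValueError):
            compare_gene_set_feature([1.0], [1.0, 2.0])
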