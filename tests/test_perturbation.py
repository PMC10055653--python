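"""Spike-in scaling, fold-change tracks, response clustering and the
heat-shock induction statistics."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from oracles import best_two_partition_ss
from pauseatlas import io_formats as io
from pauseatlas import perturbation as pert
from pauseatlas import synthetic_data as sd


class TestSpikeScaling:
    def test_factors_from_counts(self):
        s = pert.spike_in_scaling_factors({"a": 100, "b": 300})
        assert s.factors == {"a": pytest.approx(0.5), "b": pytest.approx(1.5)}
        assert np.mean(list(s.factors.values())) == pytest.approx(1.0)

    def test_equal_counts_unit_factors(self):
        s = pert.spike_in_scaling_factors({"a": 7, "b": 7, "c": 7})
        assert all(f == pytest.approx(1.0) for f in s.factors.values())

    def test_scaled_totals(self):
        s = pert.spike_in_scaling_factors({"a": 100, "b": 300})
        track = io.SignalTrack(io.THREE_PRIME)
        track.set_interval("c", "+", 0, 1000, 1.0)
        assert s.scale_track("a", track).total_reads == pytest.approx(2000.0)
        assert s.scale_track("b", track).total_reads == pytest.approx(1000.0 / 1.5)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(io.ValidationError):
            pert.spike_in_scaling_factors({"a": 0, "b": 5})

    def test_scaling_exactly_removes_planted_depth_difference(self):
        """A library sequenced 3x deeper, with 3x the spike-in reads,
        scales back to per-base equality with its shallow twin."""
        _, genes, truths = sd.generate_genome_with_genes(20, seed=1)
        _, shallow = sd.simulate_proseq_tracks(genes, truths, total_reads=50_000, seed=2)
        deep = shallow.scaled(3.0)
        s = pert.spike_in_scaling_factors({"shallow": 10_000, "deep": 30_000})
        a = s.scale_track("shallow", shallow)
        b = s.scale_track("deep", deep)
        for key in a._data:
            av, bv = a._data[key], b._data[key]
            n = min(av.size, bv.size)
            np.testing.assert_allclose(av[:n], bv[:n], rtol=1e-9)


class TestLog2FcTrack:
    def test_identical_tracks_zero(self):
        t = io.SignalTrack(io.THREE_PRIME)
        t.set_interval("c", "+", 0, 100, 2.0)
        fc = pert.log2fc_track(t, t.copy())
        assert np.allclose(fc.values("c", "+", 0, 100), 0.0)

    def test_pseudocount_arithmetic(self):
        treated = io.SignalTrack(io.THREE_PRIME)
        control = io.SignalTrack(io.THREE_PRIME)
        treated.set_interval("c", "+", 0, 1, 0.9)
        control.set_interval("c", "+", 0, 1, 0.4)
        fc = pert.log2fc_track(treated, control)
        assert fc.values("c", "+", 0, 1)[0] == pytest.approx(1.0)

    def test_zero_vs_zero_is_zero(self):
        treated = io.SignalTrack(io.THREE_PRIME)
        control = io.SignalTrack(io.THREE_PRIME)
        treated.set_interval("c", "+", 5, 6, 1.0)  # force contig to exist
        control.set_interval("c", "+", 5, 6, 1.0)
        fc = pert.log2fc_track(treated, control)
        assert fc.values("c", "+", 0, 5) == pytest.approx(np.zeros(5))


class TestBinnedMatrix:
    def _gene(self, strand="+"):
        return io.GeneAnnotation("g", "c", strand, 60_000, 120_000)

    def test_default_geometry_gives_51_columns(self):
        track = io.SignalTrack(io.THREE_PRIME)
        track.set_interval("c", "+", 0, 1, 1.0)
        gene = self._gene()
        m = pert.binned_region_matrix(track, [(gene, gene.tss)])
        assert m.n_bins == 51

    def test_uniform_track_mean_aggregation(self):
        track = io.SignalTrack(io.THREE_PRIME)
        track.set_interval("c", "+", 0, 200_000, 2.0)
        gene = self._gene()
        m = pert.binned_region_matrix(track, [(gene, gene.tss)])
        assert np.allclose(m.values[0][~m.missing[0]], 2.0)
        msum = pert.binned_region_matrix(track, [(gene, gene.tss)], aggregate="sum")
        assert np.allclose(msum.values[0][~msum.missing[0]], 2.0 * 1000)

    def test_bins_past_contig_start_marked_missing(self):
        track = io.SignalTrack(io.THREE_PRIME)
        track.set_interval("c", "+", 0, 10, 1.0)
        gene = io.GeneAnnotation("g", "c", "+", 500, 60_000)
        m = pert.binned_region_matrix(track, [(gene, gene.tss)])
        assert m.missing[0, 0]  # the upstream bin would start at -500
        assert not m.missing[0, 1]

    def test_strand_aware_orientation(self):
        """A signal block downstream of the TSS lands in the same bins
        for a plus gene and its minus mirror."""
        track_p = io.SignalTrack(io.THREE_PRIME)
        track_m = io.SignalTrack(io.THREE_PRIME)
        gp = io.GeneAnnotation("g", "c", "+", 60_000, 120_000)
        gm = io.GeneAnnotation("g", "c", "-", 60_000, 120_000)
        track_p.set_interval("c", "+", gp.tss + 2000, gp.tss + 3000, 4.0)
        track_m.set_interval("c", "-", gm.tss - 2999, gm.tss - 1999, 4.0)
        mp = pert.binned_region_matrix(track_p, [(gp, gp.tss)])
        mm = pert.binned_region_matrix(track_m, [(gm, gm.tss)])
        np.testing.assert_allclose(mp.values[0][~mp.missing[0]],
                                   mm.values[0][~mm.missing[0]])

    def test_bin_size_must_divide(self):
        track = io.SignalTrack(io.THREE_PRIME)
        gene = self._gene()
        with pytest.raises(io.ValidationError):
            pert.binned_region_matrix(track, [(gene, gene.tss)], upstream=1500, bin_size=1000)


class TestKmeans:
    def _matrix(self, X):
        return pert.ResponseMatrix(
            gene_ids=[f"g{i}" for i in range(len(X))],
            values=np.asarray(X, dtype=float),
            missing=np.zeros_like(np.asarray(X, dtype=float), dtype=bool),
            bin_size=1, upstream=0, downstream=len(X[0]) - 1,
        )

    def test_perfect_recovery_of_duplicated_archetypes(self):
        arch = np.array([[5.0, 0.0, 0.0], [0.0, 5.0, 0.0], [0.0, 0.0, 5.0]])
        X = np.repeat(arch, 10, axis=0)
        labels = pert.kmeans_cluster(self._matrix(X), k=3, seed=0)
        truth = np.repeat([0, 1, 2], 10)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 6))
        m = self._matrix(X)
        a = pert.kmeans_cluster(m, k=3, seed=11)
        b = pert.kmeans_cluster(m, k=3, seed=11)
        assert np.array_equal(a, b)

    def test_matches_exhaustive_best_two_partition(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 2))
        labels = pert.kmeans_cluster(self._matrix(X), k=2, seed=0, n_init=50)
        ss = sum(
            float(((X[labels == c] - X[labels == c].mean(axis=0)) ** 2).sum())
            for c in (0, 1)
        )
        assert ss == pytest.approx(best_two_partition_ss(X), rel=1e-9)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(io.ValidationError):
            pert.kmeans_cluster(self._matrix(np.zeros((2, 3))), k=5, seed=0)


class TestGeneBodyExcl3kb:
    def test_uniform_sum(self):
        gene = io.GeneAnnotation("g", "c", "+", 0, 10_000)
        track = io.SignalTrack(io.THREE_PRIME)
        track.set_interval("c", "+", 0, 10_000, 1.0)
        assert pert.gene_body_counts_excl3kb(gene, track) == pytest.approx(7000.0)

    def test_short_gene_excluded(self):
        gene = io.GeneAnnotation("g", "c", "+", 0, 2500)
        assert pert.gene_body_counts_excl3kb(gene, io.SignalTrack(io.THREE_PRIME)) is None

    def test_strand_symmetry(self):
        plus = io.GeneAnnotation("g", "c", "+", 1000, 11_000)
        minus = io.GeneAnnotation("g", "c", "-", 1000, 11_000)
        tp = io.SignalTrack(io.THREE_PRIME)
        tm = io.SignalTrack(io.THREE_PRIME)
        tp.set_interval("c", "+", 0, 12_000, 1.0)
        tm.set_interval("c", "-", 0, 12_000, 1.0)
        assert pert.gene_body_counts_excl3kb(plus, tp) == pert.gene_body_counts_excl3kb(minus, tm)


class TestHsClassification:
    def test_rule_application(self):
        recs = [
            {"gene_id": "up", "log2fc": 2.0, "padj": 0.01, "dtag_padj": 0.5},
            {"gene_id": "weak", "log2fc": 2.0, "padj": 0.2, "dtag_padj": 0.5},
            {"gene_id": "down", "log2fc": -1.0, "padj": 0.001, "dtag_padj": 0.01},
        ]
        classes = {c.gene_id: c for c in pert.classify_hs_response(recs)}
        assert classes["up"].hs_class == "up" and classes["up"].dtag_stable
        assert classes["weak"].hs_class == "unchanged"
        assert classes["down"].hs_class == "down" and not classes["down"].dtag_stable

    def test_missing_padj_dropped(self):
        recs = [{"gene_id": "a", "log2fc": 1.0, "padj": float("nan"), "dtag_padj": 0.5}]
        assert pert.classify_hs_response(recs) == []

    def test_planted_classes_recovered_exactly(self):
        rng = np.random.default_rng(8)
        recs, expected = [], []
        for i in range(100):
            cls = ["up", "down", "unchanged"][i % 3]
            fc = {"up": 1.5, "down": -1.5, "unchanged": 0.3}[cls]
            padj = 0.001 if cls != "unchanged" else 0.5
            recs.append({"gene_id": f"g{i}", "log2fc": fc + rng.normal(0, 0.05),
                         "padj": padj, "dtag_padj": 0.9})
            expected.append(cls)
        got = [c.hs_class for c in pert.classify_hs_response(recs)]
        assert got == expected


class TestInductionDefect:
    def _classes(self, n_up=50, n_down=50):
        out = []
        for i in range(n_up):
            out.append(pert.HsGeneClass(f"u{i}", "up", 2.0, 0.01, True))
        for i in range(n_down):
            out.append(pert.HsGeneClass(f"d{i}", "down", -2.0, 0.01, True))
        return out

    def test_identical_conditions_null(self):
        classes = self._classes()
        rng = np.random.default_rng(1)
        fc = {c.gene_id: float(rng.normal(2, 0.5)) for c in classes}
        report = pert.hs_induction_defect(classes, fc, dict(fc))
        assert report["up"]["p_value"] > 0.9
        assert report["up"]["median_difference"] == 0.0

    def test_planted_shift_detected_only_at_up_genes(self):
        classes = self._classes()
        rng = np.random.default_rng(2)
        fc_a = {c.gene_id: float(rng.normal(2, 0.3)) for c in classes}
        fc_b = {
            g: (v - 1.0 if g.startswith("u") else v + float(rng.normal(0, 1e-6)))
            for g, v in fc_a.items()
        }
        report = pert.hs_induction_defect(classes, fc_a, fc_b)
        assert report["up"]["p_value"] < 1e-3
        assert report["up"]["median_difference"] == pytest.approx(1.0, abs=0.05)
        assert report["down"]["p_value"] > 0.05

    def test_empty_class_skipped(self):
        classes = [pert.HsGeneClass("u0", "up", 2.0, 0.01, True)]
        report = pert.hs_induction_defect(classes, {"u0": 1.0}, {"u0": 0.5})
        assert report["down"].get("skipped")


def test_end_to_end_archetype_clustering_recovers_truth():
    """Simulated 3-archetype depletion course: pause-anchored
    fold-change features cluster back to the planted archetypes."""
    from pauseatlas.workflows import archetype_clustering_run

    run = archetype_clustering_run(seed=31)
    assert adjusted_rand_score(run.truth_labels, run.assigned) >= 0.9
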