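"""Pause-site calling, PWM construction/scoring and motif enrichment."""

import math

import numpy as np
import pytest

from pauseatlas import io_formats as io
from pauseatlas import pause_motif as pmo
from pauseatlas import synthetic_data as sd


def _gene(strand="+", start=5000, end=7000):
    return io.GeneAnnotation("g", "chr1", strand, start, end)


def _track(entries, strand="+"):
    t = io.SignalTrack(io.THREE_PRIME)
    for pos, v in entries:
        t.add("chr1", strand, pos, v)
    return t


class TestCallPauseSite:
    def test_single_spike(self):
        gene = _gene()
        site = pmo.call_pause_site(gene, _track([(gene.tss + 40, 6.0)]))
        assert site.position == gene.tss + 40
        assert site.positioning_score == 1.0

    def test_five_prime_most_tie_break(self):
        gene = _gene()
        site = pmo.call_pause_site(gene, _track([(gene.tss + 30, 5.0), (gene.tss + 60, 5.0)]))
        assert site.position == gene.tss + 30

    def test_five_prime_most_tie_break_minus_strand(self):
        gene = _gene("-")
        # 5'-most on minus = larger genomic coordinate (closer to TSS)
        site = pmo.call_pause_site(gene, _track([(gene.tss - 30, 5.0), (gene.tss - 60, 5.0)],
                                                strand="-"))
        assert site.position == gene.tss - 30

    def test_argmax_and_positioning_score(self):
        gene = _gene()
        site = pmo.call_pause_site(gene, _track([(gene.tss + 30, 4.0), (gene.tss + 31, 6.0)]))
        assert site.position == gene.tss + 31
        assert site.positioning_score == pytest.approx(0.6)

    def test_empty_window_is_no_call(self):
        assert pmo.call_pause_site(_gene(), io.SignalTrack(io.THREE_PRIME)) is None

    def test_signal_outside_window_ignored(self):
        gene = _gene()
        site = pmo.call_pause_site(gene, _track([(gene.tss + 40, 2.0), (gene.tss + 150, 9.0)]))
        assert site.position == gene.tss + 40


class TestQuartileSelection:
    def _sites(self, scores):
        return [
            pmo.PauseSite(f"g{i}", "chr1", "+", 100 + i, s * 10.0, 10.0)
            for i, s in enumerate(scores)
        ]

    def test_top_quartile_of_eight(self):
        top = pmo.select_top_positioned_quartile(
            self._sites([1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3])
        )
        assert [s.positioning_score for s in top] == pytest.approx([1.0, 0.9])

    def test_ceiling_of_five(self):
        assert len(pmo.select_top_positioned_quartile(self._sites([0.9, 0.5, 0.4, 0.3, 0.2]))) == 2

    def test_identical_scores_resolved_by_gene_id(self):
        top = pmo.select_top_positioned_quartile(self._sites([0.5, 0.5, 0.5, 0.5]))
        assert [s.gene_id for s in top] == ["g0"]

    def test_fewer_than_four_rejected(self):
        with pytest.raises(io.ValidationError):
            pmo.select_top_positioned_quartile(self._sites([1.0, 0.5]))


class TestSequenceExtraction:
    def test_plus_strand_window(self):
        genome = io.GenomeSequence("chr1", "A" * 90 + "CGCCGCCTTTAACCGGAATT" + "A" * 90)
        site = pmo.PauseSite("g", "chr1", "+", 100, 1.0, 1.0)
        seqs, skipped = pmo.extract_centered_sequences(genome, [site], 20)
        assert skipped == 0
        assert seqs == [genome.sequence[90:110]]

    def test_minus_strand_mirrors_pause_column(self):
        """On both strands the pause base occupies index width/2."""
        base = list("A" * 200)
        base[100] = "G"  # pause base on +
        genome = io.GenomeSequence("chr1", "".join(base))
        plus = pmo.PauseSite("g", "chr1", "+", 100, 1.0, 1.0)
        minus = pmo.PauseSite("g", "chr1", "-", 100, 1.0, 1.0)
        (pseq,), _ = pmo.extract_centered_sequences(genome, [plus], 20)
        (mseq,), _ = pmo.extract_centered_sequences(genome, [minus], 20)
        assert pseq[10] == "G" and mseq[10] == "C"
        # explicit window: revcomp of [91, 111)
        assert mseq == io.reverse_complement(genome.sequence[91:111])

    def test_edge_sites_skipped_and_counted(self):
        genome = io.GenomeSequence("chr1", "ACGT" * 30)
        site = pmo.PauseSite("g", "chr1", "+", 5, 1.0, 1.0)
        seqs, skipped = pmo.extract_centered_sequences(genome, [site], 20)
        assert seqs == [] and skipped == 1


class TestBuildPwm:
    def test_direct_formula(self):
        pwm = pmo.build_pwm(["AC", "AC"], pseudocount=0.25)
        assert pwm.probs[0, 0] == pytest.approx((2 + 0.25) / 3)
        assert pwm.probs[1, 0] == pytest.approx(0.25 / 3)
        assert pwm.probs.sum(axis=0) == pytest.approx([1.0, 1.0])

    def test_zero_pseudocount_rejected(self):
        with pytest.raises(io.ValidationError):
            pmo.build_pwm(["G"], pseudocount=0.0)

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(io.ValidationError):
            pmo.build_pwm(["AC", "ACA"])
        with pytest.raises(io.ValidationError):
            pmo.build_pwm([])

    def test_n_bases_excluded_from_counts(self):
        pwm = pmo.build_pwm(["AN", "AC"], pseudocount=0.25)
        # column 2 has one informative base (C)
        assert pwm.probs[1, 1] == pytest.approx((1 + 0.25) / (1 + 1.0))

    def test_uniform_sequences_give_near_uniform_pwm(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(10000)]
        pwm = pmo.build_pwm(seqs)
        assert np.all(np.abs(pwm.probs - 0.25) < 0.02)

    def test_columns_sum_to_one_for_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            seqs = ["".join(rng.choice(list("ACGTN"), size=6))
                    for _ in range(int(rng.integers(1, 30)))]
            pwm = pmo.build_pwm(seqs)
            assert np.allclose(pwm.probs.sum(axis=0), 1.0, atol=1e-9)


class TestScoreWindow:
    def test_uniform_pwm_scores_zero(self):
        pwm = pmo.PWM(np.full((4, 3), 0.25))
        assert pmo.score_window(pwm, "ACGTTT") == pytest.approx(0.0)

    def test_match_and_mismatch_log_odds(self):
        pwm = pmo.build_pwm(["AC", "AC"], pseudocount=0.25)
        match = 2 * math.log2(0.75 / 0.25)
        mismatch = 2 * math.log2((0.25 / 3) / 0.25)
        assert pmo.score_window(pwm, "AC") == pytest.approx(match)
        assert pmo.score_window(pwm, "GG") == pytest.approx(mismatch)
        assert match == pytest.approx(3.17, abs=0.01)

    def test_best_offset_selected(self):
        pwm = pmo.build_pwm(["AC", "AC"], pseudocount=0.25)
        assert pmo.score_window(pwm, "GGACGG") == pytest.approx(2 * math.log2(3.0))

    def test_n_contributes_zero(self):
        pwm = pmo.build_pwm(["AC", "AC"], pseudocount=0.25)
        assert pmo.score_window(pwm, "AN") == pytest.approx(math.log2(3.0))

    def test_too_short_sequence_rejected(self):
        pwm = pmo.build_pwm(["ACGT"])
        with pytest.raises(io.ValidationError):
            pmo.score_window(pwm, "AC")


class TestEnrichment:
    def test_uniform_pwm_zero_enrichment(self):
        genome, genes, truths = sd.generate_genome_with_genes(10, seed=4)
        sites = [
            pmo.PauseSite(t.gene_id, g.contig, g.strand,
                          g.offset_to_genomic(t.pause_offset), 1.0, 1.0)
            for g, t in zip(genes, truths)
        ]
        pwm = pmo.PWM(np.full((4, 4), 0.25))
        res = pmo.motif_enrichment_score(pwm, genome, sites)
        assert res.enrichment == pytest.approx(0.0, abs=1e-12)

    def test_constructed_fixture_enrichment(self):
        """Pause windows all contain the motif's preferred dinucleotide,
        flanks its worst: enrichment equals the score difference."""
        n = 1000
        seq = list("GG" * (n // 2))
        centre = n // 2
        seq[centre - 1 : centre + 1] = list("AC")
        genome = io.GenomeSequence("chr1", "".join(seq))
        site = pmo.PauseSite("g", "chr1", "+", centre, 1.0, 1.0)
        pwm = pmo.build_pwm(["AC", "AC"], pseudocount=0.25)
        res = pmo.motif_enrichment_score(pwm, genome, [site])
        assert res.enrichment == pytest.approx(4 * math.log2(3.0), abs=1e-9)
        assert res.enrichment == pytest.approx(6.34, abs=0.01)

    def test_monotone_in_planting_fraction(self):
        vals = []
        for f in (0.0, 0.5, 1.0):
            genome, genes, truths = sd.generate_genome_with_genes(
                60, seed=9, motif="CGCCGCC", motif_fraction=f
            )
            sites = [
                pmo.PauseSite(t.gene_id, g.contig, g.strand,
                              g.offset_to_genomic(t.pause_offset), 1.0, 1.0)
                for g, t in zip(genes, truths)
            ]
            pwm = pmo.build_pwm(["CGCCGCC"] * 4, pseudocount=0.25)
            vals.append(pmo.motif_enrichment_score(pwm, genome, sites).enrichment)
        assert vals[0] < vals[1] < vals[2]

    def test_reverse_complement_consistency(self):
        """Mirroring the genome and all sites to the opposite strand
        leaves the enrichment unchanged."""
        genome, genes, truths = sd.generate_genome_with_genes(
            20, seed=10, motif="CGCCG", motif_fraction=1.0
        )
        sites = [
            pmo.PauseSite(t.gene_id, g.contig, g.strand,
                          g.offset_to_genomic(t.pause_offset), 1.0, 1.0)
            for g, t in zip(genes, truths)
        ]
        pwm = pmo.build_pwm(["CGCCG"] * 4)
        fwd = pmo.motif_enrichment_score(pwm, genome, sites)

        L = len(genome)
        mirrored = io.GenomeSequence("chr1", io.reverse_complement(genome.sequence))
        msites = [
            pmo.PauseSite(s.gene_id, "chr1", "-" if s.strand == "+" else "+",
                          L - 1 - s.position, s.peak_count, s.window_total)
            for s in sites
        ]
        rev = pmo.motif_enrichment_score(pwm, mirrored, msites)
        assert rev.enrichment == pytest.approx(fwd.enrichment, abs=1e-9)


class TestPwmIO:
    def test_round_trip(self, tmp_path):
        pwm = pmo.build_pwm(["CGCCG", "CGCTG", "CACCG"])
        pmo.write_pwm(pwm, tmp_path / "m.txt")
        back = pmo.read_pwm(tmp_path / "m.txt")
        assert np.allclose(back.probs, pwm.probs, atol=1e-6)
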