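"""Reusable in-memory study workflows over the synthetic generators.

These compose the package's operations into the experiments the
analysis drivers and validation harness run: planted pausing-index
recovery, TSS-refinement accuracy, the depletion-response clustering
course, and a planted cross-species enrichment/pausing relationship.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import pause_motif as pmo
from . import perturbation as pert
from . import synthetic_data as sd
from .pausing_metrics import compute_pausing_indexes, rpm_normalize, summarize_species
from .tss_refine import refine_tss


def pausing_recovery_errors(
    planted_pi: float, n_genes: int = 100, reads_per_gene: int = 3000, seed: int = 0
) -> np.ndarray:
    """Relative errors of the window pausing-index estimator against a
    planted index, one simulated species at the given depth."""
    _, genes, truths = sd.generate_genome_with_genes(
        n_genes, gene_length=2000, seed=seed, pausing_index=planted_pi
    )
    _, three = sd.simulate_proseq_tracks(
        genes, truths, total_reads=n_genes * reads_per_gene, seed=seed + 1
    )
    recs = compute_pausing_indexes(genes, rpm_normalize(three))
    est = np.array([r.pausing_index for r in recs if r.status == "ok"])
    return np.abs(est - planted_pi) / planted_pi


def tss_refinement_errors(
    n_genes: int = 1000, reads_per_gene: int = 60, jitter_sd: float = 2.0, seed: int = 0
) -> np.ndarray:
    """Distance of each refined TSS from the true initiation site."""
    _, genes, truths = sd.generate_genome_with_genes(n_genes, seed=seed)
    five, _ = sd.simulate_proseq_tracks(
        genes, truths, total_reads=n_genes * reads_per_gene,
        tss_jitter_sd=jitter_sd, seed=seed + 1,
    )
    _, reports = refine_tss(genes, five)
    return np.array([abs(r.new_tss - t.true_tss) for r, t in zip(reports, truths)])


@dataclass
class ClusteringRun:
    truth_labels: list[int]
    assigned: np.ndarray
    archetype_names: list[str]


def archetype_clustering_run(
    n_genes: int = 120, total_reads: int = 240_000, seed: int = 0
) -> ClusteringRun:
    """Full depletion-course clustering: simulate control + 30/60 min
    tracks for three response archetypes, spike-scale, call pause sites
    on the control, build pause- and recovery-anchored binned count
    features as log2 ratios to control, and k-means with k=3.
    """
    _, genes, truths = sd.generate_genome_with_genes(
        n_genes, gene_length=4000, seed=seed, pausing_index=20.0
    )
    names = ["localized_recovery", "no_recovery", "downstream_recovery"]
    assignment = {g.gene_id: names[i % 3] for i, g in enumerate(genes)}
    _, control = sd.simulate_proseq_tracks(
        genes, truths, total_reads=total_reads, seed=seed + 1
    )
    tracks, spikes = sd.simulate_perturbation(
        genes, truths, assignment, seed=seed + 2, total_reads=total_reads
    )
    scaling = pert.spike_in_scaling_factors(spikes)
    control = scaling.scale_track("control", control)
    sites = {g.gene_id: pmo.call_pause_site(g, control) for g in genes}
    kept = [g for g in genes if sites[g.gene_id] is not None]
    shift = sd.DEFAULT_ARCHETYPES["downstream_recovery"].recovery_shift
    pause_anchors = [(g, sites[g.gene_id].position) for g in kept]
    rec_anchors = [
        (g, sites[g.gene_id].position + (shift if g.strand == "+" else -shift))
        for g in kept
    ]

    def binned_counts(track):
        cols = []
        for anchors in (pause_anchors, rec_anchors):
            m = pert.binned_region_matrix(
                track, anchors, upstream=10, downstream=10, bin_size=20,
                aggregate="sum",
            )
            cols.append(m.imputed())
        return np.hstack(cols)

    ctrl_counts = binned_counts(control)
    features = []
    for tp in ("t30", "t60"):
        tp_counts = binned_counts(scaling.scale_track(tp, tracks[tp]))
        features.append(np.log2((tp_counts + 1.0) / (ctrl_counts + 1.0)))
    X = np.hstack(features)
    combined = pert.ResponseMatrix(
        gene_ids=[g.gene_id for g in kept],
        values=X,
        missing=np.zeros_like(X, dtype=bool),
        bin_size=20, upstream=10, downstream=10,
    )
    labels = pert.kmeans_cluster(combined, k=3, seed=seed + 3)
    truth_labels = [names.index(assignment[g.gene_id]) for g in kept]
    return ClusteringRun(truth_labels, labels, names)


def null_enrichment_run(
    pwm: pmo.PWM, n_sites: int = 500, seed: int = 0, motif_fraction: float = 0.0,
    motif: str | None = None,
) -> pmo.EnrichmentResult:
    """One motif-enrichment measurement over a simulated species: sites
    are the planted pause positions, on a genome with a given fraction
    of planted motifs (0 for the null)."""
    genome, genes, truths = sd.generate_genome_with_genes(
        n_sites, gene_length=1100, margin=600, seed=seed,
        motif=motif, motif_fraction=motif_fraction,
    )
    sites = [
        pmo.PauseSite(t.gene_id, g.contig, g.strand,
                      g.offset_to_genomic(t.pause_offset), 1.0, 1.0)
        for g, t in zip(genes, truths)
    ]
    return pmo.motif_enrichment_score(pwm, genome, sites)


def species_atlas_run(
    n_species: int = 10, n_genes: int = 80, seed: int = 0
) -> dict[str, np.ndarray]:
    """A planted cross-species relationship: species with a larger
    planted motif fraction get a proportionally higher planted pausing
    index; returns measured per-species enrichment and mean log10 PI."""
    motif = "CGCCGCC"
    pwm = pmo.build_pwm([motif] * 4, pseudocount=0.25)
    fractions = np.linspace(0.0, 1.0, n_species)
    planted_pi = 2.0 * 10.0 ** (1.5 * fractions)  # PI rises with motif use
    enrich, mean_log_pi = [], []
    for i in range(n_species):
        genome, genes, truths = sd.generate_genome_with_genes(
            n_genes, gene_length=2000, seed=seed + 7 * i,
            pausing_index=float(planted_pi[i]), motif=motif,
            motif_fraction=float(fractions[i]),
        )
        five, three = sd.simulate_proseq_tracks(
            genes, truths, total_reads=n_genes * 2000, seed=seed + 7 * i + 1
        )
        genes_r, _ = refine_tss(genes, five)
        three = rpm_normalize(three)
        recs = compute_pausing_indexes(genes_r, three)
        summ = summarize_species(recs, species_id=f"s{i}")
        sites = [s for s in (pmo.call_pause_site(g, three) for g in genes_r) if s]
        res = pmo.motif_enrichment_score(pwm, genome, sites, species_id=f"s{i}")
        enrich.append(res.enrichment)
        mean_log_pi.append(summ.mean_log10_pi)
    return {
        "enrichment": np.array(enrich),
        "mean_log10_pi": np.array(mean_log_pi),
        "planted_fraction": fractions,
        "planted_pi": planted_pi,
    }
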