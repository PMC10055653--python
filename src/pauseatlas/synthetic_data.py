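"""Synthetic genomes, annotations, PRO-seq-like tracks and proteomes with
known ground truth.

The occupancy model is a deliberately simple stand-in for nascent
transcription data: each gene is a two-component mixture of a narrow
"pause" footprint 20-100 bp downstream of the TSS and a diffuse uniform
gene body, with the planted ratio of per-base densities defining the
true pausing index. Reads are allocated multinomially so per-track
totals are exact and depth normalisation is exactly invertible. This
emulates the statistical structure of promoter-proximal pausing data
(sharp 5' pileup at the TSS, 3' pileup at the pause, diffuse body
signal); it does not model elongation kinetics, sequencing error or
mappability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    FIVE_PRIME,
    THREE_PRIME,
    GeneAnnotation,
    GenomeSequence,
    SignalTrack,
    ValidationError,
    reverse_complement,
    write_fasta_sequences,
    write_gene_annotations,
    write_signal_track,
)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"


@dataclass(frozen=True)
class GeneTruth:
    """Planted per-gene parameters of the occupancy mixture.

    ``pause_density`` is the expected reads/base inside the narrow pause
    footprint; ``pausing_index`` is the planted index, defined as the
    value the standard 300 bp pause-window / body-window density ratio
    converges to at infinite depth. The generator calibrates the
    footprint density so both hold simultaneously (the wide pause
    window also contains body signal, so the footprint density exceeds
    ``pausing_index * body_density``).
    """

    gene_id: str
    true_tss: int
    pause_offset: int
    pause_density: float
    body_density: float
    pausing_index: float
    footprint_halfwidth: int = 2
    motif_planted: bool = False

    def __post_init__(self) -> None:
        if self.pause_density <= 0 or self.body_density <= 0:
            raise ValidationError(f"{self.gene_id}: densities must be positive")


@dataclass(frozen=True)
class PerturbationArchetype:
    """Response archetype for factor-depletion time courses.

    ``pause_retention`` is the fraction of pause-footprint density kept
    at the first (30 min) timepoint; at the second (60 min) timepoint a
    ``recovery_fraction`` of the lost pause mass reappears centred
    ``recovery_shift`` bases downstream of the original pause.
    """

    label: str
    pause_retention: float
    recovery_shift: int = 0
    recovery_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pause_retention <= 1.0:
            raise ValidationError("pause_retention must be in [0, 1]")
        if self.recovery_shift < 0:
            raise ValidationError("recovery_shift must be >= 0")


#: The three response archetypes used throughout: polymerase returning to
#: the original pause, polymerase lost outright, and polymerase
#: re-accumulating well downstream of the pause.
DEFAULT_ARCHETYPES: dict[str, PerturbationArchetype] = {
    "localized_recovery": PerturbationArchetype("localized_recovery", 0.2, 0, 0.9),
    "no_recovery": PerturbationArchetype("no_recovery", 0.15, 0, 0.0),
    "downstream_recovery": PerturbationArchetype("downstream_recovery", 0.15, 2000, 0.9),
}


# -- genome + annotation generation ------------------------------------


def generate_genome_with_genes(
    n_genes: int,
    gene_length: int = 2000,
    contig_length: int | None = None,
    gc_fraction: float = 0.5,
    motif: str | None = None,
    motif_fraction: float = 0.0,
    seed: int = 0,
    contig_name: str = "chrS",
    pause_offset_range: tuple[int, int] = (30, 60),
    pausing_index: float | Sequence[float] = 10.0,
    body_density: float = 1.0,
    footprint_halfwidth: int = 2,
    margin: int = 1000,
    pause_window: tuple[int, int] = (150, 150),
) -> tuple[GenomeSequence, list[GeneAnnotation], list[GeneTruth]]:
    """Lay out ``n_genes`` non-overlapping genes on one i.i.d. random
    contig and record the planted pause parameters per gene.

    ``pausing_index`` may be a scalar (shared by all genes) or one value
    per gene; the footprint density is calibrated against the
    ``pause_window`` (the downstream estimator's pause window, in bases
    up-/downstream of the TSS) so the window density ratio converges to
    the planted index. For a ``motif_fraction`` subset of genes the
    consensus ``motif`` is written into the genome centred on the pause
    site, reverse-complemented for minus-strand genes.
    """
    if not 0.0 <= motif_fraction <= 1.0:
        raise ValidationError("motif_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pitch = gene_length + 2 * margin
    needed = n_genes * pitch + margin
    if contig_length is None:
        contig_length = needed
    elif contig_length < needed:
        raise ValidationError(
            f"{n_genes} genes of {gene_length} bp with {margin} bp margins "
            f"need {needed} bp; contig is {contig_length}"
        )

    seq = rng.choice(
        list("ACGT"),
        size=contig_length,
        p=[(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2],
    )

    pis = np.broadcast_to(np.asarray(pausing_index, dtype=float), (n_genes,))
    offsets = rng.integers(pause_offset_range[0], pause_offset_range[1] + 1, size=n_genes)
    strands = rng.choice(["+", "-"], size=n_genes)
    n_motif = int(round(motif_fraction * n_genes))
    motif_genes = set(rng.choice(n_genes, size=n_motif, replace=False)) if n_motif else set()

    genes: list[GeneAnnotation] = []
    truths: list[GeneTruth] = []
    for i in range(n_genes):
        start = margin + i * pitch
        gene = GeneAnnotation(f"g{i:04d}", contig_name, strands[i], start, start + gene_length)
        planted = i in motif_genes and motif is not None
        if planted:
            lo = int(offsets[i]) - len(motif) // 2
            gs, ge = gene.offset_window(lo, lo + len(motif))
            written = motif if gene.strand == "+" else reverse_complement(motif)
            seq[gs:ge] = list(written)
        genes.append(gene)
        # calibrate footprint density so the pause-window/body-window
        # density ratio converges to the planted index: the window of
        # width pw also holds body signal downstream of the footprint
        pw = pause_window[0] + pause_window[1]
        fp_len = 2 * footprint_halfwidth + 1
        body_in_window = max(0, pause_window[1] - (int(offsets[i]) + footprint_halfwidth + 1))
        fp_density = body_density * (pw * float(pis[i]) - body_in_window) / fp_len
        if fp_density <= 0:
            raise ValidationError(
                f"pausing_index {pis[i]} too small to realise with "
                f"pause_offset {offsets[i]} and window {pause_window}"
            )
        truths.append(
            GeneTruth(
                gene_id=gene.gene_id,
                true_tss=gene.tss,
                pause_offset=int(offsets[i]),
                pause_density=fp_density,
                body_density=body_density,
                pausing_index=float(pis[i]),
                footprint_halfwidth=footprint_halfwidth,
                motif_planted=planted,
            )
        )
    return GenomeSequence(contig_name, "".join(seq)), genes, truths


# -- PRO-seq track simulation ------------------------------------------


def _gene_masses(
    gene: GeneAnnotation, truth: GeneTruth, archetype: PerturbationArchetype | None, timepoint: int
) -> tuple[list[tuple[int, int, float]], float]:
    """Mixture components as (offset_lo, offset_hi_inclusive, mass)."""
    hw = truth.footprint_halfwidth
    off = truth.pause_offset
    fp_lo, fp_hi = off - hw, off + hw
    body_lo, body_hi = fp_hi + 1, gene.length - 1
    if body_hi <= body_lo:
        raise ValidationError(f"{gene.gene_id}: gene too short for body component")
    pause_mass = truth.pause_density * (fp_hi - fp_lo + 1)
    body_mass = truth.body_density * (body_hi - body_lo + 1)
    comps = []
    if archetype is None:
        comps.append((fp_lo, fp_hi, pause_mass))
    else:
        kept = archetype.pause_retention * pause_mass
        comps.append((fp_lo, fp_hi, kept))
        if timepoint >= 60 and archetype.recovery_fraction > 0:
            rec_lo = off + archetype.recovery_shift - hw
            rec_hi = off + archetype.recovery_shift + hw
            if rec_hi >= gene.length:
                raise ValidationError(
                    f"{gene.gene_id}: recovery_shift places mass past the TES"
                )
            recovered = archetype.recovery_fraction * (pause_mass - kept)
            comps.append((rec_lo, rec_hi, recovered))
    comps.append((body_lo, body_hi, body_mass))
    total = sum(m for _, _, m in comps)
    return comps, total


def _sample_tracks(
    genes: Sequence[GeneAnnotation],
    truths: Sequence[GeneTruth],
    total_reads: int,
    tss_jitter_sd: float,
    rng: np.random.Generator,
    archetypes: Mapping[str, PerturbationArchetype] | None = None,
    assignment: Mapping[str, str] | None = None,
    timepoint: int = 0,
    make_five_prime: bool = True,
) -> tuple[SignalTrack | None, SignalTrack]:
    per_gene = []
    weights = []
    for gene, truth in zip(genes, truths):
        arch = None
        if assignment is not None:
            label = assignment[gene.gene_id]
            if label not in archetypes:
                raise ValidationError(f"unknown archetype label {label!r}")
            arch = archetypes[label]
        comps, mass = _gene_masses(gene, truth, arch, timepoint)
        per_gene.append(comps)
        weights.append(mass)
    weights = np.asarray(weights, dtype=float)
    counts = rng.multinomial(total_reads, weights / weights.sum())

    five = SignalTrack(FIVE_PRIME) if make_five_prime else None
    three = SignalTrack(THREE_PRIME)
    for gene, truth, comps, n in zip(genes, truths, per_gene, counts):
        if n == 0:
            continue
        masses = np.array([m for _, _, m in comps])
        comp_counts = rng.multinomial(n, masses / masses.sum())
        offs = []
        for (lo, hi, _), k in zip(comps, comp_counts):
            if k:
                offs.append(rng.integers(lo, hi + 1, size=k))
        offsets = np.concatenate(offs) if offs else np.zeros(0, dtype=np.int64)
        if gene.strand == "+":
            positions = gene.tss + offsets
        else:
            positions = gene.tss - offsets
        three.add_positions(gene.contig, gene.strand, positions)
        if five is not None:
            jitter = np.rint(rng.normal(0.0, tss_jitter_sd, size=n)).astype(np.int64)
            if gene.strand == "+":
                fp_pos = gene.tss + jitter
            else:
                fp_pos = gene.tss - jitter
            five.add_positions(gene.contig, gene.strand, np.maximum(fp_pos, 0))
    return five, three


def simulate_proseq_tracks(
    genes: Sequence[GeneAnnotation],
    truths: Sequence[GeneTruth],
    total_reads: int = 100_000,
    tss_jitter_sd: float = 1.0,
    seed: int = 0,
) -> tuple[SignalTrack, SignalTrack]:
    """Simulate matched 5'-end and 3'-end mapped tracks.

    Reads are allocated to genes multinomially in proportion to each
    gene's expected total occupancy, then within a gene to the pause
    footprint or the uniform body. The 3' track records the sampled
    polymerase position; the 5' track records the TSS plus rounded
    Gaussian jitter. Both tracks sum to ``total_reads`` exactly.
    """
    if total_reads < 0:
        raise ValidationError("total_reads must be >= 0")
    rng = np.random.default_rng(seed)
    five, three = _sample_tracks(genes, truths, total_reads, tss_jitter_sd, rng)
    return five, three


def simulate_perturbation(
    genes: Sequence[GeneAnnotation],
    truths: Sequence[GeneTruth],
    assignment: Mapping[str, str],
    seed: int = 0,
    total_reads: int = 300_000,
    archetypes: Mapping[str, PerturbationArchetype] | None = None,
    spike_in_counts: Mapping[str, int] | None = None,
) -> tuple[dict[str, SignalTrack], dict[str, int]]:
    """Simulate 3'-end tracks for a two-timepoint depletion course.

    Every gene must be assigned one archetype label. The 30 min track
    has its pause mass multiplied by the archetype's retention; the
    60 min track additionally restores recovered mass downstream of the
    original pause per archetype. ``total_reads`` is the depth of an
    unperturbed library from the same cells: each timepoint's total is
    scaled by its expected occupancy relative to the unperturbed state,
    emulating constant cell input with constant spike-in material, so
    that equal spike-in counts make per-base signal directly comparable
    across samples. Returns the per-timepoint tracks and per-sample
    spike-in read totals.
    """
    archetypes = dict(DEFAULT_ARCHETYPES) if archetypes is None else dict(archetypes)
    missing = {g.gene_id for g in genes} - set(assignment)
    if missing:
        raise ValidationError(f"{len(missing)} genes lack an archetype assignment")
    rng = np.random.default_rng(seed)
    base_mass = sum(
        _gene_masses(g, t, None, 0)[1] for g, t in zip(genes, truths)
    )
    tracks: dict[str, SignalTrack] = {}
    for tp in (30, 60):
        for gene in genes:
            if assignment[gene.gene_id] not in archetypes:
                raise ValidationError(
                    f"unknown archetype label {assignment[gene.gene_id]!r}"
                )
        tp_mass = sum(
            _gene_masses(g, t, archetypes[assignment[g.gene_id]], tp)[1]
            for g, t in zip(genes, truths)
        )
        n_reads = int(round(total_reads * tp_mass / base_mass))
        _, three = _sample_tracks(
            genes, truths, n_reads, 0.0, rng,
            archetypes=archetypes, assignment=assignment, timepoint=tp,
            make_five_prime=False,
        )
        tracks[f"t{tp}"] = three
    if spike_in_counts is None:
        spike_in_counts = {"control": 100_000, "t30": 100_000, "t60": 100_000}
    for sample, count in spike_in_counts.items():
        if count <= 0:
            raise ValidationError(f"spike-in count for {sample} must be positive")
    return tracks, dict(spike_in_counts)


# -- proteome generation -----------------------------------------------


@dataclass(frozen=True)
class SpeciesProteomeSpec:
    """Which query families a synthetic species keeps, loses, or carries
    only as a paralog of a different family."""

    species_id: str
    lost: frozenset[str] = frozenset()
    paralog_only: Mapping[str, str] = field(default_factory=dict)  # family -> source family


@dataclass
class ProteomeTruth:
    """Ground-truth ortholog status per (query family, species)."""

    status: dict[tuple[str, str], str]

    def expected_present(self, family: str, species: str, mode: str) -> bool:
        s = self.status[(family, species)]
        if s == "ortholog_present":
            return True
        if s == "paralog_only":
            return mode == "lenient"
        return False


def _mutate(seq: str, identity: float, rng: np.random.Generator) -> str:
    if not 0.0 < identity <= 1.0:
        raise ValidationError("identity must be in (0, 1]")
    n_mut = int(round((1.0 - identity) * len(seq)))
    if n_mut == 0:
        return seq
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in positions:
        choices = _AA20.replace(out[p], "")
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def generate_proteome_set(
    n_families: int,
    species_specs: Sequence[SpeciesProteomeSpec],
    seed: int = 0,
    identity: float = 0.6,
    paralog_identity: float = 0.85,
    duplicate_identity: float = 0.55,
    length: int = 180,
) -> tuple[list[GenomeSequence], dict[str, list[GenomeSequence]], ProteomeTruth]:
    """Build a query proteome and per-species proteomes with known
    ortholog status.

    Ortholog sequences are point-mutated copies of the query family at
    ``identity``. A ``paralog_only`` entry for family F sourced from
    family G yields a species sequence close to G (``paralog_identity``)
    but not an ortholog of F; to make F's forward search find it, query
    family G is itself generated as a diverged duplicate of F at
    ``duplicate_identity``.
    """
    if not 0.0 < identity <= 1.0:
        raise ValidationError("identity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    fam_names = [f"Q{i:02d}" for i in range(n_families)]

    # families that act as paralog sources are duplicates of their target
    dup_of: dict[str, str] = {}
    for spec in species_specs:
        for fam, src in spec.paralog_only.items():
            if fam not in fam_names or src not in fam_names:
                raise ValidationError(f"unknown family in paralog_only: {fam}/{src}")
            if fam == src:
                raise ValidationError("paralog source must be a different family")
            dup_of[src] = fam

    query: dict[str, str] = {}
    for fam in fam_names:
        if fam in dup_of and dup_of[fam] in query:
            query[fam] = _mutate(query[dup_of[fam]], duplicate_identity, rng)
        else:
            query[fam] = "".join(
                _AA20[i] for i in rng.integers(len(_AA20), size=length)
            )
    # second pass for duplicates whose target came later
    for src, fam in dup_of.items():
        if query[src] == query.get(fam):
            query[src] = _mutate(query[fam], duplicate_identity, rng)
        elif sum(a == b for a, b in zip(query[src], query[fam])) < duplicate_identity * length * 0.8:
            query[src] = _mutate(query[fam], duplicate_identity, rng)

    truth = ProteomeTruth({})
    proteomes: dict[str, list[GenomeSequence]] = {}
    for spec in species_specs:
        records: list[GenomeSequence] = []
        for fam in fam_names:
            if fam in spec.lost:
                truth.status[(fam, spec.species_id)] = "lost"
            elif fam in spec.paralog_only:
                src = spec.paralog_only[fam]
                records.append(
                    GenomeSequence(
                        f"{spec.species_id}_{fam}_para",
                        _mutate(query[src], paralog_identity, rng),
                    )
                )
                truth.status[(fam, spec.species_id)] = "paralog_only"
            else:
                records.append(
                    GenomeSequence(
                        f"{spec.species_id}_{fam}", _mutate(query[fam], identity, rng)
                    )
                )
                truth.status[(fam, spec.species_id)] = "ortholog_present"
        proteomes[spec.species_id] = records
    query_records = [GenomeSequence(f, s) for f, s in query.items()]
    return query_records, proteomes, truth


def example_proteome_specs() -> list[SpeciesProteomeSpec]:
    """A 6-family, 5-species presence/absence fixture covering complete
    retention, partial loss, total loss, and a paralog-only case."""
    return [
        SpeciesProteomeSpec("sp_full"),
        SpeciesProteomeSpec("sp_core", lost=frozenset({"Q04", "Q05"})),
        SpeciesProteomeSpec("sp_min", lost=frozenset({"Q02", "Q03", "Q04", "Q05"})),
        SpeciesProteomeSpec("sp_none", lost=frozenset({f"Q{i:02d}" for i in range(6)})),
        SpeciesProteomeSpec(
            "sp_para", lost=frozenset({"Q05"}), paralog_only={"Q00": "Q01"}
        ),
    ]


# -- on-disk emission ---------------------------------------------------


def write_truth_table(
    truths: Sequence[GeneTruth], path: str | Path, assignment: Mapping[str, str] | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttrue_tss\tpause_offset\ttrue_pi\tarchetype\tmotif_planted\n")
        for t in truths:
            arch = assignment.get(t.gene_id, "NA") if assignment else "NA"
            fh.write(
                f"{t.gene_id}\t{t.true_tss}\t{t.pause_offset}\t"
                f"{t.pausing_index:.6g}\t{arch}\t{int(t.motif_planted)}\n"
            )


def emit_species_dataset(
    outdir: str | Path,
    genome: GenomeSequence,
    genes: Sequence[GeneAnnotation],
    truths: Sequence[GeneTruth],
    five_prime: SignalTrack,
    three_prime: SignalTrack,
) -> dict[str, Path]:
    """Write one species' synthetic dataset (FASTA, BED6, bedGraph pairs,
    truth TSV) and return the path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.bed",
        "fp_plus": outdir / "five_prime.plus.bedGraph",
        "fp_minus": outdir / "five_prime.minus.bedGraph",
        "tp_plus": outdir / "three_prime.plus.bedGraph",
        "tp_minus": outdir / "three_prime.minus.bedGraph",
        "truth": outdir / "truth.tsv",
    }
    write_fasta_sequences([genome], paths["genome"])
    write_gene_annotations(genes, paths["genes"])
    write_signal_track(five_prime, paths["fp_plus"], paths["fp_minus"])
    write_signal_track(three_prime, paths["tp_plus"], paths["tp_minus"])
    write_truth_table(truths, paths["truth"])
    return paths
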