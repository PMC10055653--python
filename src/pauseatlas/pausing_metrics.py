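"""Pausing indexes: RPM normalisation, per-gene pause/body densities and
per-species summaries.

The pausing index of a gene is the ratio of Pol II density (3'-end reads
per base) in a window around the TSS to the density in the gene body,
with both windows measured along the direction of transcription:

    PI = density([TSS-150, TSS+150)) / density([TSS+300, TES-300))

Genes shorter than a minimum length are excluded, as are genes whose
body window is empty or read-free. Because indexes span orders of
magnitude across species, summaries are computed on the log10 scale and
the species mean reported as a geometric mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import THREE_PRIME, GeneAnnotation, SignalTrack, ValidationError


@dataclass(frozen=True)
class PausingParams:
    pause_upstream: int = 150
    pause_downstream: int = 150
    body_start_offset: int = 300
    body_end_offset: int = 300
    min_gene_length: int = 300

    def __post_init__(self) -> None:
        for name in ("pause_upstream", "pause_downstream", "body_start_offset",
                     "body_end_offset", "min_gene_length"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PausingRecord:
    gene_id: str
    pause_reads: float
    pause_width: int
    body_reads: float
    body_width: int
    status: str  # ok | too_short | empty_body_window | zero_body_reads

    @property
    def pause_density(self) -> float:
        return self.pause_reads / self.pause_width

    @property
    def body_density(self) -> float:
        return self.body_reads / self.body_width if self.body_width > 0 else float("nan")

    @property
    def pausing_index(self) -> float:
        if self.status != "ok":
            return float("nan")
        return self.pause_density / self.body_density


@dataclass(frozen=True)
class SpeciesSummary:
    species_id: str
    n_genes_ok: int
    log10_pi_quartiles: tuple[float, float, float]
    mean_log10_pi: float

    @property
    def geometric_mean_pi(self) -> float:
        return float(10.0 ** self.mean_log10_pi)


def rpm_normalize(track: SignalTrack) -> SignalTrack:
    """Scale per-base values to reads-per-million of the track total."""
    total = track.total_reads
    if total <= 0:
        raise ValidationError("cannot RPM-normalize an empty track")
    return track.scaled(1e6 / total)


def compute_pausing_index(
    gene: GeneAnnotation,
    three_prime_track: SignalTrack,
    params: PausingParams | None = None,
) -> PausingRecord:
    """Per-gene pausing index from sense-strand 3'-end signal.

    Windows are strand-aware and half-open in transcription space:
    pause = [-pause_upstream, +pause_downstream) around the TSS, body =
    [body_start_offset, length - body_end_offset).
    """
    params = params or PausingParams()
    if three_prime_track.mode != THREE_PRIME:
        raise ValidationError("pausing index requires a three_prime track")
    pause_width = params.pause_upstream + params.pause_downstream
    if gene.length < params.min_gene_length:
        return PausingRecord(gene.gene_id, 0.0, pause_width, 0.0, 0, "too_short")
    body_width = gene.length - params.body_start_offset - params.body_end_offset
    ps, pe = gene.offset_window(-params.pause_upstream, params.pause_downstream)
    pause_reads = three_prime_track.query(gene.contig, gene.strand, max(ps, 0), pe)
    if body_width <= 0:
        return PausingRecord(gene.gene_id, pause_reads, pause_width, 0.0, 0, "empty_body_window")
    bs, be = gene.offset_window(params.body_start_offset, gene.length - params.body_end_offset)
    body_reads = three_prime_track.query(gene.contig, gene.strand, max(bs, 0), be)
    if body_reads == 0:
        return PausingRecord(gene.gene_id, pause_reads, pause_width, 0.0, body_width,
                             "zero_body_reads")
    return PausingRecord(gene.gene_id, pause_reads, pause_width, body_reads, body_width, "ok")


def compute_pausing_indexes(
    genes: Sequence[GeneAnnotation],
    three_prime_track: SignalTrack,
    params: PausingParams | None = None,
) -> list[PausingRecord]:
    params = params or PausingParams()
    return [compute_pausing_index(g, three_prime_track, params) for g in genes]


def summarize_species(
    records: Sequence[PausingRecord], species_id: str = "species"
) -> SpeciesSummary:
    """Distributional summary over genes with a defined pausing index;
    averaging is done on log10 indexes."""
    pis = np.array([r.pausing_index for r in records if r.status == "ok"])
    if pis.size == 0:
        raise ValidationError(f"{species_id}: no genes with a defined pausing index")
    log_pi = np.log10(pis)
    q1, q2, q3 = np.percentile(log_pi, [25, 50, 75])
    return SpeciesSummary(
        species_id=species_id,
        n_genes_ok=int(pis.size),
        log10_pi_quartiles=(float(q1), float(q2), float(q3)),
        mean_log10_pi=float(log_pi.mean()),
    )


def records_to_frame(records: Sequence[PausingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "pause_reads": [r.pause_reads for r in records],
            "pause_width": [r.pause_width for r in records],
            "body_reads": [r.body_reads for r in records],
            "body_width": [r.body_width for r in records],
            "pause_density": [r.pause_density for r in records],
            "body_density": [r.body_density for r in records],
            "pausing_index": [r.pausing_index for r in records],
            "status": [r.status for r in records],
        }
    )


def write_pausing_records(records: Sequence[PausingRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)
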