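"""Pause-site calling and pause-motif PWM construction, scoring and
enrichment relative to flanking DNA.

Pause sites are called as the base with the maximal 3'-end read count in
the first 100 bp downstream of the (refined) TSS. The quartile of genes
with the most sharply positioned pause (largest fraction of window reads
at the single peak base) defines the sequences used to build a position
weight matrix; motif enrichment at the pause is the mean best-match
log-odds score of the pause-centred sequence minus the mean score of
flanking DNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    THREE_PRIME,
    GeneAnnotation,
    GenomeSequence,
    SignalTrack,
    ValidationError,
    reverse_complement,
)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_BASES = "ACGT"


@dataclass(frozen=True)
class PauseSite:
    gene_id: str
    contig: str
    strand: str
    position: int
    peak_count: float
    window_total: float

    @property
    def positioning_score(self) -> float:
        """Fraction of pause-window reads concentrated at the peak base;
        1.0 is a perfectly focused pause."""
        return self.peak_count / self.window_total


class PWM:
    """A position weight matrix over A,C,G,T with a background model,
    scored as log2 odds."""

    def __init__(self, probs: np.ndarray, background: np.ndarray | None = None) -> None:
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != 4 or probs.shape[1] < 1:
            raise ValidationError("PWM must be a 4 x L matrix")
        if np.any(probs <= 0):
            raise ValidationError("PWM entries must be strictly positive")
        if not np.allclose(probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValidationError("PWM columns must sum to 1")
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        if background.shape != (4,) or np.any(background <= 0):
            raise ValidationError("background must be 4 positive probabilities")
        self.probs = probs
        self.background = background / background.sum()
        # extra row so index 4 (N) contributes exactly 0 to any score
        lo = np.log2(self.probs / self.background[:, None])
        self._logodds = np.vstack([lo, np.zeros((1, lo.shape[1]))])

    @property
    def length(self) -> int:
        return int(self.probs.shape[1])

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=0))


_ENCODE_TABLE = np.full(256, -1, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE_TABLE[ord(_b)] = _i


def encode(sequence: str) -> np.ndarray:
    idx = _ENCODE_TABLE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if (idx < 0).any():
        bad = sequence[int(np.argmax(idx < 0))]
        raise ValidationError(f"invalid nucleotide {bad!r}")
    return idx


def call_pause_site(
    gene: GeneAnnotation,
    three_prime_track: SignalTrack,
    search_width: int = 100,
) -> PauseSite | None:
    """Pause site = argmax of sense-strand 3'-end counts over the
    strand-aware window [TSS, TSS + search_width); ties go to the
    5'-most base. Returns None (no-call) when the window holds no reads.
    """
    if three_prime_track.mode != THREE_PRIME:
        raise ValidationError("pause-site calling requires a three_prime track")
    gs, ge = gene.offset_window(0, search_width)
    vals = three_prime_track.values(gene.contig, gene.strand, max(gs, 0), ge)
    if gene.strand == "-":
        vals = vals[::-1]  # orient 5' -> 3'
    total = float(vals.sum())
    if total <= 0:
        return None
    offset = int(np.argmax(vals))  # argmax takes the first (5'-most) maximum
    return PauseSite(
        gene_id=gene.gene_id,
        contig=gene.contig,
        strand=gene.strand,
        position=gene.offset_to_genomic(offset),
        peak_count=float(vals[offset]),
        window_total=total,
    )


def select_top_positioned_quartile(sites: Sequence[PauseSite]) -> list[PauseSite]:
    """The ceil(n/4) sites with the strongest pause positioning; ties are
    resolved by gene_id for determinism."""
    if len(sites) < 4:
        raise ValidationError("need at least 4 called sites to take a quartile")
    ranked = sorted(sites, key=lambda s: (-s.positioning_score, s.gene_id))
    return ranked[: math.ceil(len(sites) / 4)]


def extract_centered_sequences(
    genome: GenomeSequence,
    sites: Sequence[PauseSite],
    width: int,
) -> tuple[list[str], int]:
    """Genomic sequences of ``width`` bases centred on each pause site,
    oriented 5'->3' on the gene's strand so the pause base always sits at
    index width/2. Returns (sequences, n_skipped_near_edges)."""
    if width % 2 != 0:
        raise ValidationError("width must be even")
    half = width // 2
    seqs: list[str] = []
    skipped = 0
    for site in sites:
        if site.strand == "+":
            s, e = site.position - half, site.position + half
        else:
            s, e = site.position - half + 1, site.position + half + 1
        if s < 0 or e > len(genome):
            skipped += 1
            continue
        chunk = genome.slice(s, e)
        seqs.append(chunk if site.strand == "+" else reverse_complement(chunk))
    return seqs, skipped


def build_pwm(
    sequences: Sequence[str],
    pseudocount: float = 0.25,
    background: np.ndarray | None = None,
) -> PWM:
    """Column-wise base frequencies with additive pseudocount; N bases
    are excluded from counts, with the column total adjusted."""
    if len(sequences) == 0:
        raise ValidationError("cannot build a PWM from zero sequences")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0 so all entries are positive")
    length = len(sequences[0])
    if length < 1 or any(len(s) != length for s in sequences):
        raise ValidationError("sequences must share one length >= 1")
    counts = np.zeros((5, length))
    for s in sequences:
        np.add.at(counts, (encode(s), np.arange(length)), 1.0)
    acgt = counts[:4]
    n_col = acgt.sum(axis=0)  # non-N count per column
    probs = (acgt + pseudocount) / (n_col + 4 * pseudocount)
    return PWM(probs, background=background)


def score_window(pwm: PWM, sequence: str, both_strands: bool = False) -> float:
    """Best log2-odds match of the PWM anywhere in ``sequence`` (sense
    strand by default); N contributes 0 at its column."""
    if len(sequence) < pwm.length:
        raise ValidationError("sequence shorter than the PWM")
    best = _best_score(pwm, encode(sequence))
    if both_strands:
        best = max(best, _best_score(pwm, encode(reverse_complement(sequence))))
    return best


def _offset_scores(pwm: PWM, idx: np.ndarray) -> np.ndarray:
    """Log-odds score at every alignment offset of the PWM along an
    encoded sequence."""
    L = pwm.length
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    return pwm._logodds[windows, np.arange(L)].sum(axis=1)


def _best_score(pwm: PWM, idx: np.ndarray) -> float:
    return float(_offset_scores(pwm, idx).max())


@dataclass(frozen=True)
class EnrichmentResult:
    species_id: str
    mean_pause_score: float
    mean_flank_score: float
    n_sites: int
    #: standard error of the mean per-site (pause - flank) difference
    std_error: float = float("nan")

    @property
    def enrichment(self) -> float:
        return self.mean_pause_score - self.mean_flank_score


def motif_enrichment_score(
    pwm: PWM,
    genome: GenomeSequence,
    sites: Sequence[PauseSite],
    pause_width: int = 20,
    flank_span: tuple[int, int] = (100, 500),
    species_id: str = "species",
    both_strands: bool = False,
) -> EnrichmentResult:
    """Mean best-match score of the pause-centred ``pause_width`` bp
    sequence minus the mean score of flanking DNA in [-far,-near) and
    [near,far) bases from the pause (within a 1 kb centred window).

    Flanks are scored as the mean of best-match scores over
    ``pause_width``-sized tiles so pause and flank scores share the same
    window-length statistics; the enrichment is then zero-centred on a
    motif-free genome.
    """
    near, far = flank_span
    if not 0 < near < far:
        raise ValidationError("flank_span must satisfy 0 < near < far")
    width = 2 * far
    seqs, _ = extract_centered_sequences(genome, sites, width)
    if not seqs:
        raise ValidationError("all sites were too close to a contig edge")
    half = width // 2
    pause_scores = []
    flank_scores = []
    L = pwm.length
    if pause_width < L:
        raise ValidationError("pause_width shorter than the PWM")
    for s in seqs:
        if both_strands:
            # per-window scoring; the strand max does not factor over a
            # single shared offset-score vector
            pause_seq = s[half - pause_width // 2 : half + pause_width // 2]
            tiles = [
                flank[i : i + pause_width]
                for flank in (s[: half - near], s[half + near :])
                for i in range(0, len(flank) - pause_width + 1, pause_width)
            ]
            pause_scores.append(score_window(pwm, pause_seq, both_strands=True))
            flank_scores.append(
                float(np.mean([score_window(pwm, t, both_strands=True) for t in tiles]))
            )
            continue
        scores = _offset_scores(pwm, encode(s))

        def window_best(a: int, b: int) -> float:
            # best match fully inside s[a:b]
            return float(scores[a : b - L + 1].max())

        pause_scores.append(window_best(half - pause_width // 2, half + pause_width // 2))
        tile_scores = []
        for fa, fb in ((0, half - near), (half + near, width)):
            for a in range(fa, fb - pause_width + 1, pause_width):
                tile_scores.append(window_best(a, a + pause_width))
        flank_scores.append(float(np.mean(tile_scores)))
    diffs = np.asarray(pause_scores) - np.asarray(flank_scores)
    se = float(diffs.std(ddof=1) / np.sqrt(diffs.size)) if diffs.size > 1 else float("nan")
    return EnrichmentResult(
        species_id=species_id,
        mean_pause_score=float(np.mean(pause_scores)),
        mean_flank_score=float(np.mean(flank_scores)),
        n_sites=len(seqs),
        std_error=se,
    )


# -- PWM plain-text I/O -------------------------------------------------


def read_pwm(path: str | Path, background: np.ndarray | None = None) -> PWM:
    """Read a whitespace-delimited 4-row (A,C,G,T) x L matrix with a
    one-line header."""
    with open(path) as fh:
        lines = [ln for ln in (l.strip() for l in fh) if ln]
    rows = [list(map(float, ln.split())) for ln in lines[1:5]]
    if len(rows) != 4:
        raise ValidationError(f"{path}: expected 4 matrix rows after the header")
    return PWM(np.array(rows), background=background)


def write_pwm(pwm: PWM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pause motif PWM, rows A C G T, length {pwm.length}\n")
        for row in pwm.probs:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def write_pause_sites(sites: Sequence[PauseSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcontig\tstrand\tposition\tpeak_count\twindow_total\tpositioning_score\n")
        for s in sites:
            fh.write(
                f"{s.gene_id}\t{s.contig}\t{s.strand}\t{s.position}\t"
                f"{s.peak_count:.6g}\t{s.window_total:.6g}\t{s.positioning_score:.6g}\n"
            )
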