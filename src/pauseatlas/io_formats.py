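"""Standard-format I/O and the shared coordinate/strand conventions.

All internal coordinates are 0-based, half-open, matching BED/bedGraph.
Strand-aware quantities (TSS, TES, windows "downstream of the TSS") are
expressed as *signed offsets along the direction of transcription* and
converted to genomic intervals here, so every other module can reason in
transcription space without repeating the minus-strand arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"

_NT_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_NT = set("ACGTN")
_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")


class ParseError(ValueError):
    """A malformed line in a text format; carries the offending line number."""


class ValidationError(ValueError):
    """Structurally parseable input that violates an invariant."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_NT_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide (or protein) sequence.

    Nucleotide sequences are uppercased with non-ACGTN characters mapped
    to N; protein sequences are uppercased over the 20-letter alphabet
    plus X.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValidationError(f"empty sequence for record {self.name!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        if start < 0 or end > len(self.sequence):
            raise ValidationError(
                f"slice [{start}, {end}) outside contig {self.name!r} "
                f"of length {len(self.sequence)}"
            )
        return self.sequence[start:end]


@dataclass(frozen=True)
class GeneAnnotation:
    """A named, stranded interval in 0-based half-open coordinates."""

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start site, strand-resolved."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site, strand-resolved."""
        return self.end - 1 if self.strand == "+" else self.start

    def offset_to_genomic(self, offset: int) -> int:
        """Genomic base at a signed offset downstream (+) of the TSS."""
        return self.tss + offset if self.strand == "+" else self.tss - offset

    def offset_window(self, lo: int, hi: int) -> tuple[int, int]:
        """Genomic half-open interval covering transcription-space offsets
        [lo, hi). Width is hi - lo on both strands."""
        if hi <= lo:
            raise ValidationError(f"empty offset window [{lo}, {hi})")
        if self.strand == "+":
            return self.tss + lo, self.tss + hi
        return self.tss - hi + 1, self.tss - lo + 1


class SignalTrack:
    """Stranded per-base read counts over named contigs.

    Backed by dense per-(contig, strand) float arrays that grow on
    demand; interval queries return the exact sum of per-base values in
    the half-open interval. ``mode`` records whether reads were mapped
    to their 5'- or 3'-ends (or a derived quantity such as a fold-change
    track, for which ``signed=True`` lifts the non-negativity rule).
    """

    def __init__(self, mode: str, signed: bool = False) -> None:
        self.mode = mode
        self.signed = signed
        self._data: dict[tuple[str, str], np.ndarray] = {}
        self._warned_contigs: set[tuple[str, str]] = set()

    # -- construction ---------------------------------------------------

    def _array(self, contig: str, strand: str, min_len: int) -> np.ndarray:
        key = (contig, strand)
        arr = self._data.get(key)
        if arr is None:
            arr = np.zeros(max(min_len, 256), dtype=np.float64)
            self._data[key] = arr
        elif arr.size < min_len:
            grown = np.zeros(max(min_len, 2 * arr.size), dtype=np.float64)
            grown[: arr.size] = arr
            arr = grown
            self._data[key] = arr
        return arr

    def add(self, contig: str, strand: str, pos: int, value: float = 1.0) -> None:
        if pos < 0:
            raise ValidationError(f"negative position {pos} on {contig}")
        self._array(contig, strand, pos + 1)[pos] += value

    def add_positions(
        self, contig: str, strand: str, positions: np.ndarray, value: float = 1.0
    ) -> None:
        positions = np.asarray(positions, dtype=np.int64)
        if positions.size == 0:
            return
        if positions.min() < 0:
            raise ValidationError("negative position in bulk add")
        arr = self._array(contig, strand, int(positions.max()) + 1)
        np.add.at(arr, positions, value)

    def set_interval(
        self, contig: str, strand: str, start: int, end: int, value: float
    ) -> None:
        if not self.signed and value < 0:
            raise ValidationError(f"negative value {value} on {contig} {strand}")
        self._array(contig, strand, end)[start:end] = value

    # -- queries --------------------------------------------------------

    def contigs(self) -> list[tuple[str, str]]:
        return sorted(self._data)

    def values(self, contig: str, strand: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end), zero-padded outside the
        stored range; negative coordinates are clipped to zero-fill."""
        if end <= start:
            return np.zeros(0)
        out = np.zeros(end - start, dtype=np.float64)
        key = (contig, strand)
        arr = self._data.get(key)
        if arr is None:
            if key not in self._warned_contigs:
                logger.warning("query on unknown contig/strand %s%s returns 0", contig, strand)
                self._warned_contigs.add(key)
            return out
        lo = max(start, 0)
        hi = min(end, arr.size)
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def query(self, contig: str, strand: str, start: int, end: int) -> float:
        return float(self.values(contig, strand, start, end).sum())

    @property
    def total_reads(self) -> float:
        return float(sum(arr.sum() for arr in self._data.values()))

    def scaled(self, factor: float) -> "SignalTrack":
        out = SignalTrack(self.mode, signed=self.signed or factor < 0)
        for (contig, strand), arr in self._data.items():
            out._data[(contig, strand)] = arr * factor
        return out

    def copy(self) -> "SignalTrack":
        return self.scaled(1.0)


# -- BED6 ---------------------------------------------------------------


def read_gene_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read gene annotations from a BED6 file (half-open convention
    preserved unchanged)."""
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 tab-separated columns")
            contig, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: strand must be + or -")
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: start {start} >= end {end} for {name!r}"
                )
            genes.append(GeneAnnotation(name, contig, strand, start, end))
    return genes


def write_gene_annotations(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.contig}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# -- bedGraph -----------------------------------------------------------


def _read_bedgraph_file(
    path: str | Path,
    track: SignalTrack,
    strand: str,
    negated: bool,
) -> None:
    last_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            contig, start_s, end_s, value_s = fields
            try:
                start, end, value = int(start_s), int(end_s), float(value_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed interval/value") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            if start < last_end.get(contig, 0):
                raise ValidationError(
                    f"{path}:{lineno}: overlapping or unsorted interval on {contig}"
                )
            last_end[contig] = end
            if negated:
                value = -value
            if value < 0:
                raise ValidationError(
                    f"{path}:{lineno}: negative value {value} on {strand} strand"
                )
            if value != 0:
                track.set_interval(contig, strand, start, end, value)


def read_signal_track(
    plus_path: str | Path,
    minus_path: str | Path,
    mode: str,
    negated_minus: bool = False,
) -> SignalTrack:
    """Read a stranded bedGraph pair into a :class:`SignalTrack`.

    ``negated_minus`` handles the common dialect in which the
    minus-strand file stores values with a negative sign; values are
    always returned as non-negative magnitudes.
    """
    if mode not in (FIVE_PRIME, THREE_PRIME):
        raise ValidationError(f"unknown track mode {mode!r}")
    track = SignalTrack(mode)
    _read_bedgraph_file(plus_path, track, "+", negated=False)
    _read_bedgraph_file(minus_path, track, "-", negated=negated_minus)
    return track


def _iter_runs(arr: np.ndarray) -> Iterator[tuple[int, int, float]]:
    """Yield (start, end, value) runs of equal nonzero values."""
    if arr.size == 0:
        return
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [arr.size]))
    for s, e in zip(starts, ends):
        v = arr[s]
        if v != 0:
            yield int(s), int(e), float(v)


def write_signal_track(
    track: SignalTrack,
    plus_path: str | Path,
    minus_path: str | Path,
    negated_minus: bool = False,
) -> None:
    """Write a track as a bedGraph pair, run-length merging adjacent equal
    values. Round-trips through :func:`read_signal_track` exactly."""

    def fmt(v: float) -> str:
        return f"{int(v)}" if float(v).is_integer() else repr(v)

    for strand, path in (("+", plus_path), ("-", minus_path)):
        sign = -1.0 if (negated_minus and strand == "-") else 1.0
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="{track.mode}{strand}"\n')
            for (contig, st), arr in sorted(track._data.items()):
                if st != strand:
                    continue
                for s, e, v in _iter_runs(arr):
                    fh.write(f"{contig}\t{s}\t{e}\t{fmt(sign * v)}\n")


# -- FASTA --------------------------------------------------------------


def _clean_nucleotide(seq: str) -> str:
    seq = seq.upper()
    return "".join(c if c in _VALID_NT else "N" for c in seq)


def _clean_protein(seq: str, name: str) -> str:
    seq = seq.upper().rstrip("*")
    bad = set(seq) - _VALID_AA
    if bad:
        raise ValidationError(f"record {name!r}: invalid residues {sorted(bad)}")
    return seq


def read_fasta_sequences(
    path: str | Path, alphabet: str = "nucleotide"
) -> list[GenomeSequence]:
    """Read FASTA records; names are the header up to first whitespace.

    ``alphabet`` selects normalisation: nucleotide sequences are
    uppercased with non-ACGTN mapped to N; protein sequences are
    validated over the 20 amino acids plus X.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate FASTA record name {rec.id!r}")
        seen.add(rec.id)
        raw = str(rec.seq)
        if not raw:
            raise ValidationError(f"empty FASTA record {rec.id!r}")
        if alphabet == "nucleotide":
            seq = _clean_nucleotide(raw)
        elif alphabet == "protein":
            seq = _clean_protein(raw, rec.id)
        else:
            raise ValidationError(f"unknown alphabet {alphabet!r}")
        records.append(GenomeSequence(rec.id, seq))
    return records


def write_fasta_sequences(
    records: Iterable[GenomeSequence], path: str | Path, width: int = 70
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
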