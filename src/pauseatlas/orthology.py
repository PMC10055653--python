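"""Presence/absence of query proteins in target proteomes by a two-pass
reciprocal local-alignment search.

The search mirrors reciprocal BLASTp at desk scale: a Smith-Waterman
local alignment (BLOSUM62, affine gaps 11/1) scores every query-target
pair, and a Karlin-Altschul E-value computed per pair (search space
m*n, fixed gapped lambda/K) is thresholded at 1e-6. Targets passing the
forward threshold are candidates; a candidate confirms presence either
when any of its reciprocal hits against the query proteome passes the
threshold (lenient mode) or when its best reciprocal hit is the
original query (strict mode, classical reciprocal-best-hit).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .io_formats import GenomeSequence, ValidationError

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class AlignParams:
    """Alignment and E-value parameters.

    ``karlin_lambda`` and ``karlin_k`` default to the standard gapped
    BLOSUM62/11/1 constants; the search space is m*n per pair (no
    database-length correction), so the E-value is a deterministic
    function of one pairwise score.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    evalue_threshold: float = 1e-6
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise ValidationError("evalue_threshold must be > 0")


def _make_aligner(params: AlignParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(params.matrix_name)
    aligner.mode = "local"
    # first gap position costs open+extend, each further position extend
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def align_score(
    a: str, b: str, params: AlignParams | None = None
) -> tuple[float, float, float]:
    """Smith-Waterman local alignment of two protein sequences.

    Returns (raw score, bit score, E-value) with bit score
    S' = (lambda*S - ln K)/ln 2 and E = m*n*2^(-S').
    """
    params = params or AlignParams()
    if not a or not b:
        raise ValidationError("sequences must be non-empty")
    for seq in (a, b):
        bad = set(seq) - _VALID_AA
        if bad:
            raise ValidationError(f"unknown residues {sorted(bad)}")
    raw = float(_make_aligner(params).score(a, b))
    bit = (params.karlin_lambda * raw - math.log(params.karlin_k)) / math.log(2.0)
    evalue = len(a) * len(b) * 2.0 ** (-bit)
    return raw, bit, evalue


@dataclass(frozen=True)
class OrthologyCall:
    query_id: str
    species_id: str
    present: bool
    mode: str
    forward_best_hit: str | None = None
    forward_evalue: float = float("inf")
    reciprocal_hit: str | None = None
    reciprocal_evalue: float = float("inf")


def detect_presence(
    query_id: str,
    query_proteome: Sequence[GenomeSequence],
    target_proteome: Sequence[GenomeSequence],
    params: AlignParams | None = None,
    mode: str = "lenient",
    species_id: str = "target",
) -> OrthologyCall:
    """Two-pass reciprocal search for one query protein in one species.

    Pass 1 collects all target sequences with forward E-value below the
    threshold. Pass 2 searches each candidate back against the full
    query proteome; ``lenient`` accepts any reciprocal hit below the
    threshold, ``strict`` additionally requires the candidate's best
    reciprocal hit to be the original query.
    """
    params = params or AlignParams()
    if mode not in ("lenient", "strict"):
        raise ValidationError(f"unknown mode {mode!r}")
    query_by_id = {r.name: r.sequence for r in query_proteome}
    if query_id not in query_by_id:
        raise ValidationError(f"query {query_id!r} not in query proteome")
    query_seq = query_by_id[query_id]

    # pass 1: forward search
    candidates: list[tuple[float, str, str]] = []
    for rec in target_proteome:
        _, _, ev = align_score(query_seq, rec.sequence, params)
        if ev < params.evalue_threshold:
            candidates.append((ev, rec.name, rec.sequence))
    candidates.sort(key=lambda c: (c[0], c[1]))
    if not candidates:
        return OrthologyCall(query_id, species_id, False, mode)

    fwd_ev, fwd_hit, _ = candidates[0]
    best_recip: tuple[float, str] | None = None
    for cand_ev, cand_name, cand_seq in candidates:
        recip = []
        for qname in sorted(query_by_id):
            _, _, ev = align_score(cand_seq, query_by_id[qname], params)
            recip.append((ev, qname))
        recip.sort()
        top_ev, top_name = recip[0]
        passing = [(ev, name) for ev, name in recip if ev < params.evalue_threshold]
        if mode == "lenient":
            if passing:
                hit_ev, hit_name = passing[0]
                return OrthologyCall(
                    query_id, species_id, True, mode,
                    forward_best_hit=cand_name, forward_evalue=cand_ev,
                    reciprocal_hit=hit_name, reciprocal_evalue=hit_ev,
                )
        else:  # strict reciprocal-best-hit
            if top_name == query_id and top_ev < params.evalue_threshold:
                return OrthologyCall(
                    query_id, species_id, True, mode,
                    forward_best_hit=cand_name, forward_evalue=cand_ev,
                    reciprocal_hit=top_name, reciprocal_evalue=top_ev,
                )
        if best_recip is None or top_ev < best_recip[0]:
            best_recip = (top_ev, top_name)
    return OrthologyCall(
        query_id, species_id, False, mode,
        forward_best_hit=fwd_hit, forward_evalue=fwd_ev,
        reciprocal_hit=best_recip[1] if best_recip else None,
        reciprocal_evalue=best_recip[0] if best_recip else float("inf"),
    )


@dataclass
class PresenceMatrix:
    """Query-protein x species presence calls with per-entry evidence."""

    matrix: pd.DataFrame  # bool entries, rows=queries, cols=species
    calls: dict[tuple[str, str], OrthologyCall] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        self.matrix.astype(int).to_csv(path, sep="\t")

    def evidence_json(self, path: str | Path) -> None:
        payload = {
            f"{q}|{s}": {
                "present": c.present,
                "mode": c.mode,
                "forward_best_hit": c.forward_best_hit,
                "forward_evalue": c.forward_evalue,
                "reciprocal_hit": c.reciprocal_hit,
                "reciprocal_evalue": c.reciprocal_evalue,
            }
            for (q, s), c in sorted(self.calls.items())
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=str))


def build_presence_matrix(
    query_ids: Sequence[str],
    query_proteome: Sequence[GenomeSequence],
    proteomes: dict[str, Sequence[GenomeSequence]],
    params: AlignParams | None = None,
    mode: str = "lenient",
) -> PresenceMatrix:
    """Presence calls for every (query, species) pair, in deterministic
    sorted order."""
    if not query_ids or not proteomes:
        raise ValidationError("need at least one query and one species")
    params = params or AlignParams()
    queries = sorted(query_ids)
    species = sorted(proteomes)
    calls: dict[tuple[str, str], OrthologyCall] = {}
    data = {}
    for sp in species:
        col = []
        for q in queries:
            call = detect_presence(q, query_proteome, proteomes[sp], params, mode, sp)
            calls[(q, sp)] = call
            col.append(call.present)
        data[sp] = col
    matrix = pd.DataFrame(data, index=pd.Index(queries, name="query"))
    return PresenceMatrix(matrix=matrix, calls=calls)
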