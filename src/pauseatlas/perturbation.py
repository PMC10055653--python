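"""Factor-depletion / heat-shock response analysis: spike-in scaling,
log2 fold-change tracks, binned response matrices, k-means response
clustering, and 3-kb-excluded gene-body induction statistics.

Samples from a depletion time course are made comparable by scaling to
exogenous spike-in reads; per-base log2 fold-change tracks (with a 0.1
pseudocount) summarised in fixed-width bins around each gene's TSS form
the feature matrix from which response clusters are derived.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .comparative_stats import mann_whitney_u
from .io_formats import GeneAnnotation, SignalTrack, ValidationError

logger = logging.getLogger(__name__)


# -- spike-in scaling ---------------------------------------------------


@dataclass(frozen=True)
class SpikeScaling:
    spike_in_reads: dict[str, float]
    factors: dict[str, float]

    def scale_track(self, sample: str, track: SignalTrack) -> SignalTrack:
        return track.scaled(1.0 / self.factors[sample])


def spike_in_scaling_factors(spike_counts: Mapping[str, float]) -> SpikeScaling:
    """Per-sample scaling factors: count divided by the mean count over
    samples (so factors average to 1); scaled signal = raw / factor."""
    if not spike_counts:
        raise ValidationError("no spike-in counts provided")
    counts = dict(spike_counts)
    if any(c <= 0 for c in counts.values()):
        raise ValidationError("spike-in counts must be positive")
    mean = sum(counts.values()) / len(counts)
    return SpikeScaling(
        spike_in_reads=counts,
        factors={s: c / mean for s, c in counts.items()},
    )


# -- fold-change tracks -------------------------------------------------


def log2fc_track(
    treated: SignalTrack, control: SignalTrack, pseudocount: float = 0.1
) -> SignalTrack:
    """Per-base log2((treated + pc) / (control + pc)); both tracks must
    already be depth/spike scaled."""
    keys_t = set(treated._data)
    keys_c = set(control._data)
    out = SignalTrack("log2fc", signed=True)
    for key in keys_t | keys_c:
        contig, strand = key
        n = max(
            treated._data[key].size if key in treated._data else 0,
            control._data[key].size if key in control._data else 0,
        )
        tv = treated.values(contig, strand, 0, n)
        cv = control.values(contig, strand, 0, n)
        out._data[key] = np.log2((tv + pseudocount) / (cv + pseudocount))
    return out


# -- binned response matrix --------------------------------------------


@dataclass
class ResponseMatrix:
    """Genes x fixed-width bins of track signal around an anchor point,
    ordered 5'->3'; bins past a contig end are missing (NaN + mask)."""

    gene_ids: list[str]
    values: np.ndarray  # (n_genes, n_bins), NaN where missing
    missing: np.ndarray  # bool mask, True where the bin was unavailable
    bin_size: int
    upstream: int
    downstream: int

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def anchor_bin(self) -> int:
        """Index of the first bin at/after the anchor point."""
        return self.upstream // self.bin_size

    def imputed(self) -> np.ndarray:
        out = self.values.copy()
        out[self.missing] = 0.0
        return out


def binned_region_matrix(
    track: SignalTrack,
    anchors: Sequence[tuple[GeneAnnotation, int]],
    upstream: int = 1000,
    downstream: int = 50000,
    bin_size: int = 1000,
    aggregate: str = "mean",
) -> ResponseMatrix:
    """Strand-aware binned signal matrix around per-gene anchor points.

    Bins tile transcription-space offsets [-upstream, downstream) from
    the anchor in ``bin_size`` steps, giving (upstream + downstream) /
    bin_size columns (51 at the defaults); the default aggregator is
    the per-base mean within the bin.
    """
    if (upstream + downstream) % bin_size:
        raise ValidationError("bin_size must divide the total window span")
    if aggregate not in ("mean", "sum"):
        raise ValidationError(f"unknown aggregator {aggregate!r}")
    n_bins = (upstream + downstream) // bin_size
    gene_ids = [g.gene_id for g, _ in anchors]
    values = np.full((len(anchors), n_bins), np.nan)
    missing = np.ones((len(anchors), n_bins), dtype=bool)
    for i, (gene, anchor) in enumerate(anchors):
        for j in range(n_bins):
            off_lo = -upstream + j * bin_size
            off_hi = off_lo + bin_size
            if gene.strand == "+":
                s, e = anchor + off_lo, anchor + off_hi
            else:
                s, e = anchor - off_hi + 1, anchor - off_lo + 1
            if s < 0:
                continue
            vals = track.values(gene.contig, gene.strand, s, e)
            agg = float(vals.mean()) if aggregate == "mean" else float(vals.sum())
            values[i, j] = agg
            missing[i, j] = False
    return ResponseMatrix(gene_ids, values, missing, bin_size, upstream, downstream)


def kmeans_cluster(
    matrix: ResponseMatrix, k: int = 3, seed: int = 0, n_init: int = 10
) -> np.ndarray:
    """Lloyd's k-means over the (zero-imputed) response matrix, best of
    ``n_init`` restarts; labels are renumbered by descending mean value
    in the pause-proximal bin so cluster 0 is always the strongest
    pause-proximal response."""
    X = matrix.imputed()
    if k > X.shape[0]:
        raise ValidationError(f"k={k} exceeds the {X.shape[0]} genes")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(X)
    anchor = matrix.anchor_bin
    order = np.argsort(
        [-X[raw == c, anchor].mean() if (raw == c).any() else np.inf for c in range(k)]
    )
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[raw]


# -- heat-shock induction statistics -----------------------------------


def gene_body_counts_excl3kb(
    gene: GeneAnnotation, track: SignalTrack, exclusion: int = 3000
) -> float | None:
    """Sense-strand read sum over [TSS + exclusion, TES], removing the
    promoter-proximal region so pause loss does not masquerade as a
    body-level change. Returns None for genes shorter than the
    exclusion (flagged excluded by callers)."""
    if gene.length <= exclusion:
        return None
    s, e = gene.offset_window(exclusion, gene.length)
    return track.query(gene.contig, gene.strand, max(s, 0), e)


@dataclass(frozen=True)
class HsGeneClass:
    gene_id: str
    hs_class: str  # up | down | unchanged
    log2fc: float
    padj: float
    dtag_stable: bool


def classify_hs_response(
    records: Sequence[Mapping[str, float]],
    alpha: float = 0.05,
) -> list[HsGeneClass]:
    """Classify genes by heat-shock response (up / down / unchanged at
    padj < alpha) and flag those unchanged under depletion alone
    (dtag_padj >= alpha); genes missing an adjusted p-value are dropped
    with a warning.

    Each record needs keys gene_id, log2fc, padj, dtag_padj.
    """
    out: list[HsGeneClass] = []
    for rec in records:
        padj = rec.get("padj")
        dtag_padj = rec.get("dtag_padj")
        if padj is None or dtag_padj is None or math.isnan(padj) or math.isnan(dtag_padj):
            logger.warning("gene %s dropped: missing adjusted p-value", rec.get("gene_id"))
            continue
        fc = float(rec["log2fc"])
        if padj < alpha and fc > 0:
            cls = "up"
        elif padj < alpha and fc < 0:
            cls = "down"
        else:
            cls = "unchanged"
        out.append(
            HsGeneClass(
                gene_id=str(rec["gene_id"]),
                hs_class=cls,
                log2fc=fc,
                padj=float(padj),
                dtag_stable=bool(dtag_padj >= alpha),
            )
        )
    return out


def hs_induction_defect(
    classes: Sequence[HsGeneClass],
    fc_condition_a: Mapping[str, float],
    fc_condition_b: Mapping[str, float],
) -> dict[str, dict[str, float]]:
    """Compare two conditions' log2 fold changes at heat-shock-responsive
    genes that are stable under depletion alone.

    Runs an unpaired two-sided Mann-Whitney separately at up- and
    down-regulated genes; a positive median difference (a - b) at up
    genes is an induction defect in condition b. Empty classes are
    skipped and reported.
    """
    report: dict[str, dict[str, float]] = {}
    for cls in ("up", "down"):
        genes = [c.gene_id for c in classes if c.hs_class == cls and c.dtag_stable]
        a = [fc_condition_a[g] for g in genes if g in fc_condition_a]
        b = [fc_condition_b[g] for g in genes if g in fc_condition_b]
        if not a or not b:
            report[cls] = {"n_a": len(a), "n_b": len(b), "skipped": True}
            continue
        u, p = mann_whitney_u(a, b)
        report[cls] = {
            "n_a": len(a),
            "n_b": len(b),
            "u": u,
            "p_value": p,
            "median_a": float(np.median(a)),
            "median_b": float(np.median(b)),
            "median_difference": float(np.median(a) - np.median(b)),
        }
    return report


# -- bundled differential engine ---------------------------------------


def simple_differential_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    gene_ids: Sequence[str],
) -> list[dict[str, float]]:
    """A minimal pluggable differential engine over replicate gene
    counts (genes x replicates, >= 2 replicates per condition):
    spike-scaled inputs, per-gene two-sided Mann-Whitney across
    replicates, Benjamini-Hochberg adjustment, log2 fold change of
    means. External engines' tables can be substituted anywhere a
    (gene_id, log2fc, padj) record is consumed."""
    from statsmodels.stats.multitest import multipletests

    counts_a = np.atleast_2d(np.asarray(counts_a, dtype=float))
    counts_b = np.atleast_2d(np.asarray(counts_b, dtype=float))
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise ValidationError("need >= 2 replicates per condition")
    pvals = []
    fcs = []
    for ra, rb in zip(counts_a, counts_b):
        _, p = mann_whitney_u(ra, rb) if not np.allclose(ra, rb) else (0.0, 1.0)
        pvals.append(p)
        fcs.append(math.log2((rb.mean() + 0.5) / (ra.mean() + 0.5)))
    padj = multipletests(pvals, method="fdr_bh")[1]
    return [
        {"gene_id": g, "log2fc": fc, "padj": float(q)}
        for g, fc, q in zip(gene_ids, fcs, padj)
    ]
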