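"""Cross-species statistics: the motif-enrichment vs pausing-index
regression, grouping species by NELF subunit complement, and
Mann-Whitney comparisons between groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import ValidationError
from .orthology import PresenceMatrix
from .pausing_metrics import SpeciesSummary


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    slope_stderr: float
    n: int

    def slope_confint(self, alpha: float = 0.05) -> tuple[float, float]:
        t = stats.t.ppf(1 - alpha / 2, self.n - 2)
        return self.slope - t * self.slope_stderr, self.slope + t * self.slope_stderr


def fit_linear_regression(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Ordinary least squares of y on x; the two-sided p-value tests a
    zero slope via the t statistic with n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in regression input")
    if np.allclose(x, x[0]):
        raise ValidationError("zero variance in x")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        slope_stderr=float(res.stderr),
        n=int(x.size),
    )


@dataclass(frozen=True)
class SubunitGroup:
    """Species sharing a count of detected NELF subunits, with pooled
    log10 pausing indexes (per-gene when available, else the species
    means)."""

    label: int
    species: tuple[str, ...]
    pooled_log10_pis: tuple[float, ...]


def group_by_subunit_count(
    species_summaries: Sequence[SpeciesSummary],
    presence: PresenceMatrix,
    subunit_rows: Sequence[str],
    per_gene_pis: dict[str, Sequence[float]] | None = None,
) -> list[SubunitGroup]:
    """Group species by how many of ``subunit_rows`` (e.g. the four NELF
    subunits) are called present, ordered by count.

    ``per_gene_pis`` optionally supplies gene-level pausing indexes per
    species; when given, groups pool the per-gene log10 indexes (the
    distribution the box plots and group tests are drawn from)."""
    missing_rows = [r for r in subunit_rows if r not in presence.matrix.index]
    if missing_rows:
        raise ValidationError(f"subunit rows missing from matrix: {missing_rows}")
    groups: dict[int, list[SpeciesSummary]] = {}
    for summ in species_summaries:
        if summ.species_id not in presence.matrix.columns:
            raise ValidationError(f"species {summ.species_id!r} missing from matrix")
        count = int(presence.matrix.loc[list(subunit_rows), summ.species_id].sum())
        groups.setdefault(count, []).append(summ)

    def pooled(members: list[SpeciesSummary]) -> tuple[float, ...]:
        if per_gene_pis is None:
            return tuple(s.mean_log10_pi for s in members)
        vals: list[float] = []
        for s in members:
            vals.extend(np.log10(np.asarray(per_gene_pis[s.species_id], dtype=float)))
        return tuple(vals)

    return [
        SubunitGroup(
            label=count,
            species=tuple(s.species_id for s in members),
            pooled_log10_pis=pooled(members),
        )
        for count, members in sorted(groups.items())
    ]


def mann_whitney_u(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Mann-Whitney U test: exact enumeration for small tie-free samples
    (n_a + n_b <= 12), otherwise the tie- and continuity-corrected
    normal approximation. Returns (U of sample_a, p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def adjacent_group_comparisons(
    groups: Sequence[SubunitGroup],
) -> list[dict[str, float]]:
    """Mann-Whitney comparisons between each pair of adjacent subunit
    groups (pooled mean log10 pausing indexes)."""
    out = []
    for g1, g2 in zip(groups, groups[1:]):
        if not g1.pooled_log10_pis or not g2.pooled_log10_pis:
            continue
        u, p = mann_whitney_u(g1.pooled_log10_pis, g2.pooled_log10_pis)
        out.append(
            {"group_a": g1.label, "group_b": g2.label, "u": u, "p_value": p,
             "n_a": len(g1.pooled_log10_pis), "n_b": len(g2.pooled_log10_pis)}
        )
    return out
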