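"""Repertoire-level statistics.

Summarises an annotated single-cell repertoire the way single-cell Ig
studies report it: per-donor and pooled detection rates, V/D/J usage at
gene and family level with chi-square comparison between repertoires,
the distribution of distinct rearrangement patterns per cell, shared
identical-junction rearrangements (public clonotypes) within and across
donors, the CDR3 amino-acid length histogram with a Gaussian fit and its
R², the genomic-position bias of V usage along the IGH locus, and the
nonfunctional-sequence fraction.

Usage is counted per distinct cell pattern (not per colony sequence), so
resequencing the same transcript does not inflate frequencies.  Percents
are computed in exact rational arithmetic and rounded half-up to the
printed precision; raw fractions are always retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as _sps

from vdjrep.annotator import AnnotatedRearrangement, CellRecord
from vdjrep.germline import ReferenceSet, family_of


def percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Exact percentage rounded half-up to ``ndigits`` decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty set")
    frac = Fraction(numerator, denominator) * 100
    q = Decimal(1).scaleb(-ndigits)
    exact = Decimal(frac.numerator) / Decimal(frac.denominator)
    return float(exact.quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Detection and productivity
# ---------------------------------------------------------------------------

@dataclass
class DetectionRate:
    per_donor: dict[str, tuple[int, int, float]]   # donor -> (pos, total, %)
    positive: int
    total: int
    percent_pooled: float                           # integer-rounded


def detection_rate(cells: Sequence[CellRecord]) -> DetectionRate:
    """Fraction of assayed cells with >=1 annotated rearrangement pattern.

    Pooled across donors by summing counts; the pooled percent is rounded
    to the nearest integer and per-donor percents to 1 decimal, the
    precision such studies print.
    """
    if not cells:
        raise ValueError("no cells")
    per_donor: dict[str, list[int]] = {}
    for cell in cells:
        pos, tot = per_donor.setdefault(cell.donor_id, [0, 0])
        per_donor[cell.donor_id][1] += 1
        per_donor[cell.donor_id][0] += int(cell.positive)
    donors = {
        d: (p, t, percent(p, t, 1)) for d, (p, t) in sorted(per_donor.items())
    }
    positive = sum(p for p, _, _ in donors.values())
    total = sum(t for _, t, _ in donors.values())
    return DetectionRate(donors, positive, total, percent(positive, total, 0))


@dataclass
class ProductivityFraction:
    nonfunctional: int
    total: int
    percent_nonfunctional: float


def productivity_fraction(
    annotations: Sequence[AnnotatedRearrangement],
) -> ProductivityFraction:
    """Nonfunctional share of annotated sequences (1-decimal percent)."""
    if not annotations:
        raise ValueError("no annotations")
    nonfunc = sum(1 for a in annotations if not a.productive)
    return ProductivityFraction(nonfunc, len(annotations),
                                percent(nonfunc, len(annotations), 1))


# ---------------------------------------------------------------------------
# Usage tables and chi-square comparison
# ---------------------------------------------------------------------------

@dataclass
class UsageTable:
    level: str                   # "gene" or "family"
    segment_class: str           # V / D / J
    counts: dict[str, int]
    total: int
    unassigned: int = 0          # D rearrangements without a D call

    @property
    def frequencies(self) -> dict[str, float]:
        return {k: v / self.total for k, v in self.counts.items()}


_CALL_ATTR = {"V": "v_call", "D": "d_call", "J": "j_call"}


def usage_frequencies(
    patterns: Sequence[AnnotatedRearrangement],
    level: str = "family",
    segment_class: str = "V",
) -> UsageTable:
    """Segment usage over distinct cell patterns.

    ``patterns`` should hold one annotation per distinct cell pattern (see
    :func:`vdjrep.annotator.dedupe_cell_patterns`); unassigned D calls are
    excluded from the D table and reported separately.
    """
    if level not in ("gene", "family"):
        raise ValueError("level must be 'gene' or 'family'")
    attr = _CALL_ATTR[segment_class]
    counts: dict[str, int] = {}
    unassigned = 0
    for ann in patterns:
        call = getattr(ann, attr)
        if call == "unassigned":
            unassigned += 1
            continue
        label = family_of(call) if level == "family" else call
        counts[label] = counts.get(label, 0) + 1
    if not patterns:
        raise ValueError("no patterns")
    if not counts:
        if unassigned:
            return UsageTable(level, segment_class, {}, 0, unassigned)
        raise ValueError(f"no assigned {segment_class} calls")
    return UsageTable(level, segment_class, dict(sorted(counts.items())),
                      sum(counts.values()), unassigned)


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    pvalue: float
    labels: list[str]


def chi_square_usage(table_a: UsageTable, table_b: UsageTable) -> ChiSquareResult:
    """Pearson chi-square comparing two usage tables.

    The label space is the union (zero-filled); the test runs on the
    2 x k contingency of counts with k-1 degrees of freedom.  A label
    with zero total count across both tables is an error (its expected
    count is not computable).
    """
    labels = sorted(set(table_a.counts) | set(table_b.counts))
    a = np.array([table_a.counts.get(l, 0) for l in labels])
    b = np.array([table_b.counts.get(l, 0) for l in labels])
    dead = [l for l, t in zip(labels, a + b) if t == 0]
    if dead:
        raise ValueError(f"labels with zero counts in both tables: {dead}")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("one table is empty")
    stat, p, df, _ = _sps.chi2_contingency(np.vstack([a, b]), correction=False)
    return ChiSquareResult(float(stat), int(df), float(p), labels)


# ---------------------------------------------------------------------------
# Patterns per cell
# ---------------------------------------------------------------------------

@dataclass
class PatternsPerCell:
    counts: dict[str, int]       # "1", "2", ">2"
    percents: dict[str, float]
    n_cells: int


def patterns_per_cell(cells: Sequence[CellRecord]) -> PatternsPerCell:
    """Distribution of distinct rearrangement patterns over positive cells."""
    positive = [c for c in cells if c.positive]
    bins = {"1": 0, "2": 0, ">2": 0}
    for cell in positive:
        n = cell.n_patterns
        bins["1" if n == 1 else "2" if n == 2 else ">2"] += 1
    n = len(positive)
    percents = {k: percent(v, n, 1) if n else 0.0 for k, v in bins.items()}
    return PatternsPerCell(bins, percents, n)


# ---------------------------------------------------------------------------
# Shared identical-junction rearrangements
# ---------------------------------------------------------------------------

@dataclass
class SharedSet:
    """>=2 cells sharing a rearrangement with identical V/D/J and junctions."""

    key: tuple[str, str, str, str, str]
    member_cells: list[tuple[str, str]]    # (donor_id, cell_id)
    cross_donor: bool

    @property
    def n_pairs(self) -> int:
        m = len(self.member_cells)
        return m * (m - 1) // 2


def shared_rearrangements(cells: Sequence[CellRecord]) -> list[SharedSet]:
    """Identical-junction rearrangements present in more than one cell.

    Patterns are keyed by (v_call, d_call, j_call, n1, n2); a set is
    ``cross_donor`` when it spans >=2 donors.  Output is ordered by key,
    so it is invariant to input cell order.
    """
    members: dict[tuple, set[tuple[str, str]]] = {}
    for cell in cells:
        for pattern in cell.patterns:
            members.setdefault(pattern.pattern_key, set()).add(
                (cell.donor_id, cell.cell_id)
            )
    out = []
    for key in sorted(members):
        cell_set = sorted(members[key])
        if len(cell_set) < 2:
            continue
        donors = {d for d, _ in cell_set}
        out.append(SharedSet(key, cell_set, len(donors) >= 2))
    return out


# ---------------------------------------------------------------------------
# CDR3 length distribution
# ---------------------------------------------------------------------------

@dataclass
class Cdr3Fit:
    histogram: dict[int, int]        # aa length -> count
    amplitude: float
    mean: float
    sd: float
    r_squared: float
    n: int


def _gaussian(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma ** 2))


def cdr3_gaussian_fit(cdr3_aa_lengths: Sequence[int]) -> Cdr3Fit:
    """Least-squares Gaussian fit to the CDR3 amino-acid length histogram.

    The fit is on length *frequencies*; R² = 1 - SS_res/SS_tot measures
    how Gaussian the length distribution is (diverse repertoires are close
    to Gaussian, clonally restricted ones are not).  Initialisation is
    deterministic: amplitude = max frequency, mean and sd weighted moments.
    """
    lengths = np.asarray(cdr3_aa_lengths, dtype=int)
    if lengths.size == 0 or np.unique(lengths).size < 3:
        raise ValueError("need >=3 distinct CDR3 lengths to fit")
    x = np.arange(lengths.min(), lengths.max() + 1)
    counts = np.array([(lengths == v).sum() for v in x])
    freq = counts / counts.sum()
    mu0 = float((x * freq).sum())
    sd0 = float(np.sqrt(((x - mu0) ** 2 * freq).sum())) or 1.0
    p0 = (freq.max(), mu0, sd0)
    try:
        popt, _ = optimize.curve_fit(_gaussian, x, freq, p0=p0, maxfev=10000)
    except RuntimeError:
        popt = p0
    resid = freq - _gaussian(x, *popt)
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((freq - freq.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return Cdr3Fit({int(v): int(c) for v, c in zip(x, counts) if c},
                   float(popt[0]), float(popt[1]), float(abs(popt[2])),
                   float(r2), int(lengths.size))


# ---------------------------------------------------------------------------
# Genomic distribution of V usage
# ---------------------------------------------------------------------------

@dataclass
class GenomicDistribution:
    by_rank: dict[int, float]       # genomic rank -> usage mass
    concentration: float            # usage-weighted mean normalised rank


def genomic_distribution(
    usage: UsageTable, reference: ReferenceSet
) -> GenomicDistribution:
    """V usage mass along the locus and its 3'-concentration statistic.

    Ranks are normalised to [0, 1] (0 = most 3', JH-proximal); the
    concentration statistic is the usage-weighted mean normalised rank, so
    a repertoire restricted to the 3' end scores near 0 and a uniform one
    near 0.5.
    """
    if usage.level != "gene" or usage.segment_class != "V":
        raise ValueError("needs a gene-level V usage table")
    n_v = len(reference.v_segments)
    by_rank: dict[int, float] = {}
    stat = 0.0
    for gene, f in usage.frequencies.items():
        rank = reference.genomic_rank(gene)     # raises for unknown genes
        by_rank[rank] = by_rank.get(rank, 0.0) + f
        stat += f * (rank / (n_v - 1) if n_v > 1 else 0.0)
    return GenomicDistribution(dict(sorted(by_rank.items())), float(stat))
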