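"""End-to-end analysis driver: annotations in, summary report out.

Glues the per-module statistics into one machine-readable summary of a
repertoire, mirroring how a single-cell Ig study reports its results:
detection rates, nonfunctional fraction, patterns per cell, hypermutation
distribution / hotspot fraction / CDR-vs-FR paired test, usage tables,
shared identical-junction rearrangements, CDR3 length Gaussian fit and
the genomic 3'-concentration of V usage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from vdjrep.annotator import (
    AnnotatedRearrangement,
    CellRecord,
    group_cells,
)
from vdjrep.germline import ReferenceSet
from vdjrep import repstats, shm


@dataclass
class RepertoireSummary:
    """All repertoire-level results plus the underlying objects."""

    detection: repstats.DetectionRate
    productivity: repstats.ProductivityFraction
    patterns: repstats.PatternsPerCell
    usage: dict[str, repstats.UsageTable]        # e.g. "V_family", "V_gene"
    shared_sets: list[repstats.SharedSet]
    cdr3_fit: repstats.Cdr3Fit | None
    genomic: repstats.GenomicDistribution
    shm_distribution: shm.ShmDistribution
    hotspot: shm.HotspotFractionResult
    region_rates: shm.RegionRatesResult | None
    cells: list[CellRecord]

    def to_dict(self) -> dict:
        shared_cross = [s for s in self.shared_sets if s.cross_donor]
        shared_within = [s for s in self.shared_sets if not s.cross_donor]
        out = {
            "detection": {
                "pooled": {
                    "positive": self.detection.positive,
                    "total": self.detection.total,
                    "percent": self.detection.percent_pooled,
                },
                "per_donor": {
                    d: {"positive": p, "total": t, "percent": pc}
                    for d, (p, t, pc) in self.detection.per_donor.items()
                },
            },
            "productivity": {
                "nonfunctional": self.productivity.nonfunctional,
                "total": self.productivity.total,
                "percent_nonfunctional": self.productivity.percent_nonfunctional,
            },
            "patterns_per_cell": {
                "counts": self.patterns.counts,
                "percents": self.patterns.percents,
                "n_cells": self.patterns.n_cells,
            },
            "usage": {
                key: {
                    "counts": table.counts,
                    "frequencies": {k: round(v, 6)
                                    for k, v in table.frequencies.items()},
                    "total": table.total,
                    "unassigned": table.unassigned,
                }
                for key, table in self.usage.items()
            },
            "shared_rearrangements": {
                "n_sets": len(self.shared_sets),
                "n_cross_donor_sets": len(shared_cross),
                "n_within_donor_sets": len(shared_within),
                "n_cross_donor_pairs": sum(
                    len([1 for a in s.member_cells for b in s.member_cells
                         if a < b and a[0] != b[0]]) for s in self.shared_sets),
                "n_within_donor_pairs": sum(
                    len([1 for a in s.member_cells for b in s.member_cells
                         if a < b and a[0] == b[0]]) for s in self.shared_sets),
                "sets": [
                    {
                        "v_call": s.key[0], "d_call": s.key[1],
                        "j_call": s.key[2], "n1": s.key[3], "n2": s.key[4],
                        "cells": [c for _, c in s.member_cells],
                        "cross_donor": s.cross_donor,
                    }
                    for s in self.shared_sets
                ],
            },
            "genomic_distribution": {
                "concentration": round(self.genomic.concentration, 4),
            },
            "shm": {
                "distribution": {
                    "counts": self.shm_distribution.counts,
                    "fractions": {k: round(v, 4) for k, v in
                                  self.shm_distribution.fractions().items()},
                    "min_percent": round(self.shm_distribution.minimum, 2),
                    "max_percent": round(self.shm_distribution.maximum, 2),
                },
                "hotspot_fraction": (
                    round(self.hotspot.pooled, 4)
                    if self.hotspot.pooled is not None else None
                ),
                "n_mutations": self.hotspot.n_mutations,
            },
        }
        if self.cdr3_fit is not None:
            out["cdr3_length"] = {
                "histogram": self.cdr3_fit.histogram,
                "gaussian": {
                    "amplitude": round(self.cdr3_fit.amplitude, 4),
                    "mean": round(self.cdr3_fit.mean, 3),
                    "sd": round(self.cdr3_fit.sd, 3),
                },
                "r_squared": round(self.cdr3_fit.r_squared, 4),
                "n": self.cdr3_fit.n,
            }
        if self.region_rates is not None:
            t = self.region_rates.paired_t
            out["shm"]["cdr_vs_fr"] = {
                "mean_cdr_rate": round(float(self.region_rates.cdr_rates.mean()), 5),
                "mean_fr_rate": round(float(self.region_rates.fr_rates.mean()), 5),
                "paired_t": round(t.statistic, 3),
                "pvalue": float(t.pvalue),
                "n": t.n,
            }
        return out


def analyze_annotations(
    annotations: Sequence[AnnotatedRearrangement],
    reference: ReferenceSet,
    all_cell_ids: Sequence[tuple[str, str]] | None = None,
) -> RepertoireSummary:
    """Compute the full repertoire summary from annotated sequences.

    ``all_cell_ids`` lists every assayed (donor_id, cell_id) so that cells
    with no annotatable sequence count as negative in the detection rate.
    """
    if not annotations:
        raise ValueError("no annotations to analyze")
    cells = group_cells(annotations, all_cell_ids)
    patterns = [p for cell in cells for p in cell.patterns]

    usage: dict[str, repstats.UsageTable] = {}
    for cls in "VDJ":
        for level in ("family", "gene"):
            try:
                usage[f"{cls}_{level}"] = repstats.usage_frequencies(
                    patterns, level, cls)
            except ValueError:
                pass

    productive = [a for a in annotations if a.productive]
    cdr3_lengths = [len(a.cdr3_aa) for a in productive if a.cdr3_aa]
    cdr3_fit = None
    if len(set(cdr3_lengths)) >= 3:
        cdr3_fit = repstats.cdr3_gaussian_fit(cdr3_lengths)

    region_rates = None
    try:
        region_rates = shm.region_mutation_rates(annotations)
    except ValueError:
        pass

    return RepertoireSummary(
        detection=repstats.detection_rate(cells),
        productivity=repstats.productivity_fraction(list(annotations)),
        patterns=repstats.patterns_per_cell(cells),
        usage=usage,
        shared_sets=repstats.shared_rearrangements(cells),
        cdr3_fit=cdr3_fit,
        genomic=repstats.genomic_distribution(usage["V_gene"], reference),
        shm_distribution=shm.shm_distribution(
            [a.mutation_frequency for a in annotations]),
        hotspot=shm.hotspot_fraction([a.mutations for a in annotations]),
        region_rates=region_rates,
        cells=cells,
    )


def compare_usage(
    summary_a: RepertoireSummary, summary_b: RepertoireSummary
) -> dict:
    """Chi-square comparison of family-level V/D/J usage between repertoires."""
    out = {}
    for cls in "VDJ":
        key = f"{cls}_family"
        if key in summary_a.usage and key in summary_b.usage:
            res = repstats.chi_square_usage(summary_a.usage[key],
                                            summary_b.usage[key])
            out[key] = {
                "statistic": round(res.statistic, 4),
                "df": res.df,
                "pvalue": float(res.pvalue),
            }
    return out


def accuracy_report(
    annotations: Sequence[AnnotatedRearrangement], truth: pd.DataFrame
) -> dict:
    """Segment-call accuracy of annotations against a simulator truth table."""
    t = truth.set_index("sequence_id")
    n = ok_v = ok_d = ok_j = ok_prod = 0
    for a in annotations:
        if a.sequence_id not in t.index:
            continue
        row = t.loc[a.sequence_id]
        n += 1
        ok_v += a.v_call == row["v_name"]
        ok_d += a.d_call == row["d_name"]
        ok_j += a.j_call == row["j_name"]
        ok_prod += a.productive == (row["nonfunctional_kind"] == "none")
    if n == 0:
        raise ValueError("no annotations matched the truth table")
    return {
        "n": n,
        "v_accuracy": round(ok_v / n, 4),
        "d_accuracy": round(ok_d / n, 4),
        "j_accuracy": round(ok_j / n, 4),
        "productivity_agreement": round(ok_prod / n, 4),
    }
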