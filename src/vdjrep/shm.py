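"""Somatic hypermutation (SHM) analysis.

Antigen-driven SHM in immunoglobulin variable regions is concentrated in
the degenerate hotspot 4-mers RGYW and WRCY (R = A/G, Y = C/T, W = A/T)
targeted by AID, and in the CDRs rather than the frameworks.  This module
quantifies those signatures over a set of annotated rearrangements:

* :func:`scan_hotspots` — positionwise hotspot mask of a germline sequence;
* :func:`hotspot_fraction` — fraction of observed mutations inside hotspots;
* :func:`region_mutation_rates` — per-sequence CDR vs FR mutation rates with
  a paired t-test;
* :func:`shm_distribution` — binned per-sequence mutation frequencies.

Hotspot matching is always performed on the germline (pre-mutation)
sequence: a mutation cannot create or destroy its own hotspot context.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _sps

_R = frozenset("AG")
_Y = frozenset("CT")
_W = frozenset("AT")

#: mutation-count convention: a mutation is "in hotspot" when it falls
#: anywhere inside a matching window (default) or only on the AID-targeted
#: G of RGYW / C of WRCY.
CONVENTIONS = ("any_position", "aid_target")


def _window_matches(w: str) -> tuple[bool, bool]:
    rgyw = w[0] in _R and w[1] == "G" and w[2] in _Y and w[3] in _W
    wrcy = w[0] in _W and w[1] in _R and w[2] == "C" and w[3] in _Y
    return rgyw, wrcy


def scan_hotspots(germline_sequence: str, convention: str = "any_position") -> np.ndarray:
    """Boolean mask marking hotspot positions of ``germline_sequence``.

    Under ``any_position`` every position inside at least one window
    matching RGYW or WRCY is marked (overlapping windows union); under
    ``aid_target`` only the G of an RGYW match / the C of a WRCY match.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    seq = germline_sequence.upper()
    if set(seq) - set("ACGT"):
        raise ValueError("sequence must be over {A,C,G,T}")
    mask = np.zeros(len(seq), dtype=bool)
    for i in range(len(seq) - 3):
        rgyw, wrcy = _window_matches(seq[i:i + 4])
        if convention == "any_position":
            if rgyw or wrcy:
                mask[i:i + 4] = True
        else:
            if rgyw:
                mask[i + 1] = True
            if wrcy:
                mask[i + 2] = True
    return mask


@dataclass
class HotspotFractionResult:
    """Pooled and per-sequence hotspot mutation fractions.

    ``pooled`` is ``None`` when no mutations were observed (undefined, not
    zero); entries of ``per_sequence`` are ``None`` for mutation-free
    sequences.
    """

    pooled: float | None
    per_sequence: list[float | None]
    n_mutations: int
    mean_per_sequence: float | None


def hotspot_fraction(mutation_lists: Iterable[Sequence]) -> HotspotFractionResult:
    """Fraction of mutations flagged ``in_hotspot``.

    ``mutation_lists`` holds one list of mutation records per sequence;
    records need only an ``in_hotspot`` attribute.  The pooled fraction
    (all mutations together) is primary; the mean of per-sequence
    fractions is also reported.
    """
    per_seq: list[float | None] = []
    hot = tot = 0
    for muts in mutation_lists:
        if len(muts) == 0:
            per_seq.append(None)
            continue
        h = sum(1 for m in muts if m.in_hotspot)
        per_seq.append(h / len(muts))
        hot += h
        tot += len(muts)
    defined = [f for f in per_seq if f is not None]
    return HotspotFractionResult(
        pooled=hot / tot if tot else None,
        per_sequence=per_seq,
        n_mutations=tot,
        mean_per_sequence=float(np.mean(defined)) if defined else None,
    )


@dataclass
class PairedTResult:
    statistic: float
    pvalue: float
    n: int
    mean_difference: float


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> PairedTResult:
    """Two-sided paired t-test from the closed formula.

    ``t = mean(d) / (sd(d) / sqrt(n))`` on the pairwise differences
    ``d = a - b`` with ``n - 1`` degrees of freedom (sd with ddof=1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-d and equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        t = 0.0 if d.mean() == 0.0 else np.inf * np.sign(d.mean())
    else:
        t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * _sps.t.sf(abs(t), df=n - 1)
    return PairedTResult(float(t), float(p), int(n), float(d.mean()))


@dataclass
class RegionRatesResult:
    """Per-sequence paired CDR and FR mutation rates and their paired t-test."""

    cdr_rates: np.ndarray
    fr_rates: np.ndarray
    paired_t: PairedTResult

_CDR_REGIONS = ("CDR2", "CDR3")
_FR_REGIONS = ("FR2", "FR3", "FR4")


def region_mutation_rates(annotations: Sequence) -> RegionRatesResult:
    """CDR vs FR mutation concentration over annotated rearrangements.

    For each annotation the CDR rate pools CDR2 and the germline-aligned
    CDR3 columns; the FR rate pools FR2, FR3 and FR4 — i.e. the amplified
    FR2→JH window.  Rates are mutations per aligned germline base.
    Annotations must expose ``mutations`` (records with a ``region``) and
    ``region_lengths`` (aligned columns per region label).
    """
    if len(annotations) < 2:
        raise ValueError("need at least 2 annotated sequences")
    cdr_rates, fr_rates = [], []
    for ann in annotations:
        counts = {r: 0 for r in _CDR_REGIONS + _FR_REGIONS}
        for m in ann.mutations:
            if m.region in counts:
                counts[m.region] += 1
        cdr_len = sum(ann.region_lengths.get(r, 0) for r in _CDR_REGIONS)
        fr_len = sum(ann.region_lengths.get(r, 0) for r in _FR_REGIONS)
        if cdr_len == 0 or fr_len == 0:
            continue
        cdr_rates.append(sum(counts[r] for r in _CDR_REGIONS) / cdr_len)
        fr_rates.append(sum(counts[r] for r in _FR_REGIONS) / fr_len)
    if len(cdr_rates) < 2:
        raise ValueError("fewer than 2 sequences with usable region maps")
    cdr = np.asarray(cdr_rates)
    fr = np.asarray(fr_rates)
    return RegionRatesResult(cdr, fr, paired_t_test(cdr, fr))


@dataclass
class ShmDistribution:
    """Binned per-sequence mutation frequencies (percent)."""

    counts: dict[str, int]
    minimum: float
    maximum: float
    n: int

    def fractions(self) -> dict[str, float]:
        return {k: v / self.n for k, v in self.counts.items()}


def shm_distribution(
    per_sequence_freqs: Sequence[float],
    edges: tuple[float, float, float] = (2.0, 5.0, 10.0),
) -> ShmDistribution:
    """Bin per-sequence mutation frequencies (percent).

    Default bins: ``<2``, ``[2,5)``, ``[5,10]`` and ``>10`` — the middle
    bin is closed on both ends, matching the usual "5 to 10%" reading.
    """
    freqs = np.asarray(per_sequence_freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("no frequencies to bin")
    lo, mid, hi = edges
    labels = (f"<{lo:g}", f"[{lo:g},{mid:g})", f"[{mid:g},{hi:g}]", f">{hi:g}")
    counts = {
        labels[0]: int((freqs < lo).sum()),
        labels[1]: int(((freqs >= lo) & (freqs < mid)).sum()),
        labels[2]: int(((freqs >= mid) & (freqs <= hi)).sum()),
        labels[3]: int((freqs > hi).sum()),
    }
    return ShmDistribution(counts, float(freqs.min()), float(freqs.max()), int(freqs.size))
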