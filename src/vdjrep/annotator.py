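"""Germline V(D)J assignment and rearrangement annotation.

Maps each rearranged heavy-chain sequence back onto a germline reference:
best-scoring local alignment picks the V and J genes, the D gene is
searched only inside the V→J window and requires at least five consecutive
exact matches (short inserts stay "unassigned"), junction N strings and
the IMGT-delimited CDR3 are read off the alignment coordinates, somatic
mutations are called per region over the FR2→JH window, and productivity
is classified (in-frame, stop-free joins are productive).

Conventions

* local alignment scoring: match +2, mismatch −1, gap open −4, gap
  extend −1; V/J calls below score 40 are annotation failures (recorded
  per sequence, not fatal);
* ties between equally scoring segments break by lower genomic rank, then
  name — deterministic;
* mutation frequency = mismatched aligned columns / total aligned germline
  columns x 100 over FR2→JH; N-region bases are never counted; a sequence
  is "mutated" at frequency >= 2%;
* the conserved Cys codon is labelled FR3 and the conserved Trp codon
  FR4, so CDR3 is the span strictly between the anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from Bio import Align

from vdjrep.germline import GermlineSegment, ReferenceSet
from vdjrep.shm import scan_hotspots

MATCH_SCORE = 2
MISMATCH_SCORE = -1
GAP_OPEN = -4
GAP_EXTEND = -1
MIN_SEGMENT_SCORE = 40
D_MIN_MATCH = 5

_STOPS = {"TAA", "TAG", "TGA"}
_CODON_TABLE = None


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner

_SHARED_ALIGNER = _aligner()


@dataclass
class GermlineAlignment:
    """A local alignment of a query against one germline segment."""

    segment: GermlineSegment
    score: float
    # matched column blocks: ((g_start, g_end), (q_start, q_end)) pairs
    blocks: tuple[tuple[tuple[int, int], tuple[int, int]], ...]

    @property
    def q_start(self) -> int:
        return self.blocks[0][1][0]

    @property
    def q_end(self) -> int:
        return self.blocks[-1][1][1]

    @property
    def g_start(self) -> int:
        return self.blocks[0][0][0]

    @property
    def g_end(self) -> int:
        return self.blocks[-1][0][1]

    def query_position(self, g_pos: int) -> int | None:
        """Query coordinate aligned to germline ``g_pos`` (None if unaligned)."""
        for (gs, ge), (qs, _) in self.blocks:
            if gs <= g_pos < ge:
                return qs + (g_pos - gs)
        return None

    @property
    def main_diagonal(self) -> int:
        """Query-minus-germline offset of the longest aligned block.

        Short flanking blocks can sit on a spurious diagonal when somatic
        mutations cluster near an alignment end; the longest block is the
        trustworthy one."""
        (gs, _), (qs, _) = max(self.blocks, key=lambda b: b[0][1] - b[0][0])
        return qs - gs

    def query_position_extrapolated(self, g_pos: int) -> int:
        """Query coordinate of ``g_pos``, extended past the aligned ends.

        Anchor codons sit close to the segment ends, where a somatic
        mutation can clip them out of the local alignment; the position is
        then inferred by ungapped extension along the main diagonal."""
        direct = self.query_position(g_pos)
        if direct is not None:
            return direct
        return self.main_diagonal + g_pos

    def columns(self):
        """Yield aligned (germline_pos, query_pos) column pairs."""
        for (gs, ge), (qs, _) in self.blocks:
            for k in range(ge - gs):
                yield gs + k, qs + k


def align_to_germline(query: str, segment: GermlineSegment) -> GermlineAlignment | None:
    """Optimal local alignment of ``query`` against one germline segment.

    Returns ``None`` (no hit) when the best local score is not positive.
    """
    if not query or not segment.sequence:
        raise ValueError("empty sequence in alignment")
    score = _SHARED_ALIGNER.score(segment.sequence, query)
    if score <= 0:
        return None
    aln = _SHARED_ALIGNER.align(segment.sequence, query)[0]
    g_blocks, q_blocks = aln.aligned
    blocks = tuple(
        ((int(gs), int(ge)), (int(qs), int(qe)))
        for (gs, ge), (qs, qe) in zip(g_blocks, q_blocks)
    )
    return GermlineAlignment(segment, float(aln.score), blocks)


@dataclass(frozen=True)
class MutationRecord:
    """One somatic substitution called against the germline."""

    position: int          # 0-based position in the query sequence
    germline_base: str
    observed_base: str
    region: str            # FR2 / CDR2 / FR3 / CDR3 / FR4
    in_hotspot: bool


@dataclass
class AnnotationFailure:
    sequence_id: str
    reason: str


@dataclass
class AnnotatedRearrangement:
    sequence_id: str
    sequence: str
    v_call: str
    d_call: str             # "unassigned" when no >=5 nt exact D match
    j_call: str
    v_score: float
    j_score: float
    n1_seq: str
    n2_seq: str
    cdr3_nt: str
    cdr3_aa: str
    cdr3_start: int             # query coords of cdr3_nt; -1 when absent
    cdr3_end: int
    productive: bool
    nonfunctional_reason: str   # none / stop_codon / out_of_frame / no_j_anchor
    mutations: list[MutationRecord]
    mutation_frequency: float   # percent over aligned FR2->JH columns
    mutated_status: bool
    region_lengths: dict[str, int]
    flags: tuple[str, ...] = ()
    donor_id: str = ""
    cell_id: str = ""

    @property
    def pattern_key(self) -> tuple[str, str, str, str, str]:
        return (self.v_call, self.d_call, self.j_call, self.n1_seq, self.n2_seq)


def _best_alignment(
    query: str,
    segments: Sequence[GermlineSegment],
    offset: int = 0,
) -> GermlineAlignment | None:
    """Best-scoring alignment over segments; ties break by (rank, name).

    Scores all segments first (cheap, no traceback) and computes the full
    alignment only for the winner."""
    scored = []
    for seg in segments:
        score = _SHARED_ALIGNER.score(seg.sequence, query)
        if score > 0:
            scored.append((-score, seg.genomic_order_index, seg.name, seg))
    if not scored:
        return None
    best = align_to_germline(query, min(scored)[3])
    if best is not None and offset:
        best.blocks = tuple(
            ((gs, ge), (qs + offset, qe + offset)) for (gs, ge), (qs, qe) in best.blocks
        )
    return best


def _columns_to_blocks(cols: list[tuple[int, int]]):
    blocks = []
    for g, q in cols:
        if blocks and blocks[-1][0][1] == g and blocks[-1][1][1] == q:
            blocks[-1] = ((blocks[-1][0][0], g + 1), (blocks[-1][1][0], q + 1))
        else:
            blocks.append(((g, g + 1), (q, q + 1)))
    return tuple(blocks)


def _rescore(blocks, germ: str, query: str) -> float:
    """Score of a block alignment under the fixed scoring scheme."""
    score = 0.0
    prev = None
    for (gs, ge), (qs, qe) in blocks:
        if prev is not None:
            gap = max(gs - prev[0], qs - prev[1])
            if gap > 0:
                score += GAP_OPEN + GAP_EXTEND * (gap - 1)
        for k in range(ge - gs):
            score += MATCH_SCORE if germ[gs + k] == query[qs + k] else MISMATCH_SCORE
        prev = (ge, qe)
    return score


def _trim_edge(aln: GermlineAlignment, query: str, end: str, run: int = 5) -> GermlineAlignment:
    """Require the alignment to terminate in ``run`` consecutive matches.

    Local alignment happily extends a segment match across the junction
    into the N region as long as matches outnumber mismatches; trimming
    the alignment back to the last clean run of matches keeps junction
    mismatches from being miscalled as somatic mutations."""
    germ = aln.segment.sequence
    cols = list(aln.columns())
    mism = {i for i, (g, q) in enumerate(cols) if germ[g] != query[q]}
    if end == "3'":
        stop = len(cols)
        while stop > 0:
            bad = [i for i in range(max(0, stop - run), stop) if i in mism]
            if not bad:
                break
            stop = bad[0]
        cols = cols[:stop]
    else:
        start = 0
        while start < len(cols):
            bad = [i for i in range(start, min(len(cols), start + run)) if i in mism]
            if not bad:
                break
            start = bad[-1] + 1
        cols = cols[start:]
    if not cols:
        return aln
    blocks = _columns_to_blocks(cols)
    return GermlineAlignment(aln.segment, _rescore(blocks, germ, query), blocks)


def _longest_exact_match(window: str, d_seq: str) -> tuple[int, int, int]:
    """Longest common substring (length, window_start, d_start); leftmost
    in the window, then leftmost in D, on ties."""
    best = (0, 0, 0)
    n, m = len(window), len(d_seq)
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        wi = window[i - 1]
        for j in range(1, m + 1):
            if wi == d_seq[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best[0]:
                    best = (cur[j], i - cur[j], j - cur[j])
        prev = cur
    return best


@dataclass
class SegmentAssignment:
    v: GermlineAlignment
    j: GermlineAlignment
    d: GermlineAlignment | None   # exact-match pseudo-alignment
    flags: tuple[str, ...] = ()


def assign_segments(
    query: str,
    reference: ReferenceSet,
    min_score: float = MIN_SEGMENT_SCORE,
    d_min_match: int = D_MIN_MATCH,
) -> SegmentAssignment | str:
    """Assign V, J and (optionally) D to a query sequence.

    Returns a :class:`SegmentAssignment`, or a failure-reason string when
    no V or J reaches ``min_score``.  The J search is constrained
    downstream of the V match end; the D search runs only inside the
    V→J window and needs ``d_min_match`` consecutive exact matches.
    """
    v = _best_alignment(query, reference.v_segments)
    if v is None or v.score < min_score:
        return "no V gene above minimum score"
    v = _trim_edge(v, query, "3'")
    tail = query[v.q_end:]
    j = _best_alignment(tail, reference.j_segments, offset=v.q_end) if tail else None
    if j is None or j.score < min_score:
        return "no J gene above minimum score"
    j = _trim_edge(j, query, "5'")

    flags: list[str] = []
    d_aln = None
    window = query[v.q_end: j.q_start]
    if window:
        best = None
        for seg in reference.d_segments:
            length, w_start, d_start = _longest_exact_match(window, seg.sequence)
            if length < d_min_match:
                continue
            key = (-length, seg.genomic_order_index, seg.name)
            if best is None or key < best[0]:
                best = (key, seg, length, w_start, d_start)
        if best is not None:
            _, seg, length, w_start, d_start = best
            q0 = v.q_end + w_start
            # extend the exact-match core along its diagonal across the
            # whole V->J window, then trim back to clean 5-match edges, so
            # somatic mutations inside the retained D are still called
            diag = q0 - d_start
            g_lo = max(0, v.q_end - diag)
            g_hi = min(len(seg.sequence), j.q_start - diag)
            d_aln = GermlineAlignment(
                seg, float(MATCH_SCORE * length),
                (((g_lo, g_hi), (g_lo + diag, g_hi + diag)),),
            )
            d_aln = _trim_edge(d_aln, query, "5'")
            d_aln = _trim_edge(d_aln, query, "3'")
            d_aln.score = _rescore(d_aln.blocks, seg.sequence, query)
    return SegmentAssignment(v, j, d_aln, tuple(flags))


def delineate_junctions(
    query: str, assignment: SegmentAssignment
) -> tuple[str, str, tuple[str, ...]]:
    """Junction insert strings (n1, n2) between the matched segments.

    When D is unassigned the entire V→J insert is reported as n1 with n2
    empty (flag ``d_unassigned``); overlapping segment matches yield two
    empty strings and an ``overlap`` flag.
    """
    v_end, j_start = assignment.v.q_end, assignment.j.q_start
    if j_start < v_end:
        return "", "", ("overlap",)
    if assignment.d is None:
        return query[v_end:j_start], "", ("d_unassigned",)
    d_start, d_end = assignment.d.q_start, assignment.d.q_end
    return query[v_end:d_start], query[d_end:j_start], ()


def _frame_shift(assignment: SegmentAssignment) -> int:
    """Query-minus-germline offset of the V alignment's main diagonal.

    The germline V reading frame starts at germline position 0, so a query
    position q is a codon start iff ``(q - shift) % 3 == 0``."""
    return assignment.v.main_diagonal


def classify_productivity(
    query: str, assignment: SegmentAssignment
) -> tuple[bool, str]:
    """Productivity of an assigned rearrangement.

    ``out_of_frame`` when the conserved J Trp codon is out of the V frame,
    ``stop_codon`` when any in-frame stop occurs between the V match start
    and the J end, ``no_j_anchor`` when the Trp codon is not covered by
    the J alignment.
    """
    j_seg = assignment.j.segment
    q_trp = assignment.j.query_position_extrapolated(j_seg.anchor)
    if not 0 <= q_trp <= len(query) - 3:
        return False, "no_j_anchor"
    shift = _frame_shift(assignment)
    if (q_trp - shift) % 3 != 0:
        return False, "out_of_frame"
    start = assignment.v.q_start
    first_codon = start + (-(start - shift)) % 3
    for c in range(first_codon, min(assignment.j.q_end, len(query)) - 2, 3):
        if query[c:c + 3] in _STOPS:
            return False, "stop_codon"
    return True, "none"


def _region_of_v(g_pos: int, v: GermlineSegment) -> str:
    for name in ("FR2", "CDR2", "FR3"):
        s, e = v.regions[name]
        if s <= g_pos < e:
            return name
    if v.regions["FR3"][1] <= g_pos < v.anchor + 3:
        return "FR3"      # conserved Cys codon counts as FR3
    return "CDR3"


def call_mutations(
    query: str, assignment: SegmentAssignment
) -> tuple[list[MutationRecord], float, bool, dict[str, int]]:
    """Somatic substitutions over the FR2→JH window.

    Mismatches are counted only in germline-aligned columns (N regions
    excluded); frequency is mismatches / aligned columns x 100, and a
    sequence is flagged mutated at >= 2%.  Hotspot context is read from
    the inferred germline sequence (query with called mutations reverted).
    """
    v_seg = assignment.v.segment
    j_seg = assignment.j.segment
    fr2_start = v_seg.regions["FR2"][0]

    germ_ctx = list(query)   # inferred germline context for hotspot scanning
    columns: list[tuple[int, str, str]] = []   # (q_pos, germline_base, region)
    region_lengths = {r: 0 for r in ("FR2", "CDR2", "FR3", "CDR3", "FR4")}

    for g, q in assignment.v.columns():
        if g < fr2_start:
            continue
        columns.append((q, v_seg.sequence[g], _region_of_v(g, v_seg)))
    if assignment.d is not None:
        for g, q in assignment.d.columns():
            columns.append((q, assignment.d.segment.sequence[g], "CDR3"))
    for g, q in assignment.j.columns():
        region = "CDR3" if g < j_seg.anchor else "FR4"
        columns.append((q, j_seg.sequence[g], region))

    raw: list[tuple[int, str, str, str]] = []
    for q, g_base, region in columns:
        region_lengths[region] += 1
        germ_ctx[q] = g_base
        if query[q] != g_base:
            raw.append((q, g_base, query[q], region))

    hot_mask = scan_hotspots("".join(germ_ctx))
    mutations = [
        MutationRecord(q, g_base, obs, region, bool(hot_mask[q]))
        for q, g_base, obs, region in raw
    ]
    n_cols = len(columns)
    freq = 100.0 * len(mutations) / n_cols if n_cols else 0.0
    return mutations, freq, freq >= 2.0, region_lengths


def _translate(nt: str) -> str:
    from Bio.Seq import Seq
    return str(Seq(nt).translate())


def annotate_sequence(
    sequence_id: str,
    query: str,
    reference: ReferenceSet,
    min_score: float = MIN_SEGMENT_SCORE,
    d_min_match: int = D_MIN_MATCH,
    donor_id: str = "",
    cell_id: str = "",
) -> AnnotatedRearrangement | AnnotationFailure:
    """Full annotation of one rearranged sequence (failures are returned,
    not raised)."""
    query = query.upper()
    assignment = assign_segments(query, reference, min_score, d_min_match)
    if isinstance(assignment, str):
        return AnnotationFailure(sequence_id, assignment)
    n1, n2, flags = delineate_junctions(query, assignment)
    productive, reason = classify_productivity(query, assignment)
    mutations, freq, mutated, region_lengths = call_mutations(query, assignment)

    cdr3_nt = cdr3_aa = ""
    cdr3_start = cdr3_end = -1
    v_seg = assignment.v.segment
    q_cys = assignment.v.query_position_extrapolated(v_seg.anchor)
    q_trp = assignment.j.query_position_extrapolated(assignment.j.segment.anchor)
    if 0 <= q_cys and q_cys + 3 <= q_trp <= len(query):
        cdr3_start, cdr3_end = q_cys + 3, q_trp
        cdr3_nt = query[cdr3_start:cdr3_end]
        if cdr3_nt and len(cdr3_nt) % 3 == 0:
            cdr3_aa = _translate(cdr3_nt)

    return AnnotatedRearrangement(
        sequence_id=sequence_id,
        sequence=query,
        v_call=v_seg.name,
        d_call=assignment.d.segment.name if assignment.d else "unassigned",
        j_call=assignment.j.segment.name,
        v_score=assignment.v.score,
        j_score=assignment.j.score,
        n1_seq=n1,
        n2_seq=n2,
        cdr3_nt=cdr3_nt,
        cdr3_aa=cdr3_aa,
        cdr3_start=cdr3_start,
        cdr3_end=cdr3_end,
        productive=productive,
        nonfunctional_reason=reason,
        mutations=mutations,
        mutation_frequency=freq,
        mutated_status=mutated,
        region_lengths=region_lengths,
        flags=flags + assignment.flags,
        donor_id=donor_id,
        cell_id=cell_id,
    )


def parse_cell_id(sequence_id: str) -> tuple[str, str]:
    """Donor and cell ids from a ``<donor>-<cell>.<colony>`` sequence id."""
    cell = sequence_id.split(".")[0]
    donor = cell.split("-")[0]
    return donor, cell


def annotate_many(
    records: Iterable,
    reference: ReferenceSet,
    min_score: float = MIN_SEGMENT_SCORE,
    d_min_match: int = D_MIN_MATCH,
    id_parser: Callable[[str], tuple[str, str]] = parse_cell_id,
) -> tuple[list[AnnotatedRearrangement], list[AnnotationFailure]]:
    """Annotate an iterable of ``(id, sequence)`` pairs or SeqRecords."""
    annotations, failures = [], []
    for rec in records:
        if hasattr(rec, "seq"):
            seq_id, seq = rec.id, str(rec.seq)
        else:
            seq_id, seq = rec
        try:
            donor, cell = id_parser(seq_id)
        except Exception:
            donor = cell = ""
        result = annotate_sequence(
            seq_id, seq, reference, min_score, d_min_match,
            donor_id=donor, cell_id=cell,
        )
        if isinstance(result, AnnotationFailure):
            failures.append(result)
        else:
            annotations.append(result)
    return annotations, failures


@dataclass
class CellRecord:
    """All colony annotations of one cell plus its distinct patterns."""

    donor_id: str
    cell_id: str
    annotations: list[AnnotatedRearrangement]
    patterns: list[AnnotatedRearrangement] = field(default_factory=list)

    @property
    def n_patterns(self) -> int:
        return len(self.patterns)

    @property
    def positive(self) -> bool:
        return bool(self.patterns)


def dedupe_cell_patterns(
    annotations: Sequence[AnnotatedRearrangement],
) -> list[AnnotatedRearrangement]:
    """Distinct rearrangement patterns among one cell's colony sequences.

    Patterns are keyed by (v_call, d_call, j_call, n1, n2); colonies that
    differ only by SHM collapse to one pattern.  Output order is by key,
    so it is invariant to colony order.
    """
    by_key: dict[tuple, AnnotatedRearrangement] = {}
    for ann in annotations:
        key = ann.pattern_key
        if key not in by_key or ann.sequence_id < by_key[key].sequence_id:
            by_key[key] = ann
    return [by_key[k] for k in sorted(by_key)]


def group_cells(
    annotations: Sequence[AnnotatedRearrangement],
    all_cell_ids: Sequence[tuple[str, str]] | None = None,
) -> list[CellRecord]:
    """Group annotations into per-cell records with deduplicated patterns.

    ``all_cell_ids`` may list (donor_id, cell_id) pairs for every assayed
    cell, so cells with no annotated sequence appear as negative cells.
    """
    cells: dict[str, CellRecord] = {}
    if all_cell_ids:
        for donor, cell in all_cell_ids:
            cells[cell] = CellRecord(donor, cell, [])
    for ann in annotations:
        rec = cells.setdefault(ann.cell_id,
                               CellRecord(ann.donor_id, ann.cell_id, []))
        rec.annotations.append(ann)
    for rec in cells.values():
        rec.annotations.sort(key=lambda a: a.sequence_id)
        rec.patterns = dedupe_cell_patterns(rec.annotations)
    return [cells[k] for k in sorted(cells)]
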