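"""Germline IGHV/IGHD/IGHJ segment reference.

Every simulation and annotation step in this package runs against a
:class:`ReferenceSet` of germline gene segments.  A segment carries its
nucleotide sequence, its family (``VH1`` .. ``VH7``, ``DH1`` .. ``DH7``,
``JH1`` .. ``JH6``), its genomic order along the IGH locus (rank 0 = most
3', i.e. JH-proximal) and, for V and J segments, the region delimitation
needed to place framework (FR) and complementarity-determining (CDR)
regions and the CDR3 anchors: the conserved FR3 cysteine codon on V and
the conserved tryptophan codon on J.  CDR3 is delimited IMGT-style, from
the codon after the conserved Cys to the codon before the conserved Trp,
anchors excluded.

Coordinates are 0-based half-open throughout.

The packaged reference (``data/synthetic_germline.*``) is a deterministic
*synthetic* stand-in for a curated germline database: IMGT-style names
(one allele per gene, covering families VH1-7, DH1-7, JH1-6) with
computer-generated sequences produced by :func:`synthesize_reference`.
It is not a copy of any real germline database.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import pandas as pd

NUCLEOTIDES = "ACGT"
V_REGION_NAMES = ("FR1", "CDR1", "FR2", "CDR2", "FR3")

_META_COLUMNS = [
    "name",
    "segment_class",
    "genomic_order_index",
    "fr1_start",
    "cdr1_start",
    "fr2_start",
    "cdr2_start",
    "fr3_start",
    "fr3_end",
    "anchor",
]

_NAME_RE = re.compile(r"^IGH([VDJ])(\d+)(-[\w.-]+)?$")


class GermlineReferenceError(ValueError):
    """Raised when a reference file or segment fails validation."""


def family_of(gene_name: str) -> str:
    """Family label of an IMGT-style heavy-chain gene name.

    ``"IGHV1-24" -> "VH1"``, ``"IGHD2-15" -> "DH2"``, ``"IGHJ4" -> "JH4"``.
    The family digit is the integer immediately after the class letter.
    """
    m = _NAME_RE.match(gene_name)
    if m is None:
        raise GermlineReferenceError(f"unparseable gene name: {gene_name!r}")
    return f"{m.group(1)}H{int(m.group(2))}"


@dataclass(frozen=True)
class GermlineSegment:
    """One germline V, D or J gene segment.

    ``regions`` holds half-open FR/CDR intervals (V only); ``anchor`` is
    the start of the conserved Cys codon (V) or Trp codon (J), ``None``
    for D segments.
    """

    name: str
    segment_class: str
    sequence: str
    genomic_order_index: int
    regions: Mapping[str, tuple[int, int]] | None = None
    anchor: int | None = None
    family: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", family_of(self.name))
        if self.segment_class not in "VDJ" or len(self.segment_class) != 1:
            raise GermlineReferenceError(
                f"{self.name}: segment_class must be V, D or J"
            )
        if not self.sequence:
            raise GermlineReferenceError(f"{self.name}: empty sequence")
        for i, base in enumerate(self.sequence):
            if base not in NUCLEOTIDES:
                raise GermlineReferenceError(
                    f"{self.name}: invalid base {base!r} at position {i}"
                )
        if self.segment_class == "V":
            self._check_v_regions()
        if self.segment_class == "J":
            if self.anchor is None:
                raise GermlineReferenceError(f"{self.name}: J needs a Trp anchor")
            if not 0 <= self.anchor <= len(self.sequence) - 3:
                raise GermlineReferenceError(f"{self.name}: anchor out of range")

    def _check_v_regions(self) -> None:
        if self.regions is None or self.anchor is None:
            raise GermlineReferenceError(
                f"{self.name}: V segment needs region boundaries and Cys anchor"
            )
        missing = [r for r in V_REGION_NAMES if r not in self.regions]
        if missing:
            raise GermlineReferenceError(f"{self.name}: missing regions {missing}")
        prev_end = None
        for rname in V_REGION_NAMES:
            start, end = self.regions[rname]
            if not 0 <= start < end <= len(self.sequence):
                raise GermlineReferenceError(
                    f"{self.name}: region {rname} {start, end} outside sequence"
                )
            if prev_end is not None and start != prev_end:
                raise GermlineReferenceError(
                    f"{self.name}: regions not contiguous at {rname}"
                )
            prev_end = end
        if not self.regions["FR3"][1] <= self.anchor <= len(self.sequence) - 3:
            raise GermlineReferenceError(f"{self.name}: Cys anchor out of range")


@dataclass
class ReferenceSet:
    """A validated germline segment collection queried by the pipeline."""

    v_segments: list[GermlineSegment]
    d_segments: list[GermlineSegment]
    j_segments: list[GermlineSegment]
    provenance: str = ""

    def __post_init__(self) -> None:
        self._by_name: dict[str, GermlineSegment] = {}
        for seg in self:
            if seg.name in self._by_name:
                raise GermlineReferenceError(f"duplicate segment name {seg.name}")
            self._by_name[seg.name] = seg
        for cls, segs in (
            ("V", self.v_segments),
            ("D", self.d_segments),
            ("J", self.j_segments),
        ):
            if not segs:
                raise GermlineReferenceError(f"no segments of class {cls}")
            ranks = sorted(s.genomic_order_index for s in segs)
            if ranks != list(range(len(segs))):
                raise GermlineReferenceError(
                    f"class {cls}: genomic_order_index not a permutation of "
                    f"0..{len(segs) - 1}"
                )

    def __iter__(self):
        yield from self.v_segments
        yield from self.d_segments
        yield from self.j_segments

    def __len__(self) -> int:
        return len(self._by_name)

    def get(self, name: str) -> GermlineSegment:
        try:
            return self._by_name[name]
        except KeyError:
            raise GermlineReferenceError(f"unknown gene {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def segments(self, segment_class: str) -> list[GermlineSegment]:
        return {
            "V": self.v_segments,
            "D": self.d_segments,
            "J": self.j_segments,
        }[segment_class]

    def genomic_rank(self, gene_name: str) -> int:
        """Rank of ``gene_name`` along the locus; 0 = most 3' in its class."""
        return self.get(gene_name).genomic_order_index

    def families(self, segment_class: str) -> set[str]:
        return {s.family for s in self.segments(segment_class)}


def load_reference(
    fasta_path: str | Path,
    metadata_path: str | Path,
    provenance: str | None = None,
) -> ReferenceSet:
    """Load a germline reference from FASTA + tab-separated metadata.

    Metadata rows are keyed by FASTA record id and supply the class, the
    genomic order index and the region boundary columns (empty for D).
    A FASTA record without a metadata row, or vice versa, is an error
    naming the record.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise GermlineReferenceError(f"no segments in {fasta_path}")
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"name": str})
    missing_cols = set(_META_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise GermlineReferenceError(f"metadata missing columns {sorted(missing_cols)}")
    meta = meta.set_index("name")
    if meta.index.has_duplicates:
        dups = meta.index[meta.index.duplicated()].tolist()
        raise GermlineReferenceError(f"duplicate metadata rows for {dups}")

    fasta_names = [r.id for r in records]
    for name in fasta_names:
        if name not in meta.index:
            raise GermlineReferenceError(f"no metadata for FASTA record {name!r}")
    for name in meta.index:
        if name not in set(fasta_names):
            raise GermlineReferenceError(f"metadata row {name!r} has no FASTA record")

    groups: dict[str, list[GermlineSegment]] = {"V": [], "D": [], "J": []}
    for rec in records:
        row = meta.loc[rec.id]
        cls = str(row["segment_class"])
        regions = None
        anchor = None
        if cls == "V":
            starts = [int(row[c]) for c in (
                "fr1_start", "cdr1_start", "fr2_start", "cdr2_start", "fr3_start"
            )]
            ends = starts[1:] + [int(row["fr3_end"])]
            regions = dict(zip(V_REGION_NAMES, zip(starts, ends)))
            anchor = int(row["anchor"])
        elif cls == "J":
            anchor = int(row["anchor"])
        seg = GermlineSegment(
            name=rec.id,
            segment_class=cls,
            sequence=str(rec.seq).upper(),
            genomic_order_index=int(row["genomic_order_index"]),
            regions=regions,
            anchor=anchor,
        )
        groups[cls].append(seg)
    if provenance is None:
        provenance = f"loaded from {fasta_path}"
    return ReferenceSet(groups["V"], groups["D"], groups["J"], provenance)


def write_reference(
    reference: ReferenceSet, fasta_path: str | Path, metadata_path: str | Path
) -> None:
    """Serialize a reference back to FASTA + metadata TSV (round-trips)."""
    records = [
        SeqRecord(Seq(seg.sequence), id=seg.name, description="")
        for seg in reference
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = []
    for seg in reference:
        row: dict[str, object] = {
            "name": seg.name,
            "segment_class": seg.segment_class,
            "genomic_order_index": seg.genomic_order_index,
        }
        if seg.regions is not None:
            for rname in V_REGION_NAMES:
                key = f"{rname.lower()}_start"
                row[key] = seg.regions[rname][0]
            row["fr3_end"] = seg.regions["FR3"][1]
        row["anchor"] = seg.anchor if seg.anchor is not None else ""
        rows.append(row)
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(
        metadata_path, sep="\t", index=False
    )


def load_builtin_reference() -> ReferenceSet:
    """Load the packaged synthetic germline reference."""
    data = resources.files("vdjrep") / "data"
    with resources.as_file(data / "synthetic_germline.fasta") as fa, \
            resources.as_file(data / "synthetic_germline_meta.tsv") as tsv:
        return load_reference(
            fa, tsv, provenance="packaged synthetic germline set (one allele per gene)"
        )


# ---------------------------------------------------------------------------
# Synthetic reference construction
# ---------------------------------------------------------------------------

# Gene inventory: name -> locus position number used for genomic ordering
# (smaller = more 3', mirroring the human IGH locus layout where IGHV6-1 is
# the most JH-proximal V gene).  One allele per gene.
_V_GENES: dict[str, float] = {
    "IGHV6-1": 1, "IGHV1-2": 2, "IGHV1-3": 3, "IGHV7-4-1": 4.1, "IGHV2-5": 5,
    "IGHV3-7": 7, "IGHV1-8": 8, "IGHV3-11": 11, "IGHV3-15": 15, "IGHV1-18": 18,
    "IGHV1-24": 24, "IGHV2-26": 26, "IGHV4-31": 31, "IGHV4-34": 34,
    "IGHV3-23": 23, "IGHV3-30": 30, "IGHV3-33": 33, "IGHV4-39": 39,
    "IGHV1-45": 45, "IGHV1-46": 46, "IGHV3-48": 48, "IGHV5-51": 51,
    "IGHV3-53": 53, "IGHV1-58": 58, "IGHV4-59": 59, "IGHV4-61": 61,
    "IGHV3-64": 64, "IGHV3-66": 66, "IGHV1-69": 69, "IGHV2-70": 70,
    "IGHV3-72": 72, "IGHV3-73": 73, "IGHV3-74": 74,
}
_D_GENES: dict[str, float] = {
    "IGHD1-1": 1, "IGHD2-2": 2, "IGHD3-3": 3, "IGHD3-9": 9, "IGHD3-10": 10,
    "IGHD5-12": 12, "IGHD6-13": 13, "IGHD2-15": 15, "IGHD4-17": 17,
    "IGHD5-18": 18, "IGHD6-19": 19, "IGHD2-21": 21, "IGHD3-22": 22,
    "IGHD1-26": 26, "IGHD7-27": 27,
}
_J_GENES: dict[str, float] = {f"IGHJ{i}": i for i in range(1, 7)}

# V region codon layout: FR1 25, CDR1 8, FR2 17, CDR2 8, FR3 38 codons,
# then the conserved Cys codon and two germline CDR3 codons.
_V_CODON_LAYOUT = (25, 8, 17, 8, 38)
_STOP_CODONS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES
    if a + b + c not in _STOP_CODONS
]


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def synthesize_reference(seed: int = 20201112) -> ReferenceSet:
    """Build the deterministic synthetic germline set packaged with vdjrep.

    V segments are 297 nt of stop-free codons with IMGT-style region
    boundaries and a conserved Cys (TGT) anchor after FR3; J segments are a
    short CDR3 tail, the conserved Trp (TGG) codon and a 10-codon stop-free
    FR4; D segments are 20-28 nt.  D segments are constructed so that no
    5-mer is shared between two D genes, which keeps the annotator's
    ">=5 consecutive matches" D assignment unambiguous on clean sequences.
    """
    rng = np.random.default_rng(seed)

    def codons(n: int) -> str:
        return "".join(rng.choice(_SENSE_CODONS, size=n))

    def rank_map(genes: dict[str, float]) -> dict[str, int]:
        ordered = sorted(genes, key=genes.__getitem__)
        return {name: i for i, name in enumerate(ordered)}

    v_rank = rank_map(_V_GENES)
    d_rank = rank_map(_D_GENES)
    j_rank = rank_map(_J_GENES)

    starts = np.cumsum((0,) + _V_CODON_LAYOUT) * 3
    regions = dict(zip(V_REGION_NAMES, zip(starts[:-1], starts[1:])))
    anchor = int(starts[-1])
    v_segments = []
    for name in sorted(_V_GENES):
        seq = codons(sum(_V_CODON_LAYOUT)) + "TGT" + codons(2)
        v_segments.append(
            GermlineSegment(name, "V", seq, v_rank[name], regions, anchor)
        )

    d_segments: list[GermlineSegment] = []
    used_5mers: set[str] = set()
    for name in sorted(_D_GENES):
        while True:
            length = int(rng.integers(20, 29))
            seq = "".join(rng.choice(list(NUCLEOTIDES), size=length))
            mers = _kmers(seq, 5)
            if not mers & used_5mers:
                used_5mers |= mers
                break
        d_segments.append(GermlineSegment(name, "D", seq, d_rank[name]))

    j_segments = []
    for name in sorted(_J_GENES):
        tail_len = int(rng.integers(4, 9))
        tail = "".join(rng.choice(list(NUCLEOTIDES), size=tail_len))
        seq = tail + "TGG" + codons(10)
        j_segments.append(
            GermlineSegment(name, "J", seq, j_rank[name], anchor=tail_len)
        )

    return ReferenceSet(
        v_segments,
        d_segments,
        j_segments,
        provenance=f"synthetic germline set (seed {seed}); not a real database",
    )
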