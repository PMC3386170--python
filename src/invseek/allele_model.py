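"""Exact algebra of rearranged haplotypes.

A haplotype (allele) of a rearranged chromosome is modelled as an ordered
list of oriented reference segments.  The allele sequence is the
concatenation of the corresponding reference substrings, reverse-complemented
where a segment is in reverse orientation.  All coordinates are 0-based,
half-open; converters to the 1-based inclusive convention used in genome
browsers live in :func:`to_printed` / :func:`from_printed`.

The module provides the primitive operations the rest of the package is
built on: allele construction, coordinate liftover in both directions,
extraction of novel junctions, junction microhomology scoring, and the
derivation of new alleles by unequal crossing over.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "CoordinateError",
    "ReferenceGenome",
    "Segment",
    "MappedSegment",
    "RearrangementAllele",
    "JunctionSide",
    "Junction",
    "MicrohomologyReport",
    "build_allele",
    "extract_junctions",
    "microhomology",
    "junction_microhomology",
    "unequal_crossover",
    "revcomp",
    "to_printed",
    "from_printed",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
DNA_ALPHABET = frozenset("ACGTN")


class CoordinateError(ValueError):
    """A position or interval falls outside the object it addresses."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_printed(pos: int) -> int:
    """0-based boundary/position -> 1-based printed coordinate."""
    return pos


def from_printed(pos: int) -> int:
    """1-based printed coordinate -> 0-based half-open boundary.

    A printed breakpoint "after base p" corresponds to the 0-based boundary
    p; a printed inclusive interval (a, b) corresponds to [a-1, b).
    """
    return pos


@dataclass(frozen=True)
class ReferenceGenome:
    """A single reference sequence (one chromosome or a toy stand-in)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("reference sequence must be non-empty")
        bad = set(self.sequence.upper()) - DNA_ALPHABET
        if bad:
            raise ValueError(f"non-DNA characters in reference: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        from Bio import SeqIO

        record = next(SeqIO.parse(str(path), "fasta"))
        return cls(name=record.id, sequence=str(record.seq).upper())

    def to_fasta(self, path: str | Path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        seqio_write(
            [SeqRecord(Seq(self.sequence), id=self.name, description="")],
            str(path),
            "fasta",
        )


@dataclass(frozen=True)
class Segment:
    """An oriented reference interval, 0-based half-open."""

    start: int
    end: int
    orientation: str = "+"

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise ValueError(f"orientation must be '+' or '-', got {self.orientation!r}")
        if not (0 <= self.start < self.end):
            raise CoordinateError(f"invalid segment [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MappedSegment:
    """A segment placed on an allele: records its allele interval."""

    allele_start: int
    allele_end: int
    segment: Segment

    def to_reference(self, pos: int) -> int:
        seg = self.segment
        offset = pos - self.allele_start
        if seg.orientation == "+":
            return seg.start + offset
        return seg.end - 1 - offset

    def from_reference(self, ref_pos: int) -> int:
        seg = self.segment
        if seg.orientation == "+":
            return self.allele_start + (ref_pos - seg.start)
        return self.allele_start + (seg.end - 1 - ref_pos)


@dataclass(frozen=True)
class RearrangementAllele:
    """An ordered, oriented set of reference segments defining a haplotype."""

    name: str
    segments: tuple[Segment, ...]
    provenance: str | None = None

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("allele needs at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))

    def __len__(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def segment_map(self) -> tuple[MappedSegment, ...]:
        placed = []
        offset = 0
        for seg in self.segments:
            placed.append(MappedSegment(offset, offset + seg.length, seg))
            offset += seg.length
        return tuple(placed)

    def validate_against(self, ref_length: int) -> None:
        for seg in self.segments:
            if seg.end > ref_length:
                raise CoordinateError(
                    f"segment [{seg.start}, {seg.end}) exceeds reference length {ref_length}"
                )

    def owning_segment(self, pos: int) -> MappedSegment:
        if not 0 <= pos < len(self):
            raise CoordinateError(f"position {pos} outside allele of length {len(self)}")
        for placed in self.segment_map:
            if placed.allele_start <= pos < placed.allele_end:
                return placed
        raise AssertionError("unreachable: segment map does not tile the allele")

    def to_reference(self, pos: int) -> tuple[int, str]:
        """Lift an allele position to (reference position, orientation)."""
        placed = self.owning_segment(pos)
        return placed.to_reference(pos), placed.segment.orientation

    def from_reference(self, ref_pos: int) -> list[tuple[int, str]]:
        """All allele positions covering a reference position (may be 0..n)."""
        hits = []
        for placed in self.segment_map:
            seg = placed.segment
            if seg.start <= ref_pos < seg.end:
                hits.append((placed.from_reference(ref_pos), seg.orientation))
        return hits

    def sequence(self, ref: ReferenceGenome) -> str:
        self.validate_against(len(ref))
        parts = []
        for seg in self.segments:
            sub = ref.sequence[seg.start : seg.end]
            parts.append(sub if seg.orientation == "+" else revcomp(sub))
        return "".join(parts)

    def normalized(self) -> "RearrangementAllele":
        """Merge adjacent segments that are reference-contiguous and co-oriented."""
        merged: list[Segment] = [self.segments[0]]
        for seg in self.segments[1:]:
            prev = merged[-1]
            if (
                prev.orientation == seg.orientation == "+"
                and prev.end == seg.start
            ):
                merged[-1] = Segment(prev.start, seg.end, "+")
            elif (
                prev.orientation == seg.orientation == "-"
                and seg.end == prev.start
            ):
                merged[-1] = Segment(seg.start, prev.end, "-")
            else:
                merged.append(seg)
        return RearrangementAllele(self.name, tuple(merged), self.provenance)

    # ------------------------------------------------------------------ IO

    def to_bed(self, path: str | Path, chrom: str) -> None:
        """Export the segment map as BED6 (score = allele offset)."""
        with open(path, "w") as fh:
            for placed in self.segment_map:
                seg = placed.segment
                fh.write(
                    f"{chrom}\t{seg.start}\t{seg.end}\t{self.name}"
                    f"\t{placed.allele_start}\t{seg.orientation}\n"
                )

    def to_spec(self) -> dict:
        return {
            "name": self.name,
            "provenance": self.provenance,
            "segments": [
                {"start": s.start, "end": s.end, "orientation": s.orientation}
                for s in self.segments
            ],
        }

    @classmethod
    def from_spec(cls, spec: dict) -> "RearrangementAllele":
        return cls(
            name=spec["name"],
            segments=tuple(
                Segment(s["start"], s["end"], s.get("orientation", "+"))
                for s in spec["segments"]
            ),
            provenance=spec.get("provenance"),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_spec(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RearrangementAllele":
        with open(path) as fh:
            return cls.from_spec(yaml.safe_load(fh))


def build_allele(
    ref_length: int,
    segments: "list[Segment] | tuple[Segment, ...]",
    name: str = "allele",
    provenance: str | None = None,
) -> RearrangementAllele:
    """Build and validate an allele from a segment specification.

    ``ref_length`` may come from an actual :class:`ReferenceGenome` or be the
    nominal chromosome length when working purely with coordinates.
    """
    allele = RearrangementAllele(name, tuple(segments), provenance)
    allele.validate_against(ref_length)
    return allele


# --------------------------------------------------------------- junctions


@dataclass(frozen=True)
class JunctionSide:
    """One reference side of a junction: boundary coordinate + orientation.

    ``ref_pos`` is the half-open boundary at which the segment ends (left
    side) or begins (right side) on the reference.
    """

    ref_pos: int
    orientation: str


@dataclass(frozen=True)
class Junction:
    """A novel adjacency between two reference loci on an allele."""

    allele_position: int
    left: JunctionSide
    right: JunctionSide
    left_flank: str = ""
    right_flank: str = ""

    @property
    def ref_sides(self) -> tuple[JunctionSide, JunctionSide]:
        return (self.left, self.right)


def _left_boundary(seg: Segment) -> JunctionSide:
    # Boundary reached when the segment is exhausted reading the allele 5'->3'.
    pos = seg.end if seg.orientation == "+" else seg.start
    return JunctionSide(pos, seg.orientation)


def _right_boundary(seg: Segment) -> JunctionSide:
    pos = seg.start if seg.orientation == "+" else seg.end
    return JunctionSide(pos, seg.orientation)


def extract_junctions(
    allele: RearrangementAllele,
    ref: ReferenceGenome | None = None,
    flank: int = 500,
) -> list[Junction]:
    """Junctions of an allele: adjacent segment pairs that are not
    reference-contiguous and co-oriented.

    A wild-type (single forward segment) allele has none.  Flank sequences
    are attached when ``ref`` is supplied.
    """
    if ref is not None and flank < 20:
        raise ValueError("flank must be >= 20 bp")
    norm = allele.normalized()
    seq = norm.sequence(ref) if ref is not None else None
    junctions = []
    offset = 0
    for prev, nxt in zip(norm.segments, norm.segments[1:]):
        offset += prev.length
        left_flank = right_flank = ""
        if seq is not None:
            left_flank = seq[max(0, offset - flank) : offset]
            right_flank = seq[offset : offset + flank]
        junctions.append(
            Junction(
                allele_position=offset,
                left=_left_boundary(prev),
                right=_right_boundary(nxt),
                left_flank=left_flank,
                right_flank=right_flank,
            )
        )
    return junctions


# ----------------------------------------------------------- microhomology


@dataclass(frozen=True)
class MicrohomologyReport:
    """Sequence overlap shared by the two reference sides of a junction.

    ``ambiguity_interval`` gives the offsets (relative to the nominal cut)
    over which the breakpoint could be placed under zero mismatches; its
    width equals the 0-mismatch overlap length.
    """

    overlap_len: int
    mismatches: int
    ambiguity_interval: tuple[int, int]


def _prefix_mismatches(a: str, b: str, n: int) -> list[int]:
    out = [0]
    mm = 0
    for i in range(n):
        mm += a[i] != b[i]
        out.append(mm)
    return out


def microhomology(
    ref_side_a: str,
    ref_side_b: str,
    junction_seq: str,
    max_mismatch: int = 0,
    scan_window: int = 50,
) -> MicrohomologyReport:
    """Score microhomology at a junction.

    Parameters
    ----------
    ref_side_a:
        Reference continuation *past* the cut on the left side, in allele
        orientation (the ``scan_window`` bases that would have followed had
        no rearrangement occurred).
    ref_side_b:
        Reference bases immediately *preceding* the cut on the right side,
        in allele orientation.
    junction_seq:
        Allele sequence around the junction, with the cut at its midpoint.
    max_mismatch:
        Mismatch budget shared between the two extension directions.

    The overlap is the longest left+right extension around the cut over
    which the allele sequence is compatible with either reference side,
    i.e. the span across which the exact breakpoint cannot be resolved.
    """
    if len(ref_side_a) < scan_window or len(ref_side_b) < scan_window:
        raise ValueError("reference sides shorter than the scan window")
    if len(junction_seq) < 2 * scan_window or len(junction_seq) % 2:
        raise ValueError("junction_seq must be even length >= 2*scan_window")

    mid = len(junction_seq) // 2
    j_left = junction_seq[:mid]
    j_right = junction_seq[mid:]

    # Right extension h: junction bases after the cut match the side-a
    # continuation -> the cut could sit h bases further right.
    mm_right = _prefix_mismatches(j_right, ref_side_a, scan_window)
    # Left extension h: junction bases before the cut match the side-b
    # preceding sequence -> the cut could sit h bases further left.
    mm_left = _prefix_mismatches(j_left[::-1], ref_side_b[::-1], scan_window)

    def best(budget: int) -> tuple[int, int, int, int]:
        best_overlap = best_l = best_r = best_mm = 0
        for l in range(scan_window + 1):
            if mm_left[l] > budget:
                break
            rem = budget - mm_left[l]
            r = 0
            for h in range(scan_window + 1):
                if mm_right[h] <= rem:
                    r = h
            if l + r > best_overlap:
                best_overlap, best_l, best_r = l + r, l, r
                best_mm = mm_left[l] + mm_right[r]
        return best_overlap, best_mm, best_l, best_r

    overlap, used_mm, _, _ = best(max_mismatch)
    exact_overlap, _, l0, r0 = best(0)
    return MicrohomologyReport(
        overlap_len=overlap,
        mismatches=used_mm,
        ambiguity_interval=(-l0, r0),
    )


def junction_microhomology(
    ref: ReferenceGenome,
    allele: RearrangementAllele,
    junction: Junction,
    max_mismatch: int = 0,
    scan_window: int = 50,
) -> MicrohomologyReport:
    """Microhomology for a junction extracted from an allele.

    Pulls both reference sides and the junction-spanning allele sequence in
    allele orientation, then delegates to :func:`microhomology`.
    """
    w = scan_window
    seq = ref.sequence

    left = junction.left
    if left.orientation == "+":
        side_a = seq[left.ref_pos : left.ref_pos + w]
    else:
        side_a = revcomp(seq[max(0, left.ref_pos - w) : left.ref_pos])

    right = junction.right
    if right.orientation == "+":
        side_b = seq[max(0, right.ref_pos - w) : right.ref_pos]
    else:
        side_b = revcomp(seq[right.ref_pos : right.ref_pos + w])

    allele_seq = allele.sequence(ref)
    pos = junction.allele_position
    junction_seq = allele_seq[pos - w : pos + w]
    return microhomology(side_a, side_b, junction_seq, max_mismatch, w)


# ------------------------------------------------------ unequal crossover


def _split_segments(
    allele: RearrangementAllele, pos: int
) -> tuple[list[Segment], list[Segment]]:
    if not 0 <= pos <= len(allele):
        raise CoordinateError(
            f"crossover position {pos} outside allele of length {len(allele)}"
        )
    prefix: list[Segment] = []
    suffix: list[Segment] = []
    for placed in allele.segment_map:
        seg = placed.segment
        if placed.allele_end <= pos:
            prefix.append(seg)
        elif placed.allele_start >= pos:
            suffix.append(seg)
        else:
            k = pos - placed.allele_start
            if seg.orientation == "+":
                prefix.append(Segment(seg.start, seg.start + k, "+"))
                suffix.append(Segment(seg.start + k, seg.end, "+"))
            else:
                prefix.append(Segment(seg.end - k, seg.end, "-"))
                suffix.append(Segment(seg.start, seg.end - k, "-"))
    return prefix, suffix


def unequal_crossover(
    allele_a: RearrangementAllele,
    allele_b: RearrangementAllele,
    pos_a: int,
    pos_b: int,
    name: str | None = None,
) -> RearrangementAllele:
    """Recombinant ``allele_a[0, pos_a) + allele_b[pos_b, end)``.

    Crossing over between misaligned positions on two haplotypes produces a
    duplication or deletion recombinant; which one depends on the offset of
    ``pos_b`` relative to the homologous position of ``pos_a``.
    """
    prefix, _ = _split_segments(allele_a, pos_a)
    _, suffix = _split_segments(allele_b, pos_b)
    segments = tuple(prefix + suffix)
    if not segments:
        raise CoordinateError("crossover would produce an empty allele")
    recombinant = RearrangementAllele(
        name or f"{allele_a.name}x{allele_b.name}",
        segments,
        provenance=(
            f"unequal crossover: {allele_a.name}[0,{pos_a}) + "
            f"{allele_b.name}[{pos_b},{len(allele_b)})"
        ),
    ).normalized()
    return recombinant
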