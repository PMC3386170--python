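"""Breakpoint interpretation against gene models.

Classifies a breakpoint's feature context (5'UTR, exon/intron k,
intergenic) with strand-aware distances to nearby landmarks, and predicts
per-gene consequences of a rearranged allele: genes cut by a junction are
disrupted (with the exon partition between the two sides), intact genes
whose neighbourhood changed are relocated, and junction-adjacent gene
fragments are reported as candidate fusion partners.

Gene models are plain exon/CDS structures, read and written as GFF3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .allele_model import Junction, RearrangementAllele, Segment, extract_junctions
from .architecture import (
    GAP_ARTIFACT_REGION,
    GAP_PREDICTED,
    RoseCombArchitecture,
    gap_artifact_residual,
)

__all__ = [
    "GeneModel",
    "BreakpointAnnotation",
    "TranscriptEffect",
    "annotate_breakpoint",
    "predict_gene_effects",
    "effects_from_junctions",
    "candidate_fusions",
    "region_arithmetic",
    "toy_gene_models",
    "write_gff3",
    "read_gff3",
]


@dataclass(frozen=True)
class GeneModel:
    """One transcript: ordered exons, start codon, UTRs (0-based half-open).

    ``exons`` are in transcription order (decreasing genomic coordinates
    for minus-strand genes); ``start_codon`` is the genomic position of the
    first transcribed base of the ATG (its highest coordinate on minus
    strand).
    """

    gene_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    start_codon: int
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        genomic = sorted(self.exons)
        for (s0, e0), (s1, e1) in zip(genomic, genomic[1:]):
            if e0 > s1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expected:
            raise ValueError(f"{self.gene_id}: exons not in transcription order")
        if not any(s <= self._atg_low() < e for s, e in self.exons):
            raise ValueError(f"{self.gene_id}: start codon outside exons")

    def _atg_low(self) -> int:
        return self.start_codon if self.strand == "+" else self.start_codon - 2

    @property
    def start_codon_interval(self) -> tuple[int, int]:
        low = self._atg_low()
        return (low, low + 3)

    @property
    def span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))


def _boundary_distance(pos: int, interval: tuple[int, int]) -> int:
    """bp between a breakpoint boundary and an interval (0 if inside)."""
    a, b = interval
    if pos <= a:
        return a - pos
    if pos >= b:
        return pos - b
    return 0


@dataclass(frozen=True)
class BreakpointAnnotation:
    """Feature context and landmark distances of one breakpoint."""

    position: int
    feature: str  # "5'UTR" | "exon k" | "intron k" | "intergenic"
    gene: str | None
    nearest_gene: str
    distances: dict = field(default_factory=dict)


def annotate_breakpoint(
    pos: int, models: dict[str, GeneModel]
) -> BreakpointAnnotation:
    """Classify a breakpoint boundary against gene models.

    Distances are reported per gene to the start codon and the outer edge
    of the 5'UTR, plus the distance to the nearest gene span; all are
    measured along the reference in bp and are >= 0.
    """
    feature = "intergenic"
    containing = None
    for gene in models.values():
        lo, hi = gene.span
        if not lo < pos < hi:
            continue
        containing = gene.gene_id
        if any(a < pos < b for a, b in gene.utr5):
            feature = "5'UTR"
            break
        exon_hit = None
        for k, (a, b) in enumerate(gene.exons, start=1):
            if min(a, b) < pos < max(a, b):
                exon_hit = k
                break
        if exon_hit is not None:
            feature = f"exon {exon_hit}"
            break
        # between exon k and k+1 in transcription order
        for k in range(len(gene.exons) - 1):
            cur, nxt = gene.exons[k], gene.exons[k + 1]
            lo_i = min(cur + nxt)
            hi_i = max(cur + nxt)
            if lo_i <= pos <= hi_i and not (min(cur) < pos < max(cur)):
                feature = f"intron {k + 1}"
                break
        break

    distances: dict[str, int] = {}
    nearest, nearest_d = "", None
    for gene in models.values():
        distances[f"{gene.gene_id}:start_codon"] = _boundary_distance(
            pos, gene.start_codon_interval
        )
        if gene.utr5:
            edges = [d for iv in gene.utr5 for d in (_boundary_distance(pos, iv),)]
            distances[f"{gene.gene_id}:utr5"] = min(edges)
        d = _boundary_distance(pos, gene.span)
        distances[f"{gene.gene_id}:gene"] = d
        if nearest_d is None or d < nearest_d:
            nearest, nearest_d = gene.gene_id, d
    if nearest_d is not None:
        distances["nearest_gene"] = nearest_d
    return BreakpointAnnotation(
        position=pos,
        feature=feature,
        gene=containing,
        nearest_gene=nearest,
        distances=distances,
    )


# ----------------------------------------------------------- gene effects


@dataclass(frozen=True)
class TranscriptEffect:
    """Consequence of a rearrangement for one gene."""

    gene_id: str
    effect: str  # disrupted | relocated | intact | truncated_transcript | candidate_fusion
    exons_proximal: tuple[int, ...] = ()
    exons_distal: tuple[int, ...] = ()
    junction_distance: int | None = None
    details: str = ""


def _gene_instances(
    allele: RearrangementAllele, gene: GeneModel
) -> list[tuple[int, int, int, int, str]]:
    """Allele placements of a gene's reference span.

    Returns (allele_lo, allele_hi, ref_lo, ref_hi, orientation) per
    overlapping segment.
    """
    gs, ge = gene.span
    out = []
    for placed in allele.segment_map:
        seg = placed.segment
        lo, hi = max(gs, seg.start), min(ge, seg.end)
        if lo >= hi:
            continue
        if seg.orientation == "+":
            a_lo = placed.allele_start + (lo - seg.start)
            a_hi = placed.allele_start + (hi - seg.start)
        else:
            a_lo = placed.allele_start + (seg.end - hi)
            a_hi = placed.allele_start + (seg.end - lo)
        out.append((a_lo, a_hi, lo, hi, seg.orientation))
    return out


def _exon_side(gene: GeneModel, ref_lo: int, ref_hi: int) -> list[int]:
    """Exon numbers whose majority lies within [ref_lo, ref_hi)."""
    out = []
    for k, (a, b) in enumerate(gene.exons, start=1):
        lo, hi = min(a, b), max(a, b)
        overlap = max(0, min(hi, ref_hi) - max(lo, ref_lo))
        if overlap * 2 > hi - lo:
            out.append(k)
    return out


def _ref_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, max(a[0], b[0]) - min(a[1], b[1]))


def predict_gene_effects(
    allele: RearrangementAllele,
    models: dict[str, GeneModel],
    relocation_threshold: int = 1000,
) -> list[TranscriptEffect]:
    """Per-gene consequences of an allele's rearrangement.

    A gene is *disrupted* when no segment carries a complete copy (a
    junction falls strictly inside its span); its exons are partitioned
    between the two allele sides, ordered by allele coordinate (the side
    nearer the allele start is "proximal").  An intact gene is *relocated*
    when its distance to its nearest reference neighbour changes by more
    than ``relocation_threshold`` on the allele.  Extra partial copies
    (e.g. from a duplicated segment) are reported as truncated-transcript
    sources in the details.
    """
    junctions = [j.allele_position for j in extract_junctions(allele)]
    effects = []
    # allele distance between closest instances of two genes
    inst = {g.gene_id: _gene_instances(allele, g) for g in models.values()}
    full = {
        gid: [i for i in ivs if i[3] - i[2] == models[gid].span[1] - models[gid].span[0]]
        for gid, ivs in inst.items()
    }

    def allele_gap(g1: str, g2: str) -> int | None:
        best = None
        for a in inst[g1]:
            for b in inst[g2]:
                gap = max(0, max(a[0], b[0]) - min(a[1], b[1]))
                best = gap if best is None else min(best, gap)
        return best

    for gene in models.values():
        gid = gene.gene_id
        instances = inst[gid]
        if not instances:
            continue
        complete = full[gid]
        partial = [i for i in instances if i not in complete]
        near_junction = None
        if junctions:
            near_junction = min(
                min(abs(j - a_lo), abs(j - a_hi))
                for j in junctions
                for (a_lo, a_hi, *_rest) in instances
            )
        if not complete:
            ordered = sorted(partial)
            prox = _exon_side(gene, ordered[0][2], ordered[0][3])
            dist = [
                k
                for piece in ordered[1:]
                for k in _exon_side(gene, piece[2], piece[3])
            ]
            missing = [k for k in range(1, len(gene.exons) + 1) if k not in prox]
            details = (
                f"truncated transcript lacking exons {prox} predicted from the "
                f"distal fragment" if prox else ""
            )
            effects.append(
                TranscriptEffect(
                    gene_id=gid,
                    effect="disrupted",
                    exons_proximal=tuple(prox),
                    exons_distal=tuple(sorted(set(dist) or set(missing))),
                    junction_distance=near_junction,
                    details=details,
                )
            )
            continue
        # intact: relocated if its distance to any other gene changed
        others = [m for m in models.values() if m.gene_id != gid]
        effect = "intact"
        details = ""
        moved = []
        for other in others:
            ref_gap = _ref_gap(gene.span, other.span)
            a_gap = allele_gap(gid, other.gene_id)
            if a_gap is not None and abs(a_gap - ref_gap) > relocation_threshold:
                moved.append((abs(a_gap - ref_gap), other.gene_id, ref_gap, a_gap))
        if moved:
            effect = "relocated"
            _, oid, ref_gap, a_gap = max(moved)
            details = f"distance to {oid} changed {ref_gap} -> {a_gap} bp"
        if partial:
            details = (details + "; " if details else "") + (
                f"{len(partial)} extra partial copies (truncated transcript source)"
            )
        effects.append(
            TranscriptEffect(
                gene_id=gid,
                effect=effect,
                exons_proximal=tuple(range(1, len(gene.exons) + 1)),
                exons_distal=(),
                junction_distance=near_junction,
                details=details,
            )
        )
    return effects


def effects_from_junctions(
    junctions: list[Junction],
    allele_length: int,
    ref_length: int,
    models: dict[str, GeneModel],
    name: str = "reconstructed",
    relocation_threshold: int = 1000,
) -> list[TranscriptEffect]:
    """Gene effects computed from a junction list alone.

    Reconstructs the segment map from the junctions' reference sides
    (assuming the allele begins at reference 0 and ends at the reference
    end, both forward -- true for any allele of this locus) and applies the
    same per-gene logic, providing an independent route to
    :func:`predict_gene_effects`.
    """
    if not junctions:
        segments = [Segment(0, ref_length, "+")]
    else:
        segments = []
        prev_ref, prev_orient = 0, "+"
        for j in junctions:
            if prev_orient == "+":
                segments.append(Segment(prev_ref, j.left.ref_pos, "+"))
            else:
                segments.append(Segment(j.left.ref_pos, prev_ref, "-"))
            prev_ref, prev_orient = j.right.ref_pos, j.right.orientation
        if prev_orient == "+":
            segments.append(Segment(prev_ref, ref_length, "+"))
        else:
            segments.append(Segment(0, prev_ref, "-"))
    allele = RearrangementAllele(name, tuple(segments))
    if len(allele) != allele_length:
        raise ValueError("junctions inconsistent with the stated allele length")
    return predict_gene_effects(allele, models, relocation_threshold)


def candidate_fusions(
    allele: RearrangementAllele,
    models: dict[str, GeneModel],
    radius: int = 5000,
) -> list[tuple[str, str, int]]:
    """Junction-adjacent gene pairs: candidate fusion/hybrid transcripts.

    For each junction, the nearest gene instance ending before it and the
    nearest starting after it (within ``radius``) form a candidate pair.
    """
    placements = []
    for gene in models.values():
        for a_lo, a_hi, *_ in _gene_instances(allele, gene):
            placements.append((a_lo, a_hi, gene.gene_id))
    out = []
    for j in extract_junctions(allele):
        pos = j.allele_position
        before = [(pos - hi, gid) for lo, hi, gid in placements if hi <= pos and pos - hi <= radius]
        after = [(lo - pos, gid) for lo, hi, gid in placements if lo >= pos and lo - pos <= radius]
        if before and after:
            ga = min(before)[1]
            gb = min(after)[1]
            if ga != gb:
                out.append((ga, gb, pos))
    return out


def region_arithmetic(region: tuple[int, int], parts: "list[int] | tuple[int, ...]") -> int:
    """Residual of a 1-based inclusive region after removing known parts."""
    return gap_artifact_residual(region, tuple(parts))


# -------------------------------------------------------------- toy models


def toy_gene_models(arch: RoseCombArchitecture) -> dict[str, GeneModel]:
    """Gene models around the two breakpoints, to the locus geometry.

    The proximal breakpoint sits in the 5'UTR of FKBP7, 72 bp upstream of
    its start codon; the divergently transcribed PLEKHA3 begins 9 bp away,
    its 5'UTR edge 42 bp and start codon 150 bp from the breakpoint.  The
    distal breakpoint falls in intron 3 of CCDC108 (exons 1-3 inside the
    inverted segment); MNR2 lies 3 kb inside the distal breakpoint.
    """
    X = arch.proximal
    D = arch.distal
    fkbp7 = GeneModel(
        gene_id="FKBP7",
        strand="+",
        exons=((X - 33, X + 172), (X + 272, X + 472)),
        start_codon=X + 72,
        utr5=((X - 33, X + 72),),
        utr3=((X + 450, X + 472),),
    )
    plekha3 = GeneModel(
        gene_id="PLEKHA3",
        strand="-",
        exons=((X - 250, X - 42), (X - 450, X - 350)),
        start_codon=X - 151,
        utr5=((X - 150, X - 42),),
        utr3=((X - 450, X - 440),),
    )
    ccdc108 = GeneModel(
        gene_id="CCDC108",
        strand="+",
        exons=(
            (D - 2000, D - 1800),
            (D - 1500, D - 1400),
            (D - 1100, D - 1000),
            (D + 500, D + 700),
            (D + 1000, D + 1200),
        ),
        start_codon=D - 1950,
        utr5=((D - 2000, D - 1950),),
        utr3=((D + 1150, D + 1200),),
    )
    mnr2 = GeneModel(
        gene_id="MNR2",
        strand="-",
        exons=((D - 3200, D - 3000), (D - 3700, D - 3500)),
        start_codon=D - 3100,
        utr5=((D - 3099, D - 3000),),
        utr3=((D - 3700, D - 3690),),
    )
    return {g.gene_id: g for g in (fkbp7, plekha3, ccdc108, mnr2)}


# ------------------------------------------------------------------ GFF3


def write_gff3(models: dict[str, GeneModel], path: str | Path, seqid: str) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS/five_prime_UTR)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in models.values():
            lo, hi = gene.span
            gid = gene.gene_id
            fh.write(
                f"{seqid}\tinvseek\tgene\t{lo + 1}\t{hi}\t.\t{gene.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{seqid}\tinvseek\tmRNA\t{lo + 1}\t{hi}\t.\t{gene.strand}\t.\t"
                f"ID={gid}.t1;Parent={gid}\n"
            )
            for k, (a, b) in enumerate(gene.exons, start=1):
                s, e = min(a, b), max(a, b)
                fh.write(
                    f"{seqid}\tinvseek\texon\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t"
                    f"ID={gid}.e{k};Parent={gid}.t1;exon_number={k}\n"
                )
            cs, ce = gene.start_codon_interval
            fh.write(
                f"{seqid}\tinvseek\tCDS\t{cs + 1}\t{ce}\t.\t{gene.strand}\t0\t"
                f"ID={gid}.cds;Parent={gid}.t1\n"
            )
            for i, (a, b) in enumerate(gene.utr5):
                fh.write(
                    f"{seqid}\tinvseek\tfive_prime_UTR\t{a + 1}\t{b}\t.\t{gene.strand}\t.\t"
                    f"ID={gid}.utr5.{i};Parent={gid}.t1\n"
                )
            for i, (a, b) in enumerate(gene.utr3):
                fh.write(
                    f"{seqid}\tinvseek\tthree_prime_UTR\t{a + 1}\t{b}\t.\t{gene.strand}\t.\t"
                    f"ID={gid}.utr3.{i};Parent={gid}.t1\n"
                )


def read_gff3(path: str | Path) -> dict[str, GeneModel]:
    """Read gene models back from GFF3 (via gffutils)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = {}
    for gene in db.features_of_type("gene"):
        gid = gene.id
        strand = gene.strand
        exons = []
        for ex in db.children(f"{gid}.t1", featuretype="exon"):
            exons.append((int(ex.attributes["exon_number"][0]), ex.start - 1, ex.end))
        exons.sort()
        cds = next(db.children(f"{gid}.t1", featuretype="CDS"))
        start_codon = cds.start - 1 if strand == "+" else cds.end - 1
        utr5 = tuple(
            (u.start - 1, u.end)
            for u in db.children(f"{gid}.t1", featuretype="five_prime_UTR")
        )
        utr3 = tuple(
            (u.start - 1, u.end)
            for u in db.children(f"{gid}.t1", featuretype="three_prime_UTR")
        )
        models[gid] = GeneModel(
            gene_id=gid,
            strand=strand,
            exons=tuple((s, e) for _, s, e in exons),
            start_codon=start_codon,
            utr5=utr5,
            utr3=utr3,
        )
    return models
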