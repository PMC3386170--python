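"""Generators for every input the pipeline consumes.

All generators are deterministic for a fixed seed and emit either plain
containers (pandas DataFrames) or standard text formats (FASTA, minimal SAM,
TSV) that round-trip through the package's own readers.

The mate-pair simulator emulates large-insert (kb-scale) libraries in which
the two 50 bp reads of a concordant pair map to the *same* reference strand
(``same_strand`` dialect, the chemistry of the emulated instrument); an
``opposite_strand`` dialect is available for FR paired-end emulation.
Reads that cross a rearrangement junction by more than a small clip
tolerance are flagged unmapped -- the emulated aligners predate split-read
mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .allele_model import ReferenceGenome, RearrangementAllele, revcomp

__all__ = [
    "InsertSizeModel",
    "MatePairRecord",
    "PedigreeDesign",
    "SnpPanel",
    "forge_reference",
    "simulate_matepairs",
    "write_sam",
    "read_sam",
    "simulate_snp_panel",
    "simulate_pedigree",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

PAIR_COLUMNS = [
    "pair_id",
    "source_allele",
    "truth_span",
    "a1",
    "a2",
    "mapped1",
    "pos1",
    "strand1",
    "mapped2",
    "pos2",
    "strand2",
    "inferred_span",
]


@dataclass(frozen=True)
class InsertSizeModel:
    """Insert-size distribution and read geometry of a mate-pair library."""

    mean: float = 3900.0
    sd: float = 300.0
    read_len: int = 50
    expected_orientation: str = "same_strand"

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if self.mean <= 2 * self.read_len:
            raise ValueError("mean insert must exceed two read lengths")
        if self.expected_orientation not in ("same_strand", "opposite_strand"):
            raise ValueError(f"unknown orientation dialect {self.expected_orientation!r}")


@dataclass(frozen=True)
class MatePairRecord:
    """One aligned mate pair in reference coordinates."""

    pair_id: str
    pos1: int
    pos2: int
    strand1: str
    strand2: str
    mapped1: bool
    mapped2: bool
    inferred_span: float
    source_allele: str = ""


def forge_reference(
    length: int, gc: float = 0.41, seed: int = 0, name: str = "chrT"
) -> ReferenceGenome:
    """Random reference sequence with a target GC fraction."""
    if length < 10_000:
        raise ValueError("reference length must be >= 10 kb")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc) / 2.0
    probs = [at, gc / 2.0, gc / 2.0, at]
    idx = rng.choice(4, size=length, p=probs)
    return ReferenceGenome(name=name, sequence=_BASES[idx].tobytes().decode())


def _map_read(
    starts: np.ndarray,
    length: int,
    a_starts: np.ndarray,
    a_ends: np.ndarray,
    s_starts: np.ndarray,
    s_ends: np.ndarray,
    is_rev: np.ndarray,
    frag_rev: np.ndarray,
    clip_tol: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised placement of reads living on one allele.

    Returns (mapped, ref_left, read_is_reverse).  A read whose tail crosses
    into the next segment by more than ``clip_tol`` is unmapped.
    """
    idx = np.searchsorted(a_starts, starts, side="right") - 1
    ends = starts + length
    owned_end = np.minimum(ends, a_ends[idx])
    mapped = (ends - owned_end) <= clip_tol
    seg_rev = is_rev[idx]
    ref_left = np.where(
        seg_rev,
        s_ends[idx] - (owned_end - a_starts[idx]),
        s_starts[idx] + (starts - a_starts[idx]),
    )
    read_rev = frag_rev ^ seg_rev
    return mapped, ref_left, read_rev


def simulate_matepairs(
    pool: dict[str, int],
    alleles: dict[str, RearrangementAllele],
    ref_length: int,
    model: InsertSizeModel,
    coverage: float,
    seed: int = 0,
    clip_tol: int = 5,
) -> pd.DataFrame:
    """Simulate a mate-pair library from a pool of chromosomes.

    Fragments are drawn per chromosome proportional to the pool weights,
    placed uniformly on the generating allele with N(mean, sd^2) insert
    sizes, and each read is independently lifted to reference coordinates.

    Returns a DataFrame with one row per pair (see ``PAIR_COLUMNS``); truth
    tags (generating allele, allele-space insert size, allele read starts)
    are retained for simulator-level checks.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    total_weight = sum(pool.values())
    if total_weight <= 0 or any(w < 0 for w in pool.values()):
        raise ValueError("pool weights must be non-negative with positive total")
    rl = model.read_len
    for name in pool:
        if pool[name] > 0 and model.mean + 10 * model.sd > len(alleles[name]):
            raise ValueError(f"insert size model exceeds allele {name!r} length")

    rng = np.random.default_rng(seed)
    n_pairs = int(round(coverage * ref_length / (2 * rl)))
    names = sorted(k for k, w in pool.items() if w > 0)
    probs = np.array([pool[k] for k in names], dtype=float)
    probs /= probs.sum()
    counts = rng.multinomial(n_pairs, probs)

    frames = []
    pair_offset = 0
    for allele_name, n in zip(names, counts):
        if n == 0:
            continue
        allele = alleles[allele_name]
        placed = allele.segment_map
        a_starts = np.array([p.allele_start for p in placed])
        a_ends = np.array([p.allele_end for p in placed])
        s_starts = np.array([p.segment.start for p in placed])
        s_ends = np.array([p.segment.end for p in placed])
        is_rev = np.array([p.segment.orientation == "-" for p in placed])
        allele_len = len(allele)

        inserts = np.rint(rng.normal(model.mean, model.sd, size=n)).astype(np.int64)
        inserts = np.clip(inserts, 2 * rl + 1, allele_len)
        starts = rng.integers(0, allele_len - inserts + 1)
        frag_rev = rng.integers(0, 2, size=n).astype(bool)

        a_lo = starts
        a_hi = starts + inserts - rl
        mapped_lo, pos_lo, rev_lo = _map_read(
            a_lo, rl, a_starts, a_ends, s_starts, s_ends, is_rev, frag_rev, clip_tol
        )
        mapped_hi, pos_hi, rev_hi = _map_read(
            a_hi, rl, a_starts, a_ends, s_starts, s_ends, is_rev, frag_rev, clip_tol
        )
        # Read 1 is the fragment's 5' read: on a reverse-sampled fragment that
        # is the allele-rightmost read.  Read facing (mate-ward direction)
        # downstream relies on this.
        swap = frag_rev
        a1 = np.where(swap, a_hi, a_lo)
        a2 = np.where(swap, a_lo, a_hi)
        mapped1 = np.where(swap, mapped_hi, mapped_lo)
        mapped2 = np.where(swap, mapped_lo, mapped_hi)
        pos1 = np.where(swap, pos_hi, pos_lo)
        pos2 = np.where(swap, pos_lo, pos_hi)
        rev1 = np.where(swap, rev_hi, rev_lo)
        rev2 = np.where(swap, rev_lo, rev_hi)
        if model.expected_orientation == "opposite_strand":
            rev2 = ~rev2

        both = mapped1 & mapped2
        left = np.minimum(pos1, pos2)
        right = np.maximum(pos1, pos2)
        span = np.where(both, right + rl - left, np.nan)

        frames.append(
            pd.DataFrame(
                {
                    "pair_id": [f"mp{pair_offset + i}" for i in range(n)],
                    "source_allele": allele_name,
                    "truth_span": inserts,
                    "a1": a1,
                    "a2": a2,
                    "mapped1": mapped1,
                    "pos1": pos1,
                    "strand1": np.where(rev1, "-", "+"),
                    "mapped2": mapped2,
                    "pos2": pos2,
                    "strand2": np.where(rev2, "-", "+"),
                    "inferred_span": span,
                }
            )
        )
        pair_offset += n

    if not frames:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    return pd.concat(frames, ignore_index=True)[PAIR_COLUMNS]


# ----------------------------------------------------------------- SAM IO


def _flag(first: bool, rev: bool, mate_rev: bool, unmapped: bool, mate_unmapped: bool) -> int:
    flag = 0x1 | (0x40 if first else 0x80)
    if unmapped:
        flag |= 0x4
    if mate_unmapped:
        flag |= 0x8
    if rev:
        flag |= 0x10
    if mate_rev:
        flag |= 0x20
    return flag


def write_sam(
    records: pd.DataFrame,
    ref: ReferenceGenome,
    alleles: dict[str, RearrangementAllele],
    model: InsertSizeModel,
    path: str | Path,
    error_rate: float = 0.0,
    seed: int = 0,
) -> None:
    """Write pairs as minimal SAM (QNAME..QUAL + XA/XS truth tags).

    Read sequences are taken from the generating allele, so junction-crossing
    bases genuinely mismatch the reference; an optional uniform substitution
    rate adds sequencing noise on top.
    """
    rl = model.read_len
    rng = np.random.default_rng(seed)
    seqs = {name: allele.sequence(ref) for name, allele in alleles.items()}
    qual = "I" * rl

    def read_seq(allele_name: str, start: int, rev: bool) -> str:
        s = seqs[allele_name][start : start + rl]
        if error_rate > 0:
            arr = np.frombuffer(s.encode(), dtype=np.uint8).copy()
            hit = rng.random(len(arr)) < error_rate
            arr[hit] = _BASES[rng.integers(0, 4, size=int(hit.sum()))]
            s = arr.tobytes().decode()
        return revcomp(s) if rev else s

    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{ref.name}\tLN:{len(ref)}\n")
        for row in records.itertuples(index=False):
            both = row.mapped1 and row.mapped2
            tlen1 = tlen2 = 0
            if both:
                span = int(row.inferred_span)
                if row.pos1 <= row.pos2:
                    tlen1, tlen2 = span, -span
                else:
                    tlen1, tlen2 = -span, span
            for first in (True, False):
                mapped = row.mapped1 if first else row.mapped2
                mate_mapped = row.mapped2 if first else row.mapped1
                pos = row.pos1 if first else row.pos2
                rev = (row.strand1 if first else row.strand2) == "-"
                mate_rev = (row.strand2 if first else row.strand1) == "-"
                astart = row.a1 if first else row.a2
                flag = _flag(first, rev and mapped, mate_rev and mate_mapped,
                             not mapped, not mate_mapped)
                rname = ref.name if mapped else "*"
                pos_field = int(pos) + 1 if mapped else 0
                cigar = f"{rl}M" if mapped else "*"
                mapq = 60 if mapped else 0
                rnext = ref.name if mate_mapped else "*"
                pnext = int(row.pos2 if first else row.pos1) + 1 if mate_mapped else 0
                tlen = tlen1 if first else tlen2
                seq = read_seq(row.source_allele, int(astart), rev and mapped)
                fh.write(
                    f"{row.pair_id}\t{flag}\t{rname}\t{pos_field}\t{mapq}\t{cigar}"
                    f"\t{rnext}\t{pnext}\t{tlen}\t{seq}\t{qual}"
                    f"\tXA:Z:{row.source_allele}\tXS:i:{int(row.truth_span)}\n"
                )


def read_sam(path: str | Path) -> pd.DataFrame:
    """Read a minimal SAM back into the pair DataFrame layout."""
    import pysam

    firsts: dict[str, object] = {}
    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_read1:
                firsts[aln.query_name] = aln
                continue
            mate = firsts.pop(aln.query_name)
            r1, r2 = mate, aln
            mapped1, mapped2 = not r1.is_unmapped, not r2.is_unmapped
            pos1 = r1.reference_start if mapped1 else -1
            pos2 = r2.reference_start if mapped2 else -1
            rl = r1.query_length
            span = np.nan
            if mapped1 and mapped2:
                span = max(pos1, pos2) + rl - min(pos1, pos2)
            rows.append(
                {
                    "pair_id": r1.query_name,
                    "source_allele": r1.get_tag("XA") if r1.has_tag("XA") else "",
                    "truth_span": r1.get_tag("XS") if r1.has_tag("XS") else np.nan,
                    "a1": -1,
                    "a2": -1,
                    "mapped1": mapped1,
                    "pos1": pos1,
                    "strand1": "-" if r1.is_reverse else "+",
                    "mapped2": mapped2,
                    "pos2": pos2,
                    "strand2": "-" if r2.is_reverse else "+",
                    "inferred_span": span,
                }
            )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


# ------------------------------------------------------------- SNP panel


@dataclass(frozen=True)
class SnpPanel:
    """Genotype matrix (loci x birds, coded 0/1/2) plus bird group labels."""

    genotypes: pd.DataFrame
    positions: np.ndarray
    groups: pd.Series

    def to_tsv(self, path: str | Path) -> None:
        out = self.genotypes.copy()
        out.insert(0, "pos", self.positions)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, groups: pd.Series | None = None) -> "SnpPanel":
        df = pd.read_csv(path, sep="\t")
        positions = df.pop("pos").to_numpy()
        if groups is None:
            groups = pd.Series(
                {c: c.rsplit("_", 1)[0] for c in df.columns}, name="group"
            )
        return cls(genotypes=df, positions=positions, groups=groups)


def simulate_snp_panel(
    groups: dict[str, int],
    m_loci: int,
    ref_length: int,
    sweep: tuple[int, int],
    seed: int = 0,
    maf_range: tuple[float, float] = (0.1, 0.5),
    sweep_group: str = "R1R1",
) -> SnpPanel:
    """SNP genotypes with a homozygous sweep in inversion-homozygous birds.

    Birds in ``sweep_group`` all carry the same fixed haplotype across the
    sweep interval (hence are homozygous and identical there); everything
    else is drawn from Hardy-Weinberg proportions at per-locus frequencies
    uniform in ``maf_range``.
    """
    if not (0 <= sweep[0] < sweep[1] <= ref_length):
        raise ValueError("sweep interval outside the reference")
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(ref_length, size=m_loci, replace=False))
    freqs = rng.uniform(*maf_range, size=m_loci)
    sweep_hap = rng.integers(0, 2, size=m_loci)  # fixed allele of the swept haplotype
    in_sweep = (positions >= sweep[0]) & (positions < sweep[1])

    data = {}
    labels = {}
    for group in sorted(groups):
        for i in range(groups[group]):
            bird = f"{group}_{i}"
            g = rng.binomial(2, freqs)
            if group == sweep_group:
                g[in_sweep] = 2 * sweep_hap[in_sweep]
            data[bird] = g
            labels[bird] = group
    return SnpPanel(
        genotypes=pd.DataFrame(data),
        positions=positions,
        groups=pd.Series(labels, name="group"),
    )


# -------------------------------------------------------------- pedigree


@dataclass(frozen=True)
class PedigreeDesign:
    """Backcross design: carrier sires (R1r) mated to wild-type (rr) dams."""

    markers: tuple[tuple[str, int], ...]  # (name, reference bp), increasing
    trait_pos: int
    suppressed: tuple[int, int]  # recombination-free interval in carrier sires
    n_sires: int = 2
    n_dams_per_sire: int = 8
    n_progeny: int = 383
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        pos = [p for _, p in self.markers]
        if pos != sorted(pos) or len(set(pos)) != len(pos):
            raise ValueError("marker positions must be strictly increasing")

    @property
    def loci(self) -> list[tuple[str, int]]:
        """Markers plus the trait locus, sorted by position."""
        loci = list(self.markers) + [("trait", self.trait_pos)]
        return sorted(loci, key=lambda x: x[1])


def simulate_pedigree(
    design: PedigreeDesign,
    theta: np.ndarray | list[float],
    seed: int = 0,
) -> pd.DataFrame:
    """Per-progeny transmitted sire haplotypes and comb phenotype.

    ``theta`` gives recombination fractions between adjacent loci (markers +
    trait, sorted); intervals lying inside the suppressed region are forced
    to zero for carrier sires, emulating an inversion heterozygote in which
    recombinant gametes across the inverted interval are unbalanced and not
    recovered.  The trait is fully dominant: one R allele gives Rose.

    Returns one row per progeny with the transmitted sire allele at each
    marker (1 = allele on the carrier haplotype, 2 = wild-type haplotype;
    -1 = missing genotype) plus the phenotype.
    """
    loci = design.loci
    theta = np.asarray(theta, dtype=float)
    if len(theta) != len(loci) - 1:
        raise ValueError(f"theta must have length {len(loci) - 1}")
    if np.any((theta < 0) | (theta > 0.5)):
        raise ValueError("theta values must be in [0, 0.5]")

    eff_theta = theta.copy()
    s, e = design.suppressed
    for i, ((_, p0), (_, p1)) in enumerate(zip(loci, loci[1:])):
        if s <= p0 and p1 <= e:
            eff_theta[i] = 0.0

    rng = np.random.default_rng(seed)
    n = design.n_progeny
    start = rng.integers(0, 2, size=n)
    switches = rng.random((n, len(eff_theta))) < eff_theta
    # haplotype state at locus j = start XOR parity of switches before j
    states = np.empty((n, len(loci)), dtype=int)
    states[:, 0] = start
    states[:, 1:] = (start[:, None] + np.cumsum(switches, axis=1)) % 2

    trait_idx = next(i for i, (name, _) in enumerate(loci) if name == "trait")
    carrier_gamete = states[:, trait_idx] == 0  # state 0 = carrier haplotype
    phenotype = np.where(carrier_gamete, "Rose", "Single")

    out = pd.DataFrame(
        {
            "progeny_id": [f"F1_{i}" for i in range(n)],
            "sire": [f"sire{i % design.n_sires}" for i in range(n)],
            "phenotype": phenotype,
        }
    )
    for j, (name, _) in enumerate(loci):
        if name == "trait":
            continue
        allele = np.where(states[:, j] == 0, 1, 2)
        if design.missing_rate > 0:
            missing = rng.random(n) < design.missing_rate
            allele = np.where(missing, -1, allele)
        out[name] = allele
    return out
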