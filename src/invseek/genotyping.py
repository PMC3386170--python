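"""In-silico breakpoint-junction PCR genotyping.

A small set of positionally anchored primers is lifted onto each allele;
every convergent primer pair within the amplifiable length yields an
amplicon.  Because novel junctions flip or displace primer binding sites,
each of the five diagnostic junction contexts of the r/R1/R2 allelic
series (wild-type proximal, wild-type distal, shared proximal novel
junction, R1-specific distal junction, R2-specific duplication junction)
produces its own band, and the six diploid genotypes give six distinct
band patterns.

Primers are positional anchors, not sequences: the assay models where a
primer binds and in which direction it extends, which is all that is
needed to predict presence/absence and size of junction amplicons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
import yaml

from .allele_model import RearrangementAllele, extract_junctions
from .architecture import RoseCombArchitecture

__all__ = [
    "Primer",
    "Amplicon",
    "PCRAssay",
    "GenotypeCall",
    "GENOTYPES",
    "default_primers",
    "build_assay",
    "predict_amplicons",
    "band_pattern",
    "call_genotype",
    "genotype_cohort",
    "cohort_summary",
]

GENOTYPES = ("rr", "R1R1", "R2R2", "R1R2", "R1r", "R2r")

_ALLELE_ORDER = {"R1": 0, "R2": 1, "r": 2}


def genotype_name(allele_a: str, allele_b: str) -> str:
    a, b = sorted((allele_a, allele_b), key=_ALLELE_ORDER.__getitem__)
    return f"{a}{b}"


@dataclass(frozen=True)
class Primer:
    """A positionally anchored primer: reference anchor + extension strand."""

    name: str
    ref_pos: int
    strand: str  # "+" extends toward higher allele coordinates at its site
    length: int = 20

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("primer strand must be '+' or '-'")


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product on one allele."""

    fwd_primer: str
    rev_primer: str
    start: int  # allele coordinates of the two anchors
    end: int
    junctions: tuple[int, ...]  # allele positions of junctions spanned

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenotypeCall:
    """Outcome of matching a band pattern against the assay truth table."""

    genotype: str | None
    supporting: frozenset
    note: str = ""

    @property
    def ok(self) -> bool:
        return self.genotype is not None


def _primer_sites(
    allele: RearrangementAllele, primer: Primer
) -> list[tuple[int, str]]:
    """All (allele position, allele strand) sites where the primer binds.

    A site is valid only if the primer body lies within a single segment;
    junction-crossing anchors do not bind.
    """
    sites = []
    for placed in allele.segment_map:
        seg = placed.segment
        if not (seg.start <= primer.ref_pos < seg.end):
            continue
        if primer.ref_pos - primer.length < seg.start or primer.ref_pos + primer.length > seg.end:
            continue
        apos = placed.from_reference(primer.ref_pos)
        strand = primer.strand
        if seg.orientation == "-":
            strand = "-" if strand == "+" else "+"
        sites.append((apos, strand))
    return sites


def predict_amplicons(
    allele: RearrangementAllele,
    primers: "list[Primer] | tuple[Primer, ...]",
    max_len: int = 1000,
) -> list[Amplicon]:
    """All products from convergent primer pairs within ``max_len``."""
    fwd_sites = []
    rev_sites = []
    for primer in primers:
        for apos, strand in _primer_sites(allele, primer):
            (fwd_sites if strand == "+" else rev_sites).append((apos, primer.name))
    junction_pos = [j.allele_position for j in extract_junctions(allele)]
    products = []
    for fpos, fname in sorted(fwd_sites):
        for rpos, rname in sorted(rev_sites):
            if fpos < rpos and rpos - fpos + 1 <= max_len:
                spanned = tuple(j for j in junction_pos if fpos < j <= rpos)
                products.append(Amplicon(fname, rname, fpos, rpos, spanned))
    return products


# ------------------------------------------------------------------ assay

# Primer anchor offsets relative to the breakpoint coordinates; in bp, kept
# fixed under coordinate scaling so amplicon sizes are scale-invariant.
_PRIMER_OFFSETS = {
    "prox_fwd": ("flank_start", -150, "+"),
    "prox_rev": ("proximal", +120, "-"),
    "inv_fwd": ("distal", -240, "+"),
    "dist_rev": ("distal", +180, "-"),
    "dup_rev": ("dup_start", +380, "-"),
}

# Diagnostic amplicon = unordered primer pair; each covers one of the five
# breakpoint contexts of the allelic series.
_DIAGNOSTIC_PAIRS = {
    frozenset(("prox_fwd", "prox_rev")): "wt_proximal",
    frozenset(("inv_fwd", "dist_rev")): "wt_distal",
    frozenset(("prox_fwd", "inv_fwd")): "proximal_novel",
    frozenset(("prox_rev", "dist_rev")): "r1_distal_novel",
    frozenset(("dup_rev", "prox_rev")): "r2_duplication",
}


def default_primers(arch: RoseCombArchitecture) -> tuple[Primer, ...]:
    """The five-primer layout giving one band per diagnostic breakpoint."""
    primers = []
    for name, (anchor, offset, strand) in _PRIMER_OFFSETS.items():
        primers.append(Primer(name, getattr(arch, anchor) + offset, strand))
    return tuple(primers)


@dataclass(frozen=True)
class PCRAssay:
    """Primer layout plus the derived per-genotype band truth table."""

    primers: tuple[Primer, ...]
    diagnostics: dict  # name -> expected size (bp)
    allele_bands: dict  # allele name -> frozenset of diagnostic names
    truth_table: dict  # genotype -> frozenset of diagnostic names
    max_len: int = 1000
    size_tol: float = 0.05

    def match_size(self, name: str, size: float) -> bool:
        expected = self.diagnostics[name]
        return abs(size - expected) <= self.size_tol * expected

    def to_yaml(self, path) -> None:
        doc = {
            "max_len": self.max_len,
            "size_tol": self.size_tol,
            "primers": [
                {"name": p.name, "ref_pos": p.ref_pos, "strand": p.strand, "length": p.length}
                for p in self.primers
            ],
            "diagnostics": dict(self.diagnostics),
            "truth_table": {g: sorted(v) for g, v in self.truth_table.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def build_assay(
    arch: RoseCombArchitecture,
    alleles: dict[str, RearrangementAllele] | None = None,
    primers: tuple[Primer, ...] | None = None,
    max_len: int = 1000,
) -> PCRAssay:
    """Derive diagnostics and the genotype truth table for a primer layout.

    Rejects layouts whose six diploid band patterns are not all distinct,
    or whose primers fail to anchor uniquely in at least one allele.
    """
    alleles = alleles if alleles is not None else arch.alleles()
    primers = primers if primers is not None else default_primers(arch)

    for primer in primers:
        n_unique = [len(_primer_sites(a, primer)) for a in alleles.values()]
        if 1 not in n_unique:
            raise ValueError(f"primer {primer.name!r} anchors uniquely in no allele")

    diagnostics: dict[str, int] = {}
    allele_bands: dict[str, frozenset] = {}
    for name, allele in alleles.items():
        bands = set()
        for amp in predict_amplicons(allele, primers, max_len=max_len):
            diag = _DIAGNOSTIC_PAIRS.get(frozenset((amp.fwd_primer, amp.rev_primer)))
            if diag is None:
                continue
            if diag in diagnostics and diagnostics[diag] != amp.size:
                raise ValueError(f"diagnostic {diag!r} has inconsistent size")
            diagnostics[diag] = amp.size
            bands.add(diag)
        allele_bands[name] = frozenset(bands)

    truth = {}
    for i, a in enumerate(alleles):
        for b in list(alleles)[i:]:
            truth[genotype_name(a, b)] = allele_bands[a] | allele_bands[b]
    patterns = list(truth.values())
    if len(set(patterns)) != len(patterns):
        raise ValueError("assay truth table is not injective over genotypes")
    return PCRAssay(
        primers=tuple(primers),
        diagnostics=diagnostics,
        allele_bands=allele_bands,
        truth_table=truth,
        max_len=max_len,
    )


def band_pattern(
    assay: PCRAssay, allele_a: str, allele_b: str
) -> dict[str, int]:
    """Expected band pattern (diagnostic -> size) for a diploid genotype."""
    names = assay.allele_bands[allele_a] | assay.allele_bands[allele_b]
    return {n: assay.diagnostics[n] for n in sorted(names)}


def call_genotype(pattern: dict[str, float], assay: PCRAssay) -> GenotypeCall:
    """Match a band pattern to the six-genotype truth table.

    Band sizes are matched within the assay tolerance; a pattern matching
    no row (or with an off-size band) is a no-call, never coerced.
    """
    observed = set()
    for name, size in pattern.items():
        if name not in assay.diagnostics:
            return GenotypeCall(None, frozenset(pattern), f"unknown band {name!r}")
        if not assay.match_size(name, size):
            return GenotypeCall(
                None, frozenset(pattern),
                f"band {name!r} size {size} outside tolerance of {assay.diagnostics[name]}",
            )
        observed.add(name)
    matches = [g for g, bands in assay.truth_table.items() if bands == observed]
    if len(matches) == 1:
        return GenotypeCall(matches[0], frozenset(observed))
    return GenotypeCall(
        None, frozenset(observed),
        "pattern matches no genotype" if not matches else "ambiguous pattern",
    )


def genotype_cohort(
    birds: pd.DataFrame, assay: PCRAssay
) -> pd.DataFrame:
    """Genotype a cohort given per-bird true allele pairs.

    ``birds`` needs columns ``allele1``/``allele2``; returns a copy with
    ``genotype`` (the call), ``true_genotype`` and ``call_ok``.
    """
    out = birds.copy()
    calls = []
    for row in birds.itertuples(index=False):
        pattern = band_pattern(assay, row.allele1, row.allele2)
        calls.append(call_genotype(pattern, assay))
    out["true_genotype"] = [
        genotype_name(r.allele1, r.allele2) for r in birds.itertuples(index=False)
    ]
    out["genotype"] = [c.genotype for c in calls]
    out["call_ok"] = [c.ok for c in calls]
    return out


ROSE_PHENOTYPES = frozenset({"Rose", "Walnut"})
WILDTYPE_PHENOTYPES = frozenset({"Single", "Pea"})


def cohort_summary(
    cohort: pd.DataFrame,
) -> tuple[pd.DataFrame, float, int]:
    """Genotype x phenotype contingency plus dominance concordance.

    Concordance is the fraction of birds whose phenotype matches the
    dominance expectation: any R allele gives Rose (or Walnut with the
    pea-comb interaction), rr gives Single (or Pea).  Records with unknown
    phenotype labels are excluded with a warning and counted.
    """
    if cohort.empty:
        raise ValueError("cohort summary needs at least one record")
    known = cohort["phenotype"].isin(ROSE_PHENOTYPES | WILDTYPE_PHENOTYPES)
    excluded = int((~known).sum())
    if excluded:
        warnings.warn(f"excluded {excluded} records with unknown phenotype labels")
    kept = cohort[known]
    index_cols = ["breed", "phenotype"] if "breed" in kept.columns else ["phenotype"]
    table = (
        kept.groupby(index_cols + ["genotype"], dropna=False)
        .size()
        .unstack("genotype", fill_value=0)
    )
    carrier = kept["genotype"].fillna("") != "rr"
    expected_rose = kept["phenotype"].isin(ROSE_PHENOTYPES)
    concordance = float((carrier == expected_rose).mean()) if len(kept) else float("nan")
    return table, concordance, excluded
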