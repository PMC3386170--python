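"""The comb-locus rearrangement architecture on chicken chromosome 7.

The locus carries three alleles:

* ``r``  -- the wild-type chromosome;
* ``R1`` -- a 7.38 Mb paracentric inversion with breakpoints at 16,499,781
  and 23,881,384(-23,881,392) bp (galGal3);
* ``R2`` -- derived from ``R1`` by unequal crossing over with a wild-type
  chromosome: a wild-type backbone carrying, inserted at the proximal
  breakpoint, a reverse-oriented 91 kb duplication (23,790,414-23,881,384)
  followed by a second copy of the 198 bp fragment (16,499,583-16,499,781)
  that natively flanks the insertion point, so the 198 bp fragment ends up
  on both sides of the duplication.

The distal breakpoint is only resolvable to an 8 bp interval because of
junction microhomology; the left edge is used as the canonical coordinate.

Coordinates here are 0-based half-open internally; printed 1-based breakpoint
positions map onto half-open boundaries directly (a break "after base p"
is boundary p), so the printed values appear verbatim below.

A toy-scale architecture maps the same topology onto a ~300 kb reference for
fast simulation: Mb-range spans scale by the factor, while the 198 bp
flank keeps its native size so junction chemistry (primer anchoring,
microhomology windows) behaves as at full scale.
"""

from __future__ import annotations

from dataclasses import dataclass

from .allele_model import RearrangementAllele, Segment, build_allele, unequal_crossover

# Printed galGal3 coordinates (1-based; equal to 0-based half-open boundaries).
PROXIMAL_BREAKPOINT = 16_499_781
DISTAL_BREAKPOINT_INTERVAL = (23_881_384, 23_881_392)
DUP_SEGMENT = (23_790_414, 23_881_384)
DUP_FLANK = (16_499_583, 16_499_781)
SWEEP_INTERVAL = (16_424_096, 23_854_241)
# Assembly-artefact region (1-based inclusive) and the gap predicted in it.
GAP_ARTIFACT_REGION = (16_499_808, 16_500_522)
GAP_PREDICTED = 628
GALGAL3_CHR7_LENGTH = 38_384_769


@dataclass(frozen=True)
class RoseCombArchitecture:
    """Breakpoint geometry of the r/R1/R2 allelic series on one reference."""

    ref_length: int
    flank_start: int  # a: start of the 198 bp duplicated flank
    proximal: int  # b: proximal inversion breakpoint
    dup_start: int  # c: proximal edge of the 91 kb duplicated segment
    distal: int  # d: distal inversion breakpoint (canonical = left edge)
    distal_interval: tuple[int, int]
    sweep: tuple[int, int]  # homozygosity sweep interval seen on SNP arrays

    def __post_init__(self) -> None:
        if not (
            0 < self.flank_start < self.proximal < self.dup_start < self.distal <= self.ref_length
        ):
            raise ValueError("architecture coordinates out of order")

    # -- derived sizes ------------------------------------------------------

    @property
    def inversion_span(self) -> int:
        return self.distal - self.proximal

    @property
    def dup_length(self) -> int:
        return self.distal - self.dup_start

    @property
    def flank_length(self) -> int:
        return self.proximal - self.flank_start

    # -- canonical alleles --------------------------------------------------

    def wildtype(self, name: str = "r") -> RearrangementAllele:
        return build_allele(
            self.ref_length,
            [Segment(0, self.ref_length, "+")],
            name=name,
            provenance="wild-type chromosome",
        )

    def r1(self, name: str = "R1") -> RearrangementAllele:
        return build_allele(
            self.ref_length,
            [
                Segment(0, self.proximal, "+"),
                Segment(self.proximal, self.distal, "-"),
                Segment(self.distal, self.ref_length, "+"),
            ],
            name=name,
            provenance=f"{self.inversion_span} bp inversion",
        )

    def r2(self, name: str = "R2") -> RearrangementAllele:
        """Directly specified R2 structure (duplication allele)."""
        return build_allele(
            self.ref_length,
            [
                Segment(0, self.proximal, "+"),
                Segment(self.dup_start, self.distal, "-"),
                Segment(self.flank_start, self.ref_length, "+"),
            ],
            name=name,
            provenance=(
                f"wild type + inserted {self.dup_length} bp reverse duplication "
                f"and {self.flank_length} bp flank copy"
            ),
        )

    def r2_by_crossover(self, name: str = "R2") -> RearrangementAllele:
        """Derive R2 by unequal crossing over between R1 and wild type.

        On the R1 chromosome the exchange happens ``dup_length`` bp into the
        inversion (reference ~23.79 Mb); on the wild-type chromosome it
        happens ``flank_length`` bp upstream of the proximal breakpoint.
        """
        recombinant = unequal_crossover(
            self.r1(),
            self.wildtype(),
            pos_a=self.proximal + self.dup_length,
            pos_b=self.flank_start,
            name=name,
        )
        return recombinant

    def alleles(self) -> dict[str, RearrangementAllele]:
        return {"r": self.wildtype(), "R1": self.r1(), "R2": self.r2()}

    # -- factories ----------------------------------------------------------

    @classmethod
    def galgal3(cls) -> "RoseCombArchitecture":
        return cls(
            ref_length=GALGAL3_CHR7_LENGTH,
            flank_start=DUP_FLANK[0],
            proximal=PROXIMAL_BREAKPOINT,
            dup_start=DUP_SEGMENT[0],
            distal=DISTAL_BREAKPOINT_INTERVAL[0],
            distal_interval=DISTAL_BREAKPOINT_INTERVAL,
            sweep=SWEEP_INTERVAL,
        )

    @classmethod
    def toy(
        cls,
        factor: float = 0.01,
        ref_length: int = 300_000,
        flank_length: int = DUP_FLANK[1] - DUP_FLANK[0],
        min_dup_length: int = 10_000,
    ) -> "RoseCombArchitecture":
        """Scaled-down architecture for fast simulation.

        Mb-range spans scale by ``factor``; sub-insert-size features do
        not: the duplicated flank keeps its native 198 bp and the
        duplicated segment is floored at ``min_dup_length`` so it stays
        longer than a mate-pair insert and the junction signatures (and the
        genes the duplication carries) keep their full-scale character.
        """
        proximal = round(PROXIMAL_BREAKPOINT * factor)
        span = round((DISTAL_BREAKPOINT_INTERVAL[0] - PROXIMAL_BREAKPOINT) * factor)
        dup_len = max(round((DUP_SEGMENT[1] - DUP_SEGMENT[0]) * factor), min_dup_length)
        distal = proximal + span
        return cls(
            ref_length=ref_length,
            flank_start=proximal - flank_length,
            proximal=proximal,
            dup_start=distal - dup_len,
            distal=distal,
            distal_interval=(distal, distal + (DISTAL_BREAKPOINT_INTERVAL[1] - DISTAL_BREAKPOINT_INTERVAL[0])),
            sweep=(round(SWEEP_INTERVAL[0] * factor), round(SWEEP_INTERVAL[1] * factor)),
        )


def gap_artifact_residual(
    region: tuple[int, int] = GAP_ARTIFACT_REGION, parts: tuple[int, ...] = (GAP_PREDICTED,)
) -> int:
    """Residual of a 1-based inclusive region after removing known parts.

    The assembly-artefact region around the proximal breakpoint consists of
    a predicted gap plus a residual of novel sequence; this computes that
    residual (87 bp for the defaults).
    """
    start, end = region
    length = end - start + 1
    total = sum(parts)
    if total > length:
        raise ValueError("parts exceed region length")
    return length - total
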