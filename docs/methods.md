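# Methods

## The locus model

The package models a three-allele series on one chromosome:

* **r** (wild type): a single forward segment covering the reference.
* **R1**: a paracentric inversion. With 0-based half-open coordinates the
  allele is `[0, b) + rev[b, d) + [d, L)`, where `b = 16,499,781` and
  `d = 23,881,384` on galGal3 chromosome 7 (span 7,381,603 bp ≈ 7.38 Mb).
  The distal breakpoint is only resolvable to the interval
  23,881,384–23,881,392 because of junction microhomology; the left edge is
  the canonical construction coordinate, and the ambiguity interval is kept
  on the architecture object.
* **R2**: derived from R1 by unequal crossing over with a wild-type
  chromosome. The exchange happens 90,970 bp into the inversion on the R1
  chromosome (reference ~23.79 Mb) and 198 bp upstream of the proximal
  breakpoint on the wild-type chromosome, producing
  `[0, b) + rev[c, d) + [a, L)` with `c = 23,790,414` and `a = 16,499,583`:
  a wild-type backbone with a reverse 91 kb duplication and one extra copy
  of the 198 bp flank, which therefore appears on both sides of the
  duplication. Length = L + 90,970 + 198.

Coordinates are 0-based half-open internally; a printed 1-based breakpoint
"after base p" is the half-open boundary p, so printed values appear
verbatim in the code. The printed flank pair 16,499,583–16,499,781 is
interpreted as the half-open difference 198 bp (the dominant usage in the
source material; an inclusive reading would give 199 and is not used).
Likewise "91 kb" is the half-open difference 90,970 bp.

R2 carries two *novel* adjacency junctions — the proximal junction shared
with R1 and the duplication junction (23,790,414-rev | 16,499,583) — while
retaining the wild-type distal context intact. Its three PCR-diagnostic
breakpoint contexts (proximal novel, duplication novel, wild-type distal)
are therefore distinct from its two geometric junctions; the genotyping
assay works at the level of diagnostic contexts.

### Junction microhomology

A junction's microhomology is the longest left+right extension around the
nominal cut over which the allele sequence is compatible with either
reference side, under a shared mismatch budget (default scan window 50 bp).
The 0-mismatch extension defines the ambiguity interval within which the
true cut cannot be placed. The implementation is an exhaustive O(w²) scan;
tests check it against an independently coded brute force and against
planted junctions with known overlaps (7 bp with 1 mismatch, 2 bp exact,
1 bp exact — the three homology classes seen at this locus's junctions).

## Toy scale

Full-coordinate work (breakpoint arithmetic, segment-map algebra, assay
design) uses printed galGal3 coordinates. Sequence-level simulation runs on
a toy architecture: a ~300 kb reference with Mb-range spans scaled by 1/100
(inversion span 73,816 bp). Two features deliberately do **not** scale:

* the 198 bp duplicated flank keeps its native size — at 1/100 it would be
  2 bp, destroying primer anchoring and microhomology geometry;
* the duplicated segment is floored at 10 kb (vs a literal 910 bp) so it
  stays longer than a mate-pair insert; otherwise fragments would straddle
  both R2 junctions at once and the junction signatures (and the genes the
  duplication carries) would lose their full-scale character.

Gene models and primer layouts are defined by fixed bp offsets from the
(scaled) breakpoints, which is why amplicon sizes and gene effects are
invariant under the scale factor — a property the tests assert.

## Mate-pair simulation

The insert model is Normal(mean 3.9 kb, sd 300 bp) with 2×50 bp reads —
the sd is a package choice (≈7.7 % CV, typical of large-insert libraries);
the mean and read geometry follow the emulated libraries. Default
chemistry is `same_strand` (both reads of a concordant pair map to the same
strand, as in the emulated instrument); an `opposite_strand` dialect exists
for FR paired-end emulation. Fragments are drawn per chromosome
proportional to pool weights (equal per-chromosome coverage within the
pool, the natural assumption for a DNA pool), placed uniformly on the
generating allele, and each read is independently lifted to the reference.
Reads crossing a junction by more than a 5 bp clip tolerance are flagged
unmapped — the emulated aligners predate split-read mapping — leaving the
mate one-end-mapped. Read 1 is the fragment's 5′ read, so a read's
mate-ward facing (read 1 faces its 3′ direction, read 2 its 5′ direction)
is meaningful; breakpoint refinement votes on these facings to decide which
edge of each read cluster holds the junction. Sequencing errors are an
optional uniform substitution rate (default 0) applied when writing SAM;
discordance calling uses placements, not base calls.

Truth tags (generating allele, allele-space insert, allele read starts)
ride along in optional SAM fields so simulator-level checks and recall
measurements need no re-inference.

## SV calling

Pairs are classified against the insert model: unexpected strand
configuration ⇒ orientation anomaly; span strictly exceeding
mean + 10 sd ⇒ distance anomaly (the multiplier is strict — a span exactly
at the threshold is concordant); spans below mean − 10 sd also count by
default (symmetric treatment, switchable off). Windows are non-overlapping
1.5 kb tiles keyed by the pair's leftmost read. A tile is a candidate when
its discordant fraction is ≥ 25 % **and** ≥ 25 % of its pairs have partners
within 1 kb of each other (the fraction is of all the tile's pairs by
default; `frac_of="discordant"` gives the alternative reading). A
minimum of 4 pairs per tile avoids one-pair "100 %" tiles at 1× coverage.
Discordant pairs from candidate tiles are single-linkage clustered in
(left, right) space with a 1 kb Chebyshev radius — this cleanly separates
the two reciprocal clusters of an inversion, whose (left+right) sums differ
by about two insert lengths — and clusters with ≥ 4 pairs become calls,
typed by majority strand pattern with ties going to inversion. Call size is
the distance between breakpoint-interval midpoints.

Refinement intersects per-pair constraints: a supporting read must end
before the junction (within clip tolerance) and its fragment, capped at
mean + 3 sd, must still reach its mate. With many supporting pairs the
intersection can exclude the true breakpoint (some fragments genuinely
exceed 3 sd) or be empty, in which case the call falls back to the
unrefined interval, flagged; at the ~20-pair support level the refined
interval contains the truth with high probability.

At the mixed pool composition (4 R1 : 9 R2 : 3 r) the shared proximal
junction sits on 13 of 16 chromosomes and the R1-specific distal junction
on 4, so proximal support exceeds distal support essentially always; the
distal tiles' expected discordant fraction (~20 %) sits below the 25 %
threshold, so the distal junction is typically *not* called from the mixed
pool — only from homozygous or 50 % carrier pools — mirroring how the
mixed-pool evidence was dominated by the proximal junction.

## Genotyping assay

Primers are positional anchors (reference coordinate + extension strand +
20 bp body), not sequences: presence/absence and size of junction products
depend only on geometry. The default five-primer layout puts anchors at
fixed offsets from the five breakpoint coordinates; every convergent pair
within 1 kb yields an amplicon. The five diagnostic products are 469 bp
(wild-type proximal), 421 bp (wild-type distal), 588 bp (shared proximal
novel junction), 302 bp (R1 distal novel junction) and 700 bp (R2
duplication junction), all > 5 % apart so band identification is
unambiguous at the ±5 % size tolerance. The per-genotype truth table is
derived from the alleles at assay-build time and rejected if not injective
over the six genotypes; patterns matching no row are no-calls, never
coerced.

## Heterozygosity scan, linkage, equilibrium

Per-locus H = 1 − Σpᵢ² from sample allele frequencies, averaged in tiled
windows (500 kb at full scale, 5 kb on the toy reference; stride
configurable for sliding windows). A sweep is a run of windows fixed in the
case group but variable in controls, reported at window resolution.

Linkage uses the phase-known carrier-sire backcross: dams are uninformative
(rr, homozygous at markers), the carrier haplotype carries marker allele 1,
so recombinants are direct disagreements between transmitted allele and
phenotype. θ̂ = r/n and LOD = n[θ̂log₁₀θ̂ + (1−θ̂)log₁₀(1−θ̂) + log₁₀2]
with 0·log₁₀0 ≡ 0; 0 recombinants give n·log₁₀2 (113.8 at n = 378, the
informative-meiosis count back-derived from the fully linked LOD since the
per-marker counts are not printed; the simulated pedigree's default 1.3 %
missing-genotype rate makes n vary by marker the same way). The simulator
forces θ = 0 for marker intervals inside the suppressed region in carrier
sires, because crossovers within a paracentric inversion heterozygote yield
unbalanced gametes that are not recovered.

The breeding equilibrium model (the cited historical treatment gives no
equations, so the assumptions are explicit parameters): discrete
non-overlapping generations; single-combed (rr) birds culled from both
parental sexes (flag); RR sires excluded in proportion to
1 − competitive fertility (default 0, i.e. fully outcompeted); random
mating otherwise. With parents taken in Hardy–Weinberg proportions at the
offspring allele frequency — the default — dams contribute r at q/(1+q)
and sires at 1/2, giving q′ = (1/2 + q/(1+q))/2 with fixed point
q\* = (√17 − 1)/8 ≈ 0.3904 and single-comb offspring fraction
q\*/(2(1+q\*)) ≈ 0.1404. Tracking the true (non-Hardy–Weinberg) offspring
genotype fractions instead (`parents="genotype"`) settles slightly higher,
at ≈ 0.1464. Both sit near the historically reported "about 15 %"; the
~1-point gap to 15 % is expected and left unreconciled, since the original
model's exact assumptions are not stated. The Monte-Carlo flock
(multinomial sampling, default N = 10,000) implements the same parental
assumption as whichever deterministic variant it is checked against and
agrees with its fixed point within sampling error.

## Problem sizes and determinism

Simulation-heavy checks use the toy reference at 10× coverage (30,000
pairs) for recall and false-positive screens over 20 seeds, 1× (the
full-scale pool's depth) for the mixed-pool support asymmetry, and 30× for
the 13:4 support-ratio expectation; the demo pipeline completes in a few
seconds on one CPU. Every generator and every pipeline stage is
deterministic for a fixed seed (NumPy `default_rng`); stage seeds are
derived from the run seed by fixed offsets, and the demo report is
byte-stable across repeated runs.

## Known limitations

* No split-read or assembly-based breakpoint detection, no read-depth
  copy-number segmentation; junction-overlapping reads are simply dropped.
* Reads are placed, not aligned: mappability, colour-space chemistry and
  quality-score realism are out of scope, so caller performance on the toy
  data is an upper bound relative to real pooled sequencing (the real
  data's specific read counts, e.g. at the gap-riddled duplication origin,
  are not reproducible).
* Gene-effect prediction is genomic: exon-skipping isoforms of hybrid
  transcripts cannot be predicted from structure and are reported only as
  candidate fusion pairs with exon partitions.
* The phenotype model is complete dominance with full penetrance;
  aberrant-comb carriers and comb-type epistasis beyond the Rose/Walnut
  grouping are not modelled.
* The equilibrium model ignores overlapping generations, family structure
  and partial sperm-competition exclusion (the latter is a parameter but
  defaults to complete exclusion).
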