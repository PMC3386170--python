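# invseek

Simulation and analysis toolkit for a classical structural-variant story in
the chicken: the *Rose-comb* locus on chromosome 7, where a dominant comb
phenotype is caused by a 7.38 Mb paracentric inversion (allele *R1*) and a
second allele (*R2*) later arose by unequal crossing over between *R1* and a
wild-type chromosome, leaving a 91 kb reverse-oriented duplication plus a
198 bp duplicated flank inserted at the proximal breakpoint.

The package is for people who want a small, fully synthetic, end-to-end
reproducible model of how such a locus is discovered and characterised:

* **allele algebra** (`invseek.allele_model`) — haplotypes as ordered,
  oriented reference segments; coordinate liftover in both directions;
  junction extraction; junction microhomology scoring; derivation of new
  alleles by unequal crossing over;
* **synthetic data** (`invseek.synthetic_data`) — random references,
  mate-pair libraries simulated from allele pools (same-strand large-insert
  chemistry, junction-crossing reads dropped as unmapped), SNP panels with a
  homozygous sweep, and carrier-sire backcross pedigrees with recombination
  suppression;
* **SV calling** (`invseek.sv_caller`) — the windowed discordance rule:
  1.5 kb tiles are candidates when ≥ 25 % of their mate pairs have mapping
  distances exceeding ten standard deviations above the mean insert (or
  discordant strands) with partners clustered within 1 kb; candidate pairs
  are clustered into typed calls (different strands ⇒ inversion, same
  strand ⇒ deletion/duplication) and breakpoints refined geometrically;
* **genotyping** (`invseek.genotyping`) — in-silico breakpoint-junction PCR:
  five positional primers produce one diagnostic band per breakpoint
  context, and the six diploid genotypes (*rr*, *R1R1*, *R2R2*, *R1R2*,
  *R1r*, *R2r*) give six distinct band patterns;
* **annotation** (`invseek.annotation`) — breakpoint feature context and
  distances against GFF3 gene models, per-gene disruption/relocation calls
  with exon partitions, candidate fusion pairs;
* **population genetics** (`invseek.popgen`) — windowed heterozygosity
  scans (H = 1 − Σpᵢ²), phase-known two-point LOD scores
  (LOD = n[θ̂log₁₀θ̂ + (1−θ̂)log₁₀(1−θ̂) + log₁₀2]), and the breeding
  equilibrium that arises when single-combed (rr) parents are culled but
  homozygous Rose-comb (RR) sires are excluded by sperm competition.

All analyses run on data generated in-repo; no external files are needed.

## Worked example

Run the whole chain at 1/100 coordinate scale (a ~300 kb toy reference)
with one command:

```bash
invseek demo --seed 2 --outdir demo_out
```

which prints

```json
{
  "r1_pool_calls": 2,
  "genotype_concordance": 1.0,
  "sweep_intervals": [
    [
      165000,
      235000
    ]
  ],
  "equilibrium_rr_fraction": 0.14038820321248377,
  "outdir": "demo_out"
}
```

Reading the numbers: the caller recovered **both** inversion junctions from
a homozygous-*R1* mate-pair pool as two reciprocal inversion-type calls
(their sizes, in `demo_out/report.json`, are within one 1.5 kb window of
the simulated 73.8 kb scaled inversion); junction-PCR genotyping of a
120-bird cohort was **100 % concordant** with the simulated truth; the
heterozygosity scan found one run of zero-heterozygosity windows in
inversion homozygotes matching the configured sweep interval at window
resolution; and the breeding recursion settled at **14 %** single-combed
chicks per generation — the equilibrium that historically frustrated
attempts to breed flocks true for Rose-comb.

`demo_out/` also contains the intermediate artifacts as plain text (FASTA
reference, SAM mate pairs, BEDPE calls, genotype and linkage TSVs, GFF3
gene models, the equilibrium trajectory), each re-readable by the package's
own readers. The linkage table mirrors a classic two-point scan: markers
inside the inversion show 0.00 recombination and LOD ≈ n·log₁₀2 ≈ 113.8 at
n = 378 informative meioses, while flanking markers recombine freely.

Library use is equally direct:

```python
from invseek import RoseCombArchitecture, rose_comb_equilibrium

arch = RoseCombArchitecture.galgal3()     # printed coordinates
arch.inversion_span / 1e6                 # 7.381603 Mb
arch.r2_by_crossover().segments == arch.r2().segments   # True
rose_comb_equilibrium().rr_fraction       # 0.14038820321248377
```

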