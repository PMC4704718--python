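# Methods

## Cross model

The parasexual cycle is modelled in three steps.

**Diploid formation.** Two haploid parents are fused into a diploid;
selection requires complementary spore-color markers (one fwnA-mutant, one
olvA-mutant parent, so the heterozygote conidiates black) and complementary
auxotrophies (one uridine-, one arginine-requiring, so only the balanced
heterokaryon grows on minimal medium). `form_diploid` raises if either
complementation is missing, because such a diploid could not have been
selected.

**Haploidization.** Each segregant inherits each of the 8 chromosomes
independently from homolog A or B with probability 1/2 — whole chromosomes
segregate as units because haploidization proceeds by chromosome loss, not
meiosis. With probability `p_mitotic_rec` per chromosome per segregant the
chromosome is instead a single-breakpoint mitotic recombinant: the
breakpoint is uniform on [1, L) and the proximal source uniform on {A, B}.
At most one crossover per chromosome per lineage is representable; mitotic
recombination is rare in this system and the data constrain nothing richer.
Default `p_mitotic_rec = 0.013` puts the expectation at about one crossover
on a given chromosome among 78 pool members, the rate actually observed.
Aneuploids and partial diploids are not modelled: only purified euploid
haploid sectors enter the analysis.

**Phenotypes.** Marker semantics are those of the cross being emulated:
fwnA is epistatic to olvA in the melanin pathway (fwnA-mutants are fawn
whatever their olvA state); the olvA disruption cassette carries a
functional pyrG copy, so uridine prototrophy tracks the olvA::pyrG allele —
both parents are pyrG378-mutant at the native locus, which is why pyrG is a
derived phenotype column rather than an independent genomic locus here; the
fwnA and argB disruptions carry hygB. Double color mutants (fwnA plus
olvA::pyrG, via a chromosome-I crossover) are fawn but uridine-prototrophic
— the signature by which they are detected.

## Sequencing model

Per SNP site: depth ~ Poisson(mean depth); alt reads ~ Binomial(depth, q)
with q = p(1−e) + (1−p)e/3, where p is the true alt frequency (0/1 for a
strain, the member fraction for an equal-mass pool) and e the per-read
error rate, split evenly over the three wrong bases. Defaults: 100× for
parent strains, 300× for the pool, e = 0.002. The published experiment
reports only library totals (gigabases), not per-site depth; these defaults
keep the 0.7/20 validation filter comfortably exercised while remaining in
the range of a deeply sequenced small fungal genome. The two physical pool
libraries are modelled as the one merged pool sample that was analysed.
Mapping bias, indels and multi-allelic sites are out of scope — the
analysis is SNP-only.

## Variant filters and the conservation scan

A variant is **validated** in a sample iff depth ≥ 20 and alt frequency
≥ 0.7, both inclusive, with no quality filtering; zero-depth sites are
skipped and logged. The **inter-parental SNP set** comprises sites
validated as alt in exactly one parent; sites alt in both are shared
variants against the reference and are excluded.

The **conservation scan** orients every SNP to the trait (mutagenized)
parent's allele: the scanned quantity is the pool frequency of that
parent's allele regardless of which parent happens to differ from the
reference. Classification thresholds are `fully_conserved ≥ 0.995`,
`high ≥ 0.95`, else `unlinked`. The source analysis distinguishes
"completely conserved" from "~98%" without naming cutoffs; these defaults
are chosen so that 78/78 and 77/78 land in the intended classes and both
are configurable. When pool member genotypes are available (simulation
truth), genotype-level conservation is preferred over the read estimate for
classification; the read estimate is always reported alongside. The 0.3
pool frequency floor is a reporting flag, not a classifier input. No
multiple-testing control is applied — the method uses absolute
conservation, not a test statistic; an exact binomial deviation-from-0.5
p-value per SNP is emitted as auxiliary output only.

**Candidate ranking**: conservation class first, then consequence
(missense/nonsense, then intronic, then synonymous/intergenic — synonymous
changes are grouped with noncoding because they are not candidate effects),
then descending conservation, then (chrom, pos). Coding effects are
computed on the strand-oriented CDS with the standard genetic code;
reverse-strand genes complement the forward-strand alleles (VCF
convention). Coordinates are 1-based fully closed throughout, matching
GFF3.

## Linkage analysis

Origin codes in the genotype table are **phenotype-scored**, as segregants
are scored on plates: the color channel cannot distinguish a fawn double
mutant from a plain fawn segregant, so the fwnA and olvA columns are
complementary and the color pair shows zero nonparental segregants even
when double mutants exist. Phase is defined by the supplied parents, never
inferred from majority class. r = NPS/N × 100 is reported as computed; a
value above 50% is flagged (`phase_suspect`) rather than clamped. The
segregation test is the two-sided exact binomial test against 1/2 (sum of
all outcomes no more likely than the observed one), via
`scipy.stats.binomtest`. Multipoint mapping and map-distance functions are
deliberately absent: the design uses only two-point recombination
fractions.

## The synthetic fixture

The fixture reconstructs the mapped cross deterministically from a seed:

- Toy karyotype: 8 chromosomes (I: 1.2 Mb with centromere at 500 kb;
  II: 3 Mb; III–VIII: 300 kb). Real chromosome lengths are not reproduced;
  only chromosome II needs room for the published coordinates.
- Toy genes: a single-exon laeA on chromosome II whose codon 327 is GCC
  with its first base at position 1,762,101; a two-exon fumR hosting an
  intronic SNP (exercising the coding-triage path); a prtT gene on
  chromosome VI whose Leu100 codon (CTA) carries the known T→C protease
  mutation (CCA, Leu→Pro). Sequence elsewhere is seeded random.
- 52 inter-parental SNPs: six on chromosome II from the mutagenized parent
  (three conserved — the causal missense, the fumR intronic site, one
  intergenic — and three distal sites spanning ~1.5 Mb in total), the prtT
  mutation, and 45 background SNPs spread evenly over the other seven
  chromosomes and split ~evenly between parents. Positions are synthetic;
  counts, classes and the causal coordinate are the constrained quantities.
- 140 segregants matching the published marker marginals exactly
  (64 fawn / 76 olive, 78 pyrG⁺, 64 argB⁺, 78 nonacidifying, 72
  protease-low), with exactly 2 fawn/olvA::pyrG double mutants and 2
  further chromosome-I recombinants forced by the argB marginal.
  Constrained chromosomes (I, II, VI) are built as deterministic class
  vectors and shuffled independently per chromosome (independent
  assortment); unconstrained chromosomes are fair coin flips. The marginals
  are matched by construction rather than free simulation because the
  plate-sampling rule that produced them (at most two differently colored
  sectors per plate) is not modelled.
- The pool is the 78 nonacidifying segregants and contains exactly one
  chromosome-II recombinant, with breakpoint placed between the causal site
  and the three distal linked SNPs: causal and proximal sites are conserved
  78/78, distal sites 77/78 (≈ 98.7%).

What the fixture does **not** emulate: real genome sequence and annotation,
read-level artifacts (mapping bias, base-quality structure, indels),
unequal pool member representation from mycelium mixing, aneuploid
intermediates, and the joint marker distribution beyond the constrained
cells. Passing tests therefore demonstrate the correctness of the
filtering, scanning, annotation and linkage logic under the stated
statistical model — not robustness to alignment artifacts in real data.

## Numerical and design choices

- All randomness flows through explicitly passed `numpy` Generators;
  fixture stages use fixed substreams of the configured seed, so identical
  seeds give byte-identical outputs (checksummed in the manifest).
- Filter boundaries are inclusive (≥ 0.7, ≥ 20) and tested exhaustively
  against a brute-force oracle over all (depth ≤ 40, alt) pairs.
- Zero-depth pool sites produce a record with missing frequency and a
  below-threshold flag rather than being dropped silently.
- Conservation ties in ranking break by genome order to keep output stable.
- Problem sizes in the statistical test suites — 200 replicate pools for
  the unlinked-50% check, 50 replicates for causal-SNP recovery, 10⁵ depth
  for read/genotype agreement — are chosen to put 3-standard-error bands
  well inside the tested tolerances while keeping the suite fast.

## Known limitations

- Only one crossover per chromosome per segregant is representable; double
  crossovers (negligible at the modelled rates) are not.
- The conserved-region span is reported as observed from the data (the
  fixture's linked SNPs span ~1.5 Mb); the pipeline does not attempt to
  reconcile differing published span figures.
- The per-sample application of the 0.7 validation threshold follows the
  more conservative reading of an ambiguous vendor-pipeline description.
- pyrG cannot be analysed as a physical locus in this cross (see above);
  its linkage column reflects the olvA::pyrG insertion.
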