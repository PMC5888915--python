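# Methods

## Genetic model

The design is an F1 pseudo-testcross: a seed parent heterozygous for a
dominant causal allele *W* (genotype *Ww*) crossed to a wildtype pollen
parent (*ww*), with progeny pooled by phenotype.  For a biallelic variant
locus at recombination fraction *r* from *W* in the seed parent, the
expected pooled variant-allele frequency is computed by exact enumeration of
the seed parent's four ordered gamete classes — (causal allele, variant
allele) with weights (1−*r*)/2 for parental and *r*/2 for recombinant
classes — conditioned on the progeny phenotype (carriers of *W* are mutant,
the trait being dominant), plus the pollen parent's unconditioned
transmission:

    freq(pool) = 100 · [ P(seed transmits variant | phenotype) + dose_pollen/2 ] / 2

where `dose_pollen` is the pollen parent's variant-allele count.  At *r* = 0
this yields 50/0 (type I `<lm×mm>`), 100/50 (type II `<lm×ll>`) and 75/25
(type III `<hk×hk>`) for the mutant/wildtype pools, each a 50-point
directional difference; at *r* = 0.5 both pools converge to the unlinked
expectation (25, 75 and 50 respectively).  The same enumeration handles the
non-informative types `<nn×np>` (25/25) and `<qq×qq>` (100/100).  The
candidate-type map behind `infer_candidate_types` (which segregation types
can produce each genotype group G1–G5) is our reconstruction from these
expectations; phase is encoded by the coupling convention rather than
enumerated as separate type symbols, and multi-allelic types (`<ab×cd>`,
`<ef×eg>`) are recognized as "complex" (G5) but not modelled quantitatively.

## Zygosity and genotype groups

A pool-level call is classified from its allele frequency: 15–80%
(inclusive) heterozygous, above 80% homozygous.  Calls below 15% are
classed low-frequency and excluded from genotype grouping (the upstream
read-count filters make such calls rare); excluded counts are always
reported.  The zygosity pair of a pool-common variant maps onto the groups
G1 (het/het), G2 (hom/het), G3 (het/hom) and G4 (hom/hom); three or more
distinct bases at a site across both pools make it G5.

## Filters

Stage one (post-detection): reference-allele calls, hyperallelic sites
(≥ 3 distinct alternate alleles), insertion/deletion calls inside a
reference homopolymer run (≥ 4 bases of the inserted/deleted base),
ambiguous reference bases (IUPAC M, R, W, S, Y, K) and the detection minima
(coverage ≥ 10, variant reads ≥ 2).  Stage two (pre-mapping confidence):
coverage ≥ 20, strand balance min(f, r)/(f + r) within [0.25, 0.5]
inclusive, unique read start positions ≥ 5.  Balance is defined on
variant-supporting reads so that 0.5 is perfect balance — the only reading
under which 0.5 is an upper bound.  The homopolymer run length (4) and
hyperallelic threshold (3) are not dictated by any published convention for
this pipeline; both are explicit `FilterConfig` parameters.  Removed calls
are attributed to the first failing filter in cascade order, so per-filter
counts plus survivors always equal the input.  The reference-allele and
homopolymer filters need the reference sequence; without a reference
context they are skipped with a warning and counted as skipped, never
silently applied.  Calls lacking strand or start-position evidence skip
those confidence metrics the same way.

## Genome scans

`moving_average` slides a fixed-count window (default 20 variants, step 1)
within each chromosome; the anchor is the mean position of the window's
members and chromosomes with fewer variants than the window yield no
profile.  `bin_density` uses non-overlapping bins (default 1 Mb) anchored at
position 1; the terminal partial bin is scaled by its true length and empty
bins are retained so they enter the significance baseline.  `z_test`
standardizes density as *z* = (X − μ)/σ with μ the mean over all bins
genome-wide and σ the population (divisor *N*) standard deviation — the
formula's source states no divisor, and divisor *N* is the deterministic
choice; a degenerate scan (σ = 0) sets all *z* to 0 with a warning.
Significance is inclusive (*z* ≥ 2.6, two-tailed normal *P* ≈ 0.01) and
regions are maximal runs of contiguous significant bins with no gap
bridging.  AFDD is strictly directional (mutant − wildtype); a `reverse`
switch recomputes with pool roles swapped as a control scan.  One published
figure caption pairs z = 5.1 with P = 3.4 × 10⁻⁶; the two-tailed normal
value at z = 5.1 is 3.4 × 10⁻⁷, and the package implements the formula, not
the printed pair.

No multiple-testing correction is applied beyond the fixed z cutoff, by
design.  A consequence worth knowing: the cutoff is multiplicity-blind, so
across B bins roughly B × 0.5% false single-bin peaks are expected under
the null (more at low per-bin counts, where Poisson skew thickens the upper
tail).  False peaks are isolated single bins; real loci produce multi-bin
clusters.

## The simulator

`simulate_cross` emulates the full experiment: variants of each segregation
type placed uniformly per chromosome at configurable densities; a random
phase (coupling of the variant allele with *W*, probability
`phase_linked_prob`, default 0.5); transmission with a crossover between
each variant and the causal locus at the Haldane fraction
r = (1 − e^(−2d/100))/2, d = `cM_per_Mb` × Mb (default 2.0 cM/Mb, a typical
plant genome-wide average); phenotype-based pooling (pools of 17 mutant and
16 wildtype progeny by default) with an optional misclassification rate and
an optional second causal locus that modulates penetrance (expressivity);
and read sampling with coverage ~ Poisson(depth, min 1, default 25×),
variant reads ~ Binomial(coverage, pooled allele fraction), balanced
binomial strand split, and a Poisson start-diversity model (mean 8) capped
at the variant read count.  Calls with zero variant reads are suppressed,
as a real caller would suppress them — this, not any explicit rule, is what
makes variants pool-specific versus common downstream.  All randomness
flows from one seed through a single `numpy` generator; identical
configurations give byte-identical outputs.

Default type densities (variants per Mb): type I 40, type II 10, type III
60, `<nn×np>` 190, `<qq×qq>` 30.  These emulate a heterogeneously
heterozygous woody-species cross sequenced at moderate depth: ~330
pool-common variants per Mb in total, with type II ~3% of common variants
and the double-homozygous class ~9%.  Recombination is modelled only
between each variant and the causal locus (no variant-to-variant linkage or
interference), which is sufficient for frequency-profile realism at 1-Mb
resolution but means local haplotype structure is absent.  The simulator
also omits sequencing error, mapping bias, uneven coverage between pools
and caller artefacts — the main sources of the pool-specific false
positives seen in real data — so passing tests demonstrate the method's
behaviour under clean Mendelian sampling, not robustness to caller noise.

## Behaviour near the causal locus at small genome scale

On the compact five-chromosome test genome, two interacting effects shape
the AFDDD scan around the causal locus.  Fully linked type I variants have
wildtype-pool frequency ~0, so their wildtype call is suppressed and they
leave the pool-common set; partially linked type I variants a few Mb away
(wildtype frequency r/2 > 0) are called in both pools and pass the
AFDD ≥ 30 selection.  The selected density therefore forms an annulus
around a relatively hollow causal bin, and with 20% of the genome linked to
the locus the genome-wide μ and σ are inflated.  The practical consequence,
measured over seeded replicates: the genome-wide peak bin always lies on
the causal chromosome within the linked neighbourhood, and no significant
bins appear on other chromosomes, but the single 1-Mb bin containing the
locus is usually not itself the peak.  At real genome scales (hundreds of
Mb, ~17 chromosomes) the linked fraction is far smaller and the causal
region stands out directly.  MAFD mapping is complementary here: the
mutant-specific set is dominated by tightly linked type I variants, so its
density peak covers the locus, at the cost of more false peaks in noisy
real data.

## Numerical and interface choices

Coordinates are 1-based inclusive internally (VCF convention); BED export
converts to 0-based half-open with score = 100·z clamped to [0, 1000].
Multi-allelic records are split into biallelic calls before any downstream
step; pool matching joins on the exact key (chromosome, position, class,
ref, alt), so the same position with different alternate alleles yields two
pool-specific records.  VCF indels are normalized to the dashed
variant-table representation (ref "−" for insertions, alt "−" for
deletions) so keys join across input formats.  Declared table frequencies
are cross-checked against count/coverage; discrepancies over 0.5 points are
logged and the recomputed value wins.  The Yates-corrected chi-square caps
the continuity term at |O − E| so tiny deviations cannot contribute
negatively; both corrected and uncorrected statistics are reported because
published segregation tests mix the two conventions.  Pipeline runs write a
manifest (version, parameters, input checksums, per-stage status) and never
overwrite a previous run without `force`.

## Test problem sizes

The simulation-backed tests use a 5 × 30 Mb genome at the default densities
and 25× depth for locus-recovery checks (20 seeded replicates), 1000
fully linked variants at 1000× depth for the pooled-frequency expectations,
and a 12-bin single-chromosome genome for the null-scan behaviour — sizes
chosen so the whole suite runs in well under a minute per property while
keeping per-bin counts in the regime the method targets.
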