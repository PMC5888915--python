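# afddmap

Segregation-type-aware pooled genome sequencing (BSA-seq) mapping of a
dominant trait in an F1 cross of two heterozygous, out-crossing parents —
the pseudo-testcross design typical of fruit trees and other woody species.

## The problem and the method

In bulked segregant analysis, two DNA pools are sequenced: progeny showing
the trait (the *mutant* pool) and progeny without it (the *wildtype* pool).
In an F1 cross of two heterogeneously heterozygous parents, a biallelic DNA
variant follows one of six segregation types (JoinMap-style notation, first
allele of the seed parent in coupling with the dominant causal allele *W*).
Three are informative for mapping *W*:

| type | configuration | expected pool frequency at full linkage (mutant / wildtype) |
|------|---------------|-----------------------------------------------|
| I    | `<lm×mm>`     | 50% / 0% — mutant-pool-specific |
| II   | `<lm×ll>`     | 100% / 50% — common to both pools |
| III  | `<hk×hk>`     | 75% / 25% — common to both pools |

All three share a directional allele-frequency difference (AFDD =
mutant − wildtype) of **50 percentage points** at full linkage. `afddmap`
implements the two genome scans built on this:

* **MAFD mapping** (mutant allele frequency and density): scans the
  mutant-pool-specific variants, profiling allele frequency in a moving
  window of 20 variants and the per-Mb density of variants with frequency
  in [40%, 60%].
* **AFDDD mapping** (AFDD and density): scans pool-common variants with
  AFDD ≥ 30 points the same way.

Density significance uses the standard score *z* = (X − μ)/σ on variants
per Mb over 1-Mb genome bins (μ, population σ over all bins genome-wide),
with an inclusive cutoff *z* ≥ 2.6 (two-tailed normal *P* ≈ 0.01).
Contiguous significant bins are merged into candidate regions.

Around the scans the package provides the full workflow: VCF / variant-table
ingestion (`DP`/`AD`, optional `ADF`/`ADR` strand counts and a documented
`USP` unique-read-start tag), the two-stage filter cascade (detection minima
coverage ≥ 10 and variant reads ≥ 2; confidence filters coverage ≥ 20,
strand balance 0.25–0.5, unique starts ≥ 5), pool comparison, pool-level
zygosity calls (15–80% heterozygous, > 80% homozygous), genotype groups
G1–G5, chi-square segregation tests (with and without Yates' correction),
and an F1 cross-and-pooling simulator with Haldane-map linkage and binomial
read sampling that makes every stage testable without sequencing data.

## Worked example

Simulate a default cross (five 30-Mb chromosomes, dominant causal locus at
chr3:15.5 Mb, pools of 17 mutant and 16 wildtype progeny, ~25× coverage)
and run AFDDD mapping:

```
$ afddmap simulate --out-dir sim --seed 11
wrote 49036 mutant and 49045 wildtype calls to sim

$ printf 'chr1\t30000000\n...chr5\t30000000\n' > layout.tsv
$ afddmap afddd --mutant sim/mutant.tsv --wildtype sim/wildtype.tsv \
      --layout layout.tsv --out-dir afddd
AFDDD: 1991/48582 variants selected, 3 significant region(s)
  chr3:9000001-10000000 peak z=2.75
  chr3:11000001-12000000 peak z=3.10
  chr3:18000001-19000000 peak z=2.92
```

Of 48 582 pool-common variants, 1 991 have AFDD ≥ 30 points; every
significant density region falls on the causal chromosome, bracketing the
simulated locus (see `docs/methods.md` for why the peaks flank rather than
cover the locus at this genome scale). `afddd/` holds the moving-average
profile, the per-bin density/z table and a BED6 file of regions
(score = 100·z).

Segregation statistics and z → p conversion:

```
$ afddmap segtest --counts 17,19
uncorrected	chi2=0.1111	p=0.739
yates	chi2=0.0278	p=0.868

$ afddmap ztest --z 2.9
z=2.9	p=0.0037
```

A 17:19 phenotype split is fully consistent with the 1:1 segregation of a
dominant single-locus trait.  The full pipeline (read → filter → compare →
groups → MAFD + AFDDD, with a run manifest) is `afddmap run --config
pipeline.yaml`.

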