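# Methods

## Codon optimality from tRNA pools

The decoding weight of sense codon *i* is

    W_i = Σ_j (1 − s_ij) · tGCN_j

over the anticodons *j* present in the pool that can decode *i*. Two
decoders are considered per codon: the Watson–Crick anticodon (the
codon's reverse complement, `s = 0`) and a single penalised wobble
decoder obtained by substituting anticodon position 34 (the 5' base,
which pairs the codon's third base):

| codon third base | wobble anticodon-34 | pairing | s (eukaryotic) |
|---|---|---|---|
| U | G | G:U | 0.7861 |
| C | A (read as inosine) | I:C | 0.4659 |
| A | A (read as inosine) | I:A | 0.9075 |
| G | U | U:G | 0.6295 |

I:U pairing (anticodon A34 against codon U) is treated as penalty-free,
so it is subsumed by the Watson–Crick term; no further special-casing
(e.g. for Ile/Met discrimination) is applied. All sequence handling is
in the DNA alphabet internally; RNA input is normalised on entry.

`W` is used raw. The classical normalisation (divide by max `W`,
geometric-mean substitution for zero-weight codons) is provided as a
reporting transform only: it is monotone within an amino-acid family,
so ranks, optimality classes and mutation directions cannot depend on
it.

**Ranking and classes.** Within each family, codons are ranked by `W`
descending, ties broken by alphabetical codon order (deterministic and
documented rather than meaningful). The high/low split takes the top
`ceil(family size / 2)` codons: 2 v 2 for four-codon families, 3 v 3
for six-codon families, 2 v 1 for Ile, and the single-codon families
(Met, Trp) are high. Under the standard code this always yields 32 high
and 29 low codons, independent of the pool — a structural fact the
tests assert for arbitrary pools.

**Directed pairs.** All ordered pairs of same-family sense codons
differing at exactly one position are enumerated; a pair is `tai_up`
iff `W(to) > W(from)`, `tai_down` for the reverse, `tie` when equal
(ties belong to neither selection class). Exhaustive enumeration over
the standard code yields 67 unordered (134 ordered) single-base
synonymous pairs. Published tables for maize report 87 tAI-changing
pairs without stating the counting convention; since 87 lies strictly
between the unordered and ordered exhaustive counts, no convention
reproduces it exactly, and the package reports its own enumeration.

**tRNA input.** GtRNAdb-dialect FASTA headers are parsed for the
anticodon (`tRNA-Ala-AGC-1-1` and the legacy `...-AlaAGC` form);
records with undetermined anticodons (NNN) are tallied separately and
excluded from decoding, unparseable records are skipped with a warning.
Records flagged as pseudogenes are counted by default (no filter is
implied by the weighting model); `--exclude-pseudogenes` removes them.
A two-column `anticodon<TAB>copies` TSV is accepted everywhere a pool
is needed.

## Codon usage weights and CAI

`w_ij` is the count of codon *i* in a reference gene set divided by the
maximum count among its synonymous codons, so `w_ij ∈ [0, 1]` with at
least one 1 per observed family. The reference set is the top half of
genes by RPKM (`read_count / (kb of CDS) / (millions of mapped
reads)`); the fraction is configurable because the underlying studies
do not state a threshold. Counting excludes the terminal stop codon and
any codon containing an ambiguous base; genes with internal stops or
non-triplet lengths are skipped with a warning. Codons of families
never observed in the reference set have *missing* (not zero) weights.

Gene CAI is the geometric mean of `w_ij` over the gene's sense codons.
Codons with zero or missing weight are skipped (their count is
reported) rather than collapsing the geometric mean to zero; a gene
with no scorable codon has undefined CAI.

## Polarization with two outgroups

Each focal CDS position of a three-way alignment is visited once.
Focal allele frequencies pass a band filter: alleles with frequency in
[0.02, 0.98] (bounds inclusive — "between" read inclusively and pinned
by boundary tests) are retained and renormalised; an allele above 0.98
makes the site monomorphic. The band absorbs sequencing error in
frequency tables derived from read data.

A site is then:

- **excluded** when the outgroups disagree, either outgroup carries a
  gap or N, either outgroup site is itself polymorphic, more than two
  focal alleles survive the band, or (two alleles) neither matches the
  shared outgroup base ("ancestral_not_segregating" — a double hit;
  the sources are silent here, exclusion is the conservative choice);
- **polymorphic** when two alleles survive and one equals the shared
  outgroup base: ancestral = that base, DAF = renormalised derived
  frequency;
- **fixed** when the focal site is monomorphic and differs from the
  shared outgroup base. Positions without frequency data are called
  from the reference alignment alone, mirroring alignment-based fixed
  calls; such ratios are known to be coverage-sensitive, which is why
  all contingency claims are comparative (up-class vs down-class).

MAF is the frequency of the second most abundant allele, computed from
the raw frequencies without outgroup information; tri-allelic sites
keep an MAF even though they are excluded from DAF analyses.
Polarization is symmetric in outgroup order. Every exclusion carries a
machine-readable reason, and the run manifest checks *site
conservation*: sites in = fixed + polymorphic + Σ excluded-by-reason.

Ortholog identification and alignment are upstream of this package;
the reader enforces strict 1:1:1 triples (`gene|focal`, `gene|out1`,
`gene|out2` records of equal aligned length).

## Functional annotation

Variants are classified by codon substitution in the focal CDS
(1-based CDS coordinates, coding strand, single-base bi-allelic
changes; multi-nucleotide variants must be decomposed upstream):
synonymous if the amino acid is unchanged, nonsense if either side of
the change is a stop codon (stop gain for polymorphic alternates, stop
loss for fixed differences whose ancestral codon was a stop), otherwise
nonsynonymous. Synonymous changes carry `ΔtAI` and `Δw_ij` with
up/down/tie directions; a missing usage weight yields direction
"missing". Reference mismatches are errors naming gene and position;
variants in the terminal stop codon and codons containing N are
rejected and counted.

## Selection statistics

- **Contingency**: 2×2 fixed/polymorphic table between mutation
  classes; two-sided Fisher exact p (hypergeometric tables-as-extreme
  summation, via scipy, verified against exhaustive enumeration in the
  tests); the sample odds ratio is reported (no conditional MLE — the
  comparisons are ratio-of-ratios, not effect estimation).
- **Spectra**: per-class DAF or MAF vectors with medians and two-sided
  Wilcoxon rank-sum tests for the standard contrasts (nonsense vs
  nonsynonymous, nonsynonymous vs each synonymous direction, up vs
  down). The exact null distribution is used for tie-free samples up to
  n1+n2 = 50 (a recurrence, not enumeration: full enumeration at n = 50
  would require ~1.3e14 labellings and is infeasible); tied small
  samples use full midrank permutation enumeration while
  C(n1+n2, n1) ≤ 2e5; all larger samples use the tie-corrected normal
  approximation with continuity correction. All tests are two-sided; no
  multiple-testing correction is applied by default (an optional
  Benjamini–Hochberg adjustment is exposed on the summary object).
- **Stratification**: genes split at the configurable top fraction
  (default half) of RPKM or GC; all contrasts recomputed per stratum;
  the effect-size contrast is the difference of up-minus-down median
  gaps. A constant stratifier is an error.
- **gBGC control**: the up-vs-down comparison restricted to A↔T and,
  separately, C↔G allele pairs. Neither substitution changes GC
  content, so GC-biased gene conversion cannot generate a spurious
  shift inside these subsets.
- **Nearest neighbour**: within each gene, every classified synonymous
  site is labelled by the direction of its nearest classified
  neighbour (absolute CDS distance, ties broken toward the upstream
  site); up-near-up vs up-near-down (and the down analogues) are
  compared by rank-sum test. Under hotspot-driven clustering the
  near-up and near-down spectra separate; under the null they do not.
- **Regression**: OLS of DAF or MAF on ΔCAI, ΔtAI and gene GC
  (complete cases; constant or collinear predictors flagged but
  reported), via statsmodels.
- **Correlation**: Spearman rho with tie-corrected p (scipy), used for
  GC~tAI, GC~structured%, tAI~structured% when a precomputed
  structured% column is supplied. RNA-structure prediction itself is
  out of scope.

## Synthetic data generator

The generator emulates the data *shape* of a codon-selection study:

- a tRNA pool over 52 of the 61 Watson–Crick anticodons with copies
  ~ 1 + Poisson(21), matching the scale of the maize pool (52
  anticodons, ≈23 copies each); emitted both as a GtRNAdb-dialect FASTA
  (one record per locus, so the parser is exercised) and a counts TSV;
- 60 genes of 120–400 codons (uniform), per-gene GC target uniform on
  0.35–0.65, valid ORFs (ATG start, single terminal stop);
- expression as Poisson read counts with lognormal(3, 1.2) per-gene
  rates, from which the pipeline recomputes RPKM;
- planted mutations per gene (Poisson means): polymorphic syn-up 2,
  syn-down 2, nonsynonymous 3, nonsense 0.3; fixed syn-up 8, syn-down
  5, nonsynonymous 6, nonsense (stop-loss) 0.1. The asymmetric fixed
  rates plant the up-class fixation excess at desk scale — the real
  genome-wide ratios (~115 vs ~69) arise from millions of divergent
  sites and are not reproduced numerically, only directionally;
- derived allele frequencies per class from Beta distributions:
  up (3, 3), down (2, 4) — the stated shifted-selection defaults —
  nonsynonymous (1.5, 4.5) and nonsense (1, 8) chosen so the class
  means order 0.50 > 0.33 > 0.25 > 0.11, the canonical
  deleteriousness ordering. Draws are redrawn into
  [0.025, 0.975] so planted sites always survive the band filter;
- planting rewrites the chosen codon to the `from` codon of a directed
  pair of the requested class (derived allele = the `to` base), so
  planted labels are exact by construction and the annotation round
  trip is a closed loop;
- outgroups equal the ancestral sequence except at planted fixed
  differences, planted exclusion sites (disagreement 1.0/gene,
  outgroup polymorphism 0.5/gene, outgroup gap 0.5/gene) and
  occasional outgroup-specific insertion columns (0.3/gene) that test
  the gap-aware column map;
- optional stratum interactions add a configurable shift to the up/down
  Beta parameters in the high-RPKM or high-GC stratum (default 0).

Everything is driven by one `numpy` Generator from the config seed;
outputs are byte-reproducible.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: linkage and recombination maps, demography
and shared genealogy (sites are independent; a Beta frequency model
replaces Wright–Fisher dynamics because the downstream claims are rank
and ratio statements, not parameter estimates), alignment error,
paralogy/orthology mistakes, read-mapping biases, and any coupling
between codon content and expression. Recovery on synthetic data
demonstrates the pipeline's bookkeeping and statistical machinery, not
the biological conclusion.

## Calibration studies and problem sizes

The acceptance script and test suite run, at sizes chosen to keep a
single-CPU run in seconds-to-minutes:

- detection power: Beta(3,3) vs Beta(2,4), n = 2,000/class, 100 seeds
  (observed: 100/100 detections);
- type-I error: identical Beta(3,3) classes, n = 200/class, 1,000
  seeds, nominal 5% ± 2% (the size of a rank test does not depend on
  n, so the smaller per-seed n only affects power, which is not under
  test here);
- OLS coverage: planted (0.5, 0.3, 0.05) with N(0, 0.3) noise at
  n = 5,000, 100 replicates, counting per-coefficient inclusion of the
  planted value in the ±2·SE interval. Note the nominal coverage of a
  2-SE interval is 95.45%, so the observed proportion over 300 checks
  carries ~1.2–1.7% sampling noise around a value only 0.45 points
  above a 95% reference line; single-seed outcomes between 92% and 98%
  are all consistent with correct calibration (the noise-free exact
  recovery test pins correctness of the estimator itself);
- nearest-neighbour null: 20 generator seeds with identical Beta
  parameters for all classes; the cross-class rank-sum tests must be
  non-significant in ≥90% of contrasts;
- full round trip: the default 60-gene study (~46,000 sites), on which
  100% of non-excluded planted sites must return the planted status,
  class, direction and DAF, and site conservation must hold exactly.

## Known limitations

- Fixed-difference calls at positions without frequency data assume
  the reference allele is fixed; low-coverage data therefore inflate
  fixed:polymorphic ratios in absolute terms (comparisons between
  classes remain valid, and the manifest records the calls).
- The wobble model is the standard eukaryotic four-penalty scheme;
  organisms with nonstandard decoding (e.g. organellar codes) are out
  of scope, as is tRNA gene prediction.
- The Fisher-test construction for base counts inside vs outside
  structured regions is exposed as the generic 2×2 contingency; no
  structure prediction is performed.
- CAI directions depend on the reference gene set; with sparse
  reference data, weights of rare families go missing and the affected
  synonymous sites are reported with direction "missing" rather than
  guessed.
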