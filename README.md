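# codonsel

Population-genetic analysis of selection on **synonymous mutations that
change codon optimality**, built for molecular-evolution studies in
plants (the default parameterisation mirrors maize, *Zea mays*) but
applicable to any species with the standard nuclear genetic code.

A synonymous substitution leaves the protein unchanged but can move a
codon between tRNA-rich and tRNA-poor decoding: it changes the codon's
tRNA adaptation index (tAI) and hence the local translation rate. If
faster decoding is favoured, optimality-increasing synonymous mutations
should (i) fix more often relative to how often they segregate, and
(ii) segregate at higher derived/minor allele frequencies, than
optimality-decreasing ones. `codonsel` implements that whole inference
chain:

1. **tAI** — for each sense codon *i*,
   `W_i = Σ_j (1 − s_ij) · tGCN_j`, summing over anticodons *j* able to
   decode *i*: the Watson–Crick decoder (reverse complement) with
   `s = 0` and one penalised wobble decoder at anticodon position 34
   (`s_G:U = 0.7861`, `s_I:C = 0.4659`, `s_I:A = 0.9075`,
   `s_U:G = 0.6295`; I:U pairing is penalty-free). `tGCN_j` is the tRNA
   gene copy number, parsed from a GtRNAdb-dialect FASTA or a counts
   TSV. Within each amino-acid family codons are ranked by `W` and
   split half/half into high/low optimality (odd family sizes round
   toward high: always 32 high / 29 low codons).
2. **CAI weights** — `w_ij` = codon count / max synonymous-codon count
   over the top-RPKM half of genes; gene CAI is the geometric mean of
   its codons' `w_ij`.
3. **Variant annotation** — single-base CDS changes classified
   synonymous / nonsynonymous / nonsense, with `ΔtAI = W_alt − W_ref`
   and `Δw_ij` directions for synonymous changes.
4. **Polarization** — two outgroups define the ancestral state; sites
   are *fixed* (focal base ≠ shared outgroup base, monomorphic),
   *polymorphic* (two alleles inside the 0.02–0.98 frequency band, one
   matching the outgroups; DAF = derived-allele frequency), or
   *excluded* with a machine-readable reason (outgroup disagreement,
   gap, outgroup polymorphism, ...). MAF needs no outgroups.
5. **Selection statistics** — fixed:polymorphic contingency with
   Fisher's exact test (McDonald–Kreitman logic), DAF/MAF spectrum
   contrasts with Wilcoxon rank-sum tests, stratification by expression
   or GC, GC-conservative (A↔T, C↔G) subsets that are immune to
   GC-biased gene conversion, a nearest-neighbour clustering null for
   recombination-hotspot artefacts, Spearman correlations, and OLS of
   allele frequency on (ΔCAI, ΔtAI, gene GC).
6. **Synthetic data** — a seeded generator that emits every input file
   the pipeline reads, with mutations planted from the directed
   codon-pair table and class-specific Beta allele-frequency models, so
   the full chain is validated without any download.

## Worked example

```python
from codonsel import SimulationConfig, simulate_dataset, run_on_dataset

ds = simulate_dataset(SimulationConfig(seed=42))      # 60-gene synthetic study
res = run_on_dataset(ds, "demo/inputs", outdir="demo/out")

m = res.manifest.counts
print(f"sites={m['sites_in']} fixed={m['fixed']} polymorphic={m['polymorphic']}")
c = res.contingency
print(f"ratio tAI-up={c.ratio_a:.1f} tAI-down={c.ratio_b:.1f} Fisher p={c.p_value:.3g}")
s = res.spectra["daf"]
print(f"median DAF up={s.median['syn_up']:.3f} down={s.median['syn_down']:.3f} "
      f"Wilcoxon p={s.p_values[('syn_up','syn_down')]:.3g}")
```

prints

```
sites=44721 fixed=1152 polymorphic=468
ratio tAI-up=4.0 tAI-down=2.2 Fisher p=4.8e-05
median DAF up=0.468 down=0.326 Wilcoxon p=2.3e-10
```

Reading: of 44,721 focal CDS sites walked through the three-way
alignments, 1,152 are fixed differences and 468 are polymorphic. The
tAI-increasing synonymous class fixes almost twice as readily as the
tAI-decreasing class (4.0 vs 2.2, Fisher p ≈ 5e-5) and segregates at
visibly higher derived allele frequencies (median 0.47 vs 0.33) — the
signature of weak positive selection on optimality gains that the
generator planted and the pipeline recovers.

The same run is available from the shell:

```bash
codonsel simulate --seed 42 --out demo/inputs
codonsel run --cds demo/inputs/cds.fa --alignments demo/inputs/alignments.fa \
    --alleles demo/inputs/alleles.tsv --trna demo/inputs/trna.fa \
    --expr demo/inputs/expression.tsv --out demo/out
codonsel spectra --sites demo/out/sites.tsv --metric daf
```

plus `codonsel tai`, `codonsel cai`, `codonsel regress`,
`codonsel neighbors` for the individual stages.

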