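# invclines

Detection, karyotyping and eco-evolutionary analysis of polymorphic
chromosomal inversions, built around the workflow used to study large
inversions in seaweed flies and similar systems.

A polymorphic inversion suppresses recombination in heterokaryotypes, so its
two arrangements (called **S** and **N** here, for the southern and northern
ends of a latitudinal cline) diverge and segregate like two alleles of a
single locus. That signature drives everything in this package:

* **`inversion_scan`** — sliding-window PCA along a chromosome. Inside the
  inverted interval PC1 splits samples into three clusters
  (SS / SN / NN, with the heterokaryotypes in the middle and maximally
  heterozygous); outside it PC1 follows ordinary population structure. The
  inversion is called as the longest run of windows with a supported,
  well-separated three-cluster structure, and karyotypes are assigned by
  k-means on the region PC1.
* **`popgen_stats`** — Hudson's FST (Bhatia form, ratio of averages,
  N = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1), D = p₁(1−p₂)+p₂(1−p₁))
  per site, in 25 kb windows and globally; IUPAC-aware pairwise divergence;
  and the ε = 0 minimum spanning network (the union of all minimum spanning
  trees of the haplotype distance graph).
* **`marker_design`** — diagnostic PCR-RFLP assays: karyotype-fixed coding
  SNPs (|freq(SS) − freq(NN)| ≥ 0.99) that create a restriction site on
  exactly one arrangement, with in-silico digestion and predicted gel
  patterns per karyotype, plus marker-vs-PCA concordance.
* **`cline_stats`** — arrangement frequencies with Wilson CIs,
  Hardy–Weinberg χ² tests, and aggregated binomial logit GLMs
  logit(p_S) = β₀ + β₁·x for x = latitude or temperature, with
  likelihood-ratio χ², deviance R² = 1 − D_resid/D_null, and Wald
  prediction ribbons.
* **`thermal_fitness`** — quadratic thermal performance curves
  (viability = a·T² + b·T + c) with closed-form rmax, Topt, CTmin/CTmax,
  tolerance and breadth; type-II binomial deviance analysis of
  karyotype × temperature × continent effects on viability.
* **`synthetic_data`** — generators reproducing the statistical structure
  all of the above assumes (Balding–Nichols continental background,
  recombination-suppressed arrangement haplotypes, logistic clines under
  HWE, binomial viability on a quadratic curve), with ground truth for
  recovery testing.
* **`io_formats`** — VCF/FASTA/GFF3/TSV readers and writers, site QC,
  and the packaged European location table and enzyme catalogue.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on synthetic
data plus the packaged location table; each writes tables under `results/`.

```sh
python analysis/01_simulate_dataset.py      # 240 diploids, 8 Mb chromosome
python analysis/02_scan_inversion.py
python analysis/05_cline_analysis.py
```

prints (abridged):

```
true inversion: 1,000,000-5,000,000; karyotypes SS/SN/NN = 65/109/66
called inversion interval: 1,000,000-5,000,000 (80 qualifying windows)
region PCA: PC1 48.99% of variance, PC2 0.50%
karyotype assignment vs truth: 240/240 concordant (100%), confidence=ok
10 locations; S frequency ranges 0.23-0.94
  OB: off HWE (chi2=4.11, p=0.0425), heterokaryotypes under-represented
  VE: off HWE (chi2=16.74, p=4.28e-05), heterokaryotypes under-represented
latitude: slope -0.11 (LRT chi2=100.44, df=1, p=1.2e-23, deviance R2=0.60)
temperature: slope 0.30 (LRT chi2=101.04, df=1, p=9e-24, deviance R2=0.61)
```

The scan recovers the simulated inversion interval exactly and re-derives
every karyotype from genotypes alone. On the real European count table the
S arrangement declines by ~0.11 logits per degree of latitude northwards
(equivalently rises by ~0.30 logits per °C of annual mean temperature) — a
steep, highly significant cline — and heterokaryotypes are significantly
under-represented at two of the ten locations.
`analysis/03_arrangement_divergence.py` and `04_design_marker.py` add the
FST contrasts (arrangements diverge at FST ≈ 0.63 inside the inversion
versus ≈ 0.13 between continents), the haplotype network, and an EcoRI
diagnostic assay whose predicted gel lanes separate all three karyotypes;
`06_thermal_performance.py` fits per-line thermal performance curves and
detects an opposite-sign karyotype-by-continent viability interaction.

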