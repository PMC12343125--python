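# fbdstrata

Analytics for comparing posterior distributions of fossilized birth–death
(FBD) dated phylogenies — in particular the comparison between a **resolved**
analysis (only taxa scored in a morphological matrix) and a **semi-resolved**
analysis (morphology plus occurrence-only taxa placed by genus-level
monophyly constraints, then pruned back to the shared leafset). Because the
occurrence-only taxa contribute nothing but stratigraphic age information,
the comparison isolates what fossil ages alone do to tree topology,
divergence-time precision and the informativeness of summary trees.

The package is aimed at palaeobiologists working with entirely extinct
clades (tip-dated analyses of trilobites and the like), where taxon
selection for morphological matrices is biased toward well-preserved
material and therefore violates the FBD assumption of uniform fossil
recovery.

## What it computes

* **Stratigraphic congruence** of a dated topology against first-appearance
  data (FADs). Under minimal node dating (each node as old as the oldest FAD
  it subtends), the summed ghost ranges give the minimum implied gap
  MIG = Σ over non-root branches of (t(parent) − t(child)), in myr.
  Its exact extremes over all rooted topologies are closed forms,
  Gmin = max(FAD) − min(FAD) and Gmax = Σᵢ (max(FAD) − FADᵢ), which yield the
  gap excess ratio GER = 1 − (MIG − Gmin)/(Gmax − Gmin). The stratigraphic
  consistency index SCI is the proportion of non-root internal nodes whose
  clade does not appear before its sister. An exhaustive topology-enumeration
  oracle (n ≤ 9) backs all three.
* **Treespace**: Robinson–Foulds and clustering-information distances,
  classical PCoA, an inverse-distance-weighted congruence "landscape",
  per-arm kernel densities and spread statistics (sum of variances, sum of
  ranges, mean centroid distance).
* **Summary-tree analytics**: majority-rule consensus and MCC trees, split
  information content h(s) = −log₂[(2a−3)!!(2b−3)!!/(2n−5)!!] bits, total
  consensus information (plain or support-discounted), and greedy rogue-taxon
  removal scored by consensus-information gain.
* **Precision**: exact shortest-window 95% HPD intervals for origin (root)
  ages and for every MCC clade's age across a sample, with percent-narrowing
  summaries between arms.
* **Synthetic data**: a constant-rate FBD simulator (λ, μ, ψ, origin time,
  ρ; sampled ancestors as zero-length pendants), genus assignment by a time
  horizon on the true tree, symmetric-Mk character matrices, abundance-biased
  morphology-taxon selection, stage-binning of occurrence ages with optional
  imprecision, and congruence-weighted pseudo-posteriors standing in for
  MCMC output — so the whole pipeline is testable without any download.

## Worked example

The numbered drivers under `analysis/` run the study end to end; the final
one executes the full two-arm comparison and prints:

```
$ python analysis/06_compare.py
arms: 120 trees each on 20 shared taxa
mean MIG: resolved 40.17 vs semi-resolved 37.87 myr (Mann-Whitney p = 2.29e-16)
mean GER: 0.846 vs 0.860; mean SCI: 0.750 vs 0.768
treespace sum of variances: resolved 8.148 vs semi-resolved 3.211
origin-age 95% HPD width: 3.18 vs 3.17 myr (0.2% narrower)
largest node-age HPD width: 2.33 vs 1.43 myr
report, tables and figures under .../results/analysis/report
```

Reading: both arms are evaluated on the identical 20-taxon leafset and equal
sample sizes. The semi-resolved arm — the one whose generation was
conditioned on stratigraphic ages — yields significantly lower implied gaps
(MIG) and higher GER/SCI, occupies a much tighter region of treespace
(sum of variances 3.2 vs 8.1), and halves the widest node-age uncertainty
(1.43 vs 2.33 myr). That is the qualitative signature expected when
occurrence ages constrain otherwise weakly supported parts of the tree.
`report.json` in the output directory contains every number above plus the
per-metric Holm-adjusted tests, the PCoA eigenvalue spectrum and the
consensus/rogue/MCC statistics per arm, validated against the shipped JSON
schema.

## Layout

```
src/fbdstrata/     library: simulate, trees, occurrences, congruence,
                   treespace, consensus, compare, splits
analysis/          numbered narrative drivers (01_simulate ... 06_compare)
scripts/           acceptance.py
tests/             pytest suite with enumeration/brute-force oracles
docs/methods.md    model, conventions, parameter choices, limitations
```
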