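# barcodepop

Analysis toolkit for COI DNA-barcode surveys of birds (or any
protein-coding mtDNA barcode): distance-based barcode-gap and
species-delimitation analysis, neighbor-joining phylogenetics with
bootstrap, haplotype networks, population differentiation (π, F<sub>ST</sub>), and a
degenerate-site diversity regression that tests for
population-size-scaled purifying selection.  A codon-aware synthetic-data
generator with full ground truth makes every stage runnable and testable
without downloading a single sequence.

It is written for molecular ecologists and barcoding practitioners who
normally stitch this workflow together from MEGA, DnaSP and POPART, and
want a scripted, reproducible, unit-tested equivalent.

## What it computes

**Kimura 2-parameter distances.** For a sequence pair with transition
proportion *P* and transversion proportion *Q* over the pairwise-comparable
sites,

> d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)

Pairs whose log argument is non-positive are flagged as saturated (NaN)
and excluded from summaries, never clamped.  The matrix decomposes into
intraspecific and interspecific summaries — both the all-pairs mean and
the mean of per-species averages are reported — and the barcode gap
(mean interspecific minus mean intraspecific distance, plus per-species
nearest-neighbour vs. maximum-intraspecific comparisons).

**Trees and delimitation.** Neighbor-joining (Saitou–Nei) with
deterministic tie-breaking, column-resampling bootstrap, outgroup
rooting, and per-species monophyly tests on unrooted bipartitions.  A
species is *confirmed* when it is monophyletic and shares no identical
(column-filtered) barcode with another species; deep intraspecific splits
(> 2% max intra by default) and low nearest-neighbour divergence (< 1%)
are flagged for inspection.

**Haplotype networks.** Alignment columns with any gap/ambiguity are
dropped, identical sequences collapse into haplotypes, and the network is
the minimum spanning network (union of all minimum spanning trees of the
Hamming graph).  `group_separation` gives the minimum number of
mutational steps between labelled groups — the "separated by 13 base
pairs" statistic of east–west phylogeographic splits.

**Population genetics.** Nucleotide diversity π (mean pairwise
differences per site) and the Hudson–Slatkin–Maddison fixation index
F<sub>ST</sub> = 1 − H<sub>w</sub>/H<sub>b</sub> on pairwise difference counts.

**Purifying selection.** Sites are classified 0-fold/2-fold/3-fold/4-fold
degenerate under the vertebrate mitochondrial code (NCBI table 2) on each
species' consensus in an auto-detected reading frame.  Since π at silent
4-fold sites proxies 2N<sub>e</sub>µ while π at 0-fold sites is exposed to
selection, more-effective purifying selection in larger populations
predicts a negative slope in the regression of log₁₀(π₀/π₄) on log₁₀(π₄),
reported with OLS coefficients and Kendall's rank correlation.

**Synthetic surveys.** `simulate()` draws a Yule species tree rescaled to
a target mean divergence (18%), coalescent samples within species with
per-species θ = 2N<sub>e</sub>µ centred at 0.4%, κ-biased stop-avoiding codon
evolution, optional deep east/west splits with an exactly known number of
separating substitutions, and an N<sub>e</sub>-scaled selection map
r(N<sub>e</sub>) thinning 0-fold mutations.  The truth JSON records the
species tree, per-species N<sub>e</sub>, r, θ and split sizes.

## Worked example

```python
from barcodepop import (SimulationConfig, simulate, pairwise_matrix,
                        summarize, barcode_gap, site_diversity,
                        selection_regression)

cfg = SimulationConfig(n_species=20, seed=7)
res = simulate(cfg)
print("n sequences:", len(res.aligned), " alignment length:", res.aligned.length)

m = pairwise_matrix(res.aligned)
s = summarize(m, res.aligned.species_labels)
print(f"intraspecific K2P mean: {100*s.intra_mean:.2f}%  "
      f"interspecific: {100*s.inter_mean:.2f}%")
_, gap = barcode_gap(s)
print(f"barcode gap: {100*gap:.2f}%")

records = [site_diversity(sp, [r.sequence for r in recs], frame=0)
           for sp, recs in sorted(res.aligned.by_species().items())
           if len(recs) >= 2]
fit = selection_regression(records)
print(f"selection regression: slope={fit.slope:.3f} (p={fit.slope_p:.3g}), "
      f"Kendall tau={fit.tau:.3f} (p={fit.tau_p:.3g}), n={fit.n} species")
```

prints

```
n sequences: 119  alignment length: 660
intraspecific K2P mean: 0.52%  interspecific: 17.46%
barcode gap: 16.94%
selection regression: slope=-0.529 (p=0.0478), Kendall tau=-0.524 (p=0.136), n=7 species
```

The 20-species survey shows the classic barcode gap (within-species
divergence two orders of magnitude below between-species divergence), and
even at 7 usable species the π₀/π₄ ratio already declines with π₄ — the
footprint of drift-sensitive purifying selection.  At the default survey
size (90 species, ~30 usable) the slope is negative with high
significance in essentially every run.

A study-shaped end-to-end run (validate → distances → tree → delimit →
networks/F<sub>ST</sub> → selection) is available from the shell:

```bash
barcodepop simulate --seed 1 --out data/
barcodepop run --config run.yaml          # paths, outgroup, thresholds, seed
```

Real alignments are analysed the same way: supply an aligned FASTA plus a
TSV with `seq_id`, `species` and optional `population` columns.

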