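# Methods

This note documents the statistical models, estimators, numerical choices
and limitations behind `barcodepop`, in the spirit of a package manual's
"models" chapter.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Distances

The Kimura 2-parameter model distinguishes transitions (A↔G, C↔T;
observed proportion *P*) from transversions (*Q*) and corrects for
multiple hits:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

*Deletion policy.* Columns containing anything but A/C/G/T (gaps, N,
IUPAC ambiguity) are excluded per pair ("pairwise deletion", the
barcoding norm, maximizing data use); a "complete" policy that drops such
columns globally is available as a switch.  Consequence: two
non-identical sequences can have distance 0 under pairwise deletion,
which is why barcode *sharing* is defined by exact identity on filtered
columns, not by zero distance.

*Saturation.* When 1−2P−Q ≤ 0 or 1−2Q ≤ 0 the estimator is undefined; the
pair is reported NaN with a flag and excluded from every mean with a
logged count.  Clamping to a large finite value would bias the
interspecific mean downward or upward arbitrarily, so it is never done.

*Estimator variants.* The global intraspecific mean is computed over all
conspecific pairs; the mean of per-species averages is co-reported,
because published summaries rarely say which of the two they used.
Species with fewer than two sequences contribute no intraspecific data.

The all-pairs matrix is assembled from one-hot encodings with BLAS
products (counts are exact integers well below float32's 2^24 limit), so
a ~550-sequence alignment takes well under a second; the scalar
`k2p_distance` performs identical arithmetic and the tests assert
agreement to 1e-12 against a 50-digit Decimal evaluation.

## Neighbor-joining, bootstrap, monophyly

Standard Saitou–Nei agglomeration on the Q-criterion, with three explicit
numerical choices: (1) ties in the Q minimization break on the lowest
(i, j) index pair, making runs bit-reproducible; (2) negative branch
lengths — possible on non-additive input — are clamped to zero with the
excess transferred to the paired branch at the same junction, and logged;
(3) the final three taxa are resolved by the three-point formulas.  On
additive matrices the true tree is recovered exactly (tested to 1e-9 on
random instances, and cross-checked against scikit-bio's independent NJ
implementation).

Bootstrap resamples alignment columns with replacement; support for each
internal bipartition of the point tree is the percentage of usable
replicate trees containing it.  Replicates whose resampled matrix has a
saturated pair are skipped and logged.  1000 replicates by default
(configurable); the full pipeline run in the acceptance script uses 50,
which is sufficient to separate strong from weak edges at desk scale.

Monophyly is evaluated on unrooted bipartitions: a tip set is
monophyletic iff some edge isolates exactly that set; singletons always
are.  Rooting places the root at the midpoint of the outgroup's pendant
or stem edge and preserves total branch length.

Zero-length regions deserve a caveat: when several identical sequences
span species boundaries, any binary resolution is arbitrary, so
delimitation lets the shared-barcode flag outrank the paraphyly flag
(sharing is the diagnostic signal; the paraphyly is its consequence).

## Haplotype networks

Columns with any unresolved character are removed first (so "steps" count
only universally resolved sites, and the kept-column map allows auditing
the dropped sites); identical sequences then collapse into haplotypes
with deterministic ids (frequency-descending, then first member id).  The
network is the ε = 0 minimum spanning network: an edge belongs to it iff
its endpoints are not connected using strictly cheaper edges (the cycle
property), implemented as a Kruskal pass that processes one weight class
at a time.  Tests verify equality with the exhaustive union of all
minimum spanning trees.  Median-joining networks (which add inferred
median vectors) are out of scope; for the separation statistic — the
minimum Hamming distance between two labelled groups — the MSN and the
raw haplotypes give the same answer, and `group_separation` computes it
directly.

## Population genetics

π is the mean over sequence pairs of per-site differences under pairwise
deletion.  F<sub>ST</sub> follows Hudson, Slatkin & Maddison (1992):
F<sub>ST</sub> = 1 − H<sub>w</sub>/H<sub>b</sub>, where H<sub>w</sub> is the *unweighted* average of the two
within-population mean pairwise difference counts and H<sub>b</sub> the mean count
between populations.  Choices and consequences:

- Populations of size 1 contribute no within term; H<sub>w</sub> averages the
  populations with ≥ 2 sequences (logged).
- H<sub>b</sub> = 0 makes the index undefined: NaN with a
  "no between-population variation" flag.
- Small negative values are possible and preserved.  In the extreme case
  of comparing a population with an exact copy of itself the estimator
  gives exactly −1/(n−1) — the between term includes self-matches — which
  vanishes with sample size; the unit tests pin this behaviour down, and
  random re-splits of one pool centre on zero.

## Degenerate-site diversity and the selection regression

Under the vertebrate mitochondrial code (NCBI translation table 2:
AGA/AGG stops, ATA = Met, TGA = Trp), a codon position is *k*-fold
degenerate when *k* of the four nucleotides there encode the same amino
acid; a change producing a stop codon never "preserves" the amino acid.
Exactly 32 sense codons have a 4-fold third position, which the tests
verify against an independently transcribed code table.

The reading frame is detected per species by translating the
majority-rule consensus at all three offsets and requiring a unique
stop-free offset; ties or stop-containing minima raise an error demanding
an explicit frame (a real COI fragment in frame has no internal stops).

Degeneracy is assigned on the species consensus; columns whose class
differs among the codons actually observed in that species — or that fall
in an observed stop codon or ambiguity — are excluded, so polymorphic
codon context never mixes classes.  π₀ and π₄ are computed by
restricting the alignment to each class's columns; species with zero
diversity at either class are excluded from the regression (their log
ratio is undefined).

The regression is OLS of log₁₀(π₀/π₄) on log₁₀(π₄), with Kendall's tau
on the same vectors.  Two documented caveats, by design not "corrected":
π₄ appears on both axes, so even a neutral null induces some negative
correlation (the simulation tests quantify the selection-model slope as
clearly more negative than this artifact alone produces); and the log
base (default 10) does not affect the slope sign or tau.  2-fold/3-fold
sites are classified but unused, mirroring the 0-fold/4-fold contrast.

## The synthetic survey generator

The generator emulates a large passerine COI survey; its defaults are the
study conditions for every simulation-based test.

| parameter | default | meaning |
|---|---|---|
| `n_species` | 90 | ingroup species count |
| `sample_size_range` | (1, 11) uniform | per-species samples, mean 6 |
| `n_codons` | 220 (660 nt) | COI barcode fragment length |
| `inter_divergence` | 0.18 | mean tip–tip species-tree path (subs/site) |
| `min_species_divergence` | 0 | optional floor on species separation |
| `mean_intra_pi` | 0.004 | target mean intraspecific distance |
| `ne_spread` | 100 | N<sub>e,max</sub>/N<sub>e,min</sub> (log-uniform) |
| `deep_split_fraction` | 0.05 | species with east/west splits |
| `deep_split_range` | (0.02, 0.04) | split depth (subs/site) |
| `kappa` | 8 | transition/transversion rate ratio (mtDNA-like) |
| `selection_exponent` | 0.5 | r(N<sub>e</sub>) = (N<sub>e</sub>/N<sub>e,min</sub>)^−0.5 |
| `mu` | calibrated | per-site per-generation mutation rate |

*Species tree.* Pure-birth (Yule), rescaled so the mean tip–tip path
equals the divergence target.  With `min_species_divergence` set, half
the floor is added to every pendant branch after rescaling the rest to
(target − floor), preserving the mean while bounding the closest species
pair — used to build "clean" datasets whose gap dwarfs the delimitation
thresholds.  Note that without the floor a Yule tree produces some
near-zero sister divergences, so a minority of simulated species pairs
can share haplotypes or interdigitate — a realistic property of recent
radiations, and the reason the acceptance report's monophyly fraction
sits below 1.

*Sequences.* The ancestor is a uniform draw over the 60 sense codons
(frame 0, stop-free).  Mutations are a continuous-time process: events
pick a site uniformly and a target base with transition bias κ among the
targets that do not create a stop codon, so every event substitutes and
the substitution count per branch is exactly Poisson(branch × L).  The
stop-avoidance couples positions within a codon, so the process is a
Markov chain on sense codons rather than pure K80 — at 18% divergence the
K2P estimator reads the true substitution count about 1% low.  The
generator therefore records, per replicate, a tree-exact expectation of
the realized interspecific K2P mean, computed by pushing every pair's
true path (species-tree path + expected coalescent tip depths +
deep-split offsets) through the matrix exponential of the sense-codon
chain, including the delta-method finite-length curvature of the
estimator.  Monte-Carlo tests compare realized means against these
expectations at 3 standard errors.

*Within species.* Samples coalesce on a Kingman genealogy (no
recombination — mtDNA); mutation rate per coalescent unit is θ<sub>i</sub>/2 per
site with θ<sub>i</sub> = 2N<sub>e,i</sub>µ.  N<sub>e,i</sub> is log-uniform; µ is calibrated in closed
form (numerically integrated over the N<sub>e</sub> distribution, including the
selection thinning, the deep-split contribution and the K2P curvature) so
that the expected all-pairs intraspecific mean equals `mean_intra_pi`.
Setting µ explicitly rescales the whole molecular clock instead
(µ = 0 collapses all variation); an unattainable calibration (deep-split
contribution alone exceeding the target) raises an informative error.

*Selection.* Candidate mutations at sites that are 0-fold in the species
ancestor are accepted with probability r<sub>i</sub> = (N<sub>e,i</sub>/N<sub>e,min</sub>)^−0.5, a
deterministic rate-scaling shortcut for fixation-probability dynamics.
It yields E[π₀/π₄] ≈ r<sub>i</sub> per species and, across species, the negative
log–log slope the analysis is designed to detect.  No selection is
applied on species-tree branches (between-species divergence is fixed by
the rescaling anyway).

*Deep splits.* A deep-split species gets "east"/"west" subpopulations:
the west founder differs from the east founder at exactly k randomly
chosen 4-fold sites (silent, stop-free), each group's first sample
carries its founder haplotype, and within-group mutations avoid the split
sites — so the minimum Hamming separation between the groups equals k
exactly, giving downstream tests (and the 13-step demonstration) an exact
oracle.  Anchoring the founder slightly reduces within-group diversity
relative to a plain coalescent; the calibration accounts for it.

*What the generator does not emulate.* Rate variation among sites beyond
the 0-fold/4-fold contrast, base-composition heterogeneity and strand
bias, indels and alignment error, ambiguity codes and missing data
(simulated data are fully resolved; the filtering and pairwise-deletion
code paths are exercised by hand-built fixtures instead), selection on
synonymous sites, migration and admixture, and finite-sample GenBank
quirks (misidentified specimens).  Passing the simulation tests therefore
demonstrates correctness of the estimators and pipeline logic under the
model, not robustness to every property of field data.

## Pipeline and reproducibility

`run_all` composes validate → census → distances → tree → delimitation →
per-focal-species networks/F<sub>ST</sub> → selection regression, writing
TSV/Newick/GraphML/JSON outputs plus one summary JSON.  All randomness
(bootstrap, simulation) flows from explicit seeds; re-running with the
same seed reproduces the summary byte for byte.  Any stage failure halts
with the stage name and cause; referenced species are checked against the
metadata before any computation.

Problem sizes in the acceptance script — the default 90-species survey,
50 bootstrap replicates, a 30-seed recovery suite — were chosen as
desk-scale renditions of the survey design, keeping the full run in the
single-digit minutes on one CPU.

## Known limitations

- NJ on matrices with many exactly tied or zero distances resolves
  arbitrarily (deterministically, but arbitrarily); monophyly conclusions
  for species involved in barcode sharing should be read through the
  shared-barcode flag, not the tree.
- The K2P saturation boundary makes distances above ~0.35 (κ-dependent)
  increasingly unstable; comparisons among uniformly random sequences are
  beyond the model's validity and are rejected as saturated.
- `detect_frame` assumes a single reading frame across the alignment span
  of a species and no frameshift indels.
- F<sub>ST</sub> significance testing (permutation), AMOVA and migration-rate
  inference are out of scope, as are Bayesian tree inference, model
  selection and median-joining networks.
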