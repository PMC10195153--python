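# Methods

`contevo` analyzes two-phase evolution experiments: replicate populations
founded from clones that previously adapted along distinct *adaptive
pathways* (here, *rho*- vs *rpoB*-mutant backgrounds of *E. coli*, plus an
unevolved ancestor control) are evolved in a new environment, and the
question is whether their phenotypic (relative fitness) and genotypic
(mutation identity) outcomes are contingent on that history.

## Relative fitness

A competition assay mixes an evolved line E with a reference competitor A,
grows them together for one cycle, and counts colonies before and after.
Relative fitness is the ratio of realized doublings,

    w_r = log2(N_f^E / N_i^E) / log2(N_f^A / N_i^A),

dimensionless, 1 = neutral. It is invariant to a common dilution of all
four densities and maps to its reciprocal when the competitors' roles are
swapped. Densities must be positive and the reference must actually change
density (denominator nonzero); violations raise rather than returning NaN.

Deviation-from-1 tests use a Shapiro–Wilk screen at α = 0.05: a one-sample
t-test when normality is not rejected, otherwise a one-sample Wilcoxon
signed-rank test. Degenerate samples (all values equal) are flagged with an
undefined p rather than silently tested.

## Variance partitioning

`nested_anova` fits sequential (Type-I) sums of squares with pathway
entered first and founder nested within pathway; reported fractions are
SS / SS_total, which are non-negative and sum to one with the residual.
F-tests follow the classic nested layout: pathway MS over
founder-within-pathway MS, founder MS over residual MS. This denominator
choice is deliberate — pathway effects must be judged against founder-level
variation, not replicate noise, when founders are a sample of possible
genotypes. One founder per pathway collapses the design; the nested term is
then dropped with a warning.

`kruskal_eta2` is the nonparametric companion: Kruskal–Wallis H with the
effect size η²_H = (H − k + 1)/(n − k), clipped at zero.

`ancova_pathway` fits w_r ~ founder-fitness covariate + pathway by least
squares and reports the pathway p from Type-II (order-independent) sums of
squares, i.e. adjusted for the covariate. Type-I output in statsmodels
reorders categorical terms ahead of numeric covariates, which would silently
un-adjust the pathway test; Type-II avoids that trap and is equivalent to
the coefficient test for a two-level factor.

`founder_slope_regression` regresses per-population fitness change on
founder fitness, per pathway, reporting both OLS (with p for slope = 0) and
a major-axis Model-II slope (the first principal axis of the covariance
matrix) since both variables are measured with error. Which Model-II
estimator best matches published slopes is generally unknowable from a
paper's methods; both are always reported and nothing is tuned to match.
Slope heterogeneity between pathways is an F-test on the OLS interaction
term.

## Mutation tables and filters

The interchange format is a plain TSV, one row per mutation call per
population, with region ids at the gene level ("geneA/geneB" for intergenic
spans). Thresholds follow the field's wording exactly: *segregating* keeps
frequency ≥ 5% (inclusive), *fixed* keeps frequency > 85% (strict), and
founder-origin (phase-1) records are excluded from phase-2 mutation sets.
Presence–absence matrices collapse multiple hits in one region of one
population to a single 1; populations with no qualifying mutations keep
their (all-zero) rows, which matters for fixed-mutation similarity.

`check_founder_inheritance` verifies that every founder-defining mutation is
fixed (> 85%) in every descendant population; violations are the standard
cross-contamination red flag.

## Contingency statistics

Dice's similarity coefficient DSC(A, B) = 2|A∩B| / (|A|+|B|) is computed
between the mutated-region sets of all population pairs. A pair of empty
profiles has no defined similarity; such pairs are excluded from averages by
default (an explicit policy can score them 0 instead — the choice only
matters for fixed-mutation profiles, where empty profiles occur).

The randomization test contrasts mean within-pathway DSC against mean
between-pathway DSC. The null permutes population → pathway labels — the
exchangeable unit — and recomputes the contrast; p is the proportion of null
statistics ≥ observed, reported both raw (can be 0) and smoothed as
(b+1)/(B+1). Ancestor-control pairs are excluded from the two-pathway
contrast but summarized per comparison class. When fewer than 10 distinct
label arrangements exist the test enumerates all of them exactly and says
so. Shuffling the similarity values themselves (rather than labels) is
available behind a flag but is not the default, since pair similarities
sharing a population are not exchangeable.

ANOSIM is Clarke's rank statistic R = (r̄_between − r̄_within)/(M/2) on the
condensed distances, M = n(n−1)/2, average ranks over ties; p is
permutational with the (b+1)/(B+1) convention, so the smallest attainable p
at 9,999 permutations is 1e-4. R is invariant under any strictly monotone
transform of the distances. The implementation is authored here for seeded
determinism; tests cross-check it against scikit-bio's to machine precision.

Per-region enrichment builds, for each region mutated in at least one
population of either pathway, a 2×2 table of (populations with/without a
mutation) × pathway and applies the two-sided Fisher exact test (summing
hypergeometric tables with probability ≤ observed). The FDR family is all
regions tested in the run, adjusted by Benjamini–Hochberg.

Mutation-type spectra are compared with a chi-square homogeneity test that
switches to a seeded Monte-Carlo p (≥ 10,000 draws conditional on the
margins) when any expected cell is below 5.

## Distances and trees

Distances between binary profiles are Euclidean: sqrt(#differing regions).
Neighbor-Joining follows Saitou–Nei with the standard Q-criterion. Pinned
conventions, chosen for reproducibility: Q ties break by lexicographic
taxon-id order (a node's id is its smallest leaf name); negative branch
lengths are clamped to zero with the deficit moved to the sister branch so
path lengths are preserved, raw values kept in a side channel; the tree is
left unrooted (trifurcating root node). On exactly additive matrices NJ
recovers the generating topology and branch lengths exactly, which the test
suite verifies on random 5–8 taxon trees. Newick output sorts children
lexicographically and quotes names containing `/` or other metacharacters.

## Synthetic-data generator

The generator emulates the statistical structure of the study design so
every stage can be exercised and calibrated offline:

- **Design:** 2 pathways × 5 founders × 6 replicate populations plus 12
  ancestor controls, with the observed extinction pattern (4 lost from one
  rpoB founder, 2 from another, 1 control) → 65 surviving populations.
- **Mutation counts:** Poisson per population, mean 21 (the study reports
  ~22 for rpoB-descended and ~20 for rho-descended populations). Real data
  may be overdispersed relative to Poisson; the per-population variance is
  not reported, so Poisson is the assumption.
- **Regions:** each pathway has a disjoint module pool (default 12 regions)
  and all populations share a background pool (default 40); a phase-2
  mutation lands in the founder's pathway module with probability
  `module_hit_prob` (default 0.15), else in the background. Ancestor
  controls draw only from the background. Defaults were set by a
  back-of-envelope to put mean pairwise DSC near ~0.3 with a small
  within-pathway excess, the regime of the emulated study. Region ids are
  opaque; ~55% are intergenic spans ("gA/gB"), ~5% pseudogenes.
- **Frequencies:** three-component mixture — 45% in [0.05, 0.10) (the
  study's "almost half below 10%"), 8.5% above 0.85 ("fixed", 119/1387),
  the rest mid-range Beta-distributed.
- **Founder genotypes:** each founder carries its pathway gene plus two
  private marker regions, injected at frequency 1.0 into every descendant —
  so the inheritance check passes by construction and fault-injection tests
  can corrupt it deliberately.
- **Fitness truth:** per-founder true w_r values default to the study's
  printed per-founder means (vs ancestor at 19 °C, vs founder at 19 °C and
  42.2 °C), plus a per-population N(0, 0.02) deviation so replicate
  populations differ. Competition assays Poisson-sample colony counts
  around an expected plating depth (default 500 colonies/plate, reference
  doublings log2(100) per daily 100-fold dilution cycle); a plate with zero
  colonies flags the assay as failed rather than emitting a zero count.

What the generator does **not** emulate: genome-wide mutational hotspots
shared across all pathways (which inflate between-pathway similarity in
real data), linkage between mutations within a population, clonal
interference dynamics, founder-specific (as opposed to pathway-specific)
gene modules, and overdispersed mutation counts. Consequently, passing
tests demonstrate the statistics are computed correctly and are calibrated
under the stated null — not that real data will show any particular effect
size. In particular, the planted modular signal shows up more strongly in
the DSC contrast than in ANOSIM-on-Euclidean-distances, because Euclidean
distances are dominated by per-population mutation-count variation.

## Numerical and design choices

- Single `numpy` Generator per simulation, threaded through all draws;
  bit-exact reproducibility per seed.
- Permutation p-values: raw proportion and (b+1)/(B+1) smoothed are both
  reported for the DSC test; ANOSIM uses the smoothed convention only.
- A sum of squares below 1e-20 × Σw² is treated as exactly zero so constant
  responses report zero variance fractions instead of floating-point fuzz.
- Frequencies are validated into [0, 1] at parse time with the offending
  row number; unknown enum values are rejected rather than coerced.
- The default test suite and the acceptance script run the full design at
  its natural size (65 populations); calibration loops use a reduced design
  (12 populations, 199-permutation tests, 200 replicates) — sizes chosen to
  give binomial standard errors around 1.5 percentage points on a 5%
  rejection rate.

## Known limitations

- The ANOSIM permutation loop is O(B · n²) in pairs; fine for tens of
  populations, not intended for thousands.
- The adapter story for variant-caller output is a documented TSV schema,
  not a parser for any specific caller's native files.
- No phylogenetically corrected convergence statistics, PERMANOVA, or
  Mantel tests; no tree-based hypothesis tests (the NJ tree is descriptive,
  association is tested by ANOSIM).
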