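# Methods

`neolith` re-implements, as a tested library, the population-genetic tool
chain used to ask whether the first Central European farmers (the
Linearbandkeramik, LBK) descend from local Mesolithic hunter-gatherers who
adopted agriculture (cultural diffusion) or from immigrant Near Eastern
populations (demic diffusion), using mitochondrial HVS-I haplotypes.  This
note records the models implemented, the parameter choices that matter, the
numerical decisions, and what the synthetic data can and cannot show.

## Haplotype model

A haplotype is a set of single-base substitutions relative to the revised
Cambridge Reference Sequence (rCRS), indexed by 1-based nucleotide position
(np).  Windows are inclusive on both ends: the full HVS-I window is np
15997–16409 (413 sites); sequence-based statistics trim to np 16069–16365 so
ancient and modern records span the same alignment.  (The trimmed window
holds 297 positions; the distance and simulation machinery uses the
conventional 377-site HVS-I locus length for per-site rates, matching how
the original analyses were parameterized.)  The empty set is the reference
motif; "n.d."/"Ambiguous" parse to an *absent* value distinct from the
reference.  Insertions and deletions are rejected: none occur in the data
this package embeds, and coordinate-anchored substitution sets make
haplotype identity a set comparison, with no alignment step.

Haplogroup labels are binned into 19 frequency categories (preHV, H, HV, J,
T, I, N1a, K, V, W, X, U2, U3, U4, U5a, U5b, pooled African L/M1, pooled
East Eurasian A/B/C/D/F/G/Z, and a residual class) by longest-prefix match,
so "U5a1a" goes to U5a before U, "HV" to HV rather than H, and "R0" joins
preHV.

The package ships the printed source data as typed fixtures: the Derenburg
graveyard table (26 individuals, 22 with HVS-I haplotypes), the pooled
haplogroup-frequency columns, the observed pairwise F_ST matrix, and the
published per-model AIC values.  The reference sequence used to materialize
sequences in tests is a deterministic synthetic 413-base segment
(`synthetic_reference`); because variants are positional, any fixed A/C/G/T
string is a valid coordinate anchor, and no download is required.  Analyses
of real data can load an actual rCRS segment from FASTA instead.

### Known inconsistencies in the printed source data

The 22 printed haplotypes give a sharing partition of 8 unique / 4 pairs /
2 trios and haplotype diversity h = (22/21)(1 − 42/22²) = 0.9567, matching
the printed h = 0.957 and the printed sharing counts.  The printed DEB22
frequency entries for H (13.64%) and T (13.64%) do **not** match the
haplotype table (2/22 rCRS carriers → 9.09% H; 4/22 T+T2 → 18.18% T).  The
package always reports values computed from the haplotype table and leaves
the frequency-column discrepancy documented rather than reconciled.

## Diversity statistics

Haplotype diversity is the unbiased estimator h = n/(n−1)(1 − Σp_i²) over
distinct trimmed haplotypes.  Tajima's D uses the textbook constants with S
the number of segregating sites and π the mean pairwise difference count;
multi-allelic positions count one segregating site, and a position carried
by two individuals with different alleles counts one pairwise difference.
D is undefined (None) at S = 0.  Because haplotypes are complete over their
window by construction, there is no missing-data handling inside these
statistics.

Kin deduplication keeps, for each repeated haplotype, the carrier with the
lexicographically smallest id (the published reduction does not state which
duplicate was kept; the choice cannot affect haplotype-level statistics).
Applied to the embedded graveyard sample this removes 8 of 22 individuals,
matching the published LBK42 → LBK34 reduction rule.

## Shared-haplotype analysis

Modern populations are pooled and subsampled without replacement to a fixed
target size (default 500, keeping only pools that reach it, the published
panel rule), deterministically per seed.  A pivot table of exact-identity
hit counts over the trimmed window drives a three-way classification of the
query haplotypes: *unique* (present in no pool), *noninformative*
(present in at least 75% of pools — the declared operationalization of
"found at high frequency in nearly all present-day populations"; the
original quantitative rule is unstated, so the threshold is a surfaced
parameter), *informative* (the rest).  Sharing percentages per pool are
carriers-of-shared-haplotypes over pool size; enrichment is tested with a
pooled-variance two-proportion z test (two-tailed, raw p, no
multiple-testing correction, matching the original analysis; a Bonferroni
flag exists in the CLI layer); confidence intervals are percentile
bootstrap over pool members (default 100 replicates).

## Distances, F_ST, ordination

Sequence distances are Kimura two-parameter with continuous-gamma rate
heterogeneity, shape a = 0.205 (the conventional HVS-I value):

    d = (a/2)[(1−2P−Q)^(−1/a) − 1] + (a/4)[(1−2Q)^(−1/a) − 1]

with P and Q the transition and transversion fractions.  Saturated pairs
(log arguments ≤ 0) are NaN by default; a "clip" policy floors the counts
half a site away from saturation so that AMOVA components stay finite in
simulation pipelines (simulation clouds occasionally contain saturated
pairs), and a "raise" policy errors.  Pairwise F_ST is the two-level AMOVA
variance-component estimator on the pairwise distance matrix (distances as
squared deviations), the estimator family used by the original software.
Negative estimates are reported as computed; note that two copies of an
identical sample give exactly −1/(n′−1), not 0 — the estimator is unbiased
around zero, not non-negative.  The same gamma correction is applied to
within- and among-population terms.

Nei's standard distance D = −ln I on 19-category frequency vectors, with an
infinite-distance marker for orthogonal vectors (capped before MDS,
cap surfaced as a parameter).  PCA is classical, column-centered on raw
frequencies (a flag standardizes for correlation-matrix PCA); loadings are
exported for biplots.  MDS is metric least-squares (SMACOF) initialized
from Torgerson classical scaling, deterministic given the seed; raw stress
and Kruskal stress-1 are both reported.

Geographic surfaces interpolate Nei distances from a reference sample by
inverse-distance weighting (power 2) over great-circle distances, 0.5°
cells over 30–75°N / −15–65°E, 2,000 km search radius, exact at cells
containing a data point.  The original mapping software's algorithm is
unpublished; IDW is the canonical gene-geography surface method and is
stamped into output metadata.  Display classes use a run of 0.02-wide
"green" intervals from zero and geometrically widening intervals (factor
1.6) beyond — the widening rule is a declared stand-in for an unquantified
published legend.

## Serial-coalescent simulator

Backwards-in-time coalescent over demes; Ne is the haploid female-lineage
size (mtDNA), so the pair-coalescence hazard with k lineages in a deme of
size N(t) is k(k−1)/(2N(t)).  Forward exponential growth at rate r gives
the backwards trajectory N(t) = Ne0·e^(−rt); waiting times under growth are
drawn exactly by inverting the time-rescaling integral.  Growth rates are
deterministic functions of the present-day size ("dependent growth rates"):
r = ln(Ne0/N_anc)/T so the deme hits the ancestral size N_anc exactly at
time T.  Events are instantaneous: fusion (all source lineages move to the
sink — the backwards view of a population split), pulse migration (each
source lineage moves with the given probability — backwards view of a
one-generation migrant contribution), resize (re-anchors size/growth, used
to hold the ancestral deme constant).  Serial samples enter the active set
at their age; samples scheduled at the same instant as an event are added
first, so the LBK sample taken at the migration time participates in the
pulse.

Mutation is finite-sites over L = 377 positions at 7.5×10⁻⁶ per site per
generation, with i.i.d. mean-1 gamma(0.205) site-rate multipliers redrawn
per simulation, Poisson mutation counts on branches, and a 15:1
transition:transversion bias (mtDNA control-region behavior; the original
simulator's emission model is not published, so the bias is a configurable,
stamped default).  Transitions flip to the complementary base within the
purine/pyrimidine class; transversions pick uniformly between the two
cross-class bases.  The root state is a fixed arbitrary sequence.

The built-in model suite (generation time 25 y):

| model | structure | priors |
|---|---|---|
| H0a | one deme, growth from 5,000 females starting 300 generations ago | Ne0 ~ U(10⁵, 3×10⁷) |
| H0b | as H0a with growth from 1,500 generations ago | Ne0 ~ U(10⁵, 3×10⁷) |
| H1  | NE and CE demes, both growing from 5,000 at 1,500 generations, fusing at 1,500 into a constant 5,000 deme | two Ne0 ~ U(10⁵, 1.2×10⁷) |
| H2_25/50/75 | H1 plus a pulse at 290 generations moving 25/50/75% of the CE deme's ancestry to the NE deme | two Ne0 ~ U(10⁵, 1.2×10⁷) |

Sampling groups: modern CE (n = 1,030) and NE (n = 737) at time 0; LBK
(n = 42) at 290 generations in the CE deme; hunter-gatherers (n = 20) at
320 generations (≈ 8,000 y; their sampling age is not published — it is a
configuration knob reported in output).  The summary statistic is the
ordered five-vector of pairwise F_ST values (HG–NE, HG–CE, LBK–NE, LBK–CE,
LBK–HG) computed with the same K2P+gamma AMOVA machinery as the observed
side.

### Desk-scale sampling design

Full-scale simulation (1,829 lineages) costs about a second per genealogy;
the rejection analyses below need hundreds of thousands of genealogies, so
the package defines a reduced sampling design for simulation studies
(`DESK_SAMPLES`: CE 40, NE 30, LBK 15, HG 8) and the acceptance experiments
use an ancient-lineage-weighted variant (CE 30, NE 30, LBK 30, HG 20) —
ancient group sizes dominate the noise of every summary statistic, since
each of the five involves an ancient sample.  F_ST estimates are
approximately unbiased in sample size, so desk-scale simulation clouds
center where full-scale clouds do; they are simply wider.  Problem sizes
for every experiment are stated in the test/script docstrings.

## ABC and model comparison

Rejection ABC samples priors uniformly, simulates one summary vector per
draw, and retains the top fraction (default 1%) by unweighted Euclidean
distance on raw F_ST values (no normalization is applied by default, none
being described for the original analysis; a variance-scaled option
exists).  Posterior summaries report median, Gaussian-KDE mode, and central
intervals.

The original pipeline re-ran the simulator at the maximum-likelihood
parameter values and extracted a likelihood from it; the internal
likelihood definition is not published.  The package's declared stand-in:
the "maximum-likelihood" point is the minimum-distance retained draw, and
lnL is the log of a product-Gaussian kernel density estimate (per-dimension
Silverman bandwidths, logged in output) over `n_reps` fresh simulated
summary vectors, evaluated at the observed vector.  AIC = 2k − 2lnL with k
the number of free (prior) parameters — 1 for H0a/H0b, 2 for H1 and each
H2 variant; migration fractions are fixed model constants, not priors.
Akaike weights are ω_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2).

Feeding the six *printed* AIC values (two decimals) through the weight
formula reproduces the printed weights to the precision those rounded
inputs support: all six to better than 0.5% relative, the two dominant
weights to ~4 significant figures.  Six-figure agreement is not possible
from the printed inputs, which were evidently derived from unrounded AICs.

### The model-recovery experiment

The self-consistency experiment generates an observed vector under H2_50 at
known parameters (Ne0 = 1.5×10⁵ for both demes — well inside the prior and
in the strong-drift regime where the scenarios are distinguishable at a
single locus) using the **full published sampling design**, then runs the
comparison pipeline desk-scale.  Because HVS-I is a single locus, one
simulated genealogy can be entirely uninformative (realized drift near
zero); the experiment therefore defines the observed vector as the mean of
ten independent full-scale draws — an estimate of the model's central
summary at the true parameters, which is the quantity a recovery experiment
should target.  With 5,000 simulations and 500 likelihood replications per
model, the demic-diffusion family (H2_25+H2_50+H2_75) is expected to carry
the majority of total Akaike weight in most seed replicates.

A qualitative re-analysis feeds the printed observed F_ST vector to the
same pipeline (10,000 simulations per model) and examines the published
*ordering* — the H2 variants beating H0a, H0b and H1 on AIC.  Exact
reproduction of the printed AIC values is not attainable on a desk: it
would require the unpublished internal likelihood of the original simulator
and its full 100,000-genealogy budgets.  At desk scale even the full
ordering is only sporadically reproduced: the printed LBK–HG value
(0.09298) sits in the far tail of every model's summary distribution (as
the original analysis itself observed, no model accounts for it), where
the kernel likelihood estimate is dominated by a handful of simulations,
and the one-parameter continuity models carry a fixed AIC advantage of 2
that routinely covers the residual likelihood gap.  What replicates
robustly is the equal-parameter head-to-head that carries the scientific
conclusion: every demic-diffusion variant fits better than the
cultural-diffusion model H1, with the 75% migrant fraction best among
them, as printed.

## Synthetic data

Modern comparative pools are emulated, not reconstructed: each of the 19
haplogroup categories gets a fixed founder haplotype at reserved, disjoint
positions (np 16090–16165 block; alleles always off-reference), and members
derive from their category founder by Poisson-many private substitutions at
positions above the founder block.  Category identity is therefore
recoverable from any haplotype, and every generator returns a ledger (per
member category and canonical key, planted-haplotype counts) sufficient to
recompute each downstream statistic by direct counting — the universal
oracle used by the sharing tests.

What the generator does **not** emulate: within-category phylogenetic
substructure, sequence-level affinity between categories (all founders are
equidistant), missing data, and damage-driven errors.  One visible
consequence: on composition-only panels, the hunter-gatherer vs modern-CE
F_ST is inflated relative to the real data (where modern Central Europeans
carry U5 sequences genuinely close to Mesolithic lineages), so the
"LBK–HG largest of all five" feature of the printed matrix reproduces only
in its LBK-centric part (LBK closest to NE, farthest from HG).  Passing
tests on synthetic panels validate the bookkeeping and the statistics, not
the historical inference.

## Numerical and engineering choices

- Sequences are encoded A=0, G=1, C=2, T=3 so transition/transversion
  classification reduces to three small Gram-matrix products over variable
  columns; K2P transforms go through a lookup table over the integer
  (transition, transversion) count grid.
- The coalescent event loop buffers its exponential/uniform draws; mutation
  placement uses inverse-CDF sampling and materializes sequences only for
  branches that actually mutate.
- Distance calibration tests that compare against closed-form oracles run
  at mild divergence, away from the K2P saturation boundary.
- Seeds: every stochastic routine takes an explicit seed or Generator;
  derived seeds use `numpy` SeedSequence spawning and stay below 2³¹.

## Limitations

- Single-locus inference: all demographic conclusions ride on one
  genealogy's realized drift; the recovery experiment quantifies this.
- The likelihood stand-in (KDE at the observed point) carries O(h²)
  smoothing bias; it cancels approximately in model *comparisons* but makes
  absolute AIC values incomparable to the printed ones.
- No recombination, no continuous migration, no selection; pulse/fusion
  events suffice for the implemented scenarios.
- The sharing classification threshold (75% of pools) is a surfaced default
  for an unpublished rule; sensitivity to it should be reported alongside
  any real analysis.
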