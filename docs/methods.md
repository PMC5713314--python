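# Methods

## The gene set regularity model

Every gene set is summarized per sample by the fraction of its gene pairs
whose within-sample expression ordering agrees with a **rank template**
learned from normal-tissue controls.  The template is the per-pair majority
vote: bit $b_{ij}=1$ iff gene $i$ exceeds gene $j$ in strictly more than half
of the control samples.  We use the per-pair majority rather than the modal
total ordering: it is well defined for any number of controls, maximizes the
mean control matching score pair by pair, and is the construction of the
differential rank conservation family of statistics.  When the template is a
total order, the score equals $1 - d_K/\binom{G}{2}$ with $d_K$ the Kendall
distance between sample and template orderings.

Deterministic tie conventions (both covered by fixtures):

* equal expression values within a sample fail the strict test
  $x_{g_i} > x_{g_j}$, so a tie matches only a template bit pointing the
  other way;
* an exactly even control vote sets the bit by lexicographic gene order and
  is logged.  Even votes occur with probability ~0 for continuous data and
  odd control counts; the rule only matters for small, even control groups.

Templates are learned per tissue: the endometriosis arm uses endometrium
controls, the two carcinoma arms use ovarian controls.  Scoring is applied
to *all* samples, controls included, so control-group summary statistics are
available.

Cross-dataset integration keeps the intersection of gene universes and
rejects an integration that drops the common-gene count below a threshold
(default 8000, matching genome-scale platforms; the synthetic pipeline
passes an explicit desk-scale threshold).  Gene sets are pruned to available
genes and dropped below 2 members, so the usable collection size emerges
from the platform rather than from a hard-coded list.

## Statistical testing

Per gene set, case and control GSR values are compared with a two-sided
Mann–Whitney U test: exact enumeration when $n_1 n_2 \le 400$ and the pooled
values are tie-free, otherwise the normal approximation with tie and
continuity corrections (GSR values are lattice-valued at resolution
$1/\binom{G}{2}$, so ties are the norm at realistic sizes).  Adjustment
across the collection is Benjamini–Hochberg; significance defaults to
q < 0.01, with a switch for the raw-p reading since "significance < 0.01
after FDR correction" is ambiguous between the two.  Ranking is by ascending
p with lexicographic tie-break, top-10% selection takes
$\lfloor 0.1\,m \rfloor$ terms (an absolute top-k override exists), and Venn
partitions are computed exactly over 2 or 3 diseases.

An important numerical fact shapes everything built on ranks: at
$n_1=40, n_2=100$ the asymptotic two-sided p of a completely separated set
saturates near $10^{-20}$ (z ≈ −9.2 up to the tie-correction term).  Ranks
*among* saturated sets therefore carry no effect-size information — they
reflect tie structure only.  The synthetic design below is spaced with this
in mind, and real-data interpretation of fine rank differences among
extremely significant sets deserves the same caution.

## Synthetic cohorts

The generator emulates the ordering structure the statistic consumes and
nothing more.  Gene $g$ has a fixed baseline $\mu_g \sim U(0,10)$ drawn once
per study (continuous, so the canonical ordering is strict); a sample is
$\mu_g + N(0, \sigma)$ with $\sigma=1$ by default, which yields control-group
functionome means near 0.9 — comparable to genome-scale microarray cohorts.
Deregulation of a set in a case sample permutes the values of a random
$\lceil f\,|S|\rceil$-subset of its members within that sample.  Because GSR
is ordering-based, mean shifts that preserve order are invisible; the
scramble fraction $f$ is the effect-size dial, and mean case GSR decreases
monotonically in $f$ (checked over $f \in \{0, .25, .5, 1\}$).  At $f=1$
with no noise, case GSR has expectation 0.5 — the uniform-permutation
pair-match rate.

The default three-disease study is desk-scale: 2000 genes, 200 sets of 8–12
genes, 40 cases/100 controls per arm (half the scale of typical curated
multi-series cohorts, preserving the case:control proportion), platform
coverage 0.90–0.95 per arm to force common-gene integration.  Three tiers of
deregulated sets are planted:

* 8 ES-only sets at f = 0.7;
* 10 shared-cancer sets at f = 0.5 in CCC and EC;
* 6 "transformation" sets graded f = 0.3 (ES) → 0.9 (CCC, EC).

The spacing is deliberately wide because of the p-saturation effect above:
the transformation sets saturate in the carcinomas (ranks 1–6) while in ES
they sit clearly below the saturated ES-only tier (ranks ≥ 9), so their
upward rank movement from ES to both cancers is a property of the
construction, not of tie-breaking.  Set sizes are kept in a narrow band
(8–12) for the same reason — saturation onset depends on set size.  Two
consequences of uniformly drawn gene sets are worth knowing when reading
test output: overlapping sets leak deregulation into nominally null sets
(a null set sharing genes with a planted one shows a mild case-GSR drop),
and a set whose baselines happen to cluster has a weak template and low
power regardless of $f$.  Both effects also exist in real GO collections.

What the generator does **not** emulate: probe/batch effects, platform noise
models, control-group heterogeneity across series, and a latent factor
structure among deregulated terms (per-sample scrambles are independent
across sets, so deregulated terms co-vary only through gene overlap).  The
factor-analysis machinery is therefore validated on explicit factor-model
data, not on the cohort generator; passing tests demonstrate the
*machinery*, not that real functionomes have few factors.

## Pattern recognition

Supervised: linear-kernel SVM (cost C = 1, the common default of
kernel-method toolkits) under stratified 5-fold cross-validation repeated 10
times with reshuffled folds.  Sensitivity, specificity and accuracy are read
off the cumulative confusion matrix (SDs across repeats); AUC is computed on
held-out decision values pooled over all folds and repeats, which equals the
exact pair-concordance statistic on those scores.  Stratification stabilizes
small-class folds; `--no-stratify` restores plain random folds.  Multiclass
uses one-vs-one linear SVMs and reports correct/total.

Unsupervised: per-group mean GSR profiles are clustered agglomeratively with
Euclidean distance and complete linkage — the documented defaults of the R
`hclust`/`heatmap.2` stack this mirrors — returning merge heights, leaf
order and the reordered profile matrix.

## Factor analysis and GO-tree summarization

Input is the significant (q < 0.01) terms' GSR submatrix.  The factor count
comes from Horn's parallel analysis: observed correlation eigenvalues
against the 95th percentile of eigenvalues from 100 same-shape standard
normal datasets, counting consecutively from the top.  Extraction is
principal-axis factoring: communalities start at squared multiple
correlations and iterate to tolerance 1e-4 (max 100 iterations); Heywood
communalities are clipped with a warning.  Oblique rotation is promax with
power 4: varimax pre-rotation, sign-preserving powered target, per-factor
least squares, column normalization, factor correlations
$\Phi = (C^\top C)^{-1}$.  Communalities are invariant under the rotation to
1e-6.  Terms are assigned to every factor with |loading| ≥ 0.4 (the
conventional salient-loading cutoff; configurable, since the element counts
reported for real cohorts cannot pin it down), multi-assignment allowed.

Merged factor elements are summarized on the GO DAG by a deterministic
formalization of "offspring cluster under common ancestors": build the
ancestor closure of the terms (is_a edges only), take connected components
of the induced subgraph, and label each component by its minimal common
ancestors — the lowest closure terms that are ancestors-or-self of every
member.  Per-factor mapping is available; merged is the default.

## Progression filter

A term is progressively deregulated when all hold (strict inequalities
throughout, matching the "less/more than" reading):

1. significant in ES, CCC and EC (same scale as the deregulation tables);
2. |rank_CCC − rank_EC| < 100;
3. (rank_CCC + rank_EC)/2 < 300;
4. rank_ES − rank_CCC > 0 **and** rank_ES − rank_EC > 0 — the conjunctive
   reading of "difference of ranks between ES and CCC or EC more than 0",
   chosen because the narrative requires upward movement into *both* cancer
   lists; `cancer_rank_mode="or"` gives the disjunctive reading;
5. case-mean GSR depressed: mean_CCC < mean_ES and mean_EC < mean_ES — the
   prose condition, implemented as an explicit criterion and toggleable.

The filter is monotone in its thresholds (relaxing 100 → 150 or 300 → 400
can only grow the passed set).  The core transformation functions are the
intersection of passed terms with the factor elements coexisting in all
three diseases, ordered by mean rank.

## Mutual-information network

Pairwise dependence between set-level GSR vectors over the merged CCC+EC
case samples (controls excluded by default — the network describes disease
pathogenesis; a toggle includes them) uses the first
Kraskov–Stögbauer–Grassberger estimator with k = 3 (its canonical choice),
max-norm neighborhoods, and seeded Gaussian jitter of SD 1e-10 to break the
lattice ties of GSR values; estimates are clipped at 0 and exactly tied
inputs without jitter are an error.  The edge floor defaults to the 95th
percentile of a permutation null (MI between randomly chosen columns after
shuffling one).  ARACNE pruning applies the multiplicative
data-processing-inequality rule — edge (i,j) is removed if some k gives
$MI_{ij} < \min(MI_{ik}, MI_{jk})(1-\varepsilon)$ with tolerance
ε = 0.05 — with all removals decided against the original matrix and applied
simultaneously, so the strongest edge of a triangle is never removed.  The
largest connected component (ties by smallest member name) is exported as
GML with per-node deregulation flags.

## Determinism and problem sizes

Every stochastic step takes an explicit seed (numpy `default_rng`);
`run-all` with a fixed seed is byte-identical across runs (sorted JSON keys,
fixed float formats, no timestamps).  Test and demonstration runs use the
desk-scale defaults above; the acceptance script runs the full study in a
few seconds.  Reported empirical claims in this note (saturation behaviour,
recovery rates, monotonicity) are exactly the properties the test suite
computes; no real-cohort numbers are reproduced here because the original
multi-series microarray inputs are outside the package's scope.

## Known limitations

* The per-pair majority template reduces richer rank-conservation machinery
  (phenotype-specific template comparison) to the control-template variant;
  nothing else is implemented.
* Probe-to-symbol collapsing is upstream and unspecified; inputs must be
  symbol-keyed and complete (missing values are rejected, not imputed).
* GSR's ordinal conversion loses magnitude information by design; effects
  that preserve orderings are invisible.
* Fine rank differences among saturated (fully separated) sets are tie
  noise; the progression criteria are meaningful only when effect grading
  keeps the relevant sets off the saturation floor.
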