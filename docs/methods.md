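# Methods

## Model and statistic

The unit of analysis is the parent–child dyad. Each subject contributes
one feature vector per modality; similarity between child *i* and parent
*j* is the Pearson correlation S(i, j) of those vectors, computed over
whatever feature mask is in force (per-vector mean and SD are taken over
the masked entries only). The identification statistic is the winning
rate: for each child, the fraction of the N−1 stranger parents whose
similarity is exceeded by the child's own parent, with ties given half
credit; accuracy is the mean over children. Under exchangeability
(no dyad structure) each stranger comparison is a fair coin, so the
expectation is exactly 50% for every N — this is the property that makes
accuracies comparable across cohorts and subgroups of different sizes.
The equivalent Monte-Carlo formulation (draw a random child and a random
stranger parent, score own-vs-stranger) is provided and converges to the
same value; the conventional rank-1 identification rate (own parent must
be the strict row maximum; ties at the maximum share credit) is included
as the baseline with chance level 1/N.

Ties in similarity receive half credit rather than a loss. This keeps
the null expectation at exactly 50% even on degenerate inputs; for
continuous data ties have measure zero, so the choice cannot affect
realistic analyses. Identification is child-centric by default (a child
is compared against all parents); the parent-centric direction is
available via `direction="parent"`.

An important subtlety: "stranger" is defined by parent identity, not by
matrix position. Bootstrap resamples may contain the same dyad twice,
and a duplicate copy of the child's own parent must not be scored as a
stranger (it would tie by construction and drag a perfect cohort below
100%). The winning rate therefore excludes same-identity columns from
each child's comparison set.

## Resampling inference

**Bootstrap CI.** Each iteration draws floor(0.9·N) dyads and recomputes
the statistic on the restricted similarity matrix; the 95% interval is
the 2.5th/97.5th percentile over 1,000 draws (default). Draws are made
**with replacement** (an m-out-of-n bootstrap). We first implemented
plain 90% subsampling without replacement and measured its calibration
on replicate null cohorts (N = 84, 200 features): its intervals covered
the 50% chance level in only 43 of 100 replicates, because deleting 9 of
84 dyads barely perturbs the statistic and the draw spread underestimates
sampling variability several-fold. With-replacement draws of 0.9·N cover
in 95 of 100 replicates. The without-replacement variant is retained
behind `replace=False` as a sensitivity option. Degenerate resamples
consisting of a single repeated dyad (possible in very small subgroups)
are redrawn.

**Permutation test.** The null shuffles the parent–child mapping with
independent uniform permutations (fixed points allowed — the standard
exchangeability null; derangements would bias the null slightly). Since
Pearson correlations between fixed vectors do not depend on the mapping,
a shuffle is implemented as a column permutation of the precomputed
similarity matrix, making nulls cheap even for many features. P-values
use the add-one convention p = (1 + #{null ≥ observed})/(1 + n_perm), so
p is never zero and the floor 1/(n_perm+1) is attained exactly when the
observed value beats every draw. Per-network analyses generate a
separate null per feature mask, so networks of different sizes are
judged against their own reference distributions.

**Paired comparisons** across network-level accuracy profiles (the 10
networks plus whole brain, df = 10) use the two-sided paired t-test with
a paired-difference Hedges g: g = J·mean(d)/sd(d), sd with denominator
n−1, J = 1 − 3/(4·df − 1). The variant of Hedges g used in the original
analyses is not documented anywhere we could verify, so the
paired-difference (d_z) form was chosen and is stated here explicitly.
Identical inputs return the degenerate t = 0, g = 0, p = 1; constant
non-zero differences are an error (t undefined).

**Best-modality count.** When one modality wins "best accuracy" in k of
n (network × age) cases, the null model awards each case uniformly among
the three modalities and refers the winner's count to the null
distribution of a single candidate's count (the binomial tail; 15 of 22
gives p ≈ 9·10⁻⁴). A selection-corrected variant using the maximum count
over candidates is available (`null_statistic="max"`); it is roughly
three times more conservative at these sizes.

**Similarity-profile correlation** between two modalities correlates the
own-dyad similarities (matrix diagonals) across dyads; its p-value
shuffles one diagonal's dyad order (two-sided on |r|, add-one).

## Edge measures

Products are computed on per-subject z-scored vectors (each subject's
masked vector centered and scaled by its own mean and n−1 SD). The raw
product of unstandardized vectors is scale-dominated and does not relate
to the Pearson similarity the rest of the framework ranks; after
standardization Σ_f φ_ii(f)/(M−1) equals the dyad's similarity exactly,
so DP and φ̄ decompose the quantity actually being classified. Raw
products remain available (`standardize=False`).

P_i(f) counts, over both comparison directions, how often a stranger
product exceeds the dyad product, divided by 2(N−1) — each dyad faces
exactly N−1 strangers per direction. A clean sweep (raw probability 0)
is floored at 1/(2(N−1)), i.e. treated as "less than one losing
comparison", keeping DP = Σ_i −ln P_i finite. DP is non-negative and
zero iff every dyad's P_i is 1.

Percentile selection is count-based: the top ⌈(1 − p/100)·M⌉ values with
ties at the cut included, so the 99.75th percentile of 35,778 edges
selects 90 edges and of 400 features selects exactly 1. Node selections
can be summarized per anatomical lobe as (#selected nodes in lobe) /
(#atlas nodes in lobe).

## Preprocessing filters

All filters operate on extracted feature tables or framewise-
displacement (FD) series; image-level preprocessing is out of scope.

* **Scrubbing** removes, for every frame with FD > 0.5 mm, the frame
  itself, its predecessor and its two successors; windows from
  consecutive offenders are unioned and clipped at the series bounds
  (not wrapped).
* **Motion vectors** are 20-bin histograms of FD over [0, 1] mm (width
  0.05; values above 1 mm fall into the last bin), normalized to sum to
  1. Proportions rather than counts: the vectors are compared by Pearson
  correlation, which is location/scale invariant, so the normalization
  cannot change any downstream accuracy while making vectors comparable
  across scans of different lengths.
* **Confound residualization** replaces each feature column by its OLS
  residual on [intercept, confounds]; rank-deficient confound sets are
  rejected with the collinear columns named (pivoted-QR diagnostic).
* **High-motion exclusion** drops dyads whose child is in the top 25%
  of mean FD at any provided timepoint; the cut is the k-th largest
  value with k = ⌈fraction·N⌉ and ties at the cut are all excluded
  (conservative).
* **Phenotype outliers**: keep scores ≤ mean + 1.5·SD (sample SD, n−1)
  computed over the present scores; a score exactly at the cut is kept
  (exclusion requires strictly exceeding it); absent scores are flagged,
  never silently excluded. Missing values are errors elsewhere — the
  analysis excludes incomplete subjects rather than imputing.
* **Median split**: strictly above the median → upper, at or below →
  lower (deterministic tie rule; group sizes logged). The split is
  invariant to strictly monotone transforms, so applying the square-root
  transform to testosterone before splitting changes nothing.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not the physiology of any particular dataset. Parents draw feature
values from N(μ_f, 1); the child's value is
c(f) = μ_f + α·(p(f) − μ_f) + √(1 − α²)·ε with ε ~ N(0, noise_sd), so at
the default noise_sd = 1 the child–parent correlation per feature is
exactly α — which is what makes parameter-recovery tests sharp (mean
diagonal similarity approaches α as the feature count grows).
Defaults mirror the emulated study design: N = 84 dyads with 39/84
female children, two child timepoints sharing one parent scan, a
10-network atlas, testosterone-like scores generated on a squared scale
(the analysis square-root transforms them back), and a CBCL-like score
formed as the mean of two correlated subscores. α can be overridden per
network (edge overrides apply when both endpoints lie in the network),
per timepoint, and per covariate subgroup (additive deltas, clipped to
[0, 1]); a configurable fraction of features receives a shared
population offset, producing group-consistent but non-discriminative
features. Every planted quantity is returned in a ground-truth record.

What the generator does **not** emulate: correlation structure between
features (edges are independent given the parent), non-Gaussian tails,
site/scanner effects, or any spatial embedding of the atlas. Passing
tests therefore demonstrate the statistical machinery — calibration,
invariances, recovery of planted structure — not performance on real
neuroimaging data, whose accuracies depend on feature covariance the
model deliberately omits.

One consequence matters for test design: with M independent features the
diagonal/stranger separation grows like α·√M, so at unit noise a cohort
with 500 features identifies perfectly for any α ≥ 0.2 and accuracy
saturates at exactly 1.0. Comparisons along an α grid are therefore run
at noise_sd = 8, which keeps accuracies inside the 50–95% operating
band actually observed for brain data and leaves the ordering visible;
the parameter-recovery check stays at unit noise where corr = α holds
exactly. Motion series are simulated as a low-motion baseline (|N(0.10,
0.05)| mm, capped below the scrub threshold) with Bernoulli spikes in
[0.55, 1.2] mm; child and parent motion are independent, so
motion-based identification is expected at chance — the negative
control.

## Problem sizes and determinism

Default analysis sizes (84 dyads, 40-node demo atlas, 500–2,000
simulated features, 200-replicate calibration runs, 99–1,000 resampling
iterations) were chosen so every check runs in seconds to a few minutes
on one core while keeping Monte-Carlo error well inside the asserted
tolerances; they are stated alongside each test. All randomness flows
through `numpy.random.default_rng` seeds (spawned per stage via
`SeedSequence`), and identical (spec, seed) inputs reproduce cohorts,
bootstrap draws and permutation nulls bit-for-bit.

## Known limitations

* Subgroup analyses draw stranger parents from the subgroup by default
  (matching how subgroup accuracies are usually displayed); the
  alternative — subgroup children against the full parent pool — is
  implemented but reports point accuracies only.
* The timepoint contrast is a paired comparison between two cohorts'
  per-network accuracy tables, since a cohort object carries one child
  timepoint.
* FC feature ordering (row-major strictly-lower-triangle, i > j) is an
  internal convention; all masks key on node-pair labels, and every
  reported quantity is invariant to feature order.
* No analytic (non-resampling) confidence interval for the accuracy is
  provided, and no similarity measures beyond Pearson correlation.
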