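# Methods

## The data and its encoding

Cypriniformes carry teeth only on the paired fifth ceratobranchial bones.
The dentition of one half-bone is written as a dental formula: a
comma-separated list of per-row tooth counts for the left side, dorsal row
first (so the last number is the ventral row), with an asymmetric right
side appended in parentheses written mirror-fashion, ventral row first.
`2,4,5` therefore means dorsal 2 / mediodorsal 4 / ventral 5, and
`2,3,5-(6,3,2)` a left ventral row of 5 against a right ventral row of 6.
Both halves are stored internally ventral-first.  Two published
descriptions of this convention conflict (one source sentence reads the
single-side list ventral-first); we adopt the dorsal-first reading for the
left half because it is the only one consistent with the printed
asymmetric formulae, where the species described as having six ventral
teeth on the left carries the 6 inside the parenthesised (right) list
mirrored against a left list ending in 5.

Two discrete characters feed the comparative analysis:

* **rows** — the number of tooth rows, the larger of the two halves when
  they differ (a species with two rows on one side and three on the other
  counts as three-rowed).  Retained states {1, 2, 3}; the toothless state 0
  occurs in a single taxon and is excluded as rare.
* **shape** — the qualitative morphotype of (ventral-row) teeth: spoon,
  compressed, spatula, conical, saw, or molariform.  Retained states
  {conical, spoon, compressed}; spatula, molariform and saw are each
  confined to one or two taxa and are excluded as rare.

Excluding a rare state can either recode the observation as missing
(default, keeping the taxon on the tree as an uninformative tip) or drop
the taxon.  The default keeps the tree and the character matrix aligned
with the published trait-mapping figures.  The two printed lists of
excluded shape states disagree in the source material (one also names
"compressed"); the run log prints both and the retained set
{conical, spoon, compressed} follows the results as actually reported.

## The phylogeny

The packaged tree is a hand transcription of the published Bayesian
consensus topology: 45 ingroup species plus the outgroup *Astyanax
mexicanus*.  Four surveyed species lack usable sequence data and are
absent from the tree; the pipeline reports them as dropped.  The
transcription respects the seven constrained monophyletic clades
(Cobitoidea, Cyprininae, Rasborinae, Cultrinae, Gobioninae, Leuciscinae,
Acheilognathinae), the basal Cobitoidea/Cyprinoidea split, and
*Psilorhynchus balitora* as the earliest-diverging Cyprinoidea lineage;
within-clade resolution that cannot be read reliably from the printed
figure follows standard cyprinid phylogenies and is flagged in the fixture
header.  The published branch lengths are not available, so the fixture
ships lengths unassigned and the pipeline installs them explicitly:

* `unit` (default) — every branch length 1.  Simple and symmetric, but it
  compresses deep divergences and stretches shallow ones relative to a
  molecular tree.
* `grafen` — node heights proportional to clade size minus one, root depth
  normalised to 1 (ultrametric).  On this particular tree Grafen heights
  make shallow internodes nearly zero, which drives the fitted rate to the
  upper search bound and the deep-node state vectors towards uniform; it
  is provided for completeness, not recommended here.

## The Mk model and ancestral reconstruction

A k-state continuous-time Markov model evolves each character along the
tree.  Off-diagonal entries of the rate matrix Q are the transition
factors; rows sum to zero.  Under **ER** all factors equal a single q;
under **ARD** all k(k−1) are free.  Branch transition probabilities are
P(t) = exp(Qt), computed in closed form for ER and by eigendecomposition
(with an `expm` fallback when the eigensystem is ill-conditioned, detected
by row sums off by more than 1e-9) for ARD.

The likelihood is evaluated with the pruning algorithm over the rooted
tree, tips contributing indicator vectors and missing tips all-ones;
polytomies are handled natively and partial vectors are rescaled at every
internal node to prevent underflow.  The root prior is uniform over the
retained states by default (the source analysis does not document its
root treatment; a custom prior can be supplied).  The outgroup is retained
for rooting with both characters coded missing.

Rates are estimated by maximum likelihood inside the bounds [1e-8, 1e3]
per unit branch length: bounded scalar search in log-space for ER
(absolute tolerance 1e-10 in log-q), and seeded multi-start (default 5
starts, one anchored at the ER optimum, the rest log-normally jittered)
bounded quasi-Newton (L-BFGS-B, ftol 1e-10) for ARD.  ARD gradient
evaluations batch the likelihood of the point and its forward differences
through one shared eigendecomposition pass.  Because ER is nested in ARD,
the ARD fit is floored at the ER optimum.  An estimate within 1e-3 (log
scale) of a search bound is flagged — this is the expected outcome for
degenerate data such as an invariant character, not an error.

ER and ARD are compared with a likelihood-ratio test: statistic
2(lnL_ARD − lnL_ER) clamped at zero, k(k−1) − 1 degrees of freedom,
chi-square upper tail.  The pipeline's default policy (`auto-LRT`) keeps
the equal-rates model unless p < 0.05, which on the packaged data selects
ER for both characters (rows p ≈ 0.58, shape p ≈ 0.07), mirroring the
equal-transition-factor constraint of the original analysis.  Because the
null hypothesis places no parameter at a boundary but the clamp and finite
trees make the statistic conservative, the test's simulated type-I error
sits at the low end of the nominal band (≈ 0.02 at α = 0.05 in the
packaged experiment).

Marginal ancestral states are computed exactly: an upward pass collects
each node's subtree partials, a downward pass carries the likelihood of
everything outside the subtree, and their normalised product is the
posterior state distribution at each node — the quantity displayed as pies
on trait-mapping figures.  This equals re-rooting at every node in turn
and is verified against brute-force enumeration over all ancestral
assignments in the test suite (max deviation below 1e-10), and against an
independent implementation (R phytools `fitMk`/`ancr`) during development.

## Parsimony cross-check

Unordered unit-cost parsimony provides a model-free check.  Counting uses
Hartigan's generalisation of the Fitch rule (exact on multifurcations);
per-node sets of most-parsimonious states come from a second, independent
dynamic programme (Sankoff with unit costs plus an upward refinement), and
the two counts are asserted equal on every call.  A general Sankoff
implementation with arbitrary non-negative step matrices backs an ordered
(|i−j| cost) variant for tooth-row number, which is exposed but not
default since the source analysis used unordered states.  Agreement is
summarised as the fraction of internal nodes whose ML argmax state lies in
the node's most-parsimonious set; on the packaged data this is 0.98 for
rows and 1.00 for shape.

## Synthetic data and what it shows

Validation experiments simulate the data-generating process the analysis
assumes: Yule (pure-birth) trees — intervals with k lineages last
Exp(k·λ), a uniformly chosen lineage splits, and the process stops after
the interval with n lineages, giving expected root depth
Σ_{k=2..n} 1/(kλ) — and characters evolved exactly along branches by
Gillespie simulation of the Markov chain.  A configurable fraction of
tips can be masked to emulate literature records without shape data and
rare-state taxa recoded as missing.  One integer seed drives everything;
replicate r uses the independent stream `default_rng([seed, r])` so any
replicate is reproducible in isolation.

Default experiment sizes are chosen to run in minutes on one CPU: the
rate-recovery experiment uses 256-tip trees, k = 3, true q = 0.5 and 200
replicates (median q̂ within a few percent of truth); the LRT calibration
uses 64-tip trees and 500 replicates.  The generator matches the model
assumed by the estimator, so these experiments test calibration and
implementation, not robustness: real comparative data add topology error,
unknown branch lengths, non-Markovian correlation between characters and
non-random missingness, none of which the simulations emulate.

## Numerical and design choices

* Node addressing in all outputs is the '|'-joined sorted list of
  subtended tip labels — stable under child reordering.
* Marginal vectors are normalised per node; their invariant sum-to-one is
  checked to 1e-9 in tests.
* Ties in parsimony sets use a 1e-9 relative tolerance on costs.
* Zero-length branches are legal (P(0) = I); negative lengths are
  rejected.
* An entirely missing character gives log-likelihood 0 (probability 1) and
  prior marginals at every node; fitting, however, requires at least two
  scored tips.
* Determinism: identical configuration and seed produce byte-identical
  JSON bundles.

## Known limitations

The reconstruction inherits every caveat of its inputs.  The packaged
topology is a transcription with acknowledged uncertainty in shallow
regions, and branch lengths are an explicit modelling choice rather than
data.  Under the default unit lengths the crown-Cyprinoidea node sits one
unit edge from the one-row *Psilorhynchus* tip and two from the uniformly
one-row Cobitoidea, and its tooth-row argmax is 1 (P ≈ 0.71 vs 0.23 for
three rows); the three-row ancestral signal reported by the original
molecular-branch-length analysis appears one node deeper (the Cyprinidae
crown, P ≈ 0.65 for three rows) and at every early-diverging subfamily
crown.  Conclusions about nodes adjacent to long-isolated, state-atypical
tips are exactly the ones most sensitive to the branch-length scheme, and
the bundle reports full per-node vectors so users can judge that
sensitivity directly.
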