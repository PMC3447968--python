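# Methods

## Transfer model

All interaction data are undirected binary edges over protein identifiers,
stored once in lexicographically sorted canonical form; self-interactions
are legitimate edges. Homology enters as a scored pair map under one of
three operational definitions: reciprocal BLAST hits at an E-value threshold
(many-to-many), reciprocal best hits under an E-value cap (one-to-one), or a
curated ortholog list (unscored, possibly many-to-many). A pair's E-value is
the *larger* of its two directional values, so thresholding a pair means both
directions pass; a pair's percent identity is the smaller of the two
directions.

Across species, a source edge (A, B) predicts (A′, B′) for every homolog
substitution A→A′, B→B′. Within a species, three inference classes are
distinguished:

* **one-same**: exactly one endpoint is substituted, (X, Y) → (X, Y′);
* **both-different-1**: both endpoints are substituted. One-same routes are
  excluded as inference *instances*; a predicted pair stays in the set as
  long as at least one genuine both-different route reaches it. Removing a
  prediction merely because a one-same route also reaches it would make the
  class empty exactly where paralogy is densest, and would make the
  both-different-2 refinement (below) incoherent;
* **both-different-2**: for every predicted pair only its single
  evolutionarily closest route is retained — smallest route E-value, where a
  route's E-value is the larger of the substitution E-values it uses (a
  one-same route uses its single substitution E-value) — and the pair is
  discarded when that closest route is one-same. This is the aggressive
  control for the known power of one-same prediction: the prediction is
  attributed to the most parsimonious (closest) homologous interaction. By
  construction both-different-2 predictions are a subset of
  both-different-1.

Ties in the closest-route ordering are broken by class (one-same wins, the
conservative choice, since it leads to exclusion from both-different-2) and
then by source-edge canonical order, making the selection deterministic.
Unscored routes from curated maps order after scored ones. A prediction
identical to its own source edge is never emitted — it would confirm itself
by construction — and a predicted pair reached by several routes counts once,
carrying its route count and best E-value.

Scoring: `f_obs = n_correct / n_predictions`, where a prediction is correct
when it is an edge of the target interaction set. Predictions involving
proteins absent from the target data set remain in the denominator; they are
real, falsifiable predictions, and missingness is what the coverage
correction is for. With zero predictions `f_obs` is reported as undefined,
never as 0/0. Inferences can optionally be restricted to proteins with at
most a fixed number of homologs (default 10) via the family-size filter.

## Null models

**Likelihood ratio.** `L = O_post / O_prior` with `O_post = f_obs / (1 -
f_obs)`. For across-species and both-different inference the prior universe
is every unordered pair (self-pairs included) of the N target-side proteins
having at least one homolog in the source interactome: `N(N+1)/2` candidate
pairs, of which the possible positives are target edges with both endpoints
homolog-bearing. The target-side protein universe is taken as the proteins
seen in the target interaction data together with those on the target side
of the homology map — divergence from a proteome-wide universe only rescales
the prior and is unavailable without a proteome list. For one-same inference
the candidate pairs are those with one protein in the interactome and the
other having a homolog elsewhere in it, counted with the same self-pair
convention; possible positives are target edges meeting that condition.
`f_obs = 1` yields an infinite posterior odds (flagged), and zero possible
positives leaves L undefined (flagged), never silently clamped.

**Degree-preserving rewiring.** The source interactions are randomized by
repeated double-edge swaps — (a,b), (c,d) → (a,d), (c,b) — rejecting swaps
that create self-loops or duplicate edges, with an attempt budget of 10x the
edge count (a mixing heuristic; any budget preserving the invariant is
valid). Degree means number of interaction partners counted from the
canonical edge set; a self-edge contributes one partner and is held fixed,
because a swap move on a self-edge has no meaning under the partner-count
constraint. Graphs admitting no valid swap (stars, too few edges) are
returned unchanged with a warning. The reported ratio is
`f_obs(real) / mean f_obs(rewired)` over 10 rewirings by default, with the
standard deviation of the per-rewiring ratios; rewirings yielding zero
predictions are excluded and counted.

## Error and coverage corrections

**False positives.** Under a linear mixture, source-side errors depress the
observed fraction by at most `Δ_under = f_obs · FP_s / (1 - FP_s)` (worst
case: no prediction from a spurious edge is ever confirmed), while
target-side errors inflate it by `Δ_over = f_obs · FP_t / (1 - FP_t)`
(matches to spurious target edges counted as confirmations, assuming
independence of being a false positive and being predicted). The target-side
form is a reconstruction from that independence argument; its direction is
validated by simulation in the test suite. Underestimation is strictly
smaller than overestimation exactly when `FP_s/(1-FP_s) < FP_t/(1-FP_t)`,
i.e. when the source's error rate is below the target's; at equal rates the
two distortions coincide. Since error rates across comparably produced data
sets are unlikely to differ enough to break this, false positives cannot
explain away low observed conservation.

**False negatives.** Uniform subsampling of the target interaction list
scales `f_obs` linearly through the origin (the confirmation of each
prediction is an independent Bernoulli trial in the retained fraction),
while subsampling the source leaves `f_obs` flat — more correct and more
incorrect inferences are lost in equal proportion. Both facts are verified
by experiment machinery that subsamples at configurable fractions (default
0.25/0.5/0.75, the full data at 1.0 always included, 10 replicates per
level) and reports the Pearson correlation, fitted slope and intercept, and
a slope confidence interval. With paralog-rich homology a small residual
slope in the source experiment can appear through the collapse of duplicate
predictions; it is an order of magnitude below the target-side slope.

## Conservation, coverage and interactome size

The two subsampling facts license `f_obs(s→t) = f_true(s,t) · c_t`. The
ordered-pair system is underdetermined, so two assumptions close it: a
designated reference species' interactome is complete (`c_ref = 1`), and
conservation with the reference is symmetric, `f_true(t,ref) =
f_true(ref,t)`. Then `f_true(t,ref) = f_obs(t→ref)`, `c_t = f_obs(ref→t) /
f_obs(t→ref)`, and size_t = observed count / `c_t`. For non-reference pairs
`f_true(s,t) = f_obs(s,t)/c_t` uses the target's coverage only (a
symmetrized alternative would be possible; the output records the
convention). Relaxing the completeness assumption to `c_ref = r` multiplies
every coverage by r and every conserved fraction and size by 1/r, preserving
the model identity — implemented as an explicit rescaling operation.
Coverage estimates above 1 are flagged, never clipped: they diagnose exactly
the reporting-bias failure mode expected for heavily literature-curated
interactomes. Threshold sweeps produce per-threshold estimates summarized by
mean ± sd across the sweep.

## Loss rate

An ancestral interaction lost independently with probability q per time unit
in each lineage is retained in both species after T units with probability
`f = (1-q)^(2T)`; the closed form inverts as `q = 1 - f^(1/(2T))`, with the
range over divergence-time uncertainty evaluated at the extremes (larger T,
smaller q). One distinction matters when feeding this formula: the
transfer-based `f_true` estimates the *conditional* retention
P(in target | in source) = `(1-q)^T`, whereas the closed form expects the
*joint* retention of an ancestral interaction. On synthetic data the joint
fraction is available directly (shared surviving ancestral edges); from
observed data the package squares the symmetric conditional estimate before
inverting. Divergence times are user input (point plus range, million
years); none are hard-coded.

## Synthetic worlds

The generator draws an ancestral network of `round(mean_degree ·
n_proteins)` distinct non-self edges placed uniformly, copies it into two
lineages, duplicates each gene with a per-lineage probability (the duplicate
inherits its template's edges to the original partners and becomes a
within-species paralog), then lets every edge survive each of T time units
with probability 1-q. Cross-species homology is the identity map on
ancestral proteins plus duplicate-to-counterpart pairs; E-value-like scores
are drawn as `10^(base + decades·depth ± jitter)` with depth the number of
duplications separating the pair (defaults: base −50, 10 decades per
duplication, 2 decades of jitter), so threshold and identity sweeps have
structure to act on. Observation is a separate layer: the first species is
reported unbiased at its coverage; the second species' true edges whose
homologous counterpart was reported in the first have their reporting
probability multiplied by `beta ≥ 1` (capped at 1) — bias affects
observation, not biology; finally false edges are injected per species so
the reported list carries the requested false-positive rate. Ground truth
recorded per world: the exact conditional conserved fractions per ordered
pair (computed by running the transfer machinery on the true networks) and
the shared ancestral fraction.

Defaults (2000 ancestral proteins, 2.5 interactions per protein, T = 10,
q = 0.02, duplication rate 0.05) give descendant networks of a few thousand
edges with a realized conserved fraction around 0.8 — large enough for
stable estimation, small enough that a full recovery grid runs in seconds.
What the generator does *not* emulate: interaction gain, loss rates that
depend on network position or duplication status, correlated experimental
error, and sequence evolution itself (similarity scores are a stylized
function of duplication depth). Passing recovery tests therefore show that
the estimators invert the stated generative model, not that real
interactomes satisfy it; the bias grid exists precisely to show the
direction of failure when the model's independence-of-observation assumption
breaks.

## Numerical and interface choices

* An E-value of exactly 0.0 (underflow) compares below every threshold; a
  log-scale floor of 1e-180 exists only for binning.
* HSP collapse keeps, per (query, subject), the minimum E-value, ties broken
  by maximum bitscore, then longer aligned region, then first occurrence;
  best-hit ties surviving all tie-breaks drop the query from reciprocal-best
  consideration (a non-unique best hit is not a best hit).
* Within-species hit tables drop self hits before any computation: a protein
  is not its own homolog for inference purposes.
* Malformed input rows are tolerated up to a configurable 10% of the file,
  then reading aborts; evidence-type vocabularies for PSI-MI filtering are
  configuration, since label spellings vary across database exports.
* Identifier remapping requires a one-to-one table; duplicate keys must be
  explicitly collapsed to first occurrence at load time.
* All randomized procedures (rewiring, subsampling, world generation,
  observation) derive every draw from an explicit integer seed through
  numpy's SeedSequence; identical configuration and seed reproduce every
  report byte for byte.
* Test and acceptance problem sizes — worlds of 2000–5000 ancestral edges,
  10 replicates per subsampling level, 4–20 worlds per recovery cell — were
  chosen so each statistical check has at least a threefold margin between
  its tolerance and the Monte-Carlo error at those sizes.
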