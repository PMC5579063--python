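# Methods

## Problem and model

`drugfams` analyses polypharmacology through protein families: given a
drug-protein affinity table, a family membership table, a weighted protein
functional-association network, molecular fingerprints, and side-effect
annotations, it

1. classifies drug-protein interactions into **targets** (pchembl >= 6,
   i.e. activity stronger than 1 uM) and **off-targets** (pchembl in
   [1, 4]);
2. tests, per drug, whether its targets are **overrepresented** among each
   family's relatives;
3. checks the **similarity property principle** (SPP): structurally similar
   drugs should share interaction profiles;
4. measures how targets and family relatives sit on the functional network
   (betweenness centrality, neighbourhood clustering, localization); and
5. models the probability that a family is **free of side-effect proteins**
   as a function of its network clustering, plus the correlation between
   target dispersion and per-drug adverse-event counts.

### Overrepresentation test

For a drug with target set T drawn from a universe of N proteins and a
family FF with n_FF relatives, the number of targets that are relatives is
modelled as Binomial(|T|, P_FF) with P_FF = n_FF / N. The
*overrepresentation threshold* is the expectation |T| * P_FF; the reported
p-value is the minimum-likelihood two-sided binomial test: with
d = Pr(X = s), it sums Pr(X = k) over every k with
Pr(X = k) <= d * (1 + 1e-7). This is the convention of R's `binom.test`
and scipy's `binomtest`; the relative tolerance absorbs floating-point ties
in the pmf. A doubled-one-tail variant is deliberately *not* the default
because it does not reproduce the standard worked values of this test. The
p-value is clamped to (0, 1]; degenerate success probabilities (p = 0 or 1)
return 1 for the forced outcome and 0-mass otherwise.

Benjamini-Hochberg step-up q-values are computed over the whole batch of
(drug, family) tests by default (`adjust_scope="per_drug"` is available).
A family is **druggable** when at least one association is significant —
q below the threshold (default 0.001) *and* the observed overlap exceeds
its expectation (the two-sided p-value alone would also flag
under-representation).

The universe N is configurable: `universe="all"` uses every protein in the
family table; `universe="dataset"` restricts N and the family relative
counts to proteins actually appearing in the activity data (a screen
against known drug-binding proteins). The two readings correspond to the
two natural reference lists and change both n_FF and N, so neither
systematically dominates the other.

### Similarity property principle

Structural similarity is the Tanimoto coefficient over binary fingerprints
(166-bit MACCS-key-sized vectors by default; any fixed length works, and
real-structure fingerprinting is left to external tooling so the package
needs no chemistry toolkit). Profile similarity is the Jaccard index over
target sets ("protein" profiles) or over families containing at least one
target ("family" profiles). The similarity threshold t* is the smallest
observed Tc whose pooled empirical survival probability 1 - F(t) is at most
alpha (default 0.005). Pooling all pairwise Tc values is the default
because a single global threshold requires a single ECDF; a
per-drug-then-median construction is provided (`per_drug_median_threshold`)
for sensitivity analysis. Pairs are binned by Tc (width 0.01, half-open
bins, last bin closed at 1.0) and the per-bin mean Jaccard is reported
together with the above/below-threshold means.

### Network statistics

Two views of the same network are used, mirroring how confidence-scored
association networks are normally consumed:

* **similarity-matrix view** (no cutoff): S(i, j) is the edge score in
  (0, 1], 0 for absent pairs, diagonal excluded. The *matrix similarity*
  of a protein set is the mean (drug sets) or median (family sets) of
  S over all C(k, 2) unordered pairs. Mean is the natural set statistic
  for target sets; the family statistic defaults to the median of pairwise
  scores (not the median of per-protein means — both are computable, this
  one is simpler and monotone under edge additions). Sets with fewer than
  two network-mapped members score "missing" rather than 0.
* **thresholded view** (cutoff 0.8 on the score): an unweighted graph for
  betweenness centrality and localization. All nodes are retained so
  size-matched null draws come from a fixed universe.

Null comparisons draw uniform size-matched protein sets (a degree-matched
null is a known alternative; uniform is the default because the planted
generative model does not confound degree with the signals under test).
Empirical p-values use the add-one rule (1 + #{null >= obs}) / (n + 1),
so they are bounded below by 1/(n+1) and never zero. Betweenness is
normalized by (n-1)(n-2)/2; the choice cancels in z-scores but is fixed
for determinism. Localization is the mean over set members of the
shortest-path distance to the nearest other member; members unreachable
from every other member receive the largest-component diameter + 1 as a
finite penalty (dropping them would silently shrink the set) and are
counted in the output.

### Side-effect model

A family is *side-effect-free* iff none of its relatives is flagged as
associated with side effects. The model is plain maximum-likelihood
logistic regression (BFGS on the Bernoulli likelihood, gradient tolerance
1e-8, via statsmodels) of that label on the family's network score:

    P(free | s) = logistic(beta0 + beta1 * s),  threshold* = -beta0 / beta1

Outcome coding is 1 = free, so a *positive* slope means tightly clustered
families are safer; threshold* is the score at which the predicted
probability crosses 0.5. No regularization by default; a ridge option
(`ridge > 0`) guards against separation on small data sets, and
(quasi-)separation is flagged on the result rather than raised. The
dispersion/side-effect relationship for drugs is a plain Pearson
correlation between per-drug target matrix similarity and adverse-event
counts, with missing scores dropped and zero-variance inputs reported as
undefined.

## Synthetic world

The generator plants every signal the pipeline is supposed to detect and
records the ground truth needed to score recovery. Defaults (all
configurable through `SyntheticConfig`):

| parameter | default | why |
|---|---|---|
| n_proteins / n_families | 400 / 30 | desk scale; >10 proteins per family on average |
| family_size_exponent | 1.2 | Zipf-like sizes: a few large families, median small |
| secondary_membership_frac | 0.10 | families are many-to-many in real annotations |
| frac_module_families / module_size_cap | 0.5 / 30 | only some families form tight functional modules; very large families are functionally diffuse grab-bags |
| p_within / p_between | 0.8 / 0.01 | module pairs must be *majority*-connected for a median-pairwise statistic to be informative |
| w_within / w_between | Beta(8,2) / Beta(2,8) | high- vs low-confidence scores, strictly in (0,1] |
| n_drugs / frac_coherent_drugs | 60 / 0.7 | most multi-target drugs concentrate on one family |
| targets_per_drug / coherent_fraction | (4,10) / 0.8 | multi-target drugs; 80% of a coherent drug's targets come from its home family's module core |
| off_targets_per_drug / off_target_home_fraction | (3,8) / 0.5 | off-targets are *loosely* clustered: intermediate between targets and random |
| target_hub_degree | 2 | targeted proteins receive extra high-confidence cross-module edges, making them bridge modules (central, as drug targets are) |
| fingerprint_length / density / bit_flip_rate | 166 / 0.30 / 0.05 | coherent drugs are noisy copies of a home-family prototype — the SPP signal |
| sidefx_base / sidefx_dispersion_gain | 3 / 25 | per-drug counts ~ Poisson(3 + 25*(1 - target matrix similarity)): dispersed targets, more adverse events |
| flag_beta0 / flag_beta1 | -0.8 / 1.67 | P(family free) = logistic(-0.8 + 1.67*score): ~31% for fully dispersed families, 0.5 crossing near 0.48 |
| flagged_relative_frac | 0.1 | flags are drawn among a family's primary members so they do not cascade through secondary memberships |

All randomness flows through one `numpy` generator seeded by
`SyntheticConfig.seed`; the same (config, seed) produces byte-identical
file bundles.

What the generator does **not** emulate: real affinity-value
distributions, real degree distributions or score calibration of
functional-association networks, chemical-series structure in
fingerprints, and identifier semantics. Passing recovery tests therefore
demonstrates that the statistics detect the planted signals under the
stated noise model — not that real extracts would show effects of the
same size.

## Problem sizes and numerics

The default test and acceptance runs use the 400-protein / 60-drug world,
50 permutation replicates for the FDR check, 100 module-vs-random draws,
and 100-200 random sets for centrality nulls; the logistic recovery
simulation uses n = 500 families. These sizes put Monte-Carlo error well
below the effect sizes being tested while keeping a full run in seconds.
Ties in the binomial pmf are handled by the 1e-7 relative tolerance;
ECDF thresholds are right-continuous with ties sharing an F value; BH
q-values are order-invariant; p-values are clamped to (0, 1].

## Known limitations

* The enrichment model treats a drug's targets as independent draws; real
  target sets are correlated through pharmacological class, so real-data
  q-values are anti-conservative to an unknown degree.
* The localization statistic is the single-set nearest-member distance,
  not a two-set separation measure.
* The logistic model uses one covariate by design; confounders (family
  size, network coverage) are not adjusted for.
* Families smaller than 2 network-mapped relatives receive no
  neighbourhood score and silently leave the druggable-vs-rest comparison.
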