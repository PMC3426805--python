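# Methods

## The statistic

For a candidate probe *i* with beta values b_i, samples are dichotomized
at b_i >= t (default t = 0.2; the comparator is >=, so a beta exactly at
the cutoff counts as methylated; missing entries are excluded). Within
each group the module-module Pearson correlation matrices r1
(unmethylated) and r2 (methylated) are computed over pairwise-complete
observations, Fisher-transformed z = atanh(r), and summarized as

    s_i = sum_{j<k} | z1(j,k) − z2(j,k) |.

The sum runs over unordered module pairs, excluding the diagonal; the
fully symmetric double sum would exactly double every score and change no
rank. A candidate is unscored when its smaller group holds fewer than 15%
of the assessed samples or fewer than 3 samples — the sampling variance
of a correlation explodes for tiny groups, and var(z) ~ 1/(n − 3) is
undefined below 3. Ranks over valid candidates are dense, score-
descending, ties broken by probe ID.

Numerical choices:

- **Fisher clip.** r is clipped to ±(1 − 1e−6) before atanh, capping a
  single pair's contribution at atanh(1 − 1e−6) ≈ 7.2543. Without the
  clip a single perfectly correlated pair would make s infinite.
- **Degenerate correlations** (< 3 complete pairs, or zero variance in a
  group) enter as r = 0, hence z = 0: absence of evidence contributes no
  differential-correlation score.
- **Baselines are split-dependent.** E[s] grows with group imbalance
  (smaller groups give noisier correlations and larger |z1 − z2| even
  under the null), so raw scores of candidates with very different split
  fractions are not directly comparable. The rank ordering is the
  product; a formal null calibration is deliberately out of scope.

## Module clustering

Randomized agglomeration with a quality floor. One iteration: all
clusters are *available*; repeatedly pick an available cluster uniformly
at random, find its nearest neighbour among all current clusters
(average-linkage Pearson similarity: the mean correlation over all cross
pairs); if the neighbour is unavailable, retire the picked cluster for
this iteration; otherwise merge tentatively and keep the merge only if
the union's *coherence* — mean correlation of each member with the
cluster's mean profile — is at least the threshold (default 0.7). On a
committed merge the merged cluster is retired; on a rejection only the
picked cluster is. The iteration ends when nothing is available; the
algorithm stops when an iteration commits no merge. Every returned
module therefore satisfies the coherence floor by construction
(singletons count as coherence 1), and each iteration retires at least
one cluster, so termination is guaranteed.

Design choices where the procedure was genuinely open:

- On a rejected merge the *picked* cluster is retired but the neighbour
  stays available — this guarantees progress and preserves the
  roughly-halving behaviour of early iterations.
- Nearest-neighbour ties are broken in favour of available clusters,
  then by lowest cluster index. Pure lowest-index tie-breaking
  degenerates on exactly tied landscapes (for n identical probes every
  pick's neighbour would be the cluster holding probe 0, which is
  retired after the first merge, stalling the iteration at n − 1
  clusters instead of ~n/2).
- Nearest neighbours are recomputed after every committed merge rather
  than frozen per iteration (the literal reading of the procedure).
- Meta-profile entries are means over non-missing members; a sample at
  which every member is missing stays missing.
- A note on the coherence floor: for two equal-sized clusters with
  cross-correlation rho, the union's coherence is approximately
  sqrt((1 + rho)/2), so two exactly *uncorrelated* clusters merge at
  coherence 1/sqrt(2) ≈ 0.707 — above the 0.7 default. Only negative
  cross-correlation reliably blocks a merge of two otherwise perfect
  clusters. Fixtures that must stay separate are built anti-correlated.

The implementation keeps a cluster-level matrix of summed member-pair
correlations, so average-linkage similarities are O(1) per lookup and the
whole procedure is O(p²) plus coherence evaluations.

## Train/test replication

`split_train_test` makes a seeded uniform split. Scores for the test set
are computed with the *training-derived* modules applied to the test
samples (meta-profiles re-averaged over test samples only). The
alternative — re-clustering the test set — answers a different question
(stability of the modules, not of the scores) and is available by simply
running the pipeline on the test matrix.

## Distance decay

Probe pairs are enumerated per chromosome in position order — adjacent
pairs by default, or every pair within a window (`adjacent_only=False`)
— and each pair's beta correlation is assigned to a half-open distance
bin (lower, upper], default 200-bp bins out to 2000 bp. Distances beyond
the last edge are counted in an explicit overflow row, never dropped.
Per bin the quartiles and Tukey whisker bounds are reported; plotting is
left to the user (the numeric table is the product).

## Sample clustering

Samples are clustered on the marker panel with dissimilarity
1 − Pearson (pairwise-complete, degenerate pairs treated as r = 0) and
average linkage, via scipy; deterministic given the input. The linkage
and metric for this display step are a convention choice (standard for
methylation heatmaps), recorded here because no part of the scoring
depends on them. Exports order probes by genomic coordinate when an
annotation is supplied, else by the probe dendrogram.

## The synthetic world

The generator is a latent Gaussian copula. Per sample, module
activations z are multivariate normal with a regime-dependent
correlation matrix realised through a single shared "methylator" factor
g: z_m = d_m (sqrt(rho) g + sqrt(1 − rho) eta_m), which gives exact
equicorrelation rho with sign pattern d. Probe latents mix module
activation, a local Ornstein-Uhlenbeck field along one synthetic
chromosome (correlation exp(−d/lambda), default lambda = 500 bp at
100-bp spacing), and private noise, with unit marginal variance; they
are pushed through the quantile map of a two-mode Beta mixture into
[0, 1]. Missing entries are injected completely at random.

The two regimes, switched by the planted marker's on/off state:

- **off** — weak baseline co-methylation between modules
  (`base_correlation`, default 0.1), unstructured probes independent of
  the factor;
- **on** — strong concurrent methylation: module equicorrelation rises
  to `on_correlation` (default 0.85) with a `switch_effect` fraction of
  module pairs sign-flipped (realised by negating k modules, which keeps
  the matrix positive semi-definite; k is chosen so k(M−k)/C(M,2) best
  matches the requested fraction), and unstructured probes acquire a
  `noise_on_coupling` (default 0.4) variance share on the shared factor.
  This mirrors the CpG-island-methylator picture, where the aberrant
  regime coordinates methylation genome-wide rather than inside a few
  modules only. With `switch_effect = 0` the regimes are identical and
  the marker is a pure null.

Marker probes are drawn state-faithfully (on ⇒ beta ≥ 0.2,
off ⇒ beta < 0.2; an optional mislabel rate flips states before
drawing). Marginals: each structured probe has its own upper-mode mass,
drawn from a trimodal propensity landscape — constitutively unmethylated
(Beta(1,19)), constitutively methylated (Beta(19,1)), and a
`variable_fraction` (default 0.3) of variable probes (Beta(15,15)) — as
on real promoter arrays, where most probes are near-constitutive and
fail any dichotomization guard. The two mixture components are
Beta distributions centred on the beta modes (default 0.1 / 0.8,
concentration 22, chosen so the lower mode leaves only ~5% mass above
the 0.2 cutoff).

`GroundTruth.regime_off/on` state the *expected beta-scale* meta-profile
correlation matrices, computed analytically from the latent regimes via
a Hermite expansion of each probe's quantile map (the monotone transform
attenuates correlations, so latent targets would be systematically
biased; the published targets are the attenuated ones and are exact for
`state_mean_shift = 0`). `state_mean_shift` (default 0) additionally
raises the latent mean of flipped modules when their marker is on,
emulating subtype hypermethylation; the `two_regime_spec` world uses a
fully penetrant shift of 5 so that sample *values*, not only
correlations, separate the regimes — value-based hierarchical clustering
cannot recover regimes that differ in correlation alone, and real
subtypes (CIMP above all) do differ in level.

What a green test does and does not establish: the generator emulates
bimodality, local decay, module structure, missingness and regime
switching, but not array-specific artefacts (batch effects, probe
cross-hybridisation, SNP-driven nulls clustered in specific probes,
cancer-type composition), so recovery results here bound the method's
behaviour in its stated world only.

## Defaults and units

| parameter | default | meaning |
|---|---|---|
| beta threshold t | 0.2 | dichotomization cutoff on beta (unit-free ratio) |
| minority guard | 0.15 | minimum fraction of assessed samples in the smaller group |
| minimum group | 3 samples | correlation needs 3 points |
| coherence floor | 0.7 | minimum member-to-mean correlation per module |
| max null fraction | 0.01 | probe filter: missing entries over sample size |
| min SD | 0.1 | probe filter: sample SD (ddof = 1) over non-missing entries |
| panel size | 200 | markers used for sample clustering |
| distance bins | 0–2000 bp, 200-bp steps | half-open (lower, upper], 1-based coordinates |
| Fisher clip | 1e−6 | distance from ±1 at which r is clipped |

## Known limitations

- s has no significance calibration; it is a ranking statistic. Its
  null expectation depends on the split fraction, so comparing raw
  scores across candidates with very different dichotomy fractions
  favours imbalanced splits.
- The module clustering is randomized; module boundaries (especially
  chains of locally correlated probes) vary across seeds, though the
  coherence floor always holds.
- Meta-profiles are unweighted member means; a module mixing probes of
  very different variances is dominated by none, which is intended but
  means meta-correlations are attenuated relative to latent module
  correlations.
- The sample-clustering step is a display convention (1 − r, average
  linkage); leaf orders are not comparable across implementations.
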