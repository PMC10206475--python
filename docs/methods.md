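# Methods

## The analysis in brief

The pipeline asks two questions of longitudinal observations of immature
group-living primates: whether immatures inherit their mothers' social
networks, and how their networks differentiate with age and sex. All
analyses operate on ego-networks: every dependent variable is computed per
immature per 30-day sampling period and modelled with mixed models whose
network terms are tested against permutation null models.

## Networks

**Periods.** Records are split per troop and network kind into consecutive
30-day windows anchored at the first observation date of each field season;
proximity and grooming streams anchor independently. Trailing partial
windows are generated and left to the observation filter. Periods with
fewer than 95 observations are dropped; individuals seen fewer than five
times in a season are excluded from that season's networks. Both filters
are logged.

**Proximity.** Scan records (focal + all individuals within 10 m,
singletons = "alone") become binary group-by-individual (GBI) matrices, one
row per sampled subgroup. The simple ratio index for a dyad is
`x / (x + yA + yB)`; "alone" rows contribute to the y terms because they
are sampled observations of non-association. A dyad whose denominator is
zero (neither member sighted) carries no information and is stored as 0
with a mask; masked edges are treated as weight 0 by the metrics. No
edge-weight thresholding is applied anywhere.

**Grooming.** Directed event counts i→j per period, viewed as given
(rows), received (transpose) or total (symmetrized sum); the similarity
models use row-normalized proportions, which represent how grooming is
distributed over partners independent of activity level. A dyad is recorded
at most once per half hour to limit pseudo-replication.

## Dominance ranks

Adult females are ordered per troop-season by the I&SI criterion: minimize
the number of inconsistencies (dyads whose lower-ranked member won more),
then their total strength (summed rank distances). Tied (equal nonzero
wins) and unknown (0–0) dyads contribute to neither objective. Exact
search is factorial, so the optimum is found by seed-controlled
random-restart hill climbing over pairwise position swaps, seeded from a
David's-score ordering; exhaustive-search tests pin exactness for n ≤ 6.
Ordinal ranks are standardized as `1 − (1 − r)/(1 − n)` (1 = highest).
Linearity statistics are not computed.

## Node metrics

Strength is the sum of incident edge weights (out / in / total for directed
grooming). Eigenvector centrality is the leading eigenvector by power
iteration (tolerance 1e-10) rescaled to max = 1; a diagonal shift breaks
the ±λ tie on bipartite graphs without changing eigenvectors; directed
grooming is symmetrized first since given/received components cannot be
separated for centrality. On disconnected graphs the vector concentrates on
the dominant component (logged, not an error). Betweenness counts weighted
shortest paths through each node with fractional splitting; the default
treats edge weights as path *costs*, replicating the convention of the
graph library this pipeline mirrors — under it, strong associations are
long edges, a known pitfall — and an `inverse_weights` option provides the
biologically intuitive reading. Transforms before analysis: log1p for
proximity betweenness and grooming strength given; sqrt for grooming
centrality and betweenness; metrics are then z-scored within each sampling
period (sample sd; constant vectors become zeros with a warning) to be
comparable across networks of different sizes.

## Responses

* Time with mother: proximity — records whose subgroup contains both
  immature and mother over records containing the immature (joint subgroup
  membership is the recorded unit, so "with the mother" means sharing a
  subgroup); grooming — events in either direction with the mother over
  events involving the immature.
* Ego-network similarity: Pearson r and cosine similarity of the mother's
  and immature's matrix rows, aligned after dropping both dyad members'
  columns (the self column is structurally zero and the mother–immature
  edge sits at different positions in the two rows). Zero-variance vectors
  make Pearson undefined (row skipped); both measures are computed and
  their positive rank correlation is asserted in tests.
* Binary comparisons: score 1 when the mother–immature r strictly exceeds
  the comparator's r (ties score 0); the comparator is a uniformly drawn
  non-mother individual (recorded for reproducibility) or the mean r over
  all non-mother individuals. Eligibility is any individual in the period's
  network except the immature and its mother — no age restriction.
* Partner categories: proportions of distinct immature (≤ 60 months), peer
  (|Δage| ≤ 6 months, inclusive) or same-sex partners the focal has a
  nonzero edge to, over the category's size in the troop-period excluding
  the focal. Ages are evaluated at the period midpoint. Direction follows
  the grooming mode (out for given, out of the transposed matrix for
  received, either for total).

## Mixed models

Every model shares fixed effects age (months, uncentred), sex (male
indicator, female reference), age×sex, mother's offspring count, mother's
relative rank and troop (a fixed factor: too few troops for a random one),
plus the mother's own metric in the strength/centrality/betweenness
models; random intercepts are year and immature nested in mother. Models
are "full": no simplification. Binomial responses are modelled as
successes/trials with a logit link; continuous responses with REML LMMs.
Single-level factors (one troop, one year) are dropped with a log note.

Estimation is delegated to lme4 (`lmer`/`glmer`) through a batched Rscript
bridge, with identical settings for observed and permuted datasets — the
property permutation inference actually needs. The backend is declared in
every result's metadata. (Variational and quasi-likelihood Python
alternatives were rejected because they understate standard errors on
exactly the small tables this pipeline fits.)

Effect sizes: `(OR − 1) × 100` per unit predictor;
`[(OR_t1 − OR_t0)/OR_t0] × 100` between t₀ = 12 and t₁ = 48 months (the
male slope adds the interaction term; main effects are read as conditional
effects); sex contrasts at 30 months; LMM slopes as percent of the
response's observed range (max − min of the fitted response). Wald p-values
are not the inferential currency — permutation p-values are.

## Permutation null models

*Datastream* (proximity MP1b, MP1c, MP2a, MP2b): chained checkerboard
swaps of the period's GBI — find rows (g,h) and columns (i,j) patterned
[[1,0],[0,1]] and flip — preserving subgroup sizes and individual sighting
counts exactly. "Swapping 20 observations" is implemented as 20 successful
flips per chain step. Chains run 300 steps per period, the first 200 states
are discarded, and the 100 kept states are converted to SRI matrices.

*Node* (all grooming models and the proximity partner-composition models):
joint row+column relabelings composed sequentially along a 300-step chain,
last 100 kept. Relabeling preserves network structure exactly while
breaking the attribute–position association, which is the right null for
partner-preference questions; individual attributes stay with matrix
positions. Composition of uniform permutations is itself uniform; the
chain layout is kept for procedural fidelity with the datastream variant.

Null dataset k is assembled from chain state k of every period
(periods are permuted independently; whole-dataset replicate k combines
their k-th states), responses and the mother's metric are recomputed from
the permuted matrices, and the model is refitted. The two-tailed p for a
term is `2·min(#null ≥ obs, #null ≤ obs)/K` capped at 1, reported with the
field's binary label ("0.05" iff p ≤ 0.05). With K = 100 the smallest
attainable nonzero p under this rule is 0.02; the time-with-mother models
get no permutation test because their response is not a network quantity.

## Synthetic troop generator

The generator emulates the field protocol: per troop, a randomized focal
list is swept once per observation day (14 sweeps per 30-day period by
default), neighbours join a focal's subgroup independently with pairwise
propensities, individuals recorded within the past hour are not re-sampled,
and grooming events arrive at ~10 per individual-month with half-hour dyad
deduplication. Default troops hold 31 individuals (5 matrilines × 3 adult
females, 4 adult males, 12 immatures aged 4–56 months with mothers shared
between siblings), two troops, and two field seasons two years apart —
a gap-year longitudinal design giving each immature a ~27-month age span,
which is what identifies within-individual age effects.

Three latent social forces, each independently switchable to zero:

* **Inheritance** — an immature's association-propensity row is
  `w·mother_row + (1 − w)·homophily` with
  `w = λ₀·exp(−(δ + δₘ·male)·age)` (defaults λ₀ = 0.9, δ = 0.05/month,
  δₘ = 0.01/month). Immature dyads are governed by the immature's own
  mixture row, so λ₀ is the single inheritance dial: at λ₀ = 0 the
  propensity rows are uncorrelated with the mother's.
* **Homophily** — baseline 0.004 plus a Gaussian age-distance kernel
  (amplitude 0.03, bandwidth 12 months) plus a same-sex affinity growing
  linearly with age (0.0004/month). Per-scan probabilities compound over
  ~2×14 exposures per period, so these values keep period-level networks
  realistically sparse rather than saturated.
* **Mother attachment** — whenever an immature is recorded in a subgroup
  its mother is present with probability
  `logit⁻¹(1.1 − 0.025·age − 0.2·male − 0.012·age·male)`. Applying the
  rule at the record level makes the proximity time-with-mother response
  binomial-logit by construction, so the generating coefficients are
  recoverable on their own scale; the grooming mother-dyad weight is
  proportional to `exp(attachment logit)`, which keeps the grooming share
  involving the mother approximately logit-linear too.

Dominance interactions among adult females are won by the latently
higher-ranked female with probability `logit⁻¹(steepness · rank gap)`
(default steepness 3 — a strong but imperfect hierarchy).

For responses that aggregate nonlinearly over scans (partner-category
proportions), the generator's implied logit-scale coefficients are measured
once by an independent large-sample oracle (pooled plain-GLM over 40
replicate troops; `scripts/compute_pseudo_true.py`) and recovery is tested
against those implied values: age +0.0195, sex −0.264, age:sex +0.0006 for
the same-sex proximity model.

**What the generator does not emulate** — and hence what passing tests do
not certify about real data: demographic turnover (births, deaths,
dispersal, fission), unmarked/unidentifiable individuals and observability
corrections, within-day spatial autocorrelation of subgroups (scans are
conditionally independent given propensities), seasonality, and
observer effects. Real mother–offspring correlations also reflect habitat
structure that the generator has no notion of.

## Numerical and design choices

* Determinism: every stream derives from the config seed; permutation
  chains take per-period children of a root seed sequence; reruns are
  bit-identical.
* The I&SI local search uses 50 restarts by default; exactness is
  oracle-tested at small n, and steep simulated hierarchies are recovered
  with Kendall τ = 1.
* Degenerate inputs: all-zero dominance or weight matrices are errors;
  constant responses and all-successes binomial tables are flagged, never
  silently fitted; > 20% non-converged permuted fits flag the permutation
  result unreliable.
* Problem sizes in the test suite (two troops of 31, five periods, 40
  calibration replicates at a 60/30/30 schedule) were chosen so the whole
  suite documents the pipeline's statistical behaviour at desk scale;
  they match the magnitudes reported for the motivating field system
  (troops of 21–74, 4–20 scans per individual-month).

## Known limitations

* The lme4 dependency is reached through a subprocess; environments
  without `Rscript` + lme4 cannot fit models (everything up to model
  fitting runs pure-Python).
* Betweenness on SRI weights-as-costs is a replication choice, not a
  recommendation; use `inverse_weights` for new analyses.
* The binary 0.05/NS permutation label is coarse by construction; the
  numeric permutation p is reported alongside.
* Cosine similarity results are computed but the similarity models report
  the Pearson variant; the two are rank-correlated on simulated data.
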