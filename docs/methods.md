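# Methods

## Problem and model

`netmiss` studies *tie non-response* in sociometric surveys: an actor takes
part but some of their reported ties are absent. The data object is a square
binary sociomatrix `x` with `x_ij = 1` when actor *i* nominates actor *j*;
self-ties are structurally absent. Undirected relations are stored as
symmetric matrices, but the *reports* remain ordered: both endpoints of an
undirected pair report the pair independently, and either report can go
missing on its own. This distinction is what makes reconstruction meaningful
for undirected data.

Two network measures are tracked, plus density as a convenience:

- **Normalized degree centrality** `C'_D(k) = deg(k) / (n − 1)`. For directed
  networks the degree mode (`in`, `out`, `total`) is configurable; the
  pipeline default is `in`, because incoming nominations survive a focal
  actor's own non-response. Total degree is normalized by `2(n − 1)` so all
  modes live on [0, 1].
- **Freeman degree centralization**
  `C = Σ_i (C_max − C'_D(i)) / max Σ_i (C_max − C'_D(i))`, where the
  denominator is the closed-form star maximum: `n − 2` for undirected (and
  directed-total) normalized degree, `n − 1` for directed in/out degree
  (one actor can monopolise all nominations). `C` is 1 exactly on stars and
  0 exactly on regular graphs, and needs `n ≥ 3`.

A useful assertable identity: mean normalized in- or out-degree equals
density, so the "degree" summary at network level is density on a different
scale. The network-level θ reported for "degree" is the mean normalized
degree (the per-actor centrality vector summarised by its mean); this is a
package design choice where a single network-level scalar is needed.

## Synthetic data

The generator emulates a 50-actor adolescent friendship network collected
with a name generator (up to six nominations) plus a 5-point alcohol score:
directed density 0.047, max-symmetrized undirected density 0.066, sizes 50,
150, 250. Networks are independent Bernoulli graphs at the target density —
the simplest mechanism consistent with generating larger networks "from a
density" — so they do not reproduce the empirical network's reciprocity,
transitivity, or degree heterogeneity. Consequences: results that depend
only on marginal tie probabilities transfer to real data; results that
depend on reciprocity (notably how well reconstruction works) are
conservative here, because in a Bernoulli graph the opposite report carries
no extra information about a missing tie beyond the density. Alcohol scores
are i.i.d. uniform on 1–5 by default (an empirical distribution can be
supplied); the six-nomination cap is off by default and only thins rows when
explicitly requested.

One master seed expands into named substreams (`network`, `attributes`,
`missingness`, `imputation`) via `numpy.random.SeedSequence` spawn keys, so
each stage is independently reproducible and adding draws to one stage never
perturbs another.

## Missingness

Mechanisms act through a per-sender weight shared by all of that sender's
outgoing report cells: MCAR `w_i = 1`; MAR `w_i = 1/alcohol_i²` (the score is
fully observed); MNAR `w_i = 1/(outdegree_i + 1)²` with the outdegree from
the complete network (unobservable in practice). Deletion hits an exact
count `M = round_half_up(p · n(n−1))` by weighted sampling without
replacement (Efraimidis–Spirakis exponential keys: smallest `Exp(1)/w`
win), which removes the deletion-count variance from bias comparisons.
`granularity="row"` instead deletes whole outgoing rows by the same actor
weights until the cell count first reaches M (overshoot < n−1 cells, last
row kept whole); this is the whole-questionnaire non-response of the worked
examples. Cell granularity is the default.

## Treatments

All treatments leave observed cells untouched (bit-level test). Undirected
reports are first collapsed pairwise — the surviving report wins; a pair is
unresolved only when both reports are missing — and each treatment's rule
fills the remainder, so completions are symmetric by construction.

- **Complete-case**: drop every actor with ≥ 1 missing outgoing cell and all
  their incident ties; measures are computed on the reduced network with its
  own n, but the bias baseline stays the full network's θ — the only reading
  under which listwise deletion can "break down". Not-applicable below 3
  retained actors (the smallest network with defined centralization); the
  driver counts such replicates instead of averaging them.
- **UMI**: missing cell ← 1 if the relevant observed mean ≥ 0.5, else 0
  (ties at exactly 0.5 impute 1; boundary behaviour is untestable
  otherwise). Variants: global density (default, the classical exposition),
  receiver's observed incoming mean, sender's observed outgoing mean; actor
  variants fall back to the global mean on empty conditioning sets.
- **Reconstruction**: directed `x_ij ← x_ji` where the opposite report is
  observed; dyads with both reports missing go to the secondary rule.
  Default secondary rule is zero-fill: the printed worked examples leave
  such dyads unresolved, and on sparse networks the thresholded-mean rule
  would also give 0, so zero is the behaviour consistent with both. The
  `umi_density` secondary is available for dense networks.
- **MI**: one logistic regression of observed tie values on cell-level
  predictors (default: sender alcohol + observed reciprocal tie — the
  smallest model that reacts to MAR structure), then m = 5 completed
  networks, each drawn with coefficients sampled from the fit's asymptotic
  normal distribution (proper imputation) and missing cells as Bernoulli at
  the predicted probabilities. Degenerate fits — constant outcome,
  separation (detected as non-convergence, non-finite or exploding
  variances), or no usable predictors — fall back to intercept-only fills at
  the observed density. Undirected data are fitted on unordered pairs with
  the pair-mean alcohol; the reciprocal predictor is dropped (it would be
  the outcome itself). Per-imputation analyses are pooled with Rubin's
  rules: point = mean, `T = W̄ + (1 + 1/m)B`; descriptive network statistics
  carry no analytic within-imputation variance, so W̄ = 0 unless supplied.

## Monte-Carlo evaluation

Per replicate the driver regenerates truth and attributes (θ varies across
replicates, so `θ̂ − θ` is paired within replicate), deletes ties, applies
every requested treatment to the *same* corrupted reports (paired
between-treatment contrasts), and accumulates `bias = Σ(θ̂_i − θ_i)/r` in
fixed replicate-major order for bit-reproducibility. Both standardizations
of the bias are reported — by the replicate SD of θ̂ and by θ (relative
bias) — because "standardized bias" has no unique definition; raw bias is
the primary quantity. Degenerate scales yield NaN rather than an error.
Failed (not-applicable) replicates are excluded from means and reported as
`n_failed`.

The default design is 3 mechanisms × {directed, undirected} × {50, 150,
250} × {0.05, 0.1, 0.25} × 4 treatments × 3 measures = 648 result rows at
r = 500. The test suite exercises a reduced qualitative replication at
n = 50, r = 200 (all mechanisms, both types, all proportions) and a full
factorial smoke run at r = 10 — sizes chosen as the smallest designs whose
Monte-Carlo error is far below the systematic effects being checked.

## Numerical and formatting choices

- Deletion counts use round-half-up (`floor(pN + 0.5)`), matching the
  study's printed example counts.
- Weighted sampling uses exponential keys with a stable argsort, so the
  missing pattern is a pure function of (spec, seed).
- Adjacency files are delimited label-indexed matrices; missing code "N"
  (configurable, never "0"/"1"), blank diagonal, rows written in label
  order. Reading infers undirectedness from exact symmetry unless told
  otherwise. Edge lists carry complete networks only.
- With constant attributes the MAR keys are the MCAR keys divided by a
  constant, so MAR with a flat covariate reproduces the MCAR selection
  exactly at the same seed — a deliberate collapse property.

## Known limitations

- Bernoulli truths understate reconstruction's real-world value (no
  reciprocity) and contain no community structure; treatment rankings that
  depend on those features will differ on empirical networks.
- MI uses a single pre-specified logistic model, not chained equations; with
  very sparse observed data it frequently falls back to intercept-only
  fills.
- Under cell-granularity missingness at the study's proportions, listwise
  deletion is not applicable in most MCAR/MAR replicates (nearly every actor
  has ≥ 1 missing cell); row granularity is the regime where complete-case
  analysis is informative.
- Actor non-response, attribute missingness, valued ties and longitudinal
  designs are out of scope.
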