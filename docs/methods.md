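# Methods

This note documents the models, numerical procedures and design choices
behind `fedmtl`, and what the synthetic studies do and do not demonstrate.

## Federation model

The federation is simulated in-process behind a transport interface
(`FederationSession.request` / `broadcast`): each `ServerNode` owns one
cohort's `TaskDataset`; the client holds no raw data and reaches a server
only through typed requests (`loss_value`, `loss_value_grad`,
`inmf_local_update`, `inmf_H_stats`, `summary_stats`).  Responses contain
only aggregates — scalar losses, length-p gradients, r×p factor-update
statistics, summary counts.  A networked backend could replace the
in-process transport without touching any algorithm code; wire protocols,
authentication and encryption are out of scope.

**Communication accounting.** One *round* is one client-initiated broadcast;
one *network access* is one request–response exchange with one server, so a
round over K servers costs K accesses.  Both counters are exposed because
either may be the binding cost depending on whether latency or per-server
load dominates.  One accepted solver iteration costs 2 rounds + 1 round per
line-search retry: a gradient evaluation at the momentum point (value and
gradient come back together) and one objective evaluation per proximal
candidate.  The candidate's objective cannot be reused from the gradient
round because the momentum point and the candidate differ.

**Privacy controls.**

- *Quantization*: any transmitted numeric payload can be rounded to
  `digits` decimal places (round-half-to-even, `numpy.round`); `digits=None`
  means unlimited.  Quantization is idempotent, applied to client payloads
  and server responses alike.  When payloads are quantized, the line search
  adds a slack of `(K+1)·10^-digits` to the sufficient-decrease test, since
  a decrease below the wire granularity cannot be certified; without the
  slack the backtracking loop can shrink the step forever on a stalled
  quantized objective.
- *Disclosure guard*: a coefficient vector released from a server context is
  rejected when its nonzero count exceeds the server's subject count (a
  saturated model supports reconstruction attacks).  The boundary is
  inclusive: exactly n nonzeros pass.
- *Shared-only iNMF policy* (default on): client-visible payloads may
  contain `H` and aggregate statistics, never `V_k` or `W_k`; requesting the
  local factors raises `PermissionError` unless the data owner disables the
  policy.

## Supervised objective

All supervised fits minimize `L(W,c) + λ·S(W) + C·ℵ(W)`.

**Losses (mean form).** Per cohort, least squares
`1/(2n_k)·‖Xw + c − y‖²` or the logistic negative log-likelihood
`1/n_k·Σ log(1+exp(−y_i(x_iᵀw+c)))` with labels in {−1,+1} ({0,1} accepted
and converted).  Normalizing by `n_k` makes cohorts of different sizes
contribute comparably under multi-task coupling.  Under *pooled* coupling
(the federated lasso) the per-server mean losses are re-weighted by
`n_k/N`, so the pooled objective equals the mean-form loss on the pooled
union exactly — a split of one dataset across servers changes nothing but
the communication pattern.  Intercepts are fitted, never penalized, and
initialized at their intercept-only optimum (outcome mean, or log class
odds).

**Penalties.** `S` is entrywise L1, row-wise L2,1, or the trace norm, each
with its closed-form proximal operator (soft-threshold, row-group
soft-threshold, singular-value soft-threshold).  `ℵ` is either a ridge
`½‖W‖²_F` or the task-graph coupling `‖W·R‖²_F` (plus an optional small
ridge `ridge_eps` for conditioning, default 0).  The graph form subsumes
both edge-incidence and Laplacian-style penalties through the choice of R;
only the mean-regularization graph `R = I − (1/T)·11ᵀ` (idempotent,
symmetric, annihilates the shared direction) is built in, since pulling
every task toward the cross-task mean is the coupling used throughout the
analyses here.  The graph-coupled fit keeps `S = λ‖W‖₁` as its only
non-smooth part, so one proximal operator suffices.

**Feature standardization** (zero mean, unit variance per server, constants
cached server-side and recorded in the model for prediction-time reversal)
is available but off by default: per-server scaling makes the federated fit
a genuinely different estimator from the same fit on pooled data, and the
package treats "federated = centralized" as its master invariant.  Users
who want scaling should standardize explicitly.

## Solver

Monotone FISTA: at each iteration the proximal candidate is computed from
the momentum point with backtracking (initial step 1, step halved per
failed sufficient-decrease probe), but the iterate is only replaced when
the candidate does not increase the objective, and the momentum is steered
toward the rejected candidate otherwise.  The recorded objective history is
therefore non-increasing by construction — an assertable invariant, where
plain FISTA oscillates.

- **Termination** (checked on accepted iterations only, since a rejected
  candidate leaves the objective unchanged): `objective_rel`
  (|Δf|/max(|f|,1) ≤ tol, default, tol 1e−5), `param_rel` (relative
  Frobenius change of W), or `iter_only` (run to `max_iter`, default 1000).
- **λ_max** is computed from the first-order optimality condition at W = 0
  with intercepts at their optimum: the dual norm of the loss gradient —
  max |entry| (L1), max row L2 norm (L2,1), largest singular value (trace).
  Fitting at λ ≥ λ_max provably returns the all-zero matrix; fitting just
  below does not.  Two rounds: one summary broadcast for the intercepts,
  one gradient broadcast.
- **Paths**: λ sequences are geometric from λ_max down to
  `min_ratio·λ_max` (defaults 0.01, depth 20); each fit warm-starts from
  the previous solution, the first from zero.  Cross-validation draws folds
  within each server (seeded, stratified for binary outcomes), fits the
  path on the in-fold union and scores held-out samples server-side (one
  access per server per fold per λ); λ_best minimizes the mean metric (MSE
  or misclassification), ties to the larger λ; the final model is refit on
  all data.

Degenerate inputs: a non-finite objective aborts with a diagnostic; a step
below 1e−18 in the line search raises rather than looping; λ = 0 is plain
gradient descent with prox = identity.

## Federated integrative NMF

Objective: `Σ_k ‖X_k − W_k(H+V_k)‖²_F + λ_het·Σ_k ‖W_k V_k‖²_F`, all
factors non-negative, adopted from the integrative-NMF literature; it is
isolated behind `inmf_objective` so an alternative heterogeneity penalty
could be swapped in.  One update round: each server multiplicatively
updates `W_k` then `V_k` against the incoming `H` and returns
`A_k = W_kᵀX_k`, `B_k = W_kᵀW_k(H+V_k)` plus its local objective; the
client updates `H ← H ⊙ ΣA_k ⊘ (ΣB_k + ε)`.  Each block update is a
standard majorization step, so the per-round objective is non-increasing;
multiplicative updates preserve non-negativity exactly; denominators are
guarded by ε = 1e−12.  Exactly one access per server per round, with r×p
payloads independent of the sample counts.

Initialization: all factors Uniform(0,1) scaled by `mean(X)/rank`, client
and servers seeded from one master seed; `n_starts` (default 5) restarts,
best final objective wins and the winning start's factors are retained
server-side.  Convergence: relative objective change below `tol` (default
1e−6) or `max_iter` (default 500) rounds.

**λ_het default 0.01.** The H/V split is what the penalty identifies: with
λ_het = 0 any allocation of structure between `H` and `V_k` that
reconstructs the data is an optimum, and with λ_het large the cohort-specific
structure is pushed *into* `H` (using V becomes expensive while a dedicated
H row loaded by only one cohort is free).  Calibrated once on planted-truth
simulations: 0.01 keeps the shared set pure (precision 1.0 at every shared
fraction) where 0.1–5 collapse it to ~0.3; it is a method hyperparameter
users should revisit for differently scaled data.

**Signature extraction.** A gene joins the shared set when its maximum
metagene weight in `H` exceeds `mean(H) + 2·sd(H)` (or `top_k` by that
score); cohort-specific sets apply the same rule to `V_k` *server-side* and
return gene names only.  The threshold rule is a declared convention, not an
estimated quantity.

**Rank selection** fits each candidate and takes the elbow of the
objective-vs-rank curve (largest second difference); the curve is only
non-increasing up to local-optimum jitter of the multi-start fits.

## Synthetic data

Two generators return data plus a truth object sufficient to score any
selection metric.

*Shared-support regression* (`gen_case1`): T cohorts (default 3), X iid
standard normal, a common support of `0.1·p` features with coefficients
±magnitude (default 1); `heterogeneous` mode draws iid Rademacher signs per
cohort over the support, `homogeneous` shares one sign vector; continuous
outcomes add Gaussian noise (sd default 1), binary outcomes sample from the
logistic model.  The study grid uses subject/feature ratios
{0.15, 0.3, 0.5, 1.0} with p = 200 as the desk-scale default.

*Shared + specific factorization* (`gen_case2`): K cohorts (default 2,
p = 300, n_k = 100), 100 signal genes partitioned disjointly into a shared
set (`shared_fraction`, swept 0.2–0.8) and equal cohort-specific sets; each
signature gene loads one of `rank` (default 4) metagene rows with weight
~ U(0.5, 1.5), specific genes load `V_k` *on the same metagene grid* so
shared and specific structure share sample loadings — the configuration
only a joint factorization can separate; `X_k = W_k(H+V_k) + |N(0, 0.1)|`.

What the generators do **not** emulate: count distributions (negative
binomial), batch effects, correlated designs, missingness.  Passing tests
show the algorithms recover the planted structure under idealized Gaussian/
uniform signals; they do not certify performance on real expression data.

## Evaluation conventions

- *Selection accuracy* = precision@k of a feature ranking against the
  planted support, k = support size, ties broken by feature index.  MTL
  models are ranked by row L2 norm of W; the lasso-bagging baseline by the
  mean absolute coefficient across cohorts (the signed model-average was
  also measured and differs negligibly with an odd number of cohorts).
- *Local baselines* are strictly non-collaborative (zero network accesses):
  per-cohort cross-validated lasso (scikit-learn `LassoCV`) and per-cohort
  NMF (scikit-learn `NMF`, fixed iteration budget).  NMF-bagging combines
  per-cohort threshold-selected sets by intersection for the shared-set
  estimate; each cohort's own set is its specific-set estimate.
- *Signature reproducibility*: split cohorts into two groups, cross-validate
  per group, compare top-200 signed scores (overlap count and
  consistent-direction count).

Study protocol sizes (package choices, stated for reproducibility): the
selection study uses 20 repetitions of 5-fold CV over a depth-20 path at
n/p = 0.15, p = 200, T = 3; the disentanglement study uses rank 4, five
starts, 3–5 repetitions per shared fraction; the scalability study averages
20 repetitions per federation size (iteration-count jitter across problem
draws is ±10% at 5 repetitions, swamping the flat-in-K signal), K = 2…20,
p = 100, n = 100 per task, λ = 0.1·λ_max.

## Known limitations

- The in-process transport models message *content* and *counts*, not
  latency, failures or stragglers; asynchronous updates are not provided.
- The L2,1-over-bagging selection advantage is direction-stable but its
  magnitude depends strongly on the generator's signal-to-noise regime; at
  the defaults above (signal variance ≫ noise) the local baseline remains
  competitive and the measured advantage is ~1.3–2×.
- Under the intersection combination rule the NMF-bagging shared-set
  estimate is nearly pure shared signal (high precision, poor recall); rule
  variants (union, rank-aggregation) trade these off differently and are
  easy to add on top of the returned per-cohort sets.
- Trace-norm fits assume a unique minimizer for reproducibility claims;
  rank-deficient designs can make the solution set non-singleton.
- The disclosure guard and quantization reduce, but do not provably
  eliminate, inference risk; no formal differential-privacy accounting is
  performed.
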