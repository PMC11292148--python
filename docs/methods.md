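# Methods

## The problem

Multi-center clinical studies rarely share one data-governance reality:
some hospitals can upload their records to a central server, others can
only participate by exchanging model updates. `fedhybrid` simulates this
continuum. Each site is assigned a role — *centralized* sites pool their
records into a single hub client; *federated* sites keep their data — and
training proceeds as federated learning over the resulting *effective
clients*. The **degree of federation** is the fraction of all records held
by federated sites: 1 is conventional federated learning, 0 is ordinary
pooled (centralized) training, and everything between is a *hybrid* run.
The simulator's purpose is to measure, on synthetic cohorts with known
ground truth, how model quality moves along this continuum.

## Task heads

Two model heads cover the common clinical prediction tasks.

**Logistic regression** for a binary outcome: parameters
(β₀, β₁…β_d), per-record probability p = σ(β₀ + xᵀβ), loss the mean
negative log-likelihood. **Cox proportional hazards** for right-censored
survival: parameters β (no intercept — the partial likelihood is invariant
to one), risk score xᵀβ, loss the Breslow negative log partial likelihood
normalized by the number of events. The risk set at an event time t is
{j : t_j ≥ t}; tied event times share a Breslow denominator. Breslow ties
were chosen over Efron as the simplest differentiable rule. Both losses
have analytic gradients (verified against central finite differences) and
are convex in the parameters.

Normalization per record (logistic) and per event (Cox) makes one local
learning rate transfer across sites of very different sizes.

During mini-batch training a survival batch may by chance contain no
events; its partial likelihood is undefined and the batch is skipped. This
is a property of the optimizer, not the loss: `cox_loss_grad` itself
rejects event-free inputs.

## Aggregation strategies

Four strategies share one local rule (mini-batch SGD from the current
global parameters, `local_epochs` passes, step η_l) and differ as follows:

| strategy | local objective | server rule |
|---|---|---|
| FedAvg | task loss | w ← Σ (nᵢ/N) wᵢ |
| FedProx | task loss + (μ/2)‖w − w_global‖² | as FedAvg |
| FedAdagrad | task loss | Δ = avg − w; m ← β₁m + (1−β₁)Δ; v ← v + Δ²; w ← w + η·m/(√v+τ) |
| FedYogi | task loss | as FedAdagrad but v ← v − (1−β₂)Δ²·sign(v−Δ²) |

Δ, the *pseudo-gradient*, is the size-weighted client average minus the
current global model. Defaults (η = 0.1, η_l = 0.05, τ = 10⁻³, β₁ = 0.9,
β₂ = 0.99, μ = 0.1, 5 local epochs, batch 32, 50 rounds) are common
desk-scale server-optimizer settings; every field is overridable and
round-trips through YAML. `v` is initialized to τ² for the adaptive
strategies so the denominator √v + τ is bounded away from zero at round 1.
Every client participates every round (no client sampling).

Two exactness guarantees are engineered deliberately: the weighted average
accumulates terms in a canonical order (sorted by size, then parameter
bytes), so permuting the client list is bitwise neutral; and unanimous
client parameters short-circuit to the common value, so Δ = 0 is an exact
fixed point rather than one up to float rounding.

## Federation mechanics and seed policy

`build_effective_clients` concatenates the centralized sites (row-wise,
holdout masks included) into one hub placed last; federated sites pass
through untouched. The hub's aggregation weight is its pooled
training-split size — consistent with FedAvg's data-weighted average; a
1-client-share weighting was the alternative and was rejected as
inconsistent with that average.

All arms are the same loop. `run_centralized` is a single-hub FedAvg run:
T rounds of E local epochs equal T×E epochs of pooled mini-batch SGD with
a reshuffle every E epochs. `run_local` is `run_centralized` on one site
(or one pooled group, for the local baseline of a centralized group).
Benchmark arms force plain SGD locally (no proximal term, no server
adaptivity), since those mechanisms are meaningless with one client.
Consequences, all exact to the bit: an all-federated plan reproduces
`run_federated`; an all-centralized plan reproduces `run_centralized`;
single-client FedAvg reproduces local training.

Randomness derives from one master seed through SHA-256 hashing of string
keys (never Python's randomized `hash`). The train/holdout split is keyed
by `(seed, site_id)` so every arm scores identical holdouts; batch
shuffling is keyed by `(seed, client position, round)` — positional rather
than by id so that a lone pooled hub and a lone raw site shuffle
identically, which the bit-equivalences above require. Global parameters
start at zero in every arm, removing initialization variance from arm
comparisons.

**Splits.** Per site, 80/20 train/holdout, stratified by label or event
indicator. Within a stratum the holdout count is round(0.2·n), clipped to
leave at least one record on each side; a singleton stratum stays in
training (a tiny site with one positive keeps it for learning — its AUC is
then undefined on the holdout and reported as such).

**Standardization.** Each effective client z-scores its features with its
own training-split statistics — no cross-site statistics are exchanged
beyond model updates, and the centralized arm naturally standardizes on the
pooled training split because its single hub *is* the pool. The fitted
coefficients therefore live on each client's standardized scale;
`destandardize_params` maps them back exactly for single-client runs.
Parameter-recovery checks generate homogeneous cohorts whose features are
already standard normal and run with `standardize=False`, because the
generator's ground-truth β is defined on the raw feature scale.

## Evaluation

Without a server-side test set, the global model is scored on each
client's holdout and aggregated as E = Σ (nᵢ/N)Eᵢ with nᵢ the holdout
size. Metrics: accuracy (threshold 0.5), ROC-AUC in the Mann–Whitney form
(computed from mid-ranks; exactly the pairwise statistic with half credit
for ties), and Harrell's C (comparable pairs are those where the shorter
observed time ends in an event; ties in time with both events are not
comparable; risk ties earn half credit). A client whose holdout cannot
support the metric — a single-class sample, no comparable pairs — is
reported as undefined and excluded from the weighted sum with its nᵢ,
with a warning. Repeats are summarized as mean and *sample* (n−1)
standard deviation; with one repeat the SD is reported missing, not zero.

A pooled-holdout evaluation for the centralized arm needs no special mode:
its effective-client list is the single hub, so the weighted evaluation
already *is* the pooled evaluation.

## Synthetic cohorts

The generator produces what the simulator needs to be falsifiable: known
coefficients, controllable quantity skew, class imbalance, and site-level
covariate shift (a per-site mean offset on otherwise standard-normal
features — deliberately the simplest mechanism; covariance shift and
categorical features are out of scope). Labels are Bernoulli with
probability σ(a_s + xᵀβ), the site intercept a_s bisected so the *expected*
positive fraction equals the site's target exactly (the realized fraction
then differs only by binomial noise). Survival times are exponential with
rate h₀·exp(xᵀβ); censoring times are independent exponentials whose rate
is bisected per site so the expected censored fraction hits the target —
with censoring probability c/(c+λ) per subject, the calibration is exact
in expectation. Per-site streams are keyed by (seed, site_id): adding a
site never perturbs the others.

Two presets fix the cohort shapes: `heart-like` — 4 sites of
(303, 261, 46, 130) records (740 total), 13 features, binary label, with
site 2 small (n = 46) and imbalanced (15% positives) to create the
small-client scenario; `brca-like` — 6 sites of (311, 206, 196, 51, 162,
162) records (1088 total), 39 features, censored survival with per-site
censoring between 40% and 65%. The per-site sizes are fixed plausible
choices within the stated totals. What the generator does **not** emulate:
categorical/ordinal clinical codings, missingness (the data-center module
has its own defect fixtures), non-proportional hazards, and
covariance-structure differences between sites — so passing tests show
correctness of the machinery and qualitative transfer of the federation
phenomena, not performance claims about any real cohort.

## Data center

The schema-driven sharing engine applies three rules in a fixed order —
missing required field, then type/range violation (an uncoercible value is
a range violation), then duplicate key (first occurrence wins) — charging
each rejected row to the first rule it violates, so the count ledger
reconciles exactly. Across shares, keys already in the core win (earlier
uploads take precedence — deterministic and auditable), each upload is
persisted as its own file, and a JSON-lines provenance log records every
append. Cleaning is idempotent. "Enhancement" beyond cleaning is a
user-supplied hook that may transform but not add or remove rows.

## Runner

`run_experiment` executes arms × strategies × repeats (default 5) with
per-repeat seeds derived by stable hashing of (master seed, repeat index),
writes per-repeat histories/parameters/reports and a summary CSV in the
benchmark-table layout (arm, strategy-or-client, metric, mean, sd), and is
byte-reproducible under a fixed config. A failed arm is logged and
skipped; other arms continue. `grid_search_centralized` scores each
(η_l, batch size, μ) grid point by centralized training on a sub-training
split against a validation split carved from the training data (the
holdout is never touched), breaks ties toward the earliest grid point, and
scores divergent points as −∞ instead of aborting.

## Problem sizes and numerical choices

Test and acceptance runs use the preset scales (740 and 1088 records,
50–100 rounds) and 3–20 repeats; recovery checks use N = 4000
(classification) and N = 2000 (survival), where the centralized logistic
MLE's ℓ∞ error against the true β is comfortably below 0.15 and the Cox
fit reproduces every coefficient sign with rank correlation ≈ 1. Bisection
tolerances are 1e−12 on a bracket of ±60 (logit) / ±40 (log censoring
rate); zero-variance feature columns are centered but not scaled; the
logistic loss is computed via `logaddexp` and the Cox loss via a shifted
log-sum-exp, so extreme parameters saturate rather than overflow.

## Known limitations

No client sampling, dropout, asynchrony, compression, secure aggregation
or differential privacy — the simulator studies the statistical, not the
systems or privacy, side of federation. Gaussian features and exponential
hazards are idealizations chosen for calibratability. The hybrid hub sees
records as one shuffled stream (no site blocking), which is what "pooling"
means here but discards site provenance inside the hub.
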