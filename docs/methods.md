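# Methods

## Data model

A temporal hypergraph is stored as per-step sets of canonical hyperlinks
(strictly ascending node tuples) over a 1-based horizon [1, T], plus the
shared node set. All interfaces speak 1-based time; arrays are 0-based
internally. The aggregated network maps every hyperlink that is active at
least once to its binary activity series. Orders above `max_order`
(default 4) are retained in files and data structures but excluded from the
ϕ-taxonomy and prediction: in the contact data this package targets, events
above order 4 are too rare to fit coefficients for. The ϕ-type order is
fixed (d′ ascending, then overlap ascending) so coefficient vectors are
byte-reproducible across runs.

## Ingestion and clique promotion

Contact streams are whitespace-separated `t i j` records; in raw-seconds
mode timestamps are divided by the step length (20 s default) and shifted
so the first contact is at step 1. Preprocessing restricts to the largest
connected component of the time-aggregated pairwise graph (ties broken
toward the component containing the smallest node id) and deletes maximal
runs of more than `gap_threshold` empty snapshots (default 180 steps = one
hour at 20 s; the threshold is a required, documented choice because
"nights and weekends" is not a number), re-indexing time contiguously.
Promotion runs per snapshot and uses Bron–Kerbosch with pivoting
(`networkx.find_cliques`); snapshots are small, so worst-case exponential
behaviour is acceptable in exchange for exactness. Promoted data satisfy
the no-nesting invariant: no event is a strict subset of a co-occurring
event. Promotion inverts pairwise decomposition exactly on promoted
networks, which the tests exercise as a round trip.

## Memory statistics

Jaccard similarity J_d(Δ) averages |ℰ_t^d ∩ ℰ_{t+Δ}^d| / |union| over t,
skipping steps whose union is empty (0/0 is undefined, not zero).
Auto-correlation is the Pearson correlation of an activity series with its
lag-Δ self; slices with zero variance are undefined and excluded from
averages rather than scored 0 — undefined is not the same as uncorrelated —
and every reported average carries its contributing count so the exclusion
is auditable. Cross-correlation R_{i,ϕ}(Δ) correlates the summed activity
of the ϕ-neighbour set at t with the target at t+Δ (neighbour leads, the
direction in which the predictors use the information; `lag_direction`
exposes the alternative). Averages weight hyperlinks equally, not by
activity. For the target type ϕ = (d,d,d) the cross-correlation reduces to
the auto-correlation exactly.

## Predictors

The decayed feature y_i^ϕ(t) sums neighbour activity over the window
[t−L+1, t] with weight e^{−τ(t−k)}; a full window is required (prediction
starts at t+1 = L+1). Defaults L = 30, τ = 5: at 20 s resolution a
10-minute observation predicting one step ahead, with τ in the range where
accuracy is known to plateau for this family of models.

Coefficients are fitted per order by Lasso over all (hyperlink, step) rows.
The penalty uses the standard per-sample-normalized convention
((1/2n)‖x−w‖² + α‖c‖₁): on the published grid of 200 log-spaced α in
[10⁻¹⁹, 10] the top of the range then genuinely shrinks every coefficient
to zero, which an unnormalized sum-of-squares objective would not. α is
selected by 5-fold cross-validated MSE (shuffled folds, seeded); the
intercept is not penalized, following standard practice — a
`penalize_intercept` switch implements the literal alternative. Features
are not standardized by default (an option enables it; fitted coefficients
are reported on the original scale either way). Training uses the whole
observation window, matching the reference evaluation protocol; a
`train_until` argument enables honest past-only fitting. Degenerate labels
(all equal) yield an intercept-only model with a warning.

Top-n selection takes the n_d highest-tendency hyperlinks per order, with
the true per-order counts supplied by the evaluation protocol (they are
assumed known). Candidates strictly above the boundary are deterministic;
boundary ties are resolved uniformly at random, and accuracy is averaged
over realizations (default 100 for tendency and activity-driven models, 10
for the costlier group-change model), each (step, realization) drawing from
a fresh substream of the root seed so runs are bit-reproducible and
parallelizable.

The self-driven baseline scores each aggregated pairwise link by its own
decayed activity, selects the true number of decomposed pairwise contacts
at t+1, and promotes maximal cliques of the predicted edge set; its
per-order event counts are emergent. The count fed to it is the
clique-decomposed pair count (the model explicitly views the network as
pairwise).

## Group-change baseline

Each node occupies exactly one group (singletons are isolated nodes). The
change probability is read as p_d(τ) = b_d(τ^β + 1)/N with β < 0 — the
printed form is typographically ambiguous and the alternative
b_d·τ^{β+1}/N is selectable — clipped to [0, 1] since the curve is a rate
proxy. Estimation from an observed network: a node's group at t is the
largest event containing it (ties toward the lexicographically smallest);
an observable change is any difference in its group's membership between
consecutive steps, and residence times reset on change. The pooled change
frequency as a function of residence time is fitted by the model-form
curve a(τ^β + 1) via weighted nonlinear least squares; given β, per-order
amplitudes b_d follow by weighted least squares and are smoothed by the
logistic b_d = d₀/(1 + e^{−a(d−1)}).

A caveat the tests make explicit: in the full sequential dynamics the
*observable* per-node change hazard exceeds the latent p_d(τ) because
co-members' moves also change a node's group, so β estimated from such data
is biased. The recovery test therefore uses an atomic-reshuffle process
(paired groups that re-split wholesale, all members sharing the residence
time), whose observable hazard equals the model curve by construction;
there the exponent is recovered to ~10 % and the amplitude ordering
exactly.

Simulation: nodes update in a random permutation, each seeing the current
configuration. A changer joins any other group — singletons included,
which is how new pairs form — with probability proportional to the fraction
of its members encountered in events within [t−L, t], or becomes isolated:
the empty set participates with multiplicity ε (default 100), each copy
with unit weight, so large ε drives changers to isolation. The changer's
old group disbands to singletons. Encounter information from t+1 (future
peeking) is off by default behind a flag. Predictions are the non-singleton
groups after one stochastic step from the state reconstructed at t; the
model does not use the true event counts, and its order-2 count
distribution measurably departs from the truth, part of why it trails every
other model.

## Synthetic generators

The Markov generator defines the package's study conditions. Defaults: 30
nodes; pools of 60/30/10 hyperlinks of orders 2/3/4 drawn top-down with
half of each lower order nested inside pooled higher-order links (so
sub/super structure exists); persistence p = 0.9; activation q = 0.05;
cross-order coupling κ multiplying the activation odds when a nested
pool-mate was active at t−1 (default 0.5; the model-ranking experiments use
κ = 2.0 so that neighbour history contributes on a par with the strong
sub-/super-correlations the refined model is designed around); horizon 200
(120 in the replicate experiments). The two-state chain gives closed-form
lag-1 autocorrelation p − q, which the tests check at 3 standard errors.
An optional maximality pass prunes events nested in co-occurring events,
reproducing the signature of clique-promoted data; note it also suppresses
a sub-link's visibility while its super-link is active, so snapshot-level
sub/super correlations on pruned data can be negative even though the
latent coupling is positive.

The refined-rule generator inverts the prediction model into a generative
process for parameter-recovery tests: after a burn-in at the target rate,
each hyperlink activates with probability base_rate + s_d·w_i(t), where
w_i(t) is the refined tendency under known per-kind coefficients. The
per-order scale s_d is computed analytically from the pool's
coefficient-weighted neighbour counts so the self-consistent activity rate
equals `expected_rate`; a fixed analytic scale keeps the rule linear in the
features (a per-step renormalization would not be recoverable) and avoids
calibration noise. Because the loop gain is 1 − base_rate/expected_rate,
base_rate should stay a substantial fraction of expected_rate (the
experiments use 0.05 against 0.15) or stochastic fluctuations push the
process into probability clipping and break linearity.

The contact-stream generator emits SocioPatterns-dialect lines whose
planted truth is, by construction, the maximal-clique promotion of its own
pairwise decomposition, so ingestion recovers it exactly.

What the generators do not emulate: circadian and weekly activity rhythms,
node-level heterogeneity in sociability beyond pool membership, group
splitting/merging dynamics, and order-5+ events. Passing tests therefore
demonstrate correctness of the machinery and the qualitative memory-driven
model ranking, not performance figures transferable to any particular
empirical dataset.

## Evaluation

Accuracy is true positives over the true number of events of that order at
that step; steps with no true event of an order are skipped for that order
(the ratio is undefined). Averaging is per step over realizations, then
over steps. Problem sizes in the shipped experiments — 120-step replicate
networks, 100-hyperlink/2000-step chains for closed forms, 210-hyperlink/
500-step recovery runs, 20 replicates for the ranking comparison — were
chosen as the smallest at which the statistical checks have comfortable
power at 3-SE tolerances.

On the synthetic conditions the refined and general models perform within
noise of each other (both fit the same dominant target/sub/super signal and
are trained in-window); the ranking test asserts the ordering refined ≥
general ≥ self-driven ≥ activity-driven up to a 3-SE allowance on the
paired per-replicate differences, which is the strongest claim the data
support.

## Known limitations

- Fitting on the full observation window is optimistic by construction;
  `train_until` exists but is not the default protocol.
- The group-change β estimator is one defensible choice among several for
  an under-specified procedure; its diagnostics (raw b_d, τ support) are
  attached to the fitted parameters.
- Lasso coefficient paths are computed by independent fits per α rather
  than a homotopy path; for the feature counts here (≤ 9 per order) this is
  simple and fast, not optimal.
- `AggregatedHypergraph.neighbors_of` scans node-indexed candidates; for
  networks far larger than the SocioPatterns scale an inverted-index or
  bitset design would be preferable.
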