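# hypercast

Memory-based prediction of higher-order temporal networks.

Face-to-face social interactions often involve groups, not just pairs. A
group interaction among nodes *u₁, …, u_d* is the activation of a
*hyperlink* of order *d* at a discrete time step, and a sequence of such
snapshots is a temporal hypergraph *H = {H₁, …, H_T}*. Predicting which
hyperlinks will be active one step ahead matters for forecasting and
mitigating spreading processes (epidemics, information) on physical-contact
networks. `hypercast` implements an interpretable, memory-based framework
for this problem: it quantifies how much such networks remember their past,
and exploits that memory with linear models whose coefficients reveal
*which kinds* of past interactions carry the predictive signal.

## The model

Every hyperlink *i* in the time-aggregated network carries a binary
activity series *xᵢ(t)*. For a target hyperlink of order *d*, a neighbour
of order *d′* sharing *o ≥ 1* nodes is a *ϕ = (d d′ o)*-neighbour; the
special cases are the target itself (*d = d′ = o*), sub-hyperlinks
(*o = d′ < d*) and super-hyperlinks (*o = d < d′*). The activation tendency
at prediction step *t + 1* is

```
w_i(t+1) = Σ_{ϕ∈Φ_d} c_ϕ · y_i^ϕ(t) + c_d,
y_i^ϕ(t) = Σ_{k=t-L+1}^{t} Σ_{j∈S_i^ϕ} x_j(k) · e^{-τ(t-k)},
```

with observation window *L*, exponential decay factor *τ*, and *S_i^ϕ* the
set of ϕ-neighbours of *i*. Coefficients are learned per order by Lasso
regression over every prediction step, with the penalty chosen by
cross-validated grid search over 200 log-spaced values in [10⁻¹⁹, 10].
Given the true number *n_d* of order-*d* events at *t + 1*, the *n_d*
highest-tendency hyperlinks are predicted active (boundary ties broken
uniformly at random, averaged over realizations).

Variants and baselines, all under one evaluation protocol:

- **general** — all neighbour types Φ_d;
- **refined** — only the target, sub- and super-hyperlinks;
- **self-driven** — pairwise-only memory (the tendency above with the
  target term only, on the clique-decomposed pairwise network), promoted
  back to higher-order events via maximal cliques;
- **activity-driven** — per-order node activity potentials, no memory;
- **group-change** — residence-time dynamics: a node in a group of size
  *d* changes group with probability *p_d(τ) = b_d(τ^β + 1)/N*, joining
  groups of recently encountered nodes or becoming isolated.

Ingestion follows SocioPatterns conventions: pairwise contact records
`t i j` at 20 s resolution, restriction to the largest connected component,
removal of long inactivity gaps, and promotion of each snapshot's maximal
cliques to events (so a hyperlink and its sub-hyperlinks are never active
simultaneously). Synthetic generators with controllable memory (per-link
Markov persistence, cross-order coupling, clique-consistent contact
streams) make every claim testable without external data.

## Worked example

Simulate a memory-rich network (30 nodes, 120 steps, orders 2–4), then
evaluate the refined model and the pairwise self-driven baseline:

```sh
hypercast simulate events.tsv --steps 120 --seed 1 --maximality
hypercast evaluate events.tsv report.tsv --model refined --realizations 10 --seed 0
hypercast evaluate events.tsv report_sd.tsv --model self-driven --realizations 10 --seed 0
```

prints

```
model       order  mean_accuracy  n_steps  n_realizations
refined     2      0.827618       90       10
refined     3      0.832513       90       10
refined     4      0.879894       90       10

self-driven 2      0.407138       90       10
self-driven 3      0.771179       90       10
self-driven 4      0.904907       90       10
```

Accuracy is the fraction of true events recovered, averaged over the 90
prediction steps (t+1 ∈ [31, 120]) and 10 tie-breaking realizations. The
refined model, which uses each hyperlink's own decayed history plus its
sub-/super-hyperlinks, recovers ≈ 83 % of order-2 and order-3 events; the
pairwise baseline collapses on order 2 (41 %) because decomposing groups
into pairs and re-promoting cliques merges co-occurring events.

The memory statistics behind this gap:

```sh
hypercast memory events.tsv memory.tsv --max-lag 3
```

```
statistic  order_or_phi  delta  value     n_samples
jaccard    2             1      0.761174  119
jaccard    2             2      0.622176  118
jaccard    2             3      0.521195  117
...
```

Snapshot similarity decays with the time lag — the time-decaying memory
that the exponential kernel converts into predictive weight.

Other subcommands: `ingest` (contact stream → preprocessed event list with
a per-order event report), `fit` (write per-order Lasso coefficients),
`predict` (one-step event prediction), `sweep` (accuracy over coefficient
or (τ, L) grids).

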