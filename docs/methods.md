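# Methods

## Observation model and data structures

A `PartialNetwork` is an undirected simple graph whose nodes carry a
respondent flag.  The observation design is the one induced by downloading
respondents' friend lists: every dyad with at least one respondent endpoint
is observed (present or absent), every nonrespondent–nonrespondent (NN)
dyad is unobserved.  The three dyad classes always satisfy

    observed_present + observed_absent + unobserved = C(n, 2),

and this conservation identity is asserted throughout the test suite.
Edges between two nonrespondents in input files are rejected with a named
error rather than reclassified: under this design they cannot have been
observed, so their presence indicates corrupted input.

Every node's *sociability covariate* `c_i` — its observed number of
respondent friends — is recomputed from the edge list at construction.  It
is therefore impossible for the covariate and the edges to disagree.  For
respondents the covariate counts respondent neighbours only; this is one of
two readings of "degree with respondents" and is the one adopted here
because it is invariant under both the boundary (respondents are never
dropped) and imputation (which only adds NN edges).

## Boundary specification

`apply_boundary(net, k)` retains all respondents and exactly the
nonrespondents with `c_i >= k`.  Sociability covariates are unchanged by
construction.  The threshold is an absolute count; the percentage form
(k as a share of respondents) is derived output only.  `boundary_table`
reports, per candidate k, the retained nonrespondents, the retained
respondent–nonrespondent edges and the implied `C(n_retained, 2)`
unobserved dyads — the quantity that makes too-low boundaries
computationally and statistically untenable (it grows quadratically).
A k above the maximum observed covariate yields an empty nonrespondent set
with a warning, not an error: it is a legitimate, if extreme, design choice.

## The dyad model and its estimation

The imputation model is an exponential-family random graph model with three
statistics: edge count, sociability (`c_i + c_j` summed over edges) and
selective mixing (number of respondent–nonrespondent edges).  All three are
*dyad-independent*: no statistic couples distinct dyads.  The likelihood
therefore factorises, and the ERGM MLE conditional on the observed dyads is
exactly the logistic regression of dyad state on
`(1, c_i + c_j, 1{mixed})` over the observed dyads.  `fit_dyad_model`
performs this fit with statsmodels' GLM (Binomial), reporting
observed-information standard errors.  Estimation is exact and
deterministic; MCMC would add noise and nothing else.

Degenerate inputs raise named errors: all-present or all-absent observed
dyads (`SeparationError` — the MLE diverges) and rank-deficient designs
(`SingularDesignError` — e.g. a single respondent makes the mixing
indicator collinear with the intercept).

The mixing term carries the *dampening* interpretation: on study-like data
it is positive, so at equal sociability an NN dyad (mixing = 0) has lower
predicted probability than a mixed dyad.  Imputed NN density is therefore
below what proportional scaling of the observed quadrants would give.

## Multiple imputation

Because the model is dyad-independent and every unobserved dyad is NN
(mixing statistic 0), a draw from the fitted model conditional on the
observed data imputes each unobserved dyad independently with probability
`logistic(theta_edges + theta_soc * (c_i + c_j))`.  `impute_ensemble` does
exactly this for M networks (default M = 100).  Covariates are frozen at
their observed values: the sociability covariate counts respondent
friends, which imputation cannot change.

Per-imputation randomness comes from streams derived from the master seed
by fixed offsets (`default_rng([seed, m])`), so member m is reproducible in
isolation and under any execution order.

`toggling_sampler` implements the Metropolis toggling restricted to
unobserved dyads that a general ERGM simulator would use.  Its acceptance
ratio depends only on the toggled dyad's log-odds, so its stationary
distribution equals the independent-Bernoulli scheme; the acceptance suite
verifies the two samplers agree within Monte-Carlo error.  It exists as a
fidelity check on the procedure, not as the default path.

`imputation_diagnostics` reports the mean/min/max imputed edge count, the
maximum deviation as a percentage of the mean (the "is M large enough"
diagnostic) and the mean imputed NN density.

## Selection algorithms

**Eigenvector centrality.**  Power iteration with a uniform start vector,
relative-change tolerance 1e-10 and a 10,000-iteration cap, normalised to
unit Euclidean length.  Iteration runs on `A + I` rather than `A`: the
shift preserves eigenvectors while making the Perron root strictly dominant
in modulus, without which power iteration oscillates on bipartite graphs
(adjacency spectra symmetric about zero — star graphs are the simplest
failure case).  Nodes outside the dominant component receive scores
decaying to ~0.  On an edgeless graph every vector is an eigenvector of
`A + I`; the uniform vector is returned and selection falls back to the id
tie-break.  `top_m` breaks boundary ties lexicographically by node id, so
selection is fully deterministic.

**Keyplayer positive (KPP-Pos).**  The fitness of a set S is Borgatti's
distance-weighted reach `D_R(S) = (Σ_{j∉S} 1/d(S,j)) / n`, with `1/∞ = 0`
for unreachable nodes and members contributing through the normalisation
only.  The verbal description of the keyplayer objective admits several
formalisations; the distance-weighted reach implemented by the R packages
in this literature is adopted and documented as an interpretation.  The
search is greedy seeding (add the node with the largest fitness gain, ties
to the lexicographically first id) followed by improvement-only swap
sweeps: members are visited in a seeded random order and each is offered
its best nonmember replacement; a sweep with no accepted swap terminates
the search.  Restarts beyond the first hill-climb from seeded random
initial sets, and the best set across restarts is returned — never worse
than the pure greedy seed.  Defaults (`kp_restarts=1, kp_max_sweeps=4`)
keep an 885-node, m=300 selection well under a minute; the small-graph
oracle comparisons in the acceptance suite use more restarts, where
exhaustive search shows the optimum is then attained essentially always.
All-pairs hop distances come from scipy's csgraph BFS.

**Ensemble aggregation and the sufficiency cutoff.**  Each algorithm runs
on the observed network (unobserved dyads treated as absent) and on every
ensemble member; `counts[v]` is the number of members on which v was
selected.  The sPCA set is `{v : counts[v] >= t*}` where `t*` scans
M down to 1 and minimises `| |set(t)| - m |`; ties prefer the larger t,
i.e. the smallest set closest to the target size.

## Evaluation measures

*Sensitivity* is, per respondent-status class, the share of sPCAs that
were also PCAs on the observed network.  The sPCA side is the denominator,
matching the reading "sPCAs who also appeared on the observed network".
*Stability* summarises counts conditional on selection (mean, sample SD,
mode with ties to the smallest value — a tie rule the source material does
not specify).  *Boundary effect* is the minimum sociability covariate among
selected nonrespondents, flagged when it equals k (selection pinned to the
inclusion rule).  Boundary sensitivity across k is operationalised as the
Jaccard overlap of sPCA sets for consecutive k — an extension chosen here
because the minimum-degree observation alone does not quantify overlap.
Every reported proportion carries its numerator/denominator pair and is
mechanically checked to be recomputable from them.

## The synthetic generator

`generate_complete_network` draws, in order: (1) respondent–respondent
dyads as homogeneous Bernoulli(`p_rr`); (2) a latent gamma propensity per
node, then respondent–nonrespondent dyads with log-odds
`theta_edges + theta_soc (prop_i + prop_j) + theta_mix`; (3) NN dyads with
log-odds `theta_edges + theta_soc (c_i + c_j)` using the *realised* degree
with respondents from step 2 — the same covariate the imputation model
conditions on.  A misspecification toggle substitutes the latent
propensities in step 3 for robustness experiments.  Masking then hides all
NN dyads, retaining their true states for evaluation.

Defaults are calibrated to the study conditions the package is designed
around and then frozen: 300 respondents, a 2,100-node nonrespondent pool,
`p_rr = 0.074`, gamma(shape 4, rate 1/7) propensities and boundary k = 30.
These yield roughly 520–660 retained nonrespondents, a
respondent–respondent density of ~7.5%, a retained mixed-quadrant density
of ~15–16%, retained covariates starting exactly at 30 with a long right
tail, and a mean imputed NN density around 19–20% — the qualitative
signature of the motivating setting (denser mixed quadrant, right-skewed
degrees, boundary-pinned minimum).  `theta_true` defaults to
(−5.36, 0.044, 0.208), a realistic magnitude profile for sparse friendship
networks of this kind.

What the generator does **not** emulate: recruitment dynamics (the
respondent set is given, not chain-referred), homophily on nodal
attributes, triadic closure, and the pre-boundary scale of real friend-list
data (hundreds of thousands of weakly attached nonrespondents).  Passing
tests therefore certify the pipeline's internal correctness and its
behaviour under the stated dyad-level data-generating process — not
robustness to higher-order structure real networks possess.

## Identifiability of the generative parameters (known limitation)

The acceptance suite includes a generate–mask–refit experiment asking
whether the fitted `(theta_edges, theta_soc, theta_mix)` land within 3
standard errors of the generating values.  They systematically do not, and
the reason is structural, not a bug: the sociability covariate is the
realised degree built from the very dyads being modelled.  For a mixed dyad
(i, j), `Σ_i y_ij = c_j` *identically*, so `E[y_ij | c_j = k] = k/R`
whatever `theta_soc` generated the data; the slope visible to the
likelihood in the `c_j` direction is `d logit(k/R)/dk ≈ 1/k + 1/(R−k)`, a
function of network scale only.  With ~230,000 observed dyads the standard
errors are ~10⁻⁴ while this structural gap is ~10⁻², so the recovery rate
is ~0%.  The estimator itself is correct — the unit suite shows exact
3-SE recovery when responses are simulated from an exogenous design
matrix — and the fitted model remains the right *predictive* object for
imputation, which conditions on the same realised covariates.  The
experiment is retained, reported honestly by `scripts/acceptance.py`
(`theta_recovery_rate_pct`), and its failing assertion is kept in the
acceptance tests as a documented red: degree-defined covariates do not
identify the generative slope.

## Problem sizes and determinism

Unit tests run on hand-built fixtures (≤ 20 nodes) and small generated
datasets (30 respondents / 120-node pool); the acceptance experiments use
the study-scale defaults for recovery and imputation summaries, 100 random
graphs of ≤ 12 nodes for the eigensolver and exhaustive-search oracles,
M = 2000 imputations for the Monte-Carlo closed-form check, and a
60-respondent / 120-pool configuration for the byte-identical end-to-end
rerun.  These sizes were chosen so the whole suite completes in about half
a minute while leaving every Monte-Carlo comparison with comfortable
standard-error margins.

All randomness flows from explicit integer seeds through numpy
`SeedSequence` derivations; identical configurations produce byte-identical
artifacts (the config echo excludes the output directory so the guarantee
holds across locations, and log lines carry no timestamps).  Reported
percentages are rounded half-away-from-zero to one decimal at the reporting
layer only; proportions are kept unrounded internally.
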