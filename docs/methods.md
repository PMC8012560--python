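# Methods

## Model

A symptom network over $n$ binary nodes is parameterized by thresholds
$\tau \in \mathbb{R}^n$ and a symmetric zero-diagonal weight matrix
$W$.  In the default $\{0,1\}$ coding the joint law is
$P(x) \propto \exp(\sum_i \tau_i x_i + \sum_{i<j} W_{ij} x_i x_j)$;
each unordered pair contributes once.  The $\{-1,1\}$ coding describes
the same family after an exact, involutive reparameterization
(`convert_domain`): under $x=(s+1)/2$,

$$W' = W/4, \qquad \tau_i' = \tau_i/2 + \tfrac14\textstyle\sum_j W_{ij},$$

and conversely $W = 4W'$, $\tau_i = 2\tau_i' - 2\sum_j W_{ij}'$.  All
analyses default to $\{0,1\}$, where the sum score $Y=\sum_i x_i$ is
the number of active symptoms.

### Exact computation

`joint_distribution` enumerates all $2^n$ states in blocks and
normalizes with log-sum-exp, so strongly activated regimes (the risk
conditions reach potentials of order $e^{36}$) stay finite.  The
enumeration cap defaults to 20 nodes ($2^{20}$ states, ~1 M rows,
comfortably in memory) and is a per-call parameter; beyond it the error
message points to the sampler.  ESA and SAS are moments of the
sum-score marginal; probabilities are validated to sum to 1 within
1e-10.

A useful exact symmetry: whenever $\tau_i = -\tfrac12\sum_j W_{ij}$ for
all $i$ (which includes every uniform network with $\tau = -w(n-1)/2$,
and is preserved by multiplying $\tau$ and $W$ by one common constant),
the sum-score law is mirror-symmetric and ESA is exactly $n/2$.  This
is why "both"-target sweeps of the 9-node baseline hold ESA at 4.5
while SAS varies.

### Metrics

ESA is $E(Y)$; SAS is $1/\sigma$ with the *population* denominator,
mirroring the probability-level definition (a `ddof` switch provides
the sample convention for observed data).  A point-mass sum score has
$\sigma=0$; SAS is then reported as a typed degenerate signal
(`sas=None`, `degenerate=True`), never as infinity, so result tables
can render the condition explicitly.  The joint-distribution entropy
$-\sum p \log p$ is reported in nats; it tracks the same
organized-vs-diffuse notion that SAS measures on the sum score.

## Perturbations

RP-factor influence multiplies parameters by a positive constant:
thresholds (main effects), present edge weights (moderators), or both
with one shared constant.  Absent edges stay absent; inputs are never
mutated; applying $c_1$ then $c_2$ equals applying $c_1 c_2$.  The
canonical grid is $\{0.5,\dots,0.9,1\}$ together with the *exact*
inverses $1/0.9,\dots,1/0.5$ — the printed forms 1.11/1.25/1.43/1.67/2
are display roundings.  Risk/protective labels are derived from the
sign conventions (negative thresholds, positive weights), not stored.
Targeted designs pass node subsets (thresholds) and the subset of edges
incident to those nodes (moderators); incident-edge semantics is the
default, with a `within_only` flag restricting to edges inside the set.

## Sampler

For large networks, `sample_chain` runs a single-site chain: node $i$
is redrawn from its full conditional
$P(x_i=1\mid x_{-i}) = \mathrm{logistic}(\tau_i + \sum_j W_{ij}x_j)$.
This full-conditional (Gibbs) update coincides with the
Metropolis-Hastings variant whose proposal flips one node and accepts
with the conditional probability of the proposed value, so both
descriptions yield the same chain.  An *iteration* is one single-node
update by default (sequential sweep order); `per_sweep=True` makes an
iteration a full sweep of $n$ updates, which is the right unit when
kept states should be nearly decorrelated (e.g. when comparing
empirical state frequencies against exact probabilities).  Burn-in
defaults to 0 and initialization to i.i.d. Bernoulli(1/2).  Chains are
bit-reproducible under a seed; multiple chains derive child seeds from
the root seed and stack row-wise.

## Estimation

`fit_elasso` re-implements the nodewise penalized-regression estimator
for Ising networks: each item is regressed on all others with L1
logistic regression over 100 log-spaced penalties (from the smallest
all-zero penalty down to 0.001 of it), the per-node model minimizes
$\mathrm{EBIC}_\gamma = -2\ell + d\log N + 2\gamma d \log(p-1)$ with
$\gamma = 0.25$, and directed neighborhoods are symmetrized by the AND
rule (edge present only if both directions retain it; weight = mean of
the two coefficients; OR rule and max-magnitude combination available).
Intercepts become thresholds.  The inner solver is scikit-learn's
liblinear; because liblinear penalizes the intercept, a large
`intercept_scaling` keeps the threshold effectively unpenalized, as is
conventional.  Predictors are left on their 0/1 scale.  Items constant
in the data are dropped with a warning; suspiciously large coefficients
trigger a separation warning.

Ordinal five-level items are binarized before estimation with the
standard cut: levels 0–2 (no/modest presence) map to 0, levels 3–4
(moderate/high presence) to 1; the cut is configurable.

## Hybrid models and conditioning

A hybrid model holds symptoms and RP factors with per-node intercepts
and linear coefficients on every other node (a nodewise-linear
parameter set, as produced by mixed-graphical-model or OLS nodewise
regressions; ordinal variables treated as continuous).  Conditioning
clamps chosen factors ("presence" = scale maximum, "absence" = 0, both
configurable), holds the other factors at baseline means, and iterates
every symptom's regression

$$m_s \leftarrow a_s + \sum_{t\neq s} B_{st}\, m_t$$

to a fixed point (tolerance 1e-8, cap 1000 iterations; divergence
raises with the worst-residual nodes named).  The fixed point was
chosen over a single prediction step so that effects propagate through
neighboring symptoms — a symptom with no RP association can still move
if its neighbors have one; a `one_step` mode supports sensitivity
analysis.  Conditioned means are clipped to each symptom's observed
scale with clipping counted; in-hull scenarios on consistent models
never clip.  ESA of a conditioned system is the sum of conditioned
symptom means; the delta of a scenario is taken against the
*empty-scenario fixed point*, so an empty scenario yields exactly 0
(for models fitted by OLS, whose regressions pass through the data
means, this equals the stored baseline).  SAS is deliberately not
defined here: clamping factors in a nodewise-linear model does not
change symptom variance patterns, so an inverse standard deviation
would not measure stability.

## Synthetic data

Three generators, all seed-deterministic:

- `sample_ising_exact` draws i.i.d. states by inverse-CDF over the
  enumerated distribution — the independent-sample counterpart of the
  chain, used as the oracle route in estimator tests.
- `generate_ordinal_scl` produces correlated five-level items from a
  one-factor latent Gaussian (pairwise latent correlation 0.3 by
  default) with item cutpoints calibrated so binarized prevalences are
  uniform in 5–40%, the realistic screening range.  It exercises
  binarization and estimation; it does not claim to match any
  particular instrument's empirical margins.
- `generate_hybrid_dataset` builds a linear structural system: sparse
  symmetric symptom-symptom coupling, planted symptom-factor
  coefficients whose sign follows the factor role (risk positive,
  protective negative), Gaussian residuals, and intercepts solved so
  population symptom means hit a target.  It returns the data together
  with the generating nodewise model, so conditioning and fitting can
  be checked against known truth.  Symptom scores are continuous and
  unclipped — a deliberate simplification keeping the nodewise-linear
  truth exact; it does not emulate ordinal discreteness or
  non-Gaussian residuals, so passing tests speak to the conditioning
  machinery, not to robustness against those features of real data.

The default hybrid recipe has 27 symptoms and five factors (a 0–3
substance-use risk score; binary physical activity; five-level
religious practice and volunteer work; six-level sexual-life
satisfaction) with modest planted effects, mirroring the situation
where RP factors exert small pulls on total symptom activity.

## Experiment drivers and problem sizes

`run_study1` sweeps 11 constants x 3 target types x densities
(1, 0.5, 0.3) on the 9-node uniform family, exactly; density-1 results
are seed-independent, lower densities regenerate a random structure per
seed and are trend-level quantities.  `run_study2` targets the 5
strongest/weakest nodes (by node strength, the sum of absolute incident
weights; ties broken by label order) of a heterogeneous 27-node
network and sweeps with chain sampling; the bundled synthetic network
draws weights log-uniform on [0.05, 1] and thresholds around -2.5,
keeping the unperturbed regime healthy (ESA ≈ 3 of 27) so targeted risk
effects have room to act.  `run_study3` evaluates
protective-present/risk-absent and the reverse scenario on a hybrid
model.  Every output row carries the config hash, seed and package
version.

Default chain lengths in tests and drivers (6k–200k kept states) were
sized so Monte-Carlo error is a small fraction of the effects examined;
oracle-equivalence checks use 200k kept states separated by full
sweeps.  Estimator-recovery simulations use a sparse 10-node truth
(density 0.25, weights 1, thresholds -2, giving realistic 10–35%
prevalences) at N = 500–2000 persons over 50 seeds.

## Known limitations

- Exact computation is exponential in $n$; the practical ceiling is the
  configured 20-node cap.
- The Ising model is static: feedback loops between factors and
  symptoms, differing time scales, and time-varying parameters are out
  of scope.
- Conditioning treats ordinal variables as continuous and is silent on
  causal direction; estimated edges are associations.
- The eLasso false-positive behavior depends on the data regime; in
  high-prevalence, strongly coupled regimes even the reference
  procedure admits occasional spurious small-weight edges.
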