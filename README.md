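# netresil

Resilience analysis of binary symptom networks under risk and
protective factors.

## The problem

In the network view of psychopathology a mental disorder is not the
downstream effect of one latent cause but the behavior of a system of
causally interacting symptoms.  Each symptom $X_i \in \{0, 1\}$ carries
a *threshold* $\tau_i$ (its autonomous disposition toward activation)
and each symptom pair an *edge weight* $W_{ij}$ (the strength of their
interaction); together these form the network architecture, modelled as
an Ising distribution

$$P(x) = \frac{1}{Z}\exp\Big(\sum_i \tau_i x_i + \sum_{i<j} W_{ij} x_i x_j\Big).$$

External risk and protective (RP) factors — substance use, social
support, physical activity, vicious cognitive patterns — do not appear
as nodes of this network; they *reshape its parameters*.  A factor
acting on thresholds is a causal **main effect**; a factor acting on
edge weights is a causal **moderator**.  `netresil` operationalizes
such influences as multiplicative perturbations and quantifies the
resulting resilience with two metrics on the sum score
$Y = \sum_i X_i$:

- **ESA** (Expected Symptom Activity): $\mu = E(Y) = \sum_i i\,P(Y=i)$ —
  how many symptoms the network keeps active on average;
- **SAS** (Symptom Activity Stability): $1/\sigma$ where
  $\sigma^2 = \sum_i (i-\mu)^2 P(Y=i)$ — how tightly activity
  concentrates around that mean.

A resilient network has low ESA *and* high SAS: few symptoms, stably
few.  For networks of up to ~20 nodes both metrics are computed exactly
by full state enumeration; larger networks are handled by a single-site
Gibbs/Metropolis sampler.  The package also estimates networks from
binary item data (nodewise L1-penalized logistic regression with EBIC
selection), and analyzes hybrid symptom + RP-factor models by
conditioning on factor values.

It is written for researchers in network psychometrics and
computational psychiatry who want to simulate, estimate and stress-test
symptom networks from Python.

## Worked example

```python
import netresil as nr

net = nr.uniform_network(9, tau=-2.0, w=0.5)   # fully connected baseline
ssd = nr.sumscore_distribution(nr.joint_distribution(net))
rep = nr.resilience_exact(ssd)
print(f"ESA = {rep.esa:.2f}, SAS = {rep.sas:.2f}")

risky = nr.apply_moderator(net, 2.0)            # risk moderator: edges x2
rep2 = nr.resilience_exact(nr.sumscore_distribution(nr.joint_distribution(risky)))
print(f"ESA = {rep2.esa:.2f}, SAS = {rep2.sas:.2f}")
```

prints

```
ESA = 4.50, SAS = 0.34
ESA = 8.98, SAS = 6.47
```

The unperturbed network keeps 4.5 of 9 symptoms active on average, with
a sum-score standard deviation near 3 (SAS 0.34): moderate but highly
unstable activity.  Doubling every edge weight — a global risk
moderator — locks the network into a nearly fully active, very stable
disorder state (ESA 8.98, SAS 6.47): high stability is only desirable
around a *healthy* state.

The `examples/` directory walks through each capability: exact metrics,
perturbation sweeps, chain sampling with strong/weak-node targeting,
network estimation from ordinal data, and hybrid-model conditioning.
A thin CLI wraps the experiment drivers
(`netresil study1|study2|study3|metrics|estimate`).

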