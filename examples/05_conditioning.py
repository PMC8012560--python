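"""Conditioning a hybrid symptom + RP-factor model on factor values.

Generates a hybrid dataset with planted effects (risk factors push
symptoms up, protective factors pull them down), fits a nodewise linear
model, and conditions on the two canonical scenarios: protective
factors present (at their scale maximum) with risk absent (at 0), and
the reverse.  The ESA deltas quantify how much total symptom activity
the factors move; their signs follow the planted structure.
"""

import netresil as nr

spec = nr.default_hybrid_spec(seed=11, n_persons=3000)
data, truth = nr.generate_hybrid_dataset(spec)
model = nr.fit_nodewise_linear(
    data, truth.symptom_labels, truth.factor_labels,
    factor_roles=truth.factor_roles,
)

protective = [f for f, r in model.factor_roles.items() if r == "protective"]
risk = [f for f, r in model.factor_roles.items() if r == "risk"]

baseline = nr.condition_means(model, nr.ConditioningScenario({}))
print(f"27 symptoms on a 0-4 scale; highest possible ESA = {4 * 27}")
print(f"baseline ESA = {nr.conditioned_esa(baseline):.2f}")

for name, sc in {
    "protective present / risk absent": nr.presence_scenario(
        model, present=protective, absent=risk),
    "risk present / protective absent": nr.presence_scenario(
        model, present=risk, absent=protective),
}.items():
    esa = nr.conditioned_esa(nr.condition_means(model, sc))
    delta = nr.esa_delta(model, sc)
    print(f"{name}: ESA = {esa:.2f} (delta {delta:+.2f})")
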