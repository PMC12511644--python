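"""Simulate the drug-choice DCE and fit the standard-practice model.

Generates a small version of the simulated drug study (200 persons, 10 tasks,
4 alternatives), fits the all-normal mixed logit by maximum simulated
likelihood, and prints the estimates: each taste coefficient's population
mean (mu) and standard deviation (sigma), plus fit statistics.
"""

from hetlogit import CoefficientSpec, ModelSpec, fit_msl, simulate_drug_dce

dataset, truth = simulate_drug_dce(n_persons=200, n_tasks=10, seed=1)
print(f"simulated {len(dataset.table)} rows "
      f"({truth['n_persons']} persons x {truth['n_tasks']} tasks x 4 alternatives)")

spec = ModelSpec(
    tuple(CoefficientSpec(a, "normal", (a,), sign=1) for a in dataset.attributes)
)
fitted = fit_msl(spec, dataset, R=100, seed=2, name="all-normal")

print(fitted.summary().round(3).to_string(index=False))
print(f"\nLL = {fitted.LL:.1f}, k = {fitted.n_params}, "
      f"AIC = {fitted.AIC:.1f}, BIC = {fitted.BIC:.1f}, converged = {fitted.converged}")
print("\nA large branded:sigma relative to branded:mu flags strong taste")
print("heterogeneity for brands: the generator's branded taste is bimodal at")
print("-2/+2, which an all-normal model can only absorb as a wide normal.")
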