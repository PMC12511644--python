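"""Sequential latent-class model averaging over fitted constituents.

Fits all-normal, FM2 and FM3 models to data whose branded taste is bimodal,
estimates the averaging weights from the constituents' person-level
likelihoods only (their parameters stay frozen), and prints the weights,
the averaged log-likelihood and the conservative AIC.
"""

import numpy as np

from hetlogit import (
    CoefficientSpec,
    ModelSpec,
    TrueTasteConfig,
    average_models,
    fit_msl,
    sample_unconditionals,
    density_summary,
    simulate_drug_dce,
)

fixed = {"country_CH": 0.5, "char_fast": 0.5, "char_double": 0.7, "risk": -1.1, "price": -0.8}
config = TrueTasteConfig(
    {
        "branded": {"dist": "mixture", "components": [(0.5, -2.0, 0.5), (0.5, 2.0, 0.5)]},
        **{k: {"dist": "fixed", "value": v} for k, v in fixed.items()},
    }
)
dataset, _ = simulate_drug_dce(250, 10, config=config, seed=8)

others = tuple(CoefficientSpec(k, "fixed", (k,)) for k in fixed)
fits = []
for tag, dist in [("S", "normal"), ("FM2", "fm2"), ("FM3", "fm3")]:
    spec = ModelSpec((CoefficientSpec("branded", dist, ("branded",), sign=1),) + others)
    fits.append(fit_msl(spec, dataset, R=100, seed=4, name=tag, compute_covariance=False))
    print(f"{tag:4s} LL = {fits[-1].LL:9.1f}  AIC = {fits[-1].AIC:9.1f}")

ma = average_models(fits)
print(f"\nweights pi = {np.round(ma.pi, 3).tolist()}  (order: S, FM2, FM3)")
print(f"LL_MA = {ma.LL:.1f}  conservative AIC = {ma.AIC:.1f} "
      f"(counts all {ma.n_params_conservative} constituent + weight parameters)")

unc = sample_unconditionals(ma, 20000, seed=9, constituents=fits, coefficients=["branded"])
d = density_summary(unc["branded"])
print(f"\nunconditional branded-taste density has modes near {np.round(d.modes, 1).tolist()}")
print("The average leans on the flexible FM models, whose folded polynomial")
print("densities can reproduce the generator's bimodal -2/+2 branded taste;")
print("a single all-normal model cannot.")
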