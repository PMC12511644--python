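"""Compare mixing distributions on the same data by AIC.

Fits the all-normal (S), uniform (U), lognormal (LN) and second-order
polynomial (FM2) specifications to one simulated dataset with a skewed
price taste and prints the AIC ladder: lower AIC = better fit, so a
specification matching the generating shape should beat standard practice.
"""

from hetlogit import (
    CoefficientSpec,
    ModelSpec,
    TrueTasteConfig,
    compare_models,
    fit_msl,
    simulate_generic_dce,
)

config = TrueTasteConfig(
    {
        "quality": {"dist": "lognormal", "mu": 0.0, "sigma": 0.9, "sign": 1},
        "price": {"dist": "fixed", "value": -1.0},
    }
)
dataset, _ = simulate_generic_dce(
    ["A", "B", "C"], {"quality": [0.0, 1.0, 2.0], "price": [0.0, 1.0, 2.0, 3.0]},
    config, n_persons=400, n_tasks=8, seed=5,
)

fits = []
for tag, dist in [("S", "normal"), ("U", "uniform"), ("LN", "lognormal"), ("FM2", "fm2")]:
    spec = ModelSpec(
        (
            CoefficientSpec("quality", dist, ("quality",), sign=1),
            CoefficientSpec("price", "fixed", ("price",)),
        )
    )
    fits.append(fit_msl(spec, dataset, R=100, seed=3, name=tag, compute_covariance=False))

table = compare_models(fits)
print(table[["model", "LL", "n_params", "AIC", "BIC"]].round(1).to_string(index=False))
print("\nThe generating quality taste is lognormal (strictly positive, right-")
print("skewed); the AIC ladder ranks the matching LN specification above the")
print("all-normal standard practice (S).")
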