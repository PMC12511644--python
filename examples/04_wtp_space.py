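"""Willingness-to-pay-space estimation.

Utility is parameterized V = beta_price * (price + w * x): the designated
price coefficient scales a money-metric bracket, so the non-price parameter
w is estimated directly in money units (w = beta_x / beta_price; with a
negative price coefficient, a positively valued attribute gets a negative w).
Prints the mean WTP with its delta-method 95% confidence interval.
"""

from hetlogit import (
    CoefficientSpec,
    ModelSpec,
    TrueTasteConfig,
    fit_msl,
    simulate_generic_dce,
    wtp_means,
)

config = TrueTasteConfig(
    {
        "quality": {"dist": "normal", "mu": 1.0, "sigma": 0.5},
        "price": {"dist": "fixed", "value": -0.5},
    }
)
dataset, _ = simulate_generic_dce(
    ["A", "B", "C"], {"quality": [0.0, 1.0], "price": [1.0, 2.0, 3.0]},
    config, n_persons=400, n_tasks=8, seed=12,
)

spec = ModelSpec(
    (
        CoefficientSpec("quality", "normal", ("quality",), sign=1),
        CoefficientSpec("price", "lognormal", ("price",), sign=-1),
    ),
    space="wtp",
    price_coefficient="price",
)
fitted = fit_msl(spec, dataset, R=100, seed=6, name="wtp-normal")
print(fitted.summary().round(3).to_string(index=False))
print()
print(wtp_means(fitted).round(2).to_string(index=False))
print("\nGenerating tastes imply quality/price = 1.0 / -0.5, so the money-")
print("metric quality parameter should be close to -2.0 per unit of quality.")
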