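import numpy as np
import pandas as pd
import pytest

from helpers import expected_group_share, logit_choice_prob_quadrature
from hetlogit import (
    TrueTasteConfig,
    default_drug_config,
    rp_composition_dataset,
    rp_intercepts_for_shares,
    simulate_drug_dce,
    simulate_generic_dce,
    simulate_rp_binary,
    true_density,
)


def flat_config(**overrides):
    base = {
        "branded": {"dist": "fixed", "value": 0.0},
        "country_CH": {"dist": "fixed", "value": 0.0},
        "char_fast": {"dist": "fixed", "value": 0.0},
        "char_double": {"dist": "fixed", "value": 0.0},
        "risk": {"dist": "fixed", "value": 0.0},
        "price": {"dist": "fixed", "value": 0.0},
    }
    base.update(overrides)
    return TrueTasteConfig(base)


def chosen_share(ds, pred):
    chosen = ds.table[ds.table["chosen"]]
    return pred(chosen).mean()


def test_indifferent_tastes_give_uniform_alternative_shares():
    ds, _ = simulate_drug_dce(400, 10, config=flat_config(), seed=3)
    counts = ds.table[ds.table.chosen].groupby("alt_id").size()
    n = counts.sum()
    se = np.sqrt(0.25 * 0.75 / n)
    for a in counts.index:
        assert abs(counts[a] / n - 0.25) < 3 * se


def test_dominant_brand_taste():
    ds, _ = simulate_drug_dce(150, 5, config=flat_config(branded={"dist": "fixed", "value": 10.0}), seed=4)
    share = chosen_share(ds, lambda c: c["alt_id"].str.startswith("branded"))
    assert share > 0.999


def test_bimodal_brand_share_matches_integration_oracle():
    cfg = flat_config(
        branded={"dist": "mixture", "components": [(0.5, -2.0, 0.5), (0.5, 2.0, 0.5)]},
        price={"dist": "fixed", "value": -0.5},
    )
    ds, truth = simulate_drug_dce(500, 8, config=cfg, seed=9)
    observed = chosen_share(ds, lambda c: c["alt_id"].str.startswith("branded"))
    expected = expected_group_share(
        ds.table,
        ds.attributes,
        {"price": -0.5},
        "branded",
        [(0.5, -2.0, 0.5), (0.5, 2.0, 0.5)],
        "branded",
    )
    n_tasks = 500 * 8
    se = np.sqrt(expected * (1 - expected) / n_tasks)
    assert abs(observed - expected) < 3 * se
    # truth record keeps the generating mixture
    assert truth["config"]["branded"]["dist"] == "mixture"


def test_generic_share_matches_quadrature():
    # 2 alternatives, 1 attribute, beta ~ N(1, 1): the generator's observed
    # choice share of alternative A must match the task-by-task quadrature of
    # the logit probability over the taste distribution
    cfg = TrueTasteConfig({"x": {"dist": "normal", "mu": 1.0, "sigma": 1.0}})
    ds, _ = simulate_generic_dce(["A", "B"], {"x": [0.0, 1.0]}, cfg, 800, 4, seed=8)
    expected = 0.0
    n_tasks = 0
    for (_, _), g in ds.table.groupby(["person_id", "task_id"], sort=False):
        x = g["x"].to_numpy(dtype=float)
        expected += logit_choice_prob_quadrature(x, 0, mu=1.0, sigma=1.0)
        n_tasks += 1
    expected /= n_tasks
    obs_share = (ds.table[ds.table.chosen]["alt_id"] == "A").mean()
    se = np.sqrt(expected * (1 - expected) / n_tasks)
    assert abs(obs_share - expected) < 3 * se


def test_generic_counts_and_determinism():
    cfg = TrueTasteConfig({"x": {"dist": "fixed", "value": 0.3}})
    ds, _ = simulate_generic_dce(["A", "B"], {"x": [0.0, 1.0]}, cfg, 10, 1, seed=5)
    assert ds.n_tasks() == 10
    assert len(ds.table) == 10 * 1 * 2
    ds2, _ = simulate_generic_dce(["A", "B"], {"x": [0.0, 1.0]}, cfg, 10, 1, seed=5)
    pd.testing.assert_frame_equal(ds.table, ds2.table)


def test_opt_out_has_zero_attributes():
    cfg = TrueTasteConfig({"x": {"dist": "fixed", "value": 1.0}})
    ds, _ = simulate_generic_dce(["A", "B"], {"x": [1.0, 2.0]}, cfg, 30, 2, seed=2, opt_out=True)
    oo = ds.table[ds.table.alt_id == "optout"]
    assert (oo["x"] == 0).all()
    assert len(ds.table) == 30 * 2 * 3


def test_rp_independence_at_zero_sigma():
    ds = simulate_rp_binary(4000, (0.0, 0.0), sigma_rho=0.0, seed=7)
    t = ds.table
    assert abs(t.cig.mean() - 0.5) < 3 * np.sqrt(0.25 / 4000)
    tab = pd.crosstab(t.cig, t.ecig).to_numpy() + 0.5
    odds_ratio = tab[0, 0] * tab[1, 1] / (tab[0, 1] * tab[1, 0])
    assert 0.75 < odds_ratio < 1.33


def test_rp_strong_shared_component_associates():
    ds = simulate_rp_binary(3000, (0.0, 0.0), sigma_rho=3.0, sign=1, seed=8)
    tab = pd.crosstab(ds.table.cig, ds.table.ecig).to_numpy() + 0.5
    odds_ratio = tab[0, 0] * tab[1, 1] / (tab[0, 1] * tab[1, 0])
    assert odds_ratio > 5.0


def test_rp_intercept_targeting_hits_sample_shares():
    p_c, p_e = 1657 / 2031, 767 / 2031
    a_c, a_e = rp_intercepts_for_shares(p_c, p_e, sigma_rho=0.8)
    ds = simulate_rp_binary(2031, (a_c, a_e), sigma_rho=0.8, seed=10)
    t = ds.table
    assert abs(t.cig.mean() - p_c) < 3 * np.sqrt(p_c * (1 - p_c) / 2031)
    assert abs(t.ecig.mean() - p_e) < 3 * np.sqrt(p_e * (1 - p_e) / 2031)


def test_rp_composition_dataset_counts():
    ds = rp_composition_dataset()
    t = ds.table
    assert len(t) == 2031
    assert int(t.cig.sum()) == 1038 + 619
    assert int(t.ecig.sum()) == 148 + 619
    assert int((t.cig & t.ecig).sum()) == 619


def test_true_density_values_and_mass():
    cfg = default_drug_config()
    grid = np.linspace(-8, 8, 4001)
    assert true_density(
        TrueTasteConfig({"z": {"dist": "normal", "mu": 0.0, "sigma": 1.0}}), "z", [0.0]
    )[0] == pytest.approx(0.3989422804, abs=1e-9)
    mix = true_density(cfg, "branded", grid)
    from scipy.stats import norm

    assert mix[2000] == pytest.approx(
        0.5 * norm.pdf(0, -2, 0.5) + 0.5 * norm.pdf(0, 2, 0.5), abs=1e-12
    )
    assert np.trapezoid(mix, grid) == pytest.approx(1.0, abs=1e-4)
    for name in ("country_CH", "char_fast", "char_double", "risk"):
        # bounded densities are discontinuous at their support edges, so the
        # trapezoid mass carries O(grid step) edge error
        d = true_density(cfg, name, grid)
        assert np.trapezoid(d, grid) == pytest.approx(1.0, abs=2 * (grid[1] - grid[0]))


def test_drug_default_row_count_and_groups():
    ds, truth = simulate_drug_dce(25, 3, seed=1)
    assert len(ds.table) == 25 * 3 * 4
    assert set(ds.alt_groups) == {"branded", "unbranded"}
    assert truth["n_persons"] == 25 and truth["seed"] == 1
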