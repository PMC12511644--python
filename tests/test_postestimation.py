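import numpy as np
import pandas as pd
import pytest

from hetlogit import (
    ChoiceDataset,
    CoefficientSpec,
    ModelSpec,
    TrueTasteConfig,
    ValidationError,
    average_models,
    compare_models,
    density_summary,
    fit_msl,
    sample_enumeration,
    sample_unconditionals,
    simulate_generic_dce,
    wtp_means,
)
from hetlogit.postestimation import PreferenceSample


@pytest.fixture(scope="module")
def asc_only_fit():
    """Intercept-only MNL on unbalanced choices; alternative B is popular."""
    rng = np.random.default_rng(17)
    rows = []
    for p in range(120):
        choice = rng.choice(3, p=[0.2, 0.5, 0.3])
        for j, a in enumerate("ABC"):
            rows.append(
                {
                    "person_id": p,
                    "task_id": 0,
                    "alt_id": a,
                    "available": True,
                    "chosen": j == choice,
                }
            )
    ds = ChoiceDataset(pd.DataFrame(rows), (), {"B": ("B",), "C": ("C",)})
    spec = ModelSpec(
        (
            CoefficientSpec("asc_B", "fixed", (), asc_group="B"),
            CoefficientSpec("asc_C", "fixed", (), asc_group="C"),
        )
    )
    return fit_msl(spec, ds, seed=0), ds


def test_asc_enumeration_equals_observed_shares(asc_only_fit):
    fm, ds = asc_only_fit
    shares = sample_enumeration(fm, ds).shares
    observed = (
        ds.table[ds.table.chosen].groupby("alt_id").size() / ds.n_persons
    )
    for a in "ABC":
        assert abs(shares[a] - observed.get(a, 0.0)) < 1e-6


def test_equal_utility_tasks_give_uniform_shares(asc_only_fit):
    import copy

    fm, ds = asc_only_fit
    fm0 = copy.deepcopy(fm)  # same spec, constants forced to zero utility
    fm0.params["asc_B"]["params"]["value"] = 0.0
    fm0.params["asc_C"]["params"]["value"] = 0.0
    shares = sample_enumeration(fm0, ds).shares
    for a in "ABC":
        assert shares[a] == pytest.approx(1 / 3, abs=1e-9)


def test_grouping_must_partition(asc_only_fit):
    fm, ds = asc_only_fit
    with pytest.raises(ValidationError):
        sample_enumeration(fm, ds, {"g1": ("A", "B")})  # C missing
    with pytest.raises(ValidationError):
        sample_enumeration(fm, ds, {"g1": ("A", "B"), "g2": ("B", "C")})


def test_grouped_shares_sum_to_one(asc_only_fit):
    fm, ds = asc_only_fit
    shares = sample_enumeration(fm, ds, {"bc": ("B", "C"), "a": ("A",)}).shares
    assert sum(shares.values()) == pytest.approx(1.0, abs=1e-9)


@pytest.fixture(scope="module")
def two_fits():
    cfg = TrueTasteConfig(
        {
            "x": {"dist": "normal", "mu": 0.8, "sigma": 0.6},
            "price": {"dist": "fixed", "value": -1.0},
        }
    )
    ds, _ = simulate_generic_dce(
        ["A", "B"], {"x": [0.0, 1.0], "price": [0.0, 1.0, 2.0]}, cfg, 150, 5, seed=77
    )
    base = (CoefficientSpec("price", "fixed", ("price",)),)
    fm_n = fit_msl(ModelSpec((CoefficientSpec("x", "normal", ("x",), sign=1),) + base),
                   ds, R=40, seed=1, name="S", compute_covariance=False)
    fm_u = fit_msl(ModelSpec((CoefficientSpec("x", "uniform", ("x",)),) + base),
                   ds, R=40, seed=1, name="U", compute_covariance=False)
    return ds, fm_n, fm_u


def test_ma_enumeration_is_weighted_mix(two_fits):
    ds, fm_n, fm_u = two_fits
    ma = average_models([fm_n, fm_u])
    sh = sample_enumeration(ma, ds, constituents=[fm_n, fm_u]).shares
    sh_n = sample_enumeration(fm_n, ds).shares
    sh_u = sample_enumeration(fm_u, ds).shares
    for a in sh:
        assert sh[a] == pytest.approx(ma.pi[0] * sh_n[a] + ma.pi[1] * sh_u[a], abs=1e-12)


def test_unconditionals_degenerate_and_mixture(two_fits):
    ds, fm_n, fm_u = two_fits
    # sigma = 0: every unconditional draw equals the mean exactly
    fm_point = fit_msl(
        fm_n.spec, ds, R=10, seed=2, compute_covariance=False,
        start={"x": {"mu": 1.0, "sigma": 0.0}}, maxiter=0,
    )
    fm_point.params["x"]["params"]["sigma"] = 0.0
    u = sample_unconditionals(fm_point, 500, seed=3)["x"].values
    assert np.allclose(u, u[0])

    ma = average_models([fm_n, fm_u])
    ma.pi = np.array([1.0, 0.0])
    u_ma = sample_unconditionals(ma, 2000, seed=4, constituents=[fm_n, fm_u])["x"]
    u_n = sample_unconditionals(fm_n, 2000, seed=9)["x"]
    # same generating distribution: matching moments within MC error
    assert u_ma.values.mean() == pytest.approx(u_n.values.mean(), abs=0.1)


def test_mixture_unconditionals_bimodal():
    # hand-built mixture: N(-1, 0.1) w.p. 0.3 and N(+1, 0.1) w.p. 0.7
    from hetlogit.averaging import ModelAverage

    rng = np.random.default_rng(0)
    samples = np.where(rng.random(20000) < 0.3, rng.normal(-1, 0.1, 20000), rng.normal(1, 0.1, 20000))
    ps = PreferenceSample("x", samples, "model_average", 0)
    mean = samples.mean()
    se = samples.std() / np.sqrt(len(samples))
    assert abs(mean - 0.4) < 3 * se
    d = density_summary(ps)
    assert len(d.modes) >= 2
    assert any(m < -0.5 for m in d.modes) and any(m > 0.5 for m in d.modes)


def test_density_share_positive():
    rng = np.random.default_rng(5)
    d = density_summary(PreferenceSample("x", rng.normal(0, 1, 10000), "model", 0))
    assert abs(d.share_positive - 0.5) < 3 * 0.5 / np.sqrt(10000) + 0.01
    neg = -np.exp(rng.normal(0, 1, 5000))
    d2 = density_summary(PreferenceSample("x", neg, "model", 0))
    assert d2.share_positive == 0.0


def test_density_degenerate_point_mass():
    d = density_summary(PreferenceSample("x", np.full(100, 2.5), "model", 0))
    assert d.point_mass == pytest.approx(2.5)


@pytest.fixture(scope="module")
def wtp_fit():
    cfg = TrueTasteConfig(
        {
            "x": {"dist": "normal", "mu": 1.0, "sigma": 0.5},
            "price": {"dist": "fixed", "value": -0.5},
        }
    )
    ds, _ = simulate_generic_dce(
        ["A", "B", "C"], {"x": [0.0, 1.0], "price": [1.0, 2.0, 3.0]}, cfg, 300, 6, seed=55
    )
    spec = ModelSpec(
        (
            CoefficientSpec("w_x", "normal", ("x",), sign=1),
            CoefficientSpec("b_price", "fixed", ("price",)),
        ),
        space="wtp",
        price_coefficient="b_price",
    )
    return fit_msl(spec, ds, R=60, seed=8)


def test_wtp_means_normal_coefficient(wtp_fit):
    tbl = wtp_means(wtp_fit).set_index("coefficient")
    row = tbl.loc["w_x"]
    assert row["mean_wtp"] == pytest.approx(wtp_fit.estimates["w_x:mu"])
    assert row["ci_low"] == pytest.approx(row["mean_wtp"] - 1.96 * row["se"], rel=1e-3)
    # money-metric: w = beta_x / beta_price = 1.0 / -0.5 = -2
    assert abs(row["mean_wtp"] - (-2.0)) < 4 * row["se"]


def test_wtp_means_requires_wtp_space(two_fits):
    _, fm_n, _ = two_fits
    with pytest.raises(ValueError):
        wtp_means(fm_n)


def test_compare_models_sorted_by_aic(two_fits):
    ds, fm_n, fm_u = two_fits
    tbl = compare_models([fm_n, fm_u])
    assert list(tbl["AIC"]) == sorted(tbl["AIC"])
    assert set(tbl["model"]) == {"S", "U"}
    single = compare_models([fm_n])
    assert len(single) == 1


def test_compare_models_rejects_mixed_datasets(two_fits):
    _, fm_n, _ = two_fits
    other_ds, _ = simulate_generic_dce(
        ["A", "B"], {"x": [0.0, 1.0], "price": [0.0, 1.0]},
        TrueTasteConfig({"x": {"dist": "fixed", "value": 0.0},
                         "price": {"dist": "fixed", "value": 0.0}}),
        40, 2, seed=1,
    )
    spec = ModelSpec((CoefficientSpec("x", "fixed", ("x",)),))
    fm_other = fit_msl(spec, other_ds, seed=0, compute_covariance=False)
    with pytest.raises(ValidationError):
        compare_models([fm_n, fm_other])
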