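import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import logit_choice_prob_quadrature, rp_joint_prob_quadrature
from hetlogit import (
    ChoiceDataset,
    CoefficientSpec,
    ModelSpec,
    ValidationError,
    mlhs,
    mnl_probabilities,
    panel_probability,
    rp_person_likelihood,
    rp_probabilities,
    simulated_person_probability,
)
from hetlogit.likelihood import build_design, build_utilities
import pandas as pd


def one_person_dataset(x_alt, chosen_idx):
    J = len(x_alt)
    df = pd.DataFrame(
        {
            "person_id": 0,
            "task_id": 0,
            "alt_id": [f"a{j}" for j in range(J)],
            "available": True,
            "chosen": [j == chosen_idx for j in range(J)],
            "x": list(map(float, x_alt)),
        }
    )
    return ChoiceDataset(df, ("x",))


class TestMNLProbabilities:
    def test_equal_utilities(self):
        np.testing.assert_allclose(mnl_probabilities([0.0, 0.0]), [0.5, 0.5])

    def test_log_two(self):
        np.testing.assert_allclose(
            mnl_probabilities([np.log(2), 0.0]), [2 / 3, 1 / 3], rtol=1e-12
        )

    def test_unavailable_renormalizes(self):
        p = mnl_probabilities([5.0, 1.0, 3.0], [True, False, True])
        assert p[1] == 0.0
        e5, e3 = np.exp(5.0), np.exp(3.0)
        np.testing.assert_allclose(p, [e5 / (e5 + e3), 0.0, e3 / (e5 + e3)], rtol=1e-12)

    def test_all_unavailable_rejected(self):
        with pytest.raises(ValidationError):
            mnl_probabilities([0.0, 0.0], [False, False])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        v=st.lists(st.floats(-20, 20), min_size=2, max_size=5),
        shift=st.floats(-50, 50),
    )
    def test_constant_shift_invariance(self, v, shift):
        p0 = mnl_probabilities(v)
        p1 = mnl_probabilities(np.asarray(v) + shift)
        np.testing.assert_allclose(p0, p1, atol=1e-10)
        assert p0.sum() == pytest.approx(1.0)


class TestPanelProbability:
    def test_product(self):
        assert panel_probability([0.5, 0.5]) == pytest.approx(0.25)

    def test_single_task_identity(self):
        assert panel_probability([0.37]) == pytest.approx(0.37)

    def test_log_additivity(self):
        ps = [0.2, 0.5, 0.9]
        assert np.log(panel_probability(ps)) == pytest.approx(sum(np.log(ps)))

    def test_empty_panel_rejected(self):
        with pytest.raises(ValidationError):
            panel_probability([])


class TestRPProbabilities:
    def test_zero_utilities(self):
        pc, pe = rp_probabilities(0.0, 0.0, 0.0)
        assert pc == pytest.approx(0.5) and pe == pytest.approx(0.5)

    def test_unit_cig_utility(self):
        pc, pe = rp_probabilities(1.0, 0.0, 0.0)
        assert pc == pytest.approx(np.e / (1 + np.e))
        assert pe == pytest.approx(0.5)

    def test_large_rho_comoves(self):
        pc, pe = rp_probabilities(0.0, 0.0, 40.0, sign=1)
        assert pc > 0.999999 and pe > 0.999999
        pc, pe = rp_probabilities(0.0, 0.0, 40.0, sign=-1)
        assert pc > 0.999999 and pe < 1e-6

    def test_person_likelihood_exact_quarter(self):
        assert rp_person_likelihood(1, 0, 0.0, 0.0, [0.0]) == pytest.approx(0.25)

    def test_person_likelihood_matches_quadrature(self):
        sigma = 4.0
        rng = np.random.default_rng(1)
        rho = sigma * rng.standard_normal(200_000)
        sim = rp_person_likelihood(1, 1, 0.0, 0.0, rho)
        oracle = rp_joint_prob_quadrature(1, 1, 0.0, 0.0, sigma)
        assert sim == pytest.approx(oracle, abs=3e-3)
        assert oracle > 0.4  # a strong shared component makes outcomes comove

    def test_zero_sigma_independent(self):
        lik = rp_person_likelihood(1, 0, 0.7, -0.3, np.zeros(10))
        pc, pe = rp_probabilities(0.7, -0.3, 0.0)
        assert lik == pytest.approx(pc * (1 - pe))


class TestSimulatedPersonProbability:
    def test_all_fixed_equals_panel_product(self, tiny_dataset):
        spec = ModelSpec(
            (
                CoefficientSpec("x", "fixed", ("x",)),
                CoefficientSpec("price", "fixed", ("price",)),
            )
        )
        params = {"x": {"value": 0.8}, "price": {"value": -0.4}}
        P = simulated_person_probability(spec, params, tiny_dataset, None)
        # hand-compute person 0's panel product
        expected = []
        for p in (0, 1):
            prod = 1.0
            sub = tiny_dataset.table[tiny_dataset.table.person_id == p]
            for t, g in sub.groupby("task_id"):
                V = 0.8 * g["x"].to_numpy() + -0.4 * g["price"].to_numpy()
                prod *= mnl_probabilities(V)[g["chosen"].to_numpy()][0]
            expected.append(prod)
        np.testing.assert_allclose(P, expected, rtol=1e-12)

    def test_zero_sigma_equals_mnl(self, tiny_dataset):
        spec = ModelSpec(
            (
                CoefficientSpec("x", "normal", ("x",), sign=1),
                CoefficientSpec("price", "fixed", ("price",)),
            )
        )
        draws = mlhs(tiny_dataset.n_persons, 1, 16, seed=0)
        P = simulated_person_probability(
            spec,
            {"x": {"mu": 0.8, "sigma": 0.0}, "price": {"value": -0.4}},
            tiny_dataset,
            draws,
        )
        fixed_spec = spec.with_all_fixed()
        P0 = simulated_person_probability(
            fixed_spec, {"x": {"value": 0.8}, "price": {"value": -0.4}}, tiny_dataset, None
        )
        np.testing.assert_allclose(P, P0, rtol=1e-14)

    def test_matches_gauss_hermite_quadrature(self):
        # one task, two alternatives, beta ~ N(0,1) on x = (1, 0)
        ds = one_person_dataset([1.0, 0.0], chosen_idx=0)
        spec = ModelSpec((CoefficientSpec("x", "normal", ("x",), sign=1),))
        draws = mlhs(1, 1, 100_000, seed=3)
        P = simulated_person_probability(
            spec, {"x": {"mu": 0.0, "sigma": 1.0}}, ds, draws
        )[0]
        oracle = logit_choice_prob_quadrature([1.0, 0.0], 0, mu=0.0, sigma=1.0)
        assert abs(P - oracle) < 1e-3


class TestBuildUtilities:
    def test_linear(self, tiny_dataset):
        spec = ModelSpec((CoefficientSpec("x", "fixed", ("x",)),))
        design = build_design(tiny_dataset, spec)
        beta = np.full((1, 2, 1), 2.0)
        V, _ = build_utilities(design, beta)
        assert V[0, 0, 2, 0] == pytest.approx(2.0 * 2.0)  # x=2 for alt C

    def test_wtp_bracket(self, tiny_dataset):
        # V = beta_p * (price + w * x): beta_p = -0.5, price = 4, w = 7, x = 1
        df = tiny_dataset.table.copy()
        df["price"] = 4.0
        df["x"] = 0.0
        df.loc[df["alt_id"] == "B", "x"] = 1.0
        ds = ChoiceDataset(df, ("x", "price"))
        spec = ModelSpec(
            (
                CoefficientSpec("w", "fixed", ("x",)),
                CoefficientSpec("bp", "fixed", ("price",)),
            ),
            space="wtp",
            price_coefficient="bp",
        )
        design = build_design(ds, spec)
        beta = np.zeros((2, 2, 1))
        beta[0] = 7.0
        beta[1] = -0.5
        V, inner = build_utilities(design, beta, "wtp")
        b_pos = design.alt_codes[0, 0].tolist().index(1)  # alt B
        assert V[0, 0, b_pos, 0] == pytest.approx(-0.5 * (4.0 + 7.0))
        a_pos = design.alt_codes[0, 0].tolist().index(0)
        assert V[0, 0, a_pos, 0] == pytest.approx(-0.5 * 4.0)

    def test_all_zero_attributes(self, tiny_dataset):
        df = tiny_dataset.table.copy()
        df[["x", "price"]] = 0.0
        ds = ChoiceDataset(df, ("x", "price"))
        spec = ModelSpec((CoefficientSpec("x", "fixed", ("x",)),))
        design = build_design(ds, spec)
        V, _ = build_utilities(design, np.full((1, 2, 1), 3.0))
        assert np.all(V == 0.0)
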