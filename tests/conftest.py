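import numpy as np
import pandas as pd
import pytest

from hetlogit import ChoiceDataset, CoefficientSpec, ModelSpec, TrueTasteConfig
from hetlogit.simulate import simulate_generic_dce


@pytest.fixture
def tiny_table():
    """Two persons, two tasks each, three alternatives, handmade."""
    rows = []
    chosen_map = {(0, 0): "B", (0, 1): "A", (1, 0): "C", (1, 1): "B"}
    for p in (0, 1):
        for t in (0, 1):
            for j, a in enumerate(["A", "B", "C"]):
                rows.append(
                    {
                        "person_id": p,
                        "task_id": t,
                        "alt_id": a,
                        "available": True,
                        "chosen": a == chosen_map[(p, t)],
                        "x": float(j),
                        "price": float(1 + j + t),
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_dataset(tiny_table):
    return ChoiceDataset(tiny_table, ("x", "price"), {"late": ("B", "C")})


@pytest.fixture(scope="session")
def normal_taste_dataset():
    """Generic DCE generated from a normal taste; shared across tests."""
    cfg = TrueTasteConfig(
        {
            "x": {"dist": "normal", "mu": 1.0, "sigma": 0.8},
            "price": {"dist": "fixed", "value": -1.0},
        }
    )
    ds, truth = simulate_generic_dce(
        ["A", "B", "C"], {"x": [0.0, 1.0, 2.0], "price": [1.0, 2.0, 3.0, 4.0]},
        cfg, n_persons=250, n_tasks=6, seed=42,
    )
    return ds, truth


def normal_spec(sign=1):
    return ModelSpec(
        (
            CoefficientSpec("x", "normal", ("x",), sign=sign),
            CoefficientSpec("price", "fixed", ("price",)),
        )
    )
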