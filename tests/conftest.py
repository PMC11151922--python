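"""Shared fixtures: an independent brute-force partition oracle and small
survey-table builders."""

from __future__ import annotations

import statistics

import numpy as np
import pandas as pd
import pytest

from pollistab import MetacommunityTensor, survey_table_from_frame


def brute_force_partition(values) -> dict:
    """Reference partition computed with explicit loops and the stdlib
    statistics module — deliberately shares no code with the package.

    ``values`` is any (U, K, T) nested sequence of numbers.
    """
    values = [[list(series) for series in unit] for unit in values]
    U = len(values)
    K = len(values[0])
    T = len(values[0][0])

    def sd(series):
        return statistics.stdev(series)

    total = [sum(values[u][k][t] for u in range(U) for k in range(K)) for t in range(T)]
    mu = statistics.mean(total)

    cv_s_l = sum(sd(values[u][k]) for u in range(U) for k in range(K)) / mu
    cv_c_l = (
        sum(sd([sum(values[u][k][t] for u in range(U)) for t in range(T)]) for k in range(K))
        / mu
    )
    cv_s_r = (
        sum(sd([sum(values[u][k][t] for k in range(K)) for t in range(T)]) for u in range(U))
        / mu
    )
    cv_c_r = sd(total) / mu

    def ratio(num, den):
        return 1.0 if den == 0 else num / den

    return {
        "cv_s_l": cv_s_l,
        "cv_c_l": cv_c_l,
        "cv_s_r": cv_s_r,
        "cv_c_r": cv_c_r,
        "phi_s2c_l": ratio(cv_c_l, cv_s_l),
        "phi_c_l2r": ratio(cv_c_r, cv_c_l),
        "phi_s_l2r": ratio(cv_s_r, cv_s_l),
        "phi_s2c_r": ratio(cv_c_r, cv_s_r),
    }


def random_tensor(rng, max_units=4, max_patches=3, max_times=6) -> MetacommunityTensor:
    """Small random tensor with strictly positive entries."""
    u = int(rng.integers(1, max_units + 1))
    k = int(rng.integers(1, max_patches + 1))
    t = int(rng.integers(2, max_times + 1))
    values = rng.uniform(0.1, 10.0, size=(u, k, t))
    return MetacommunityTensor(
        values=values,
        unit_labels=[f"u{i}" for i in range(u)],
        patch_labels=[f"k{j}" for j in range(k)],
        time_labels=list(range(t)),
        variable="flower_availability",
    )


@pytest.fixture
def micro_tensor() -> MetacommunityTensor:
    """The 2 units x 2 patches x 3 years worked example."""
    return MetacommunityTensor(
        values=np.array([[[1, 2, 3], [2, 2, 2]], [[3, 1, 2], [1, 3, 2]]], float),
        unit_labels=["u1", "u2"],
        patch_labels=["k1", "k2"],
        time_labels=[2020, 2021, 2022],
        variable="flower_availability",
    )


@pytest.fixture
def flowers_table():
    df = pd.DataFrame(
        {
            "year": [2020, 2020, 2021, 2021, 2020, 2021],
            "round": [1, 2, 1, 2, 1, 1],
            "site": ["A", "A", "A", "A", "B", "B"],
            "subplot": [1, 1, 1, 2, 1, 1],
            "plant": ["p1", "p1", "p1", "p2", "p2", "p1"],
            "count": [3, 4, 5, 2, 6, 1],
        }
    )
    return survey_table_from_frame(df, "flowers")


@pytest.fixture
def visits_table():
    df = pd.DataFrame(
        {
            "year": [2020, 2020, 2021, 2021, 2020, 2021],
            "round": [1, 1, 1, 1, 2, 2],
            "site": ["A", "A", "A", "A", "B", "B"],
            "subplot": [1, 2, 1, 1, 1, 1],
            "plant": ["p1", "p2", "p1", "p2", "p1", "p1"],
            "pollinator": ["x", "x", "y", "x", "y", "x"],
            "visits": [3, 5, 2, 1, 4, 2],
        }
    )
    return survey_table_from_frame(df, "visits")


@pytest.fixture
def fruitset_table():
    df = pd.DataFrame(
        {
            "year": [2020, 2020, 2021, 2021, 2020, 2021],
            "site": ["A", "A", "A", "A", "B", "B"],
            "plant": ["p1", "p1", "p1", "p1", "p1", "p1"],
            "individual": ["i1", "i2", "i3", "i4", "i5", "i6"],
            "flowers_marked": [20, 5, 10, 10, 8, 12],
            "fruits": [10, 1, 6, 2, 4, 9],
        }
    )
    return survey_table_from_frame(df, "fruitset")
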