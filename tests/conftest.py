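import numpy as np
import pandas as pd
import pytest

from depsurv.lifetables import LifeTable


def build_life_table(rate=0.02, sexes=("male", "female"), ages=range(50, 80),
                     years=range(2004, 2016), region="R1", fn=None):
    """Complete one-region life table; ``fn(sex, age, year)`` overrides the rate."""
    rows = []
    for s in sexes:
        for a in ages:
            for y in years:
                r = rate if fn is None else fn(s, a, y)
                rows.append((s, a, y, region, r))
    return LifeTable(pd.DataFrame(rows, columns=["sex", "age", "year", "region", "rate"]))


def build_cohort(T, D, sex="male", age=60.0, year=2006.0, region="R1",
                 edi=0.0, quintile=3):
    n = len(T)
    as_arr = lambda v: np.full(n, v) if np.ndim(v) == 0 else np.asarray(v)
    return pd.DataFrame({
        "id": np.arange(n),
        "sex": np.full(n, sex, dtype=object) if np.ndim(sex) == 0 else np.asarray(sex, object),
        "age_dx": as_arr(age).astype(float),
        "year_dx": as_arr(year).astype(float),
        "region": np.full(n, region, dtype=object),
        "edi": as_arr(edi).astype(float),
        "quintile": as_arr(quintile).astype(int),
        "time": np.asarray(T, dtype=float),
        "status": np.asarray(D, dtype=int),
    })


@pytest.fixture
def small_lt():
    return build_life_table(rate=0.02, ages=range(55, 75), years=range(2005, 2014))


@pytest.fixture
def rng():
    return np.random.default_rng(20230120)
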