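"""Transfer of an external deprivation gradient onto a base life table."""

import numpy as np
import pandas as pd
import pytest

from depsurv.lifetables import LifeTableError
from depsurv.lt_simulation import (
    ExternalRateSource,
    RateRatioTable,
    aggregate_vingtiles,
    apply_rate_ratios,
    compute_rate_ratios,
    extend_years,
    read_external_source,
)

from conftest import build_life_table


def vingtile_source(rate_fn, weights=True):
    rows = [(s, a, lv, rate_fn(s, a, lv))
            for s in ("male", "female") for a in (60, 70) for lv in range(1, 21)]
    return ExternalRateSource(
        pd.DataFrame(rows, columns=["sex", "age", "level", "rate"]),
        level_weights=np.full(20, 0.05) if weights else None,
        overall=None if weights else pd.DataFrame(
            [(s, a, np.mean([rate_fn(s, a, lv) for lv in range(1, 21)]))
             for s in ("male", "female") for a in (60, 70)],
            columns=["sex", "age", "rate"]),
    )


def quintile_rr(values, sexes=("male", "female"), ages=(60, 61, 62), years=None):
    rows = []
    for s in sexes:
        for a in ages:
            for y in (years or [None]):
                for d in range(1, 6):
                    row = [s, a] + ([y] if years else []) + [d, values[d - 1]]
                    rows.append(row)
    cols = ["sex", "age"] + (["year"] if years else []) + ["quintile", "rr"]
    return RateRatioTable(pd.DataFrame(rows, columns=cols))


class TestAggregateVingtiles:
    def test_sequential_rates_average_in_blocks_of_four(self):
        agg = aggregate_vingtiles(vingtile_source(lambda s, a, lv: float(lv)))
        got = (agg.rates[(agg.rates.sex == "male") & (agg.rates.age == 60)]
               .sort_values("level")["rate"].tolist())
        assert got == [2.5, 6.5, 10.5, 14.5, 18.5]

    def test_constant_vingtiles_stay_constant(self):
        agg = aggregate_vingtiles(vingtile_source(lambda s, a, lv: 0.37))
        assert np.allclose(agg.rates["rate"], 0.37)

    def test_randomized_against_bruteforce_means(self, rng):
        vals = {(s, a, lv): rng.uniform(0.1, 9.0)
                for s in ("male", "female") for a in (60, 70) for lv in range(1, 21)}
        agg = aggregate_vingtiles(vingtile_source(lambda s, a, lv: vals[(s, a, lv)]))
        for s in ("male", "female"):
            for a in (60, 70):
                for k in range(1, 6):
                    brute = sum(vals[(s, a, lv)] for lv in range(4 * k - 3, 4 * k + 1)) / 4.0
                    got = float(agg.rates.loc[
                        (agg.rates.sex == s) & (agg.rates.age == a)
                        & (agg.rates.level == k), "rate"].iloc[0])
                    assert got == pytest.approx(brute, rel=1e-12)

    def test_wrong_level_count_rejected(self):
        five = aggregate_vingtiles(vingtile_source(lambda s, a, lv: 1.0))
        with pytest.raises(ValueError, match="20 levels"):
            aggregate_vingtiles(five)


class TestComputeRateRatios:
    def test_direct_division(self):
        rows = [("male", 60, lv, (7 + lv) / 1000.0) for lv in range(1, 6)]
        src = ExternalRateSource(
            pd.DataFrame(rows, columns=["sex", "age", "level", "rate"]),
            overall=pd.DataFrame([("male", 60, 0.010)], columns=["sex", "age", "rate"]),
        )
        rrt = compute_rate_ratios(src)
        assert np.allclose(sorted(rrt.rr["rr"]), [0.8, 0.9, 1.0, 1.1, 1.2])

    def test_levels_equal_to_overall_give_unit_ratios(self):
        rows = [("male", 60, lv, 0.01) for lv in range(1, 6)]
        src = ExternalRateSource(
            pd.DataFrame(rows, columns=["sex", "age", "level", "rate"]),
            level_weights=np.full(5, 0.2),
        )
        assert np.allclose(compute_rate_ratios(src).rr["rr"], 1.0)

    def test_derived_overall_yields_unit_weighted_mean(self, rng):
        rows = [(s, a, lv, rng.uniform(0.005, 0.05))
                for s in ("male", "female") for a in (60, 70) for lv in range(1, 6)]
        src = ExternalRateSource(
            pd.DataFrame(rows, columns=["sex", "age", "level", "rate"]),
            level_weights=np.full(5, 0.2),
        )
        rrt = compute_rate_ratios(src)
        for (s, a), grp in rrt.rr.groupby(["sex", "age"]):
            assert np.average(grp["rr"], weights=np.full(5, 0.2)) == pytest.approx(1.0, abs=1e-12)

    def test_zero_overall_with_nonzero_level_errors(self):
        rows = [("male", 60, lv, 0.01) for lv in range(1, 6)]
        src = ExternalRateSource(
            pd.DataFrame(rows, columns=["sex", "age", "level", "rate"]),
            overall=pd.DataFrame([("male", 60, 0.0)], columns=["sex", "age", "rate"]),
        )
        with pytest.raises(ZeroDivisionError, match="male"):
            compute_rate_ratios(src)

    def test_all_zero_stratum_gives_unit_ratio(self):
        rows = [("male", 60, lv, 0.0) for lv in range(1, 6)]
        src = ExternalRateSource(
            pd.DataFrame(rows, columns=["sex", "age", "level", "rate"]),
            overall=pd.DataFrame([("male", 60, 0.0)], columns=["sex", "age", "rate"]),
        )
        assert np.allclose(compute_rate_ratios(src).rr["rr"], 1.0)


class TestExtendYears:
    def test_last_year_carried_forward(self):
        rrt = quintile_rr([0.8, 0.9, 1.0, 1.1, 1.2], ages=(60,),
                          years=range(2006, 2012))
        # make the ratios year-dependent so carry-forward is observable
        df = rrt.rr.copy()
        df["rr"] = df["rr"] * (1 + 0.01 * (df["year"] - 2006))
        rrt = RateRatioTable(df)
        ext = extend_years(rrt, range(2006, 2014))
        for y in (2012, 2013):
            got = ext.rr[ext.rr.year == y].sort_values("quintile")["rr"].to_numpy()
            want = ext.rr[ext.rr.year == 2011].sort_values("quintile")["rr"].to_numpy()
            assert np.array_equal(got, want)

    def test_year_free_table_unchanged(self):
        rrt = quintile_rr([0.8, 0.9, 1.0, 1.1, 1.2])
        ext = extend_years(rrt, range(2006, 2014))
        assert ext.rr.equals(rrt.rr)

    def test_targets_within_coverage_identity(self):
        rrt = quintile_rr([1.0] * 5, ages=(60,), years=range(2006, 2012))
        ext = extend_years(rrt, [2007, 2008])
        assert ext.rr.sort_index(axis=1).equals(rrt.rr.sort_index(axis=1))

    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError):
            extend_years(quintile_rr([1.0] * 5), [])


class TestApplyRateRatios:
    def test_unit_ratios_reproduce_base_for_every_quintile(self):
        base = build_life_table(rate=0.013, ages=range(60, 63), years=(2006, 2007))
        sim = apply_rate_ratios(base, quintile_rr([1.0] * 5))
        for d in range(5):
            assert np.array_equal(sim.rates[..., d], base.rates)

    def test_single_multiplication(self):
        base = build_life_table(rate=0.010, ages=range(60, 63), years=(2006, 2007))
        sim = apply_rate_ratios(base, quintile_rr([0.8, 0.9, 1.0, 1.15, 1.35]))
        assert sim.rates[0, 0, 0, 0, 4] == pytest.approx(0.0135, abs=1e-15)

    def test_every_cell_is_the_recomputed_product(self, rng):
        vals = rng.uniform(0.5, 1.6, (2, 3, 5))  # sex x age x quintile
        sexes = ("male", "female")
        rows = [(s, a, d, vals[si, ai, d - 1])
                for si, s in enumerate(sexes) for ai, a in enumerate((60, 61, 62))
                for d in range(1, 6)]
        rrt = RateRatioTable(pd.DataFrame(rows, columns=["sex", "age", "quintile", "rr"]))
        base = build_life_table(fn=lambda s, a, y: rng.uniform(0.005, 0.05),
                                ages=range(60, 63), years=(2006, 2007))
        sim = apply_rate_ratios(base, rrt)
        for si in range(2):
            for ai in range(3):
                for yi in range(2):
                    for d in range(5):
                        assert sim.rates[si, 0, yi, ai, d] == pytest.approx(
                            base.rates[si, 0, yi, ai] * vals[si, ai, d], rel=1e-14)

    def test_gradient_transfer_is_exact(self, rng):
        rr_vals = [0.7, 0.95, 1.0, 1.2, 1.5]
        base = build_life_table(fn=lambda s, a, y: rng.uniform(0.005, 0.05),
                                ages=range(60, 63), years=(2006, 2007))
        sim = apply_rate_ratios(base, quintile_rr(rr_vals))
        ratio = sim.rates[..., 4] / sim.rates[..., 0]
        assert np.allclose(ratio, rr_vals[4] / rr_vals[0], rtol=1e-14)

    def test_conservation_under_weights(self, rng):
        w = np.array([0.15, 0.2, 0.25, 0.2, 0.2])
        raw = rng.uniform(0.5, 1.5, 5)
        rr_vals = raw / np.average(raw, weights=w)  # weighted mean exactly 1
        base = build_life_table(fn=lambda s, a, y: rng.uniform(0.005, 0.05),
                                ages=range(60, 63), years=(2006, 2007))
        sim = apply_rate_ratios(base, quintile_rr(list(rr_vals)))
        mean = np.tensordot(sim.rates, w, axes=([4], [0]))
        assert np.allclose(mean, base.rates, atol=1e-12)

    def test_renormalization_flag_preserves_population_average(self, rng):
        w = np.full(5, 0.2)
        base = build_life_table(rate=0.02, ages=range(60, 63), years=(2006, 2007))
        sim = apply_rate_ratios(base, quintile_rr([0.8, 0.9, 1.0, 1.15, 1.35]),
                                renormalize_weights=w)
        mean = np.tensordot(sim.rates, w, axes=([4], [0]))
        assert np.allclose(mean, base.rates, atol=1e-14)

    def test_coarse_age_grid_expands_by_nearest_matching(self):
        base = build_life_table(rate=0.01, ages=range(60, 65), years=(2006,))
        rrt = quintile_rr([2.0, 2.0, 2.0, 2.0, 4.0], ages=(60, 64))
        sim = apply_rate_ratios(base, rrt)
        assert np.allclose(sim.rates[..., 4], 0.04)

    def test_stratified_base_rejected(self):
        base = build_life_table(rate=0.01, ages=range(60, 63), years=(2006,))
        sim = apply_rate_ratios(base, quintile_rr([1.0] * 5))
        with pytest.raises(LifeTableError):
            apply_rate_ratios(sim, quintile_rr([1.0] * 5))

    def test_missing_sex_stratum_errors(self):
        base = build_life_table(rate=0.01, ages=range(60, 63), years=(2006,))
        rrt = quintile_rr([1.0] * 5, sexes=("male",))
        with pytest.raises(LifeTableError, match="female"):
            apply_rate_ratios(base, rrt)


class TestPipelineDeterminism:
    def test_full_composition_is_byte_stable(self, tmp_path, rng):
        from depsurv.lifetables import write_life_table
        vals = {(s, a, lv): rng.uniform(1.0, 9.0)
                for s in ("male", "female") for a in (60, 70) for lv in range(1, 21)}
        base = build_life_table(fn=lambda s, a, y: 0.01 + 0.001 * (a - 60),
                                ages=range(60, 71), years=range(2006, 2010))
        outputs = []
        for run in range(2):
            src = vingtile_source(lambda s, a, lv: vals[(s, a, lv)])
            rrt = extend_years(compute_rate_ratios(aggregate_vingtiles(src)),
                               range(2006, 2010))
            sim = apply_rate_ratios(base, rrt)
            path = tmp_path / f"sim_{run}.csv"
            write_life_table(sim, path)
            outputs.append(path.read_bytes())
        assert outputs[0] == outputs[1]


def test_read_external_source_units_and_overall_rows(tmp_path):
    df = pd.DataFrame(
        [("male", 60, 0, 1000.0)] + [("male", 60, lv, 800.0 + 100 * lv) for lv in range(1, 6)],
        columns=["sex", "age", "level", "rate"],
    )
    path = tmp_path / "src.csv"
    df.to_csv(path, index=False)
    src = read_external_source(path, units="per_100000")
    assert src.overall is not None
    assert src.overall["rate"].iloc[0] == pytest.approx(0.01)
    rrt = compute_rate_ratios(src)
    assert np.allclose(sorted(rrt.rr["rr"]), [0.9, 1.0, 1.1, 1.2, 1.3])
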