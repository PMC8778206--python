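"""ANOVA decompositions against independent oracles, heritability and LSD."""

import itertools

import numpy as np
import pandas as pd
import pytest

from grain_ionome.anova import (
    AnovaTable,
    factorial_anova,
    heritability_factorial,
    heritability_single_year,
    lsd,
    oneway_anova,
)


def _long(values):
    """dict {(genotype, year): [reps]} -> long frame."""
    rows = [
        {"genotype": g, "year": y, "value": v}
        for (g, y), reps in values.items()
        for v in reps
    ]
    return pd.DataFrame(rows)


def brute_force_oneway(values_by_genotype):
    """Direct deviation sums of squares for a balanced one-way layout."""
    all_values = np.concatenate(list(values_by_genotype.values()))
    grand = all_values.mean()
    ss_g = sum(
        len(v) * (np.mean(v) - grand) ** 2 for v in values_by_genotype.values()
    )
    ss_e = sum(
        ((np.asarray(v) - np.mean(v)) ** 2).sum()
        for v in values_by_genotype.values()
    )
    return ss_g, ss_e


def brute_force_factorial(cells):
    """Direct two-way decomposition with replication from cell values.

    ``cells`` maps (genotype, year) to replicate arrays; returns
    (ss_g, ss_y, ss_gy, ss_e) from marginal and cell means.
    """
    genos = sorted({g for g, _ in cells})
    years = sorted({y for _, y in cells})
    r = len(next(iter(cells.values())))
    everything = np.concatenate([np.asarray(v) for v in cells.values()])
    grand = everything.mean()
    gm = {g: np.mean([np.mean(cells[(g, y)]) for y in years]) for g in genos}
    ym = {y: np.mean([np.mean(cells[(g, y)]) for g in genos]) for y in years}
    ss_g = len(years) * r * sum((gm[g] - grand) ** 2 for g in genos)
    ss_y = len(genos) * r * sum((ym[y] - grand) ** 2 for y in years)
    ss_gy = r * sum(
        (np.mean(cells[(g, y)]) - gm[g] - ym[y] + grand) ** 2
        for g in genos
        for y in years
    )
    ss_e = sum(
        ((np.asarray(v) - np.mean(v)) ** 2).sum() for v in cells.values()
    )
    return ss_g, ss_y, ss_gy, ss_e


class TestOneWay:
    def test_toy_example_matches_brute_force(self):
        data = {"a": [1, 2], "b": [3, 5], "c": [8, 10]}
        tab = oneway_anova(_long({(g, 2017): v for g, v in data.items()}))
        ss_g, ss_e = brute_force_oneway(data)
        assert tab.table.loc["genotype", "ss"] == pytest.approx(ss_g)
        assert tab.table.loc["residual", "ss"] == pytest.approx(ss_e)
        assert tab.table.loc["genotype", "df"] == 2
        assert tab.table.loc["residual", "df"] == 3

    def test_equal_means_no_genotype_signal(self):
        data = {(f"g{i}", 1): [10.0 + d for d in (-1, 1)] for i in range(6)}
        tab = oneway_anova(_long(data))
        h = heritability_single_year(tab)
        assert h.sigma2_g == 0.0
        assert h.H2 == 0.0

    def test_zero_within_variance_perfect_heritability(self):
        data = {("a", 1): [1.0, 1.0], ("b", 1): [2.0, 2.0], ("c", 1): [5.0, 5.0]}
        h = heritability_single_year(oneway_anova(_long(data)))
        assert h.H2 == 1.0

    def test_unbalanced_rejected(self):
        data = {("a", 1): [1, 2], ("b", 1): [3, 4, 5]}
        with pytest.raises(ValueError, match="unbalanced"):
            oneway_anova(_long(data))

    def test_statsmodels_cross_check(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(11)
        data = {(f"g{i}", 1): rng.normal(10, 2, 3) for i in range(5)}
        df = _long(data)
        tab = oneway_anova(df)
        fit = ols("value ~ C(genotype)", data=df).fit()
        ref = sm.stats.anova_lm(fit, typ=1)
        assert tab.table.loc["genotype", "ss"] == pytest.approx(
            ref.loc["C(genotype)", "sum_sq"]
        )
        assert tab.table.loc["genotype", "F"] == pytest.approx(
            ref.loc["C(genotype)", "F"]
        )


class TestFactorial:
    def test_small_2x2x2_matches_brute_force(self):
        rng = np.random.default_rng(1)
        cells = {
            (g, y): rng.normal(10, 3, 2) for g in "ab" for y in (2017, 2018)
        }
        tab = factorial_anova(_long(cells))
        ss = brute_force_factorial(cells)
        for effect, expected in zip(
            ["genotype", "year", "genotype:year", "residual"], ss
        ):
            assert tab.table.loc[effect, "ss"] == pytest.approx(expected, rel=1e-8)

    @pytest.mark.parametrize(
        "g,y,r", list(itertools.product([2, 3, 4], [2], [2, 3]))
    )
    def test_all_small_designs_match_brute_force(self, g, y, r):
        rng = np.random.default_rng(g * 100 + y * 10 + r)
        cells = {
            (f"g{i}", 2000 + j): rng.normal(50, 8, r)
            for i in range(g)
            for j in range(y)
        }
        tab = factorial_anova(_long(cells))
        ss = brute_force_factorial(cells)
        for effect, expected in zip(
            ["genotype", "year", "genotype:year", "residual"], ss
        ):
            assert tab.table.loc[effect, "ss"] == pytest.approx(expected, rel=1e-8)
        assert tab.table["df"].sum() == g * y * r - 1

    def test_degrees_of_freedom(self):
        rng = np.random.default_rng(2)
        cells = {
            (f"g{i}", y): rng.normal(0, 1, 3)
            for i in range(4)
            for y in (1, 2)
        }
        tab = factorial_anova(_long(cells))
        assert tab.table.loc["genotype", "df"] == 3
        assert tab.table.loc["year", "df"] == 1
        assert tab.table.loc["genotype:year", "df"] == 3
        assert tab.table.loc["residual", "df"] == 16

    def test_statsmodels_cross_check(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(3)
        cells = {
            (f"g{i}", y): rng.normal(20, 4, 3)
            for i in range(4)
            for y in (2017, 2018)
        }
        df = _long(cells)
        tab = factorial_anova(df)
        fit = ols("value ~ C(genotype) * C(year)", data=df).fit()
        ref = sm.stats.anova_lm(fit, typ=1)
        assert tab.table.loc["genotype", "ss"] == pytest.approx(
            ref.loc["C(genotype)", "sum_sq"]
        )
        assert tab.table.loc["genotype:year", "ss"] == pytest.approx(
            ref.loc["C(genotype):C(year)", "sum_sq"]
        )
        assert tab.table.loc["genotype:year", "F"] == pytest.approx(
            ref.loc["C(genotype):C(year)", "F"]
        )

    def test_interaction_power(self):
        """σ²_GY = 0.5·σ²_G at full trial size is detected nearly always."""
        from grain_ionome.simulate import SimConfig, TraitSim, simulate_trial

        hits = 0
        for seed in range(20):
            cfg = SimConfig(
                n_genotypes=135,
                seed=seed,
                gy_ratio=0.5,
                group_counts={"check": 135},
                elements={
                    "Sr": TraitSim(mean=2.0, h2_target=0.6, residual_cv=20)
                },
                agronomic={
                    "protein": TraitSim(mean=16.5, h2_target=0.6, residual_cv=7)
                },
            )
            records, _ = simulate_trial(cfg)
            long = records[["genotype", "year", "Sr"]].rename(
                columns={"Sr": "value"}
            )
            tab = factorial_anova(long)
            if tab.table.loc["genotype:year", "p"] < 0.05:
                hits += 1
        assert hits >= 18  # ≥90%


class TestHeritability:
    def test_equal_mean_squares_clamps_to_zero(self):
        tab = _fake_oneway(ms_g=4.0, ms_e=4.0, g=10, r=3)
        assert heritability_single_year(tab).H2 == 0.0

    def test_no_error_gives_one(self):
        tab = _fake_oneway(ms_g=4.0, ms_e=0.0, g=10, r=3)
        assert heritability_single_year(tab).H2 == 1.0

    def test_factorial_limits(self):
        tab = _fake_factorial(ms_g=10.0, ms_gy=0.0, ms_e=0.0)
        assert heritability_factorial(tab).H2 == 1.0
        tab = _fake_factorial(ms_g=1.0, ms_gy=4.0, ms_e=1.0)
        assert heritability_factorial(tab).H2 == 0.0

    def test_plot_basis_never_exceeds_entry_mean(self):
        tab = _fake_factorial(ms_g=30.0, ms_gy=6.0, ms_e=2.0)
        entry = heritability_factorial(tab, basis="entry_mean").H2
        plot = heritability_factorial(tab, basis="plot").H2
        assert plot <= entry

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        cells = {
            (f"g{i}", y): rng.normal(10, 2, 3)
            for i in range(6)
            for y in (1, 2)
        }
        df = _long(cells)
        h1 = heritability_factorial(factorial_anova(df))
        df2 = df.assign(value=3.5 * df["value"] + 100)
        h2 = heritability_factorial(factorial_anova(df2))
        assert h1.H2 == pytest.approx(h2.H2, rel=1e-9)

    def test_components_never_negative(self):
        rng = np.random.default_rng(6)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cells = {
                (f"g{i}", y): rng.normal(0, 1, 2)
                for i in range(4)
                for y in (1, 2)
            }
            h = heritability_factorial(factorial_anova(_long(cells)))
            assert h.sigma2_g >= 0 and h.sigma2_gy >= 0
            assert 0 <= h.H2 <= 1


class TestLsd:
    def test_zero_error_zero_lsd(self):
        assert lsd(0.0, 100, 8).value == 0.0

    def test_closed_form(self):
        res = lsd(50.0, 1000, 8, alpha=0.05)
        assert res.value == pytest.approx(1.962 * np.sqrt(12.5), rel=1e-3)

    def test_alpha_one_gives_zero(self):
        assert lsd(10.0, 50, 4, alpha=1.0).value == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            lsd(-1.0, 10, 4)
        with pytest.raises(ValueError):
            lsd(1.0, 0, 4)


def _fake_oneway(ms_g, ms_e, g, r):
    table = pd.DataFrame(
        {
            "df": [g - 1, g * (r - 1)],
            "ss": [ms_g * (g - 1), ms_e * g * (r - 1)],
            "ms": [ms_g, ms_e],
            "F": [np.nan, np.nan],
            "p": [np.nan, np.nan],
        },
        index=pd.Index(["genotype", "residual"], name="effect"),
    )
    return AnovaTable(table=table, design="oneway", g=g, y=1, r=r)


def _fake_factorial(ms_g, ms_gy, ms_e, g=10, y=2, r=4):
    idx = pd.Index(
        ["genotype", "year", "genotype:year", "residual"], name="effect"
    )
    table = pd.DataFrame(
        {
            "df": [g - 1, y - 1, (g - 1) * (y - 1), g * y * (r - 1)],
            "ss": [0.0] * 4,
            "ms": [ms_g, 1.0, ms_gy, ms_e],
            "F": [np.nan] * 4,
            "p": [np.nan] * 4,
        },
        index=idx,
    )
    return AnovaTable(table=table, design="factorial", g=g, y=y, r=r)
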