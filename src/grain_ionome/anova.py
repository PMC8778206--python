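"""Balanced ANOVA, method-of-moments variance components and heritability.

Two designs are supported, matching a replicated multi-year trial:

* one-way ANOVA per year (genotype effect against within-plot error), and
* factorial genotype × year ANOVA with interaction.

Variance components are obtained by equating observed mean squares to
their expectations under the balanced design (EMS method of moments),
with negative estimates clamped to zero.  Broad-sense heritability is
reported on the entry-mean basis by default::

    single year:  H² = σ²_g / (σ²_g + σ²_e / r)
    factorial:    H² = σ²_g / (σ²_g + σ²_gy / y + σ²_e / (r·y))

where r is the number of replicates and y the number of years.  A plot
basis (no division of the noise components) is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .elements import ElementRegistry, default_registry

__all__ = [
    "AnovaTable",
    "HeritabilityResult",
    "LsdResult",
    "oneway_anova",
    "factorial_anova",
    "heritability_single_year",
    "heritability_factorial",
    "lsd",
    "HeritabilityAnova",
]


@dataclass(frozen=True)
class AnovaTable:
    """Effect-by-effect decomposition: df, SS, MS, F, p.

    ``table`` is indexed by effect name ('genotype', 'year',
    'genotype:year', 'residual') with columns df, ss, ms, F, p.
    """

    table: pd.DataFrame
    design: str  # "oneway" or "factorial"
    g: int
    y: int
    r: int

    def ms(self, effect: str) -> float:
        return float(self.table.loc[effect, "ms"])

    def df(self, effect: str) -> float:
        return float(self.table.loc[effect, "df"])


@dataclass(frozen=True)
class HeritabilityResult:
    element: str | None
    basis: str  # "entry_mean" or "plot"
    scope: str  # "single_year" or "factorial"
    sigma2_g: float
    sigma2_gy: float | None
    sigma2_e: float
    r: int
    y: int
    H2: float


@dataclass(frozen=True)
class LsdResult:
    alpha: float
    ms_error: float
    df_error: float
    n_per_mean: int
    value: float


def _check_balanced(counts: pd.Series, label: str) -> int:
    sizes = counts.unique()
    if len(sizes) != 1:
        offenders = counts[counts != counts.mode().iloc[0]].index.tolist()
        raise ValueError(f"unbalanced design: uneven {label} for {offenders}")
    return int(sizes[0])


def oneway_anova(
    data: pd.DataFrame,
    value_col: str = "value",
    genotype_col: str = "genotype",
) -> AnovaTable:
    """One-way genotype ANOVA on a balanced single-year table.

    Every genotype must carry the same number r ≥ 2 of replicates.
    """
    counts = data.groupby(genotype_col)[value_col].size()
    r = _check_balanced(counts, "replicate counts")
    if r < 2:
        raise ValueError("one-way ANOVA requires at least 2 replicates")
    g = counts.size
    values = data[value_col].to_numpy(float)
    grand = values.mean()
    geno_means = data.groupby(genotype_col)[value_col].mean()

    ss_total = float(((values - grand) ** 2).sum())
    ss_g = float(r * ((geno_means - grand) ** 2).sum())
    ss_e = ss_total - ss_g
    df_g, df_e = g - 1, g * (r - 1)
    ms_g, ms_e = ss_g / df_g, ss_e / df_e
    if ms_e > 0:
        f_stat = ms_g / ms_e
        p = float(stats.f.sf(f_stat, df_g, df_e))
    else:
        f_stat, p = np.inf, 0.0
    table = pd.DataFrame(
        {
            "df": [df_g, df_e],
            "ss": [ss_g, ss_e],
            "ms": [ms_g, ms_e],
            "F": [f_stat, np.nan],
            "p": [p, np.nan],
        },
        index=pd.Index(["genotype", "residual"], name="effect"),
    )
    return AnovaTable(table=table, design="oneway", g=g, y=1, r=r)


def factorial_anova(
    data: pd.DataFrame,
    value_col: str = "value",
    genotype_col: str = "genotype",
    year_col: str = "year",
    random_model: bool = False,
) -> AnovaTable:
    """Factorial genotype × year ANOVA on a balanced g × y × r table.

    Fixed-effects F tests by default (all effects against MS_e); with
    ``random_model=True`` the genotype effect is tested against the
    interaction mean square instead.
    """
    counts = data.groupby([genotype_col, year_col])[value_col].size()
    r = _check_balanced(counts, "cell sizes")
    if r < 2:
        raise ValueError("factorial ANOVA requires at least 2 replicates per cell")
    g = data[genotype_col].nunique()
    y = data[year_col].nunique()
    if y < 2:
        raise ValueError("factorial ANOVA requires at least 2 years")
    if len(counts) != g * y:
        raise ValueError("unbalanced design: missing genotype×year cells")

    values = data[value_col].to_numpy(float)
    grand = values.mean()
    m_g = data.groupby(genotype_col)[value_col].mean()
    m_y = data.groupby(year_col)[value_col].mean()
    m_gy = data.groupby([genotype_col, year_col])[value_col].mean()

    ss_total = float(((values - grand) ** 2).sum())
    ss_g = float(y * r * ((m_g - grand) ** 2).sum())
    ss_y = float(g * r * ((m_y - grand) ** 2).sum())
    # interaction deviations: cell mean minus both marginal means plus grand
    dev = (
        m_gy
        - m_g.reindex(m_gy.index.get_level_values(0)).to_numpy()
        - m_y.reindex(m_gy.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_gy = float(r * (dev**2).sum())
    ss_e = ss_total - ss_g - ss_y - ss_gy

    df_g, df_y = g - 1, y - 1
    df_gy, df_e = (g - 1) * (y - 1), g * y * (r - 1)
    ms = np.array([ss_g / df_g, ss_y / df_y, ss_gy / df_gy, ss_e / df_e])

    def _f(ms_num: float, df_num: int, ms_den: float, df_den: int):
        if ms_den > 0:
            f_stat = ms_num / ms_den
            return f_stat, float(stats.f.sf(f_stat, df_num, df_den))
        return np.inf, 0.0

    denom_g = (ms[2], df_gy) if random_model else (ms[3], df_e)
    f_g, p_g = _f(ms[0], df_g, *denom_g)
    f_y, p_y = _f(ms[1], df_y, ms[3], df_e)
    f_gy, p_gy = _f(ms[2], df_gy, ms[3], df_e)

    table = pd.DataFrame(
        {
            "df": [df_g, df_y, df_gy, df_e],
            "ss": [ss_g, ss_y, ss_gy, ss_e],
            "ms": ms,
            "F": [f_g, f_y, f_gy, np.nan],
            "p": [p_g, p_y, p_gy, np.nan],
        },
        index=pd.Index(
            ["genotype", "year", "genotype:year", "residual"], name="effect"
        ),
    )
    return AnovaTable(table=table, design="factorial", g=g, y=y, r=r)


def heritability_single_year(
    anova: AnovaTable,
    r: int | None = None,
    basis: str = "entry_mean",
    element: str | None = None,
) -> HeritabilityResult:
    """Broad-sense heritability from a one-way table.

    σ̂²_g = max(0, (MS_g − MS_e) / r); the entry-mean basis divides the
    error by r, the plot basis does not.
    """
    if anova.design != "oneway":
        raise ValueError("expected a one-way ANOVA table")
    r = r or anova.r
    ms_g, ms_e = anova.ms("genotype"), anova.ms("residual")
    if not (np.isfinite(ms_g) and np.isfinite(ms_e)):
        raise ValueError("non-finite mean squares")
    sigma2_g = max(0.0, (ms_g - ms_e) / r)
    noise = ms_e / r if basis == "entry_mean" else ms_e
    denom = sigma2_g + noise
    h2 = sigma2_g / denom if denom > 0 else 0.0
    return HeritabilityResult(
        element=element,
        basis=basis,
        scope="single_year",
        sigma2_g=sigma2_g,
        sigma2_gy=None,
        sigma2_e=ms_e,
        r=r,
        y=1,
        H2=min(1.0, max(0.0, h2)),
    )


def heritability_factorial(
    anova: AnovaTable,
    r: int | None = None,
    y: int | None = None,
    basis: str = "entry_mean",
    element: str | None = None,
) -> HeritabilityResult:
    """Broad-sense heritability from the factorial genotype×year table.

    Components from the balanced EMS relations::

        σ̂²_e  = MS_e
        σ̂²_gy = max(0, (MS_gy − MS_e) / r)
        σ̂²_g  = max(0, (MS_g − MS_gy) / (r·y))
    """
    if anova.design != "factorial":
        raise ValueError("expected a factorial ANOVA table")
    r = r or anova.r
    y = y or anova.y
    ms_g = anova.ms("genotype")
    ms_gy = anova.ms("genotype:year")
    ms_e = anova.ms("residual")
    if not all(np.isfinite(m) for m in (ms_g, ms_gy, ms_e)):
        raise ValueError("non-finite mean squares")
    sigma2_e = ms_e
    sigma2_gy = max(0.0, (ms_gy - ms_e) / r)
    sigma2_g = max(0.0, (ms_g - ms_gy) / (r * y))
    if basis == "entry_mean":
        denom = sigma2_g + sigma2_gy / y + sigma2_e / (r * y)
    else:
        denom = sigma2_g + sigma2_gy + sigma2_e
    h2 = sigma2_g / denom if denom > 0 else 0.0
    return HeritabilityResult(
        element=element,
        basis=basis,
        scope="factorial",
        sigma2_g=sigma2_g,
        sigma2_gy=sigma2_gy,
        sigma2_e=sigma2_e,
        r=r,
        y=y,
        H2=min(1.0, max(0.0, h2)),
    )


def lsd(
    ms_error: float, df_error: float, n_per_mean: int, alpha: float = 0.05
) -> LsdResult:
    """Least significant difference between two means at level alpha.

    LSD = t(1 − α/2, df_e) · sqrt(2·MS_e / n).
    """
    if ms_error < 0:
        raise ValueError("ms_error must be nonnegative")
    if df_error < 1 or n_per_mean < 1:
        raise ValueError("df_error and n_per_mean must be >= 1")
    t_crit = stats.t.ppf(1 - alpha / 2, df_error)
    value = float(t_crit * np.sqrt(2 * ms_error / n_per_mean))
    return LsdResult(
        alpha=alpha,
        ms_error=ms_error,
        df_error=df_error,
        n_per_mean=n_per_mean,
        value=max(0.0, value),
    )


class HeritabilityAnova(BaseEstimator):
    """Per-trait ANOVA and heritability over a replicate-level trial table.

    Parameters
    ----------
    scope : {"factorial", "single_year", "both"}
        Which designs to fit per trait.
    basis : {"entry_mean", "plot"}
        Heritability basis.
    random_model : bool
        Test the genotype effect against the interaction MS in the
        factorial design.

    Attributes
    ----------
    anova_ : dict
        ``{(trait, scope_key): AnovaTable}`` where scope_key is
        ``"factorial"`` or a year.
    results_ : DataFrame
        Long table: trait, scope, year, variance components, H², F, p.
    """

    def __init__(
        self,
        scope: str = "both",
        basis: str = "entry_mean",
        random_model: bool = False,
        traits: list[str] | None = None,
    ):
        self.scope = scope
        self.basis = basis
        self.random_model = random_model
        self.traits = traits

    def fit(self, records: pd.DataFrame, y=None):
        if self.scope not in ("factorial", "single_year", "both"):
            raise ValueError(f"unknown scope {self.scope!r}")
        registry = default_registry()
        traits = self.traits or [
            c for c in registry.codes if c in records.columns
        ]
        self.anova_: dict[tuple[str, object], AnovaTable] = {}
        rows = []
        years = sorted(records["year"].unique())
        for trait in traits:
            long = records[["genotype", "year", trait]].rename(
                columns={trait: "value"}
            )
            if self.scope in ("factorial", "both") and len(years) >= 2:
                tab = factorial_anova(long, random_model=self.random_model)
                self.anova_[(trait, "factorial")] = tab
                h = heritability_factorial(tab, basis=self.basis, element=trait)
                rows.append(self._row(trait, "factorial", None, tab, h))
            if self.scope in ("single_year", "both"):
                for yr in years:
                    tab = oneway_anova(long[long["year"] == yr])
                    self.anova_[(trait, yr)] = tab
                    h = heritability_single_year(
                        tab, basis=self.basis, element=trait
                    )
                    rows.append(self._row(trait, "single_year", yr, tab, h))
        self.results_ = pd.DataFrame(rows)
        return self

    @staticmethod
    def _row(trait, scope, year, tab: AnovaTable, h: HeritabilityResult) -> dict:
        return {
            "trait": trait,
            "scope": scope,
            "year": year,
            "sigma2_g": h.sigma2_g,
            "sigma2_gy": h.sigma2_gy,
            "sigma2_e": h.sigma2_e,
            "H2": h.H2,
            "F_genotype": tab.table.loc["genotype", "F"],
            "p_genotype": tab.table.loc["genotype", "p"],
            "F_gxy": (
                tab.table.loc["genotype:year", "F"]
                if "genotype:year" in tab.table.index
                else np.nan
            ),
            "p_gxy": (
                tab.table.loc["genotype:year", "p"]
                if "genotype:year" in tab.table.index
                else np.nan
            ),
        }
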