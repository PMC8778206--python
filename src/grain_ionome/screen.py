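"""Per-year Pearson correlation screen of elements against a covariate panel.

Each element's genotype means for one year are correlated with grain
yield, protein content, TKW and the five macroelement concentrations.
Cells are flagged significant at p < α (two-sided t transform of r, no
multiple-testing correction); a macroelement is never correlated with
itself.  The flags gate the downstream covariate adjustment, and the
per-element tally of significant correlations feeds the suitability
index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .elements import ElementRegistry, default_registry

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_COVARIATES",
    "ScreenResult",
    "CorrelationScreen",
    "pearson_r",
    "correlation_p_value",
    "screen",
    "tally_significant",
    "Tally",
]

# panel order: agronomic traits then macroelements
DEFAULT_COVARIATES = ("yield", "protein", "tkw", "Ca", "K", "Mg", "P", "S")


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    return float(stats.pearsonr(x, y).statistic)


def correlation_p_value(r: float, n: int) -> float:
    """Two-sided p-value for a correlation coefficient at sample size n.

    Uses t = r·sqrt((n−2)/(1−r²)) with n−2 degrees of freedom; |r| = 1
    returns p = 0 exactly.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) > 1:
        raise ValueError("|r| cannot exceed 1")
    if abs(r) == 1:
        return 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(2 * stats.t.sf(abs(t), n - 2))


@dataclass(frozen=True)
class ScreenResult:
    """One year's screen: r, p, significance flags and sample sizes.

    All four matrices are element × covariate DataFrames.  Undefined
    cells (an element against itself, or a constant trait) hold NaN in
    ``r``/``p`` and False in ``flags``.
    """

    year: int
    r: pd.DataFrame
    p: pd.DataFrame
    flags: pd.DataFrame
    n_used: pd.DataFrame
    alpha: float

    def covariates_for(self, element: str) -> list[str]:
        """Covariates flagged significant for one element, in panel order."""
        row = self.flags.loc[element]
        return [c for c in self.flags.columns if bool(row[c])]


class CorrelationScreen(BaseEstimator):
    """Correlate every element with the covariate panel for one year.

    Parameters
    ----------
    alpha : float
        Significance level for flagging (default 0.05).
    covariates : sequence of str
        Covariate panel; defaults to yield, protein, TKW, Ca, K, Mg, P, S.

    Attributes
    ----------
    result_ : ScreenResult
        Fitted correlation matrices and flags.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        covariates: Sequence[str] = DEFAULT_COVARIATES,
    ):
        self.alpha = alpha
        self.covariates = covariates

    def fit(self, means: pd.DataFrame, y=None):
        """Fit on one year's genotype-mean table (one row per genotype)."""
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        registry = default_registry()
        elements = [c for c in registry.codes if c in means.columns]
        missing = [c for c in self.covariates if c not in means.columns]
        if missing:
            raise ValueError(f"covariate column(s) missing: {missing}")
        n = len(means)
        if n < 3:
            raise ValueError("screen requires at least 3 genotypes")
        if "year" in means.columns and means["year"].nunique() > 1:
            raise ValueError("screen expects a single year of genotype means")

        covs = list(self.covariates)
        r = pd.DataFrame(np.nan, index=elements, columns=covs)
        p = pd.DataFrame(np.nan, index=elements, columns=covs)
        flags = pd.DataFrame(False, index=elements, columns=covs)
        n_used = pd.DataFrame(0, index=elements, columns=covs)
        for e in elements:
            for c in covs:
                if e == c:
                    continue  # self-pair: undefined by construction
                x = means[e].to_numpy(float)
                z = means[c].to_numpy(float)
                ok = np.isfinite(x) & np.isfinite(z)
                if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(z[ok]) == 0:
                    logger.warning(
                        "undefined correlation cell (%s, %s): constant or "
                        "insufficient data",
                        e,
                        c,
                    )
                    continue
                rv = pearson_r(x[ok], z[ok])
                pv = correlation_p_value(rv, int(ok.sum()))
                r.loc[e, c] = rv
                p.loc[e, c] = pv
                flags.loc[e, c] = pv < self.alpha
                n_used.loc[e, c] = int(ok.sum())

        year = int(means["year"].iloc[0]) if "year" in means.columns else 0
        self.result_ = ScreenResult(
            year=year, r=r, p=p, flags=flags, n_used=n_used, alpha=self.alpha
        )
        return self


def screen(
    means: pd.DataFrame,
    alpha: float = 0.05,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> ScreenResult:
    """Functional wrapper over :class:`CorrelationScreen` for one year."""
    return CorrelationScreen(alpha=alpha, covariates=covariates).fit(means).result_


class Tally(NamedTuple):
    """Counts of significant cells by element row and by covariate column."""

    element_counts: pd.Series
    covariate_counts: pd.Series


def tally_significant(results: Sequence[ScreenResult]) -> Tally:
    """Tally flagged cells across all years.

    The element count sums an element's flagged cells over every year and
    covariate; the covariate count sums a column over every element row
    and year.  Totals are conserved: both tallies sum to the number of
    True flags.
    """
    if not results:
        raise ValueError("need at least one ScreenResult")
    element_counts = sum(res.flags.sum(axis=1) for res in results)
    covariate_counts = sum(res.flags.sum(axis=0) for res in results)
    return Tally(
        element_counts=element_counts.astype(int),
        covariate_counts=covariate_counts.astype(int),
    )
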