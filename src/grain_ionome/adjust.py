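"""Correlation-gated covariate adjustment of element concentrations.

For each element and year, the covariates flagged significant by the
correlation screen (among yield, protein, TKW and the macroelements,
never the element itself) enter an ordinary least-squares fit on
genotype means, and the adjusted value is the grand mean plus the
residual::

    adjusted_i = ȳ + (y_i − ŷ_i)

This preserves the mean exactly while removing the covariate-explained
share of the variance, so group and genotype comparisons are no longer
confounded by maturity, yield level or protein content.  Elements with
no significant covariates in a year pass through unchanged.  The fitted
genotype offset (ŷ_i − ȳ) is subtracted from every replicate of that
genotype-year, preserving the replicate structure for downstream ANOVA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .elements import default_registry
from .screen import DEFAULT_COVARIATES, CorrelationScreen, ScreenResult
from .trial import aggregate_genotype_year_means

logger = logging.getLogger(__name__)

__all__ = [
    "AdjustmentModel",
    "CovariateAdjuster",
    "select_covariates",
    "fit_adjustment",
    "adjust_panel",
]


@dataclass(frozen=True)
class AdjustmentModel:
    """Per element-year regression adjustment and its diagnostics."""

    element: str
    year: int
    covariates: tuple[str, ...]
    intercept: float
    coefficients: pd.Series  # slope per covariate, units per covariate unit
    adjusted: pd.Series  # adjusted genotype means, indexed by genotype
    offsets: pd.Series  # fitted minus grand mean, per genotype
    mean_original: float
    mean_adjusted: float
    cv_original: float
    cv_adjusted: float
    r_original_adjusted: float
    r_squared: float = 0.0

    @property
    def is_identity(self) -> bool:
        return len(self.covariates) == 0


def select_covariates(element: str, screen: ScreenResult) -> list[str]:
    """Covariates flagged significant for an element in one year's screen.

    The element itself is never in its own set (the screen leaves the
    self-pair undefined).  An empty list means the adjustment is skipped
    for that element-year.
    """
    if element not in screen.flags.index:
        raise KeyError(f"element {element!r} not present in screen")
    return screen.covariates_for(element)


def fit_adjustment(
    values: pd.Series,
    X: pd.DataFrame,
    element: str = "",
    year: int = 0,
) -> AdjustmentModel:
    """OLS fit of genotype means on covariates; adjusted = mean + residual.

    ``values`` and ``X`` are indexed by genotype.  With an empty
    covariate frame the adjustment is the identity.
    """
    values = values.astype(float)
    grand = float(values.mean())
    n = len(values)
    covs = tuple(X.columns)

    if len(covs) == 0:
        adjusted = values.copy()
        cv = _cv_percent(values)
        return AdjustmentModel(
            element=element,
            year=year,
            covariates=(),
            intercept=grand,
            coefficients=pd.Series(dtype=float),
            adjusted=adjusted,
            offsets=pd.Series(0.0, index=values.index),
            mean_original=grand,
            mean_adjusted=grand,
            cv_original=cv,
            cv_adjusted=cv,
            r_original_adjusted=1.0,
        )

    if n < len(covs) + 2:
        raise ValueError(
            f"need at least {len(covs) + 2} genotypes for {len(covs)} covariates"
        )
    if not X.index.equals(values.index):
        raise ValueError("values and covariates must share the genotype index")

    design = np.column_stack([np.ones(n), X.to_numpy(float)])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"rank-deficient covariate matrix; collinear columns among {list(covs)}"
        )
    beta, *_ = np.linalg.lstsq(design, values.to_numpy(), rcond=None)
    fitted = design @ beta
    residuals = values.to_numpy() - fitted
    adjusted = pd.Series(grand + residuals, index=values.index)
    offsets = pd.Series(fitted - grand, index=values.index)

    ss_tot = float(((values - grand) ** 2).sum())
    ss_res = float((residuals**2).sum())
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if adjusted.std() > 0 and values.std() > 0:
        r_oa = float(np.corrcoef(values, adjusted)[0, 1])
    else:
        r_oa = np.nan  # perfect fit: adjusted is constant
    return AdjustmentModel(
        element=element,
        year=year,
        covariates=covs,
        intercept=float(beta[0]),
        coefficients=pd.Series(beta[1:], index=list(covs)),
        adjusted=adjusted,
        offsets=offsets,
        mean_original=grand,
        mean_adjusted=float(adjusted.mean()),
        cv_original=_cv_percent(values),
        cv_adjusted=_cv_percent(adjusted),
        r_original_adjusted=r_oa,
        r_squared=r2,
    )


def _cv_percent(values: pd.Series) -> float:
    m = values.mean()
    return float(100 * values.std(ddof=1) / m) if m != 0 else np.nan


class CovariateAdjuster(BaseEstimator):
    """Screen-gated regression adjustment of a replicate-level trial table.

    Parameters
    ----------
    alpha : float
        Significance level of the gating correlation screen.
    covariates : sequence of str
        Covariate panel for screen and regression.

    Attributes
    ----------
    screens_ : dict[int, ScreenResult]
        Per-year screens used for gating (computed in fit unless given).
    models_ : dict[tuple[str, int], AdjustmentModel]
        One fitted model per (element, year), identity models included.
    """

    def __init__(self, alpha: float = 0.05, covariates=DEFAULT_COVARIATES):
        self.alpha = alpha
        self.covariates = covariates

    def fit(self, records: pd.DataFrame, screens: dict[int, ScreenResult] | None = None):
        registry = default_registry()
        means = aggregate_genotype_year_means(records, registry)
        years = sorted(means["year"].unique())
        if screens is None:
            screens = {}
            for yr in years:
                est = CorrelationScreen(
                    alpha=self.alpha, covariates=self.covariates
                )
                screens[yr] = est.fit(means[means["year"] == yr]).result_
        missing_years = [yr for yr in years if yr not in screens]
        if missing_years:
            raise ValueError(f"no screen provided for year(s) {missing_years}")
        self.screens_ = screens

        elements = [c for c in registry.codes if c in records.columns]
        self.models_ = {}
        for yr in years:
            ym = means[means["year"] == yr].set_index("genotype")
            for element in elements:
                covs = select_covariates(element, screens[yr])
                X = ym[covs] if covs else ym[[]]
                model = fit_adjustment(
                    ym[element], X, element=element, year=int(yr)
                )
                self.models_[(element, int(yr))] = model
        return self

    def transform(self, records: pd.DataFrame) -> pd.DataFrame:
        """Return a copy with per-genotype offsets removed from replicates."""
        if not hasattr(self, "models_"):
            raise ValueError("CovariateAdjuster is not fitted")
        out = records.copy()
        for (element, yr), model in self.models_.items():
            if model.is_identity:
                continue
            mask = out["year"] == yr
            genos = out.loc[mask, "genotype"]
            unseen = set(genos) - set(model.offsets.index)
            if unseen:
                raise ValueError(
                    f"genotypes absent from fitted model {element}-{yr}: "
                    f"{sorted(unseen)[:5]}"
                )
            out.loc[mask, element] = (
                out.loc[mask, element].to_numpy()
                - model.offsets.reindex(genos).to_numpy()
            )
        return out

    def fit_transform(self, records: pd.DataFrame, screens=None) -> pd.DataFrame:
        return self.fit(records, screens=screens).transform(records)

    def model_table(self) -> pd.DataFrame:
        """Long summary of every fitted model (original vs adjusted rows)."""
        rows = []
        for (element, yr), m in sorted(self.models_.items()):
            rows.append(
                {
                    "element": element,
                    "year": yr,
                    "data": "original",
                    "variables": "-",
                    "mean": m.mean_original,
                    "cv_percent": m.cv_original,
                    "r_original_adjusted": np.nan,
                }
            )
            if not m.is_identity:
                rows.append(
                    {
                        "element": element,
                        "year": yr,
                        "data": "adjusted",
                        "variables": ", ".join(m.covariates),
                        "mean": m.mean_adjusted,
                        "cv_percent": m.cv_adjusted,
                        "r_original_adjusted": m.r_original_adjusted,
                    }
                )
        return pd.DataFrame(rows)


def adjust_panel(
    records: pd.DataFrame,
    screens: dict[int, ScreenResult] | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, "CovariateAdjuster"]:
    """Adjust every element-year of a trial; returns (adjusted records,
    model summary table, fitted adjuster)."""
    adjuster = CovariateAdjuster(alpha=alpha)
    adjusted = adjuster.fit_transform(records, screens=screens)
    return adjusted, adjuster.model_table(), adjuster
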