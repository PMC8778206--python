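"""Rank-sum index of each element's suitability for genetic enhancement.

Three criteria are ranked over the 15 elements with mid-rank tie
handling and summed:

* phenotypic CV% of the two-year genotype means — highest variation
  ranks 1 (more room for selection),
* number of significant correlations with the agronomic traits and
  macroelements — fewest ranks 1 (an independent trait is easier to
  select on),
* broad-sense heritability from the factorial genotype×year ANOVA of
  the original data — highest ranks 1.

The sum of the three ranks is ranked again ascending; rank 1 marks the
element most amenable to breeding improvement.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

__all__ = [
    "phenotypic_cv",
    "rank_with_ties",
    "suitability_table",
    "SuitabilityRanker",
]


def phenotypic_cv(values) -> float:
    """Coefficient of phenotypic variation: 100 · sample sd / mean."""
    values = np.asarray(values, float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    m = values.mean()
    if m <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(100 * values.std(ddof=1) / m)


def rank_with_ties(values, direction: str = "descending") -> np.ndarray:
    """Mid-ranks with rank 1 = best for the given direction.

    direction='descending' ranks the largest value 1 (CV, H²);
    'ascending' ranks the smallest value 1 (correlation counts).  Tied
    values receive the arithmetic mean of the rank positions they span.
    """
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("empty input")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    if direction == "descending":
        return rankdata(-values, method="average")
    if direction == "ascending":
        return rankdata(values, method="average")
    raise ValueError(f"unknown direction {direction!r}")


class SuitabilityRanker(BaseEstimator):
    """Combine CV%, correlation count and H² into the rank-sum index.

    ``fit`` takes a DataFrame indexed by element with columns
    ``cv_percent``, ``n_sig_corr`` and ``h2``; the fitted ``table_``
    carries the three mid-rank columns, their sum and the final rank.
    """

    def fit(self, criteria: pd.DataFrame, y=None):
        required = {"cv_percent", "n_sig_corr", "h2"}
        missing = required - set(criteria.columns)
        if missing:
            raise ValueError(f"missing criterion column(s): {sorted(missing)}")
        out = criteria[["cv_percent", "n_sig_corr", "h2"]].copy()
        out["rank_cv"] = rank_with_ties(out["cv_percent"], "descending")
        out["rank_corr"] = rank_with_ties(out["n_sig_corr"], "ascending")
        out["rank_h2"] = rank_with_ties(out["h2"], "descending")
        out["rank_sum"] = out["rank_cv"] + out["rank_corr"] + out["rank_h2"]
        out["final_rank"] = rank_with_ties(out["rank_sum"], "ascending")
        self.table_ = out
        return self

    def transform(self, criteria: pd.DataFrame) -> pd.DataFrame:
        return self.fit(criteria).table_


def suitability_table(
    cv: pd.Series, counts: pd.Series, h2: pd.Series
) -> pd.DataFrame:
    """Build the suitability table from three element-indexed criteria.

    All three series must share the same element index.
    """
    if not (cv.index.equals(counts.index) and cv.index.equals(h2.index)):
        raise ValueError("criteria must share the same element index")
    criteria = pd.DataFrame(
        {"cv_percent": cv, "n_sig_corr": counts, "h2": h2}
    )
    return SuitabilityRanker().fit(criteria).table_
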