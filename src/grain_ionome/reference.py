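"""Published reference values from the two-year Siberian spring-wheat
trial this pipeline was designed around.

The raw replicate-level data of that trial are not public, but its
printed summary tables are: the per-year significance pattern of the
element × covariate correlation screen, and the three per-element
suitability criteria (phenotypic CV% of the two-year means, count of
significant correlations, factorial-ANOVA H²).  They serve two roles
here: calibration targets for the synthetic generator, and fixed inputs
for validating the tally and rank-sum arithmetic against the published
results.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .elements import default_registry
from .screen import DEFAULT_COVARIATES, ScreenResult

__all__ = [
    "SIGNIFICANT_CELLS",
    "SUITABILITY_CRITERIA",
    "reference_screens",
    "reference_criteria",
]

# starred cells of the published per-year correlation screen:
# (element, year) -> covariates flagged significant at the 0.05 level
SIGNIFICANT_CELLS: dict[tuple[str, int], tuple[str, ...]] = {
    ("Ca", 2017): (),
    ("Ca", 2018): ("Mg",),
    ("K", 2017): ("S",),
    ("K", 2018): (),
    ("Mg", 2017): ("yield", "protein", "P", "S"),
    ("Mg", 2018): ("protein", "Ca", "P", "S"),
    ("P", 2017): ("protein", "K", "Mg", "S"),
    ("P", 2018): ("yield", "protein", "K", "Mg", "S"),
    ("S", 2017): ("yield", "protein", "K", "Mg", "P"),
    ("S", 2018): ("yield", "protein", "Mg", "P"),
    ("Cu", 2017): ("protein", "Mg", "P", "S"),
    ("Cu", 2018): ("yield", "protein", "K", "Mg", "P", "S"),
    ("Fe", 2017): ("protein", "tkw", "Mg"),
    ("Fe", 2018): (),
    ("Mn", 2017): ("protein", "Mg", "P", "S"),
    ("Mn", 2018): ("Ca", "Mg", "P", "S"),
    ("Zn", 2017): ("protein", "Mg", "P", "S"),
    ("Zn", 2018): ("yield", "protein", "K", "Mg", "P", "S"),
    ("Cd", 2017): ("yield", "protein", "Mg", "P", "S"),
    ("Cd", 2018): ("yield", "protein", "Mg", "P", "S"),
    ("Co", 2017): (),
    ("Co", 2018): (),
    ("Ni", 2017): ("Mg", "P", "S"),
    ("Ni", 2018): ("yield", "protein", "Mg", "P", "S"),
    ("Mo", 2017): ("protein", "P", "S"),
    ("Mo", 2018): ("K", "Mg", "P", "S"),
    ("Rb", 2017): (),
    ("Rb", 2018): (),
    ("Sr", 2017): ("yield", "protein", "Ca"),
    ("Sr", 2018): ("yield", "protein", "tkw", "Ca"),
}

# per-element suitability criteria as published:
# CV% of the 2017-2018 genotype means, number of significant
# correlations, factorial-ANOVA H² of the original data
SUITABILITY_CRITERIA: dict[str, tuple[float, int, float]] = {
    "Ca": (14.5, 1, 0.73),
    "K": (13.0, 1, 0.61),
    "Mg": (8.8, 8, 0.67),
    "P": (11.3, 9, 0.60),
    "S": (9.6, 9, 0.81),
    "Cu": (14.6, 10, 0.61),
    "Fe": (13.6, 2, 0.58),
    "Mn": (11.5, 7, 0.55),
    "Zn": (17.4, 10, 0.27),
    "Cd": (35.7, 10, 0.76),
    "Co": (22.1, 0, 0.65),
    "Ni": (25.1, 8, 0.49),
    "Mo": (23.2, 7, 0.84),
    "Rb": (20.3, 0, 0.48),
    "Sr": (28.8, 7, 0.87),
}


def reference_screens(alpha: float = 0.05) -> dict[int, ScreenResult]:
    """ScreenResults carrying the published significance flags.

    Correlation coefficients and p-values are not reconstructed from the
    rounded print; only the flags (and the self-pair gaps) are encoded,
    which is all the tally and the covariate gating consume.
    """
    elements = default_registry().codes
    covs = list(DEFAULT_COVARIATES)
    years = sorted({yr for _, yr in SIGNIFICANT_CELLS})
    screens = {}
    for yr in years:
        flags = pd.DataFrame(False, index=elements, columns=covs)
        for element in elements:
            for cov in SIGNIFICANT_CELLS[(element, yr)]:
                flags.loc[element, cov] = True
        nan = pd.DataFrame(np.nan, index=elements, columns=covs)
        screens[yr] = ScreenResult(
            year=yr,
            r=nan,
            p=nan.copy(),
            flags=flags,
            n_used=pd.DataFrame(135, index=elements, columns=covs),
            alpha=alpha,
        )
    return screens


def reference_criteria() -> pd.DataFrame:
    """The three published suitability criteria, indexed by element."""
    frame = pd.DataFrame.from_dict(
        SUITABILITY_CRITERIA,
        orient="index",
        columns=["cv_percent", "n_sig_corr", "h2"],
    )
    frame.index.name = "element"
    return frame
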