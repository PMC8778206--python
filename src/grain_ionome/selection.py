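"""Group summaries and direction-aware superior-germplasm selection.

Genotypes are ranked per element on adjusted two-year means.  Superior
performance is membership in the top-k (nutrients: macro- and
microelements, favorable high) or bottom-k (toxic and other trace
elements, favorable low).  Genotypes favorable for at least m elements
form the selection report, annotated with their grain-yield and protein
ranks.  Group means are compared against a designated check cultivar.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .elements import ElementDef, ElementRegistry, default_registry
from .trial import aggregate_genotype_year_means

logger = logging.getLogger(__name__)

__all__ = [
    "two_year_genotype_means",
    "group_summaries",
    "rank_genotypes_per_element",
    "superior_set",
    "multi_element_favorables",
    "SuperiorSelector",
]


def two_year_genotype_means(
    records: pd.DataFrame, registry: ElementRegistry | None = None
) -> pd.DataFrame:
    """Across-year genotype means (mean of the per-year genotype means)."""
    registry = registry or default_registry()
    per_year = aggregate_genotype_year_means(records, registry)
    traits = [c for c in per_year.columns if c not in ("genotype", "group", "year")]
    return per_year.groupby(["genotype", "group"], as_index=False)[traits].mean()


def group_summaries(
    original: pd.DataFrame,
    adjusted: pd.DataFrame,
    check_id: str,
    registry: ElementRegistry | None = None,
) -> pd.DataFrame:
    """Per group × element means (original and adjusted) with standard
    errors and percent difference versus the check genotype.

    Standard error is sd over the group's genotype means divided by
    sqrt(n genotypes); undefined (NaN) for single-genotype groups.
    Percent difference uses the check genotype's own two-year mean:
    100·(group mean − check)/check.
    """
    registry = registry or default_registry()
    mo = two_year_genotype_means(original, registry).set_index("genotype")
    ma = two_year_genotype_means(adjusted, registry).set_index("genotype")
    if check_id not in mo.index:
        raise KeyError(f"check genotype {check_id!r} not found")
    rows = []
    for element in registry.codes:
        check_orig = float(mo.loc[check_id, element])
        check_adj = float(ma.loc[check_id, element])
        for group, sub in mo.groupby("group"):
            sub_adj = ma.loc[sub.index]
            n = len(sub)
            if n == 1:
                logger.warning(
                    "group %s has a single genotype; SE undefined", group
                )
            se_o = float(sub[element].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            se_a = (
                float(sub_adj[element].std(ddof=1) / np.sqrt(n))
                if n > 1
                else np.nan
            )
            mean_o = float(sub[element].mean())
            mean_a = float(sub_adj[element].mean())
            rows.append(
                {
                    "group": group,
                    "element": element,
                    "n_genotypes": n,
                    "mean_original": mean_o,
                    "se_original": se_o,
                    "mean_adjusted": mean_a,
                    "se_adjusted": se_a,
                    "pct_vs_check_original": 100 * (mean_o - check_orig) / check_orig,
                    "pct_vs_check_adjusted": 100 * (mean_a - check_adj) / check_adj,
                }
            )
    return pd.DataFrame(rows)


def rank_genotypes_per_element(
    means: pd.DataFrame, element: str
) -> pd.DataFrame:
    """Deterministic ordering of genotypes by concentration, highest first.

    Ties are broken by genotype id for reproducibility and annotated in
    the ``tied`` column.
    """
    sub = means[["genotype", element]].sort_values(
        [element, "genotype"], ascending=[False, True]
    )
    values = sub[element].to_numpy()
    tied = np.zeros(len(sub), bool)
    if len(sub) > 1:
        same_prev = np.r_[False, values[1:] == values[:-1]]
        same_next = np.r_[values[:-1] == values[1:], False]
        tied = same_prev | same_next
    return pd.DataFrame(
        {
            "genotype": sub["genotype"].to_numpy(),
            "value": values,
            "rank": np.arange(1, len(sub) + 1),
            "tied": tied,
        }
    )


def superior_set(
    element: ElementDef, ordering: pd.DataFrame, k: int = 15
) -> set[str]:
    """Top-k (favorable high) or bottom-k (favorable low) genotypes.

    ``ordering`` is the highest-first frame from
    :func:`rank_genotypes_per_element`.
    """
    if k <= 0:
        return set()
    n = len(ordering)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} genotypes available")
    if element.favorable_direction == "high":
        chosen = ordering.head(k)
    else:
        chosen = ordering.tail(k)
    return set(chosen["genotype"])


def multi_element_favorables(
    sets: dict[str, set[str]],
    means: pd.DataFrame,
    m: int = 3,
) -> pd.DataFrame:
    """Genotypes favorable for at least m elements, with trait ranks.

    Yield and protein ranks (1 = highest) are attached from the two-year
    genotype means for context, mirroring a breeder's selection sheet.
    """
    membership: dict[str, list[str]] = {}
    for element, genos in sets.items():
        for geno in genos:
            membership.setdefault(geno, []).append(element)
    meta = means.set_index("genotype")
    yield_rank = meta["yield"].rank(ascending=False, method="min")
    protein_rank = meta["protein"].rank(ascending=False, method="min")
    rows = []
    for geno, elements in membership.items():
        if len(elements) < m:
            continue
        rows.append(
            {
                "genotype": geno,
                "group": meta.loc[geno, "group"],
                "n_favorable": len(elements),
                "favorable_elements": ", ".join(sorted(elements)),
                "yield_rank": int(yield_rank.loc[geno]),
                "protein_rank": int(protein_rank.loc[geno]),
            }
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "genotype",
            "group",
            "n_favorable",
            "favorable_elements",
            "yield_rank",
            "protein_rank",
        ],
    )
    if not report.empty:
        report = report.sort_values(
            ["n_favorable", "genotype"], ascending=[False, True]
        ).reset_index(drop=True)
    return report


class SuperiorSelector(BaseEstimator):
    """Direction-aware top-k selection over adjusted two-year means.

    Parameters
    ----------
    k : int
        Superior-set size per element (default 15).
    m : int
        Minimum number of favorable elements for the report (default 3).

    Attributes
    ----------
    means_ : DataFrame
        Two-year genotype means used for ranking.
    orderings_ : dict[str, DataFrame]
        Highest-first ordering per element.
    sets_ : dict[str, set[str]]
        Superior set per element.
    report_ : DataFrame
        Genotypes favorable for ≥ m elements with yield/protein ranks.
    """

    def __init__(self, k: int = 15, m: int = 3):
        self.k = k
        self.m = m

    def fit(self, adjusted_records: pd.DataFrame, y=None):
        registry = default_registry()
        self.means_ = two_year_genotype_means(adjusted_records, registry)
        self.orderings_ = {}
        self.sets_ = {}
        for element in registry.codes:
            if element not in self.means_.columns:
                continue
            ordering = rank_genotypes_per_element(self.means_, element)
            self.orderings_[element] = ordering
            self.sets_[element] = superior_set(
                registry[element], ordering, k=self.k
            )
        self.report_ = multi_element_favorables(
            self.sets_, self.means_, m=self.m
        )
        return self
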