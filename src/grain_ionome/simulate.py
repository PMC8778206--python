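"""Synthetic replicated multi-year wheat trials with known ground truth.

The generator reproduces the structure of a two-year replicated
genotype trial: for every trait (agronomic and element concentrations)

    value_ijk = µ + G_i + Y_j + GY_ij + ε_ijk

with independent Gaussian genotype, year, genotype×year and plot
effects.  Genotype effects of the elements are weighted sums of two
shared latent genotype factors — a "protein factor" and a
"macroelement factor" — plus an element-specific part, so configured
element↔protein and element↔macroelement correlations are realised in
expectation at the genotype-mean level.  Protein, yield and TKW are
driven by the same latent factors, which is what makes the covariate
adjustment downstream meaningful.

Variance components are derived from a target entry-mean heritability
on the factorial scale, the residual CV% and the interaction/genotype
variance ratio, so every simulated element has an exactly known true
H² for parameter-recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .anova import factorial_anova, heritability_factorial
from .elements import default_registry
from .trial import AGRONOMIC_TRAITS, aggregate_genotype_year_means

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfigError",
    "TraitSim",
    "SimConfig",
    "SimTruth",
    "simulate_trial",
    "realized_statistics",
    "default_config",
]

DEFAULT_GROUP_COUNTS = {
    "CIMMYT_synthetic": 37,
    "Japan_synthetic": 8,
    "USA": 14,
    "KASIB_early": 15,
    "KASIB_intermediate": 42,
    "KASIB_late": 17,
    "check": 2,
}

# per-element calibration: mean µg/g, observed within-year genotype-mean
# CV% target, factorial entry-mean H² target, genotype-mean correlation
# targets with the protein factor and the shared macroelement factor.
# Magnitudes follow published spring-wheat grain-ionome surveys.
_ELEMENT_CALIBRATION: dict[str, tuple[float, float, float, float, float]] = {
    #        mean     CV%   H²    ρ_protein ρ_macro
    "Ca": (380.0, 14.5, 0.73, 0.00, 0.15),
    "K": (3647.0, 13.0, 0.61, 0.10, 0.20),
    "Mg": (1216.0, 8.8, 0.67, 0.36, 0.65),
    "P": (4940.0, 11.3, 0.60, 0.31, 0.65),
    "S": (2054.0, 9.6, 0.81, 0.46, 0.60),
    "Fe": (36.8, 13.6, 0.58, 0.20, 0.10),
    "Cu": (4.19, 14.6, 0.61, 0.27, 0.55),
    "Mn": (44.0, 11.5, 0.55, 0.20, 0.55),
    "Zn": (47.6, 17.4, 0.27, 0.20, 0.35),
    "Cd": (0.037, 35.7, 0.76, 0.34, 0.40),
    "Co": (0.0095, 22.1, 0.65, 0.00, 0.00),
    "Ni": (0.180, 25.1, 0.49, 0.26, 0.25),
    "Mo": (0.328, 23.2, 0.84, 0.18, 0.25),
    "Rb": (3.93, 20.3, 0.48, 0.00, 0.00),
    "Sr": (2.26, 28.8, 0.87, 0.26, 0.20),
}

_AGRONOMIC_CALIBRATION: dict[str, tuple[float, float, float, float, float]] = {
    "dh": (39.5, 8.0, 0.90, 0.00, 0.00),
    "yield": (370.0, 25.0, 0.80, -0.45, 0.00),
    "tkw": (43.7, 8.0, 0.80, 0.00, 0.00),
    "protein": (16.5, 7.0, 0.80, 1.00, 0.00),
}


class SimConfigError(ValueError):
    """The configured variance/correlation targets are inconsistent."""


@dataclass(frozen=True)
class TraitSim:
    """Simulation settings for one trait.

    ``h2_target`` is the factorial entry-mean heritability; the genotype
    variance is solved from it, the residual CV and the interaction
    ratio.  ``rho_protein``/``rho_macro`` are target genotype-mean
    correlations with the latent protein and macroelement factors.  Set
    ``genetic_cv`` to fix σ_G directly (required when residual_cv is 0).
    """

    mean: float
    h2_target: float
    residual_cv: float
    rho_protein: float = 0.0
    rho_macro: float = 0.0
    genetic_cv: float | None = None

    def variance_components(
        self, reps: int, years: int, gy_ratio: float, year_cv: float
    ) -> tuple[float, float, float, float]:
        """(σ²_G, σ²_Y, σ²_GY, σ²_e) implied by the targets."""
        sigma2_e = (self.residual_cv / 100 * self.mean) ** 2
        sigma2_y = (year_cv / 100 * self.mean) ** 2
        if self.genetic_cv is not None:
            sigma2_g = (self.genetic_cv / 100 * self.mean) ** 2
        else:
            if not 0 <= self.h2_target <= 1:
                raise SimConfigError("h2_target must lie in [0, 1]")
            entry_noise = sigma2_e / (reps * years)
            denom = 1 - self.h2_target * (1 + gy_ratio / years)
            if self.h2_target > 0 and sigma2_e == 0:
                raise SimConfigError(
                    "residual_cv 0 with 0 < h2_target leaves σ²_G "
                    "unidentified; set genetic_cv explicitly"
                )
            if denom <= 0:
                raise SimConfigError(
                    f"h2_target {self.h2_target} unreachable with "
                    f"gy_ratio {gy_ratio}: lower the ratio or the target"
                )
            sigma2_g = self.h2_target * entry_noise / denom
        sigma2_gy = gy_ratio * sigma2_g
        return sigma2_g, sigma2_y, sigma2_gy, sigma2_e


@dataclass(frozen=True)
class SimConfig:
    """Full trial configuration: design, per-trait settings and seed."""

    n_genotypes: int = 135
    years: int = 2
    reps: int = 4
    seed: int = 0
    first_year: int = 2017
    gy_ratio: float = 0.2  # σ²_GY / σ²_G
    year_cv: float = 5.0  # year-effect sd as % of the trait mean
    elements: dict[str, TraitSim] = field(default_factory=dict)
    agronomic: dict[str, TraitSim] = field(default_factory=dict)
    group_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_COUNTS)
    )
    # additive shifts of a group's genotype effects: {(trait, group): shift}
    group_shifts: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.group_counts.values()) != self.n_genotypes:
            raise SimConfigError(
                f"group counts sum to {sum(self.group_counts.values())}, "
                f"expected n_genotypes={self.n_genotypes}"
            )
        if self.years < 1 or self.reps < 1:
            raise SimConfigError("years and reps must be >= 1")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The default 135-genotype × 2-year × 4-replicate trial.

    Element means, CVs, heritabilities and correlation structure follow
    the calibration table above; the residual CV is back-solved so the
    realised within-year genotype-mean CV lands near its target.
    """
    reps = overrides.get("reps", 4)
    years = overrides.get("years", 2)
    gy_ratio = overrides.get("gy_ratio", 0.2)
    elements = {
        code: _calibrated_trait(*row, reps=reps, years=years, gy_ratio=gy_ratio)
        for code, row in _ELEMENT_CALIBRATION.items()
    }
    agronomic = {
        name: _calibrated_trait(*row, reps=reps, years=years, gy_ratio=gy_ratio)
        for name, row in _AGRONOMIC_CALIBRATION.items()
    }
    return SimConfig(
        seed=seed, elements=elements, agronomic=agronomic, **overrides
    )


def _calibrated_trait(
    mean: float,
    observed_cv: float,
    h2: float,
    rho_protein: float,
    rho_macro: float,
    reps: int,
    years: int,
    gy_ratio: float,
) -> TraitSim:
    """Back-solve the residual CV from the observed genotype-mean CV.

    Within one year, Var(genotype mean) = σ²_G(1 + gy_ratio) + σ²_e/r
    and σ²_G = h2·σ²_e/(r·y·(1 − h2(1 + gy_ratio/y))), so the observed
    CV scales linearly with the residual CV.
    """
    denom = 1 - h2 * (1 + gy_ratio / years)
    if denom <= 0:
        raise SimConfigError(f"h2 {h2} unreachable with gy_ratio {gy_ratio}")
    a = h2 / (reps * years * denom)
    scale = np.sqrt(a * (1 + gy_ratio) + 1 / reps)
    return TraitSim(
        mean=mean,
        h2_target=h2,
        residual_cv=observed_cv / scale,
        rho_protein=rho_protein,
        rho_macro=rho_macro,
    )


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated trial."""

    components: pd.DataFrame  # per trait: sigma2_g, sigma2_y, sigma2_gy, sigma2_e, h2
    genotype_effects: pd.DataFrame  # genotype × trait
    loadings: pd.DataFrame  # per trait: w_protein, w_macro, w_specific
    protein_betas: pd.Series  # implied regression slope of each element on protein

    def h2(self, trait: str) -> float:
        return float(self.components.loc[trait, "h2_factorial"])


def _loadings(
    trait: str, cfg: TraitSim, h2_protein: float
) -> tuple[float, float, float]:
    """Convert genotype-mean correlation targets into factor loadings.

    corr(mean_e, mean_protein) = w_p·sqrt(h2_e·h2_protein) and
    corr(mean_e, F_macro) = w_m·sqrt(h2_e), so the loadings are the
    targets divided by the attenuation factors.
    """
    if trait == "protein":
        return 1.0, 0.0, 0.0
    h2 = cfg.h2_target
    if cfg.rho_protein == 0 and cfg.rho_macro == 0:
        return 0.0, 0.0, 1.0
    if h2 <= 0:
        raise SimConfigError(
            f"{trait}: nonzero correlation targets need h2_target > 0"
        )
    w_p = cfg.rho_protein / np.sqrt(h2 * h2_protein)
    w_m = cfg.rho_macro / np.sqrt(h2)
    rest = 1.0 - w_p**2 - w_m**2
    if rest < 0:
        raise SimConfigError(
            f"{trait}: correlation targets imply negative element-specific "
            f"variance (w_p²+w_m² = {w_p**2 + w_m**2:.3f} > 1)"
        )
    return float(w_p), float(w_m), float(np.sqrt(rest))


def simulate_trial(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Draw one replicate-level trial; identical config → identical output."""
    if not config.elements:
        config = replace(
            config,
            elements=default_config().elements,
            agronomic=config.agronomic or default_config().agronomic,
        )
    if not config.agronomic:
        config = replace(config, agronomic=default_config().agronomic)
    rng = np.random.default_rng(config.seed)
    n_g, n_y, n_r = config.n_genotypes, config.years, config.reps

    genotypes = [f"G{i + 1:03d}" for i in range(n_g)]
    groups = []
    for group, count in config.group_counts.items():
        groups.extend([group] * count)
    year_labels = [config.first_year + j for j in range(n_y)]

    # shared latent genotype factors, standard normal
    f_protein = rng.standard_normal(n_g)
    f_macro = rng.standard_normal(n_g)

    h2_protein = config.agronomic["protein"].h2_target
    traits = {**config.agronomic, **config.elements}
    comp_rows, load_rows, beta = {}, {}, {}
    effects = pd.DataFrame(index=genotypes)
    data = {}
    clipped_total = 0
    registry = default_registry()

    for trait, cfg in traits.items():
        s2_g, s2_y, s2_gy, s2_e = cfg.variance_components(
            n_r, n_y, config.gy_ratio, config.year_cv
        )
        sd_g = np.sqrt(s2_g)
        w_p, w_m, w_u = _loadings(trait, cfg, h2_protein)
        u = rng.standard_normal(n_g)
        g_eff = sd_g * (w_p * f_protein + w_m * f_macro + w_u * u)
        for (shift_trait, group), shift in config.group_shifts.items():
            if shift_trait == trait:
                g_eff = g_eff + np.where(np.array(groups) == group, shift, 0.0)
        y_eff = rng.normal(0.0, np.sqrt(s2_y), n_y)
        gy_eff = rng.normal(0.0, np.sqrt(s2_gy), (n_g, n_y))
        eps = rng.normal(0.0, np.sqrt(s2_e), (n_g, n_y, n_r))
        values = (
            cfg.mean
            + g_eff[:, None, None]
            + y_eff[None, :, None]
            + gy_eff[:, :, None]
            + eps
        )
        # concentrations and agronomic traits are physically nonnegative
        n_clip = int((values < 0).sum())
        if n_clip:
            clipped_total += n_clip
            logger.warning("%s: clipped %d negative values to 0", trait, n_clip)
        values = np.clip(values, 0.0, None)
        if trait == "protein":
            values = np.clip(values, np.nextafter(0, 1), 99.9)
        entry_noise = s2_gy / n_y + s2_e / (n_r * n_y)
        h2_real = s2_g / (s2_g + entry_noise) if (s2_g + entry_noise) > 0 else 0.0
        comp_rows[trait] = {
            "mean": cfg.mean,
            "sigma2_g": s2_g,
            "sigma2_y": s2_y,
            "sigma2_gy": s2_gy,
            "sigma2_e": s2_e,
            "h2_factorial": h2_real,
        }
        load_rows[trait] = {"w_protein": w_p, "w_macro": w_m, "w_specific": w_u}
        effects[trait] = g_eff
        data[trait] = values
        if trait in registry.codes:
            sd_gp = np.sqrt(
                config.agronomic["protein"].variance_components(
                    n_r, n_y, config.gy_ratio, config.year_cv
                )[0]
            )
            beta[trait] = sd_g * w_p / sd_gp if sd_gp > 0 else np.nan

    if clipped_total:
        logger.warning("total zero-clipped concentrations: %d", clipped_total)

    rows = {
        "genotype": np.repeat(genotypes, n_y * n_r),
        "group": np.repeat(groups, n_y * n_r),
        "year": np.tile(np.repeat(year_labels, n_r), n_g),
        "rep": np.tile(np.arange(1, n_r + 1), n_g * n_y),
    }
    records = pd.DataFrame(rows)
    order = [t for t in AGRONOMIC_TRAITS + registry.codes if t in data]
    for trait in order:
        records[trait] = data[trait].reshape(-1)

    truth = SimTruth(
        components=pd.DataFrame(comp_rows).T,
        genotype_effects=effects,
        loadings=pd.DataFrame(load_rows).T,
        protein_betas=pd.Series(beta),
    )
    return records, truth


def realized_statistics(
    records: pd.DataFrame, truth: SimTruth, config: SimConfig | None = None
) -> pd.DataFrame:
    """Realised per-element mean, CV%, factorial H² and protein correlation
    next to the configured truth — the generator's self-check table."""
    registry = default_registry()
    means = aggregate_genotype_year_means(records, registry)
    two_year = means.groupby("genotype").mean(numeric_only=True)
    rows = []
    for element in registry.codes:
        if element not in records.columns:
            continue
        long = records[["genotype", "year", element]].rename(
            columns={element: "value"}
        )
        if records["year"].nunique() >= 2:
            tab = factorial_anova(long)
            h2_est = heritability_factorial(tab).H2
        else:
            h2_est = np.nan
        per_year_cv = (
            means.groupby("year")[element]
            .apply(lambda v: 100 * v.std(ddof=1) / v.mean())
            .mean()
        )
        rows.append(
            {
                "element": element,
                "mean_true": truth.components.loc[element, "mean"],
                "mean_realized": float(records[element].mean()),
                "cv_realized": float(per_year_cv),
                "h2_true": truth.h2(element),
                "h2_realized": float(h2_est),
                "r_protein_realized": float(
                    np.corrcoef(two_year[element], two_year["protein"])[0, 1]
                ),
            }
        )
    return pd.DataFrame(rows).set_index("element")
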