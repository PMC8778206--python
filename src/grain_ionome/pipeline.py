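"""End-to-end pipeline: trial → screen → adjust → ANOVA → rank → select.

Each stage writes one plain CSV shaped like the corresponding report
table, and the whole run is deterministic under a fixed seed and
configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .adjust import CovariateAdjuster
from .anova import HeritabilityAnova
from .elements import default_registry
from .ranking import phenotypic_cv, suitability_table
from .screen import CorrelationScreen, ScreenResult, tally_significant
from .selection import SuperiorSelector, group_summaries, two_year_genotype_means
from .simulate import SimConfig, default_config, simulate_trial
from .trial import aggregate_genotype_year_means, read_phenotype_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_all"]


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    input_path: str | None = None  # replicate-level CSV; None → simulate
    sim: SimConfig | None = None
    alpha: float = 0.05
    h2_basis: str = "entry_mean"
    k: int = 15
    m: int = 3
    check_id: str | None = None
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass
class PipelineResult:
    records: pd.DataFrame
    adjusted: pd.DataFrame
    screens: dict[int, ScreenResult]
    models: pd.DataFrame
    h2: pd.DataFrame
    suitability: pd.DataFrame
    groups: pd.DataFrame
    selection: pd.DataFrame
    files: list[Path] = field(default_factory=list)


def _screen_frame(res: ScreenResult) -> pd.DataFrame:
    """Flatten one year's screen into a long CSV-friendly table."""
    rows = []
    for element in res.r.index:
        for cov in res.r.columns:
            rows.append(
                {
                    "year": res.year,
                    "element": element,
                    "covariate": cov,
                    "r": res.r.loc[element, cov],
                    "p": res.p.loc[element, cov],
                    "significant": bool(res.flags.loc[element, cov]),
                    "n": int(res.n_used.loc[element, cov]),
                }
            )
    return pd.DataFrame(rows)


def run_all(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the report CSV bundle to ``out_dir``."""
    registry = default_registry()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_path is not None:
        logger.info("stage ingest: %s", config.input_path)
        records = read_phenotype_table(config.input_path, registry)
    else:
        sim = config.sim or default_config(seed=config.seed)
        sim = sim.with_seed(config.seed)
        logger.info(
            "stage simulate: %d genotypes × %d years × %d reps, seed %d",
            sim.n_genotypes,
            sim.years,
            sim.reps,
            sim.seed,
        )
        records, _ = simulate_trial(sim)

    # screen
    means = aggregate_genotype_year_means(records, registry)
    years = sorted(means["year"].unique())
    screens: dict[int, ScreenResult] = {}
    screen_frames = []
    for yr in years:
        res = CorrelationScreen(alpha=config.alpha).fit(
            means[means["year"] == yr]
        ).result_
        screens[yr] = res
        screen_frames.append(_screen_frame(res))
        logger.info(
            "stage screen %s: %d significant cells", yr, int(res.flags.sum().sum())
        )

    # adjust
    adjuster = CovariateAdjuster(alpha=config.alpha)
    adjusted = adjuster.fit_transform(records, screens=screens)
    models = adjuster.model_table()
    logger.info(
        "stage adjust: %d element-year models, %d non-identity",
        len(adjuster.models_),
        sum(not m.is_identity for m in adjuster.models_.values()),
    )

    # ANOVA / heritability on original and adjusted data
    h2_orig = (
        HeritabilityAnova(scope="both", basis=config.h2_basis)
        .fit(records)
        .results_.assign(data="original")
    )
    h2_adj = (
        HeritabilityAnova(scope="both", basis=config.h2_basis)
        .fit(adjusted)
        .results_.assign(data="adjusted")
    )
    h2 = pd.concat([h2_orig, h2_adj], ignore_index=True)

    # suitability index: CV of two-year means, tally, factorial H² (original)
    two_year = two_year_genotype_means(records, registry).set_index("genotype")
    cv = pd.Series(
        {e: phenotypic_cv(two_year[e]) for e in registry.codes}, name="cv_percent"
    )
    tally = tally_significant(list(screens.values()))
    counts = tally.element_counts.reindex(registry.codes)
    h2_fact = (
        h2_orig[h2_orig["scope"] == "factorial"]
        .set_index("trait")["H2"]
        .reindex(registry.codes)
    )
    suitability = suitability_table(cv, counts, h2_fact)

    # groups and selection
    check_id = config.check_id
    if check_id is None:
        checks = records.loc[records["group"] == "check", "genotype"]
        if checks.empty:
            raise ValueError("no check genotype found and none configured")
        check_id = sorted(checks.unique())[0]
    groups = group_summaries(records, adjusted, check_id, registry)
    selector = SuperiorSelector(k=config.k, m=config.m).fit(adjusted)
    logger.info(
        "stage select: %d genotypes favorable for >= %d elements",
        len(selector.report_),
        config.m,
    )

    result = PipelineResult(
        records=records,
        adjusted=adjusted,
        screens=screens,
        models=models,
        h2=h2,
        suitability=suitability,
        groups=groups,
        selection=selector.report_,
    )

    files = []
    for yr, frame in zip(years, screen_frames):
        path = out / f"screen_{yr}.csv"
        frame.to_csv(path, index=False)
        files.append(path)
    for name, frame in [
        ("models.csv", models),
        ("adjusted.csv", adjusted),
        ("h2.csv", h2),
        ("suitability.csv", suitability.reset_index(names="element")),
        ("groups.csv", groups),
        ("selection.csv", selector.report_),
    ]:
        path = out / name
        frame.to_csv(path, index=False)
        files.append(path)
    log_path = out / "run_log.json"
    log_path.write_text(
        json.dumps(
            {
                "version": __version__,
                "seed": config.seed,
                "alpha": config.alpha,
                "h2_basis": config.h2_basis,
                "k": config.k,
                "m": config.m,
                "check_id": check_id,
                "input": config.input_path or "simulated",
                "years": [int(y) for y in years],
            },
            indent=2,
        )
    )
    files.append(log_path)
    result.files = files
    return result
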