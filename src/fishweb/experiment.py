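"""Three-model-type ensemble experiment and its summary statistics.

For each generated web the same structure, parameter draws and initial
conditions feed three model variants: (1) the *original* ATN model with
one node per species, (2) the *unlinked* model where each fish species
is split into four life-history stages treated as independent nodes,
and (3) the *linked* model where the annual Leslie step couples the
stages through growth and reproduction.  Runs last 300 years (a
200-year burn-in whose statistics are discarded plus a 100-year
analysis window).

Acceptance filters: the *preliminary* filter keeps webs where fish
survived in at least one variant; the *stringent* filter keeps webs
where at least one fish species persisted in every variant.  Stability
is summarised by the coefficient of variation (CV) of annual biomass
series, and per-species mean/CV of biomass are regressed on asymptotic
(adult) body mass by OLS after removing outliers (mass > 1e10 or
CV > 800%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import webgen
from .lifehistory import (
    Community,
    EmptyStageDiet,
    community_from_web,
    insert_stages,
)
from .trophic import SingularTrophicSystem, TrophicAnnotation, annotate
from .dynamics import (
    MODEL_TYPES,
    DynamicsParams,
    StateTrajectory,
    draw_growth_rates,
    draw_initial_conditions,
    initial_biomass,
    run_simulation,
)

__all__ = [
    "EnsembleConfig",
    "EnsembleResult",
    "build_model_variants",
    "generate_study_web",
    "fish_survival",
    "stabilization_check",
    "cv",
    "size_stability_regression",
    "size_ordering_fraction",
    "run_ensemble",
]

logger = logging.getLogger(__name__)

BLOWUP_CEILING = 1e10
OUTLIER_MASS = 1e10
OUTLIER_CV_PERCENT = 800.0


@dataclass
class EnsembleConfig:
    """Study conditions for one ensemble."""

    n_webs: int = 500
    years: int = 300
    burn_in: int = 200
    S: int = 30
    C: float = 0.15
    Z: float = 100.0
    seed: int = 0
    model_types: tuple[str, ...] = MODEL_TYPES
    connectance_tol: float = webgen.DEFAULT_CONNECTANCE_TOL
    max_web_attempts: int = 200
    blowup_ceiling: float = BLOWUP_CEILING
    allow_conspecific_predation: bool = True
    reject_empty_diet: bool = True
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)

    @property
    def analysis_years(self) -> int:
        return self.years - self.burn_in


@dataclass
class EnsembleResult:
    """Ensemble outputs: per-run table, per-surviving-fish table,
    survivor frequencies, regressions and the headline fractions."""

    runs: pd.DataFrame
    species: pd.DataFrame
    survivor_freq: pd.DataFrame
    regressions: pd.DataFrame | None
    headline: dict
    config: EnsembleConfig


def build_model_variants(
    web: webgen.NicheWeb,
    ann: TrophicAnnotation,
    stage_seed: int,
    **stage_kwargs,
) -> dict[str, Community]:
    """The original/unlinked/linked triple sharing one web.

    The unlinked and linked variants share the identical staged
    structure; only the annual Leslie step distinguishes them at run
    time.
    """
    staged = insert_stages(web, ann, seed=stage_seed, **stage_kwargs)
    return {
        "original": community_from_web(web, ann),
        "unlinked": staged,
        "linked": staged,
    }


def generate_study_web(
    config: EnsembleConfig, rng: np.random.Generator, stage_seed: int
) -> tuple[webgen.NicheWeb, TrophicAnnotation, dict[str, Community]]:
    """Generate a web that survives every structural gate: the niche
    validation rules, a solvable trophic system, three fish species and
    no empty stage diets.  Retries with fresh draws otherwise."""
    for attempt in range(config.max_web_attempts):
        web = webgen.generate_valid_web(
            config.S, config.C, rng, tol=config.connectance_tol
        )
        try:
            ann = annotate(web, Z=config.Z)
            variants = build_model_variants(
                web, ann, stage_seed=(stage_seed + attempt) % 2**31,
                allow_conspecific_predation=config.allow_conspecific_predation,
                reject_empty_diet=config.reject_empty_diet,
            )
        except (SingularTrophicSystem, EmptyStageDiet, ValueError) as exc:
            logger.debug("web rejected post-validation: %s", exc)
            continue
        return web, ann, variants
    raise webgen.WebGenerationError(
        f"no study-ready web in {config.max_web_attempts} attempts"
    )


def fish_survival(
    traj: StateTrajectory, community: Community, threshold: float = 1e-6
) -> tuple[dict[int, bool], int]:
    """A fish species survives if any of its nodes (its single node in
    the original model, any stage otherwise) holds at least the
    extinction-threshold biomass in the final year."""
    final = traj.year_end[-1]
    flags = {
        sp: bool((final[idx] >= threshold).any())
        for sp, idx in community.fish_nodes_of.items()
    }
    return flags, sum(flags.values())


def stabilization_check(
    traj: StateTrajectory,
    community: Community,
    burn_in: int,
    threshold: float = 1e-6,
    ceiling: float = BLOWUP_CEILING,
) -> bool:
    """Operational fish-biomass stabilization: the run completed the
    burn-in without solver failure, total fish biomass at the end of
    burn-in is at least the extinction threshold, and no node exceeded
    the blow-up ceiling during burn-in."""
    if traj.failed and (traj.fail_year is None or traj.fail_year < burn_in):
        return False
    fish_nodes = np.concatenate(
        [idx for idx in community.fish_nodes_of.values()]
    )
    fish_total = traj.year_end[burn_in - 1, fish_nodes].sum()
    if fish_total < threshold:
        return False
    if traj.year_end[:burn_in].max() > ceiling:
        return False
    if traj.annual_mean[:burn_in].max() > ceiling:
        return False
    return True


def cv(series: np.ndarray) -> float:
    """Coefficient of variation: sample standard deviation over mean.

    Returns NaN for degenerate (all-zero / sub-2-point) series, which
    downstream tables exclude.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        return float("nan")
    mean = series.mean()
    if mean == 0:
        return float("nan")
    return float(series.std(ddof=1) / mean)


def size_stability_regression(
    species_table: pd.DataFrame,
    mass_col: str = "mass_adult",
    outlier_mass: float = OUTLIER_MASS,
    outlier_cv: float = OUTLIER_CV_PERCENT,
) -> pd.DataFrame:
    """OLS of per-species mean and CV of biomass on adult mass.

    Four responses — mean ecosystem biomass, mean fish-species biomass,
    CV of ecosystem biomass, CV of fish-species biomass (CVs in %) —
    each regressed on asymptotic adult mass after dropping rows with
    mass > 1e10 and, for CV responses, CV > 800%.  Reports slope, t,
    df = n - 2 and the two-sided p per response.
    """
    responses = {
        "mean_ecosystem_biomass": "mean_eco",
        "mean_fish_biomass": "mean_species",
        "cv_ecosystem_biomass": "cv_eco_percent",
        "cv_fish_biomass": "cv_species_percent",
    }
    rows = []
    base = species_table[species_table[mass_col] <= outlier_mass]
    for label, col in responses.items():
        table = base.dropna(subset=[col, mass_col])
        if col.startswith("cv_"):
            table = table[table[col] <= outlier_cv]
        n = len(table)
        if n < 3:
            rows.append({"response": label, "n": n, "slope": np.nan,
                         "t": np.nan, "df": max(n - 2, 0), "p": np.nan})
            continue
        X = sm.add_constant(table[mass_col].to_numpy())
        fit = sm.OLS(table[col].to_numpy(), X).fit()
        rows.append({
            "response": label,
            "n": n,
            "slope": float(fit.params[1]),
            "t": float(fit.tvalues[1]),
            "df": int(fit.df_resid),
            "p": float(fit.pvalues[1]),
        })
    return pd.DataFrame(rows)


def size_ordering_fraction(species_table: pd.DataFrame) -> dict:
    """Fraction of staged simulations in which the youngest stage of the
    largest surviving fish species is lighter than the oldest stage of
    the smallest surviving species.

    Runs with fewer than two surviving fish species have no such
    comparison and are excluded from the conditional denominator; the
    fraction over all accepted staged runs is reported alongside.
    """
    qualifying = 0
    ordered = 0
    total_runs = 0
    for (_, _), group in species_table.groupby(["web_id", "model_type"]):
        total_runs += 1
        if len(group) < 2:
            continue
        qualifying += 1
        largest = group.loc[group["mass_adult"].idxmax()]
        smallest = group.loc[group["mass_adult"].idxmin()]
        if largest["mass_stage0"] < smallest["mass_stage3"]:
            ordered += 1
    return {
        "n_qualifying": qualifying,
        "n_ordered": ordered,
        "fraction_conditional": ordered / qualifying if qualifying else float("nan"),
        "fraction_all_accepted": ordered / total_runs if total_runs else float("nan"),
    }


def _run_one_web(
    config: EnsembleConfig, web_id: int
) -> tuple[list[dict], list[dict]]:
    """Generate web `web_id`, run all model types, return per-run and
    per-fish-species records."""
    seed = config.seed
    rng_struct = np.random.default_rng([seed, web_id, 0])
    stage_seed = int(np.random.default_rng([seed, web_id, 1]).integers(2**31))
    web, ann, variants = generate_study_web(config, rng_struct, stage_seed)

    rng_params = np.random.default_rng([seed, web_id, 2])
    n_auto = int((ann.guild == "autotroph").sum())
    r_auto = draw_growth_rates(n_auto, rng_params, config.dynamics)
    rng_init = np.random.default_rng([seed, web_id, 3])
    species_draws = draw_initial_conditions(config.S, rng_init, config.dynamics)

    run_rows = []
    species_rows = []
    for model_type in config.model_types:
        community = variants[model_type]
        B0 = initial_biomass(community, species_draws)
        traj = run_simulation(
            community, model_type, config.years, config.dynamics, B0, r_auto
        )
        flags, n_surv = fish_survival(
            traj, community, config.dynamics.extinction_threshold
        )
        stable = stabilization_check(
            traj, community, config.burn_in,
            config.dynamics.extinction_threshold, config.blowup_ceiling,
        )
        analysis = traj.annual_mean[config.burn_in:]
        eco_series = analysis.sum(axis=1)
        fish_nodes = np.concatenate(list(community.fish_nodes_of.values()))
        fish_series = analysis[:, fish_nodes].sum(axis=1)
        completed = not traj.failed
        run_rows.append({
            "web_id": web_id,
            "model_type": model_type,
            "completed": completed,
            "stabilized": stable,
            "n_surviving_fish": n_surv if completed else 0,
            "mean_eco": eco_series.mean() if completed else np.nan,
            "cv_eco_percent": 100 * cv(eco_series) if completed else np.nan,
            "mean_fish": fish_series.mean() if completed else np.nan,
            "cv_fish_percent": 100 * cv(fish_series) if completed else np.nan,
            "n_events": len(traj.events),
        })
        if not completed:
            continue
        for sp, survived in flags.items():
            if not survived:
                continue
            idx = community.fish_nodes_of[sp]
            sp_series = analysis[:, idx].sum(axis=1)
            struct = community.stage_structures.get(sp)
            species_rows.append({
                "web_id": web_id,
                "model_type": model_type,
                "species": sp,
                "mass_adult": float(ann.M[sp]),
                "W_inf": struct.W_inf if struct else float(ann.M[sp]) / 0.9,
                "mass_stage0": struct.W[0] if struct else np.nan,
                "mass_stage3": struct.W[-1] if struct else float(ann.M[sp]),
                "mean_species": sp_series.mean(),
                "cv_species_percent": 100 * cv(sp_series),
                "mean_eco": eco_series.mean(),
                "cv_eco_percent": 100 * cv(eco_series),
            })
    return run_rows, species_rows


def run_ensemble(config: EnsembleConfig, progress: bool = False) -> EnsembleResult:
    """Run the full ensemble and assemble every summary table.

    Headline fractions reported:

    - ``stabilization_fraction``: webs whose fish biomass stabilized in
      at least one model variant (preliminary criterion).
    - ``stringent_fraction``: webs with at least one surviving fish
      species in every model variant.
    - ``size_ordering_fraction``: staged runs (within the preliminary
      set) whose surviving fish species' stage-weight ranges overlap in
      the young-of-the-largest vs oldest-of-the-smallest sense.
    """
    all_runs: list[dict] = []
    all_species: list[dict] = []
    for web_id in range(config.n_webs):
        if progress:
            logger.info("web %d / %d", web_id + 1, config.n_webs)
        run_rows, species_rows = _run_one_web(config, web_id)
        all_runs.extend(run_rows)
        all_species.extend(species_rows)

    runs = pd.DataFrame(all_runs)
    species = pd.DataFrame(all_species)

    per_web = runs.groupby("web_id")
    any_stable = per_web["stabilized"].any()
    all_fish_persist = per_web.apply(
        lambda g: bool((g["n_surviving_fish"] >= 1).all()), include_groups=False
    )
    preliminary = per_web["n_surviving_fish"].max() >= 1
    accepted_webs = set(preliminary[preliminary].index)
    stringent_webs = set(all_fish_persist[all_fish_persist].index)

    acc_runs = runs[runs["web_id"].isin(accepted_webs)]
    survivor_freq = (
        acc_runs.pivot_table(
            index="model_type", columns="n_surviving_fish",
            values="web_id", aggfunc="count", fill_value=0,
        )
        .reindex(columns=range(4), fill_value=0)
        .reindex(list(config.model_types))
        .fillna(0)
        .astype(int)
    )

    staged_species = species[
        species["model_type"].isin(("unlinked", "linked"))
        & species["web_id"].isin(accepted_webs)
    ]
    ordering = size_ordering_fraction(staged_species) if len(staged_species) else {
        "n_qualifying": 0, "n_ordered": 0,
        "fraction_conditional": float("nan"),
        "fraction_all_accepted": float("nan"),
    }

    reg_table = species[
        (species["model_type"] == "linked")
        & species["web_id"].isin(stringent_webs)
    ]
    regressions = (
        size_stability_regression(reg_table) if len(reg_table) >= 3 else None
    )

    n_webs = config.n_webs
    headline = {
        "n_webs": n_webs,
        "n_accepted_preliminary": len(accepted_webs),
        "n_accepted_stringent": len(stringent_webs),
        "stabilization_fraction": float(any_stable.mean()) if n_webs else np.nan,
        "preliminary_fraction": len(accepted_webs) / n_webs if n_webs else np.nan,
        "stringent_fraction": len(stringent_webs) / n_webs if n_webs else np.nan,
        "size_ordering_fraction": ordering["fraction_conditional"],
        "size_ordering_fraction_all_accepted": ordering["fraction_all_accepted"],
        "size_ordering_n_qualifying": ordering["n_qualifying"],
    }
    return EnsembleResult(
        runs=runs, species=species, survivor_freq=survivor_freq,
        regressions=regressions, headline=headline, config=config,
    )
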