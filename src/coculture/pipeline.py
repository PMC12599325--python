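"""End-to-end pipeline: from a culture table and environment definitions to
every report the analysis produces, with the run's FDR and seed recorded in
a manifest for reproducibility."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .calls import adjust_and_call, classify_interactions, unidirectional_tests
from .core import (
    Environment,
    PipelineConfig,
    ValidationError,
    apply_detection_floor,
    mono_summaries,
    summarize_yields,
)
from .effects import average_theta_by_env, average_theta_by_pair, effect_table
from .growers import (
    class_enrichment,
    grower_fraction_by_carbon_number,
    growth_calls,
    stratify_interactions,
)
from .mixing import mixing_report
from .stats import (
    chisq_mc,
    class_count_table,
    default_category_partition,
    pairwise_permanova,
    spearman_trend,
    species_rank_enrichment,
    subseed,
)


@dataclass
class PipelineResult:
    """Bundle of report tables; see the attribute names for contents."""

    observations: pd.DataFrame
    yields: pd.DataFrame
    unidirectional: pd.DataFrame
    interactions: pd.DataFrame  # calls + class + E + theta per (pair, env)
    theta_by_env: pd.DataFrame
    theta_by_pair: pd.DataFrame
    mixing: pd.DataFrame
    mixing_fractions: pd.DataFrame
    growth_calls: pd.DataFrame
    grower_fractions: pd.DataFrame
    strata: pd.DataFrame
    enrichment: pd.DataFrame | None
    chisq: pd.DataFrame
    trend: pd.DataFrame
    permanova: pd.DataFrame | None
    species_enrichment: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            name: tab
            for name, tab in vars(self).items()
            if isinstance(tab, pd.DataFrame)
        }


def _stage(name: str):
    """Tag stage failures with the stage identity."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_full_pipeline(
    culture: pd.DataFrame,
    environments: dict[str, Environment],
    config: PipelineConfig | None = None,
    category_partition: dict[str, str] | None = None,
) -> PipelineResult:
    """Run every analysis stage on a validated culture table.

    Community statistics that depend on biochemical categories (PERMANOVA,
    and the packaged default partition) are skipped with a warning when the
    single-source environments are not covered by the partition."""
    config = config or PipelineConfig()
    unknown_envs = set(culture["env"]) - set(environments)
    if unknown_envs:
        raise ValidationError(f"culture table references unknown environments {sorted(unknown_envs)}")

    with _stage("flooring"):
        floored = apply_detection_floor(culture, config.detection_floor)
    with _stage("yield summaries"):
        yields = summarize_yields(floored)
    with _stage("unidirectional calls"):
        tests = adjust_and_call(unidirectional_tests(floored), config.fdr)
        classes = classify_interactions(tests)
    with _stage("interaction types"):
        effects = effect_table(yields, config.detection_floor)
        interactions = classes.merge(effects, on=["species_i", "species_j", "env"])
        single_envs = [e.env_id for e in environments.values() if e.n_sources == 1]
        theta_by_env = average_theta_by_env(effects)
        theta_by_pair = (
            average_theta_by_pair(effects, single_envs) if single_envs else pd.DataFrame()
        )
    with _stage("mixing analysis"):
        mixing, mixing_fracs = mixing_report(
            floored, environments, fdr=config.fdr, welch=config.welch
        )
    with _stage("grower stratification"):
        mono = mono_summaries(yields)
        calls = growth_calls(mono, config.detection_floor, axis=config.cluster_axis)
        fractions = grower_fraction_by_carbon_number(calls, environments)
        strata = stratify_interactions(classes, calls, environments)
        enrichment = None
        try:
            enrichment = class_enrichment(strata, fdr=config.fdr, bins=config.enrichment_bins)
        except ValidationError as exc:
            warnings.warn(f"class enrichment skipped: {exc}", stacklevel=2)
    with _stage("community statistics"):
        single = interactions.loc[interactions["env"].isin(single_envs)]
        chisq_rows = []
        for by, frame in (("carbon_source", single), ("pair", interactions)):
            tab = class_count_table(frame, by="env" if by == "carbon_source" else "pair")
            if tab.shape[0] >= 2 and tab.shape[1] >= 2:
                stat, p = chisq_mc(
                    tab, iters=config.chisq_iterations, seed=subseed(config.seed, "chisq", by)
                )
                chisq_rows.append(
                    {"grouping": by, "statistic": stat, "p": p,
                     "iterations": config.chisq_iterations}
                )
        chisq = pd.DataFrame(chisq_rows)

        n_sources = interactions["env"].map(lambda e: environments[e].n_sources)
        with_carbon = n_sources > 0
        if int(with_carbon.sum()) >= 3:
            rho, p = spearman_trend(
                n_sources[with_carbon].to_numpy(),
                interactions.loc[with_carbon, "theta_deg"].to_numpy(),
            )
        else:
            rho = p = float("nan")
        trend = pd.DataFrame(
            [{"x": "n_sources", "y": "theta_deg", "rho": rho, "p": p,
              "n": int(with_carbon.sum())}]
        )

        permanova_res = None
        species_enr = None
        partition = category_partition
        if partition is None:
            default = default_category_partition()
            if set(single_envs) <= set(default):
                partition = default
        if partition is not None and single_envs:
            theta_matrix = (
                interactions.loc[interactions["env"].isin(single_envs)]
                .assign(pair=lambda d: d["species_i"] + "-" + d["species_j"])
                .pivot(index="env", columns="pair", values="theta_deg")
            )
            permanova_res = pairwise_permanova(
                theta_matrix,
                partition,
                perms=config.permanova_permutations,
                seed=config.seed,
                fdr=config.fdr,
            )
        if len(theta_by_pair):
            species_enr = species_rank_enrichment(
                theta_by_pair.rename(columns={"theta_bar": "theta"}),
                perms=config.enrichment_permutations,
                seed=config.seed,
                fdr=config.fdr,
            )

    manifest = {
        "coculture_version": __version__,
        "config": config.to_dict(),
        "n_species": int(
            pd.concat([culture["focal"], culture.loc[culture["partner"] != "", "partner"]])
            .nunique()
        ),
        "n_environments": len(environments),
        "n_interactions": int(len(interactions)),
        "welch": config.welch,
    }
    return PipelineResult(
        observations=floored,
        yields=yields,
        unidirectional=tests,
        interactions=interactions,
        theta_by_env=theta_by_env,
        theta_by_pair=theta_by_pair,
        mixing=mixing,
        mixing_fractions=mixing_fracs,
        growth_calls=calls,
        grower_fractions=fractions,
        strata=strata,
        enrichment=enrichment,
        chisq=chisq,
        trend=trend,
        permanova=permanova_res,
        species_enrichment=species_enr,
        manifest=manifest,
    )


def write_report(result: PipelineResult, out_dir: str | Path) -> None:
    """Write every table as tidy CSV plus a JSON run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, tab in result.tables().items():
        tab.to_csv(out / f"{name}.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
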