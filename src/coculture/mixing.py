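"""Mixing-effect analysis: does growth on a carbon-source mixture match,
exceed, or fall below the average growth on its components?

Group 1 is the actual sample: the three observed log10 yields of a species
in a mixture environment.  Group 2 is a constructed three-point pseudo-sample
{m + s, m, m - s} whose mean m is the average (over components) of the mean
log10 single-source yields and whose unbiased standard deviation s is the
root of the average unbiased log10 variance -- it encodes the expected
"no mixing effect" population exactly.  The two samples are compared with a
two-tailed two-sample t-test, BH-corrected across all (species, mixture)
comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import Environment, ValidationError, mono_summaries

VERDICTS = ("higher", "not_different", "lower")


def build_group2(mean_log10s: np.ndarray, var_log10s: np.ndarray) -> np.ndarray:
    """Construct the pseudo-sample {m + s, m, m - s} from the component
    single-source summaries.  Its sample mean is m exactly and its unbiased
    standard deviation is s exactly."""
    mean_log10s = np.asarray(mean_log10s, dtype=float)
    var_log10s = np.asarray(var_log10s, dtype=float)
    if mean_log10s.size == 0:
        raise ValidationError("no component summaries")
    if np.isnan(var_log10s).any():
        raise ValidationError("component variance missing")
    m = mean_log10s.mean()
    s = np.sqrt(var_log10s.mean())
    return np.array([m + s, m, m - s])


def compare_mix(
    group1: np.ndarray, group2: np.ndarray, welch: bool = True
) -> tuple[float, int]:
    """Two-sample two-tailed t-test between the observed mixture sample and
    the constructed component pseudo-sample.

    Returns (p, direction) with direction = sign(mean(group1) - mean(group2)).
    Welch's unequal-variance form is the default; Student's pooled form is
    available.  When both samples are constant the t statistic is degenerate:
    p = 1 if the means agree, else 0.
    """
    group1 = np.asarray(group1, dtype=float)
    group2 = np.asarray(group2, dtype=float)
    if group1.size != 3 or group2.size != 3:
        raise ValidationError("both samples must have size 3")
    diff = group1.mean() - group2.mean()
    direction = int(np.sign(diff))
    if np.ptp(group1) == 0.0 and np.ptp(group2) == 0.0:
        return (1.0 if diff == 0.0 else 0.0), direction
    res = stats.ttest_ind(group1, group2, equal_var=not welch)
    return float(res.pvalue), direction


def mixing_report(
    floored: pd.DataFrame,
    environments: dict[str, Environment],
    fdr: float = 0.05,
    welch: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per (species, mixture) verdicts plus per-mixture-size fractions.

    Every mixture environment (n_sources >= 2) is compared against its
    single-source component environments.  Comparisons whose component
    environments are absent are skipped with a reason.  Returns
    (comparisons, fractions); fractions gives, per mixture size, the share of
    higher / not_different / lower verdicts and the combined
    "matched or exceeded" share.
    """
    yields = None
    mono = floored.loc[floored["partner"] == ""]
    from .core import summarize_yields

    yields = mono_summaries(summarize_yields(mono))
    summ = yields.set_index(["focal", "env"])

    source_env = {}
    for e in environments.values():
        if e.n_sources == 1:
            (src,) = e.carbon_sources
            source_env[src] = e.env_id
    mixtures = [e for e in environments.values() if e.n_sources >= 2]

    rows = []
    for env in sorted(mixtures, key=lambda e: e.env_id):
        comps = []
        missing = [s for s in sorted(env.carbon_sources) if s not in source_env]
        for species in sorted(mono["focal"].unique()):
            if missing:
                rows.append(
                    {
                        "species": species,
                        "env": env.env_id,
                        "n_components": env.n_sources,
                        "p": np.nan,
                        "direction": 0,
                        "skipped": f"missing component environments: {missing}",
                    }
                )
                continue
            try:
                g1_dens = mono.loc[
                    (mono["focal"] == species) & (mono["env"] == env.env_id), "density"
                ].to_numpy()
                comps = [summ.loc[(species, source_env[s])] for s in sorted(env.carbon_sources)]
            except KeyError:
                rows.append(
                    {
                        "species": species,
                        "env": env.env_id,
                        "n_components": env.n_sources,
                        "p": np.nan,
                        "direction": 0,
                        "skipped": "missing component summary",
                    }
                )
                continue
            if g1_dens.size == 0:
                rows.append(
                    {
                        "species": species,
                        "env": env.env_id,
                        "n_components": env.n_sources,
                        "p": np.nan,
                        "direction": 0,
                        "skipped": "no mixture observations",
                    }
                )
                continue
            group1 = np.log10(g1_dens)
            group2 = build_group2(
                np.array([c["mean_log10"] for c in comps]),
                np.array([c["var_log10"] for c in comps]),
            )
            p, direction = compare_mix(group1, group2, welch=welch)
            rows.append(
                {
                    "species": species,
                    "env": env.env_id,
                    "n_components": env.n_sources,
                    "group1_mean": group1.mean(),
                    "group2_mean": group2.mean(),
                    "p": p,
                    "direction": direction,
                    "skipped": "",
                }
            )
    comparisons = pd.DataFrame(rows)
    if len(comparisons) == 0:
        return comparisons, pd.DataFrame(
            columns=["n_components", "n", "higher", "not_different", "lower",
                     "matched_or_exceeded"]
        )

    tested = comparisons["skipped"] == ""
    q = np.full(len(comparisons), np.nan)
    if tested.any():
        q[tested.to_numpy()] = multipletests(
            comparisons.loc[tested, "p"].to_numpy(), method="fdr_bh"
        )[1]
    comparisons["q"] = q

    def verdict(row) -> str:
        if row["skipped"]:
            return ""
        if row["q"] < fdr and row["direction"] > 0:
            return "higher"
        if row["q"] < fdr and row["direction"] < 0:
            return "lower"
        return "not_different"

    comparisons["verdict"] = comparisons.apply(verdict, axis=1)

    done = comparisons.loc[tested]
    frac_rows = []
    for n, grp in done.groupby("n_components"):
        counts = grp["verdict"].value_counts()
        total = len(grp)
        fr = {v: counts.get(v, 0) / total for v in VERDICTS}
        frac_rows.append(
            {
                "n_components": int(n),
                "n": total,
                **fr,
                "matched_or_exceeded": fr["higher"] + fr["not_different"],
            }
        )
    fractions = pd.DataFrame(frac_rows)
    return comparisons, fractions
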