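"""Quantitative interaction typing: log2 effect sizes E and the interaction
type angle theta.

E is the log2 ratio of mean co-culture to mean mono-culture density for the
focal species.  The pair of effects (E_ij, E_ji) is plotted as
(min, max) on a Cartesian plane, and theta is the angle (in degrees, within
[-90, 90]) between that point and the anti-diagonal max = -min: +90 means
equal mutual facilitation, -90 equal mutual inhibition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ValidationError, canonical_pair, mono_summaries


def compute_E(mean_co: float, mean_mono: float) -> float:
    """log2 ratio of co-culture to mono-culture mean density."""
    if mean_co <= 0 or mean_mono <= 0:
        raise ValidationError("densities must be positive (flooring violated)")
    return float(np.log2(mean_co / mean_mono))


def compute_theta(e_ij: float, e_ji: float, at_floor: bool = False) -> float:
    """Interaction type angle in degrees.

    theta = arctan((E_ij + E_ji) / |E_ij - E_ji|) when the effects differ,
    0 when both are 0 or when all four underlying means sat at the detection
    floor.  Equal nonzero effects make the denominator vanish; the continuity
    limit sign(E_ij + E_ji) * 90 is used (see ``equal_nonzero`` flag in
    :func:`effect_table`).
    """
    if not (np.isfinite(e_ij) and np.isfinite(e_ji)):
        raise ValidationError("effect values must be finite")
    if at_floor:
        return 0.0
    if e_ij == e_ji:
        if e_ij == 0.0:
            return 0.0
        return 90.0 if e_ij > 0 else -90.0
    return float(np.degrees(np.arctan((e_ij + e_ji) / abs(e_ij - e_ji))))


def effect_table(yields: pd.DataFrame, floor: float) -> pd.DataFrame:
    """Per (pair, environment) effect sizes and interaction type.

    ``yields`` is the output of :func:`coculture.core.summarize_yields` on a
    floored culture table.  ``at_floor`` is true when all four means (two
    mono, two co) equal the floor exactly, in which case theta is set to 0.
    """
    mono = mono_summaries(yields).set_index(["focal", "env"])["mean_density"]
    co = yields.loc[yields["partner"] != ""].set_index(["focal", "partner", "env"])[
        "mean_density"
    ]
    rows = []
    seen = set()
    for (focal, partner, env) in co.index:
        i, j = canonical_pair(focal, partner)
        if (i, j, env) in seen:
            continue
        seen.add((i, j, env))
        try:
            mean_co_ij = float(co.loc[(i, j, env)])
            mean_co_ji = float(co.loc[(j, i, env)])
            mean_mono_i = float(mono.loc[(i, env)])
            mean_mono_j = float(mono.loc[(j, env)])
        except KeyError as exc:
            raise ValidationError(f"incomplete cultures for pair ({i}, {j}) in {env}") from exc
        e_ij = compute_E(mean_co_ij, mean_mono_i)
        e_ji = compute_E(mean_co_ji, mean_mono_j)
        at_floor = all(
            m == floor for m in (mean_co_ij, mean_co_ji, mean_mono_i, mean_mono_j)
        )
        theta = compute_theta(e_ij, e_ji, at_floor)
        rows.append(
            {
                "species_i": i,
                "species_j": j,
                "env": env,
                "E_ij": e_ij,
                "E_ji": e_ji,
                "coord_min": min(e_ij, e_ji),
                "coord_max": max(e_ij, e_ji),
                "theta_deg": theta,
                "at_floor": at_floor,
                "equal_nonzero": (not at_floor) and e_ij == e_ji and e_ij != 0.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species_i",
            "species_j",
            "env",
            "E_ij",
            "E_ji",
            "coord_min",
            "coord_max",
            "theta_deg",
            "at_floor",
            "equal_nonzero",
        ],
    )


def average_theta_by_env(effects: pd.DataFrame) -> pd.DataFrame:
    """Mean theta over all pairs present in each environment (theta-bar_m)."""
    if len(effects) == 0:
        raise ValidationError("no effect records")
    out = (
        effects.groupby("env")["theta_deg"]
        .agg(theta_bar="mean", n_pairs="count")
        .reset_index()
    )
    return out


def average_theta_by_pair(
    effects: pd.DataFrame, single_source_envs: list[str]
) -> pd.DataFrame:
    """Mean theta per pair over the single-carbon-source environments
    (theta-bar^{i,j}); by definition restricted to those environments."""
    sub = effects.loc[effects["env"].isin(single_source_envs)]
    if len(sub) == 0:
        raise ValidationError("no effect records in single-source environments")
    out = (
        sub.groupby(["species_i", "species_j"])["theta_deg"]
        .agg(theta_bar="mean", n_envs="count")
        .reset_index()
    )
    return out
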