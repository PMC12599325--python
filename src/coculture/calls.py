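"""Unidirectional effect testing and six-class interaction classification.

For every focal species in co-culture, the three replicate ratios of its
co-culture density to its mean mono-culture density are tested against 1
with a one-sample two-sided t-test.  After Benjamini-Hochberg correction
across every unidirectional test in the run, each direction is called
facilitated (+), unaffected (0) or inhibited (-), and the unordered pair of
calls determines one of six interaction classes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ValidationError, canonical_pair

CALLS = ("+", "0", "-")

#: Six-way classification from the unordered pair of unidirectional calls.
CLASS_FROM_CALLS = {
    frozenset({"+"}): "mutualism",
    frozenset({"+", "0"}): "commensalism",
    frozenset({"+", "-"}): "exploitation",
    frozenset({"0"}): "neutralism",
    frozenset({"-", "0"}): "amensalism",
    frozenset({"-"}): "competition",
}

INTERACTION_CLASSES = (
    "competition",
    "amensalism",
    "exploitation",
    "neutralism",
    "commensalism",
    "mutualism",
)

#: Aggregates used in community summaries: synergistic = both facilitative
#: classes; competitive = both inhibitory classes.
SYNERGISTIC_CLASSES = frozenset({"mutualism", "commensalism"})
COMPETITIVE_CLASSES = frozenset({"competition", "amensalism"})


def compute_ratios(co_reps: np.ndarray, mono_mean: float) -> np.ndarray:
    """Replicate co-culture densities divided by the mono-culture mean."""
    if mono_mean <= 0:
        raise ValidationError("mono-culture mean must be positive (flooring violated)")
    return np.asarray(co_reps, dtype=float) / mono_mean


def test_unidirectional(ratios: np.ndarray) -> tuple[float, float]:
    """One-sample two-sided t-test of the raw ratios against 1.

    Returns (mean ratio, p).  A zero-variance sample is degenerate for the
    t statistic; by convention p = 1 when the (constant) mean equals 1 and
    p = 0 otherwise, which floored constant triplicates can produce.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size < 2:
        raise ValidationError("need at least 2 ratios for a t-test")
    mean = float(ratios.mean())
    if np.ptp(ratios) == 0.0:
        return mean, (1.0 if mean == 1.0 else 0.0)
    res = stats.ttest_1samp(ratios, popmean=1.0)
    return mean, float(res.pvalue)


def call_from(q: float, mean_ratio: float, fdr: float) -> str:
    if q < fdr and mean_ratio > 1:
        return "+"
    if q < fdr and mean_ratio < 1:
        return "-"
    return "0"


def classify_pair(call_ij: str, call_ji: str) -> str:
    """Map an unordered pair of unidirectional calls to one of the six
    interaction classes (order-insensitive)."""
    for c in (call_ij, call_ji):
        if c not in CALLS:
            raise ValidationError(f"invalid call symbol {c!r}")
    return CLASS_FROM_CALLS[frozenset({call_ij, call_ji})]


def unidirectional_tests(floored: pd.DataFrame) -> pd.DataFrame:
    """One row per (affected, partner, env): replicate ratios, their mean and
    the raw p-value.  ``floored`` is a floored culture table containing both
    the co-cultures and the matching mono-cultures."""
    mono = (
        floored.loc[floored["partner"] == ""]
        .groupby(["focal", "env"])["density"]
        .mean()
    )
    rows = []
    co = floored.loc[floored["partner"] != ""]
    for (focal, partner, env), grp in co.groupby(["focal", "partner", "env"], sort=True):
        try:
            mono_mean = float(mono.loc[(focal, env)])
        except KeyError:
            raise ValidationError(
                f"no mono-culture for focal {focal!r} in environment {env!r}"
            ) from None
        ratios = compute_ratios(grp["density"].to_numpy(), mono_mean)
        mean_ratio, p = test_unidirectional(ratios)
        rows.append(
            {
                "affected": focal,
                "partner": partner,
                "env": env,
                "n_reps": len(ratios),
                "mean_ratio": mean_ratio,
                "p": p,
            }
        )
    return pd.DataFrame(
        rows, columns=["affected", "partner", "env", "n_reps", "mean_ratio", "p"]
    )


def adjust_and_call(tests: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up across the whole family of unidirectional
    tests, then assign +/0/- calls."""
    out = tests.copy()
    if len(out) == 0:
        out["q"] = pd.Series(dtype=float)
        out["call"] = pd.Series(dtype=str)
        return out
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["call"] = [
        call_from(q, m, fdr) for q, m in zip(out["q"], out["mean_ratio"])
    ]
    return out


def classify_interactions(calls: pd.DataFrame) -> pd.DataFrame:
    """Join the two directions of each pair into one row per (pair, env) with
    both calls, both q-values and the six-way class."""
    indexed = calls.set_index(["affected", "partner", "env"])
    rows = []
    seen = set()
    for (affected, partner, env) in indexed.index:
        i, j = canonical_pair(affected, partner)
        key = (i, j, env)
        if key in seen:
            continue
        seen.add(key)
        try:
            fwd = indexed.loc[(i, j, env)]
            rev = indexed.loc[(j, i, env)]
        except KeyError as exc:
            raise ValidationError(f"missing direction for pair ({i}, {j}) in {env}") from exc
        rows.append(
            {
                "species_i": i,
                "species_j": j,
                "env": env,
                "call_ij": fwd["call"],
                "call_ji": rev["call"],
                "q_ij": fwd["q"],
                "q_ji": rev["q"],
                "interaction_class": classify_pair(fwd["call"], rev["call"]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species_i",
            "species_j",
            "env",
            "call_ij",
            "call_ji",
            "q_ij",
            "q_ji",
            "interaction_class",
        ],
    )
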