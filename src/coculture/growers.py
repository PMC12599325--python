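"""Grower/non-grower stratification and class enrichment.

Mono-culture mean log10 yields of one species across its environments fall
into two well-separated clusters: environments supporting substantial growth
("growers") and environments where the species stays near the detection
floor ("non-growers").  The split is the two-cluster partition minimising
Ward's criterion (total within-cluster sum of squares).  For one-dimensional
data the optimal two-partition is contiguous in sorted order, so it is
computed exactly by scanning the n-1 contiguous splits -- greedy
agglomerative merging can return a suboptimal top split and is deliberately
not used.

Interactions are then stratified by whether both members of the pair are
growers in that environment, and class enrichment within each stratum is
assessed with one-sided hypergeometric tests against the pooled table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import Environment, ValidationError

GROWER, NON_GROWER = "grower", "non_grower"

#: Minimum separation (log10 units) between the two cluster means for the
#: split to be considered real; below it all points get one label.
MIN_CLUSTER_GAP = 0.5


def ward_two_cluster_split(values: np.ndarray) -> np.ndarray:
    """Exact two-cluster partition of 1-D data under Ward's criterion.

    Returns a boolean mask, True for members of the upper (higher-mean)
    cluster.  The optimum over all bipartitions is attained by a contiguous
    split of the sorted values, found by minimising the total within-cluster
    sum of squares over the n-1 split points (prefix-sum scan, O(n))."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValidationError("need at least 2 values to cluster")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    cs = np.cumsum(xs)
    cs2 = np.cumsum(xs**2)
    k = np.arange(1, n)  # lower-cluster sizes
    sse_lo = cs2[:-1] - cs[:-1] ** 2 / k
    sse_hi = (cs2[-1] - cs2[:-1]) - (cs[-1] - cs[:-1]) ** 2 / (n - k)
    cut = int(np.argmin(sse_lo + sse_hi)) + 1
    upper = np.zeros(n, dtype=bool)
    upper[order[cut:]] = True
    return upper


def ward_growers(values: np.ndarray, floor: float) -> np.ndarray:
    """Label 1-D mean log10 yields as grower / non_grower.

    All values at the floor skip clustering (all non-growers).  When the two
    cluster means are closer than ``MIN_CLUSTER_GAP`` the data are considered
    unimodal and every point gets one label, chosen by comparing the grand
    mean against log10(floor) + MIN_CLUSTER_GAP."""
    x = np.asarray(values, dtype=float)
    log_floor = np.log10(floor)
    if np.all(x <= log_floor + 1e-12):
        return np.array([NON_GROWER] * x.size)
    upper = ward_two_cluster_split(x)
    gap = x[upper].mean() - x[~upper].mean()
    if gap < MIN_CLUSTER_GAP:
        label = GROWER if x.mean() >= log_floor + MIN_CLUSTER_GAP else NON_GROWER
        return np.array([label] * x.size)
    return np.where(upper, GROWER, NON_GROWER)


def growth_calls(
    mono_yields: pd.DataFrame, floor: float, axis: str = "species"
) -> pd.DataFrame:
    """Grower/non-grower call per (species, environment).

    ``mono_yields`` holds mono-culture summaries (focal, env, mean_log10).
    ``axis`` selects the clustering family: "species" clusters each species
    across its environments (default), "environment" clusters each
    environment across species."""
    if axis not in {"species", "environment"}:
        raise ValidationError("axis must be 'species' or 'environment'")
    key = "focal" if axis == "species" else "env"
    rows = []
    for _, grp in mono_yields.groupby(key, sort=True):
        labels = ward_growers(grp["mean_log10"].to_numpy(), floor)
        for (idx, row), lab in zip(grp.iterrows(), labels):
            rows.append(
                {
                    "species": row["focal"],
                    "env": row["env"],
                    "mean_log10": row["mean_log10"],
                    "label": lab,
                }
            )
    return pd.DataFrame(rows, columns=["species", "env", "mean_log10", "label"]).sort_values(
        ["species", "env"], ignore_index=True
    )


def grower_fraction_by_carbon_number(
    calls: pd.DataFrame, environments: dict[str, Environment]
) -> pd.DataFrame:
    """Fraction of grower calls per number of carbon sources."""
    n_sources = calls["env"].map(lambda e: environments[e].n_sources)
    df = calls.assign(n_sources=n_sources)
    out = (
        df.groupby("n_sources")["label"]
        .agg(n="count", grower_fraction=lambda s: (s == GROWER).mean())
        .reset_index()
    )
    return out


BOTH_GROWERS, ANY_NON_GROWER = "both_growers", "any_non_grower"


def stratify_interactions(
    classes: pd.DataFrame,
    calls: pd.DataFrame,
    environments: dict[str, Environment],
    mono_yields: pd.DataFrame | None = None,
    floor: float | None = None,
    exclude_floor_pairs: bool = False,
) -> pd.DataFrame:
    """Assign each (pair, env) interaction to a growth stratum and tabulate
    class counts per stratum and carbon-source-number bin.

    A record lands in ``both_growers`` iff both species are growers in that
    environment.  With ``exclude_floor_pairs`` records where either species'
    mono-culture mean density sits at the detection floor are dropped
    (sensitivity variant requiring ``mono_yields`` and ``floor``)."""
    lab = calls.set_index(["species", "env"])["label"]
    at_floor = None
    if exclude_floor_pairs:
        if mono_yields is None or floor is None:
            raise ValidationError("exclude_floor_pairs requires mono_yields and floor")
        at_floor = (
            mono_yields.set_index(["focal", "env"])["mean_density"] <= floor
        )
    rows = []
    for rec in classes.itertuples(index=False):
        try:
            li = lab.loc[(rec.species_i, rec.env)]
            lj = lab.loc[(rec.species_j, rec.env)]
        except KeyError as exc:
            raise ValidationError(
                f"missing growth call for pair ({rec.species_i}, {rec.species_j}) "
                f"in {rec.env}"
            ) from exc
        if at_floor is not None and (
            at_floor.loc[(rec.species_i, rec.env)] or at_floor.loc[(rec.species_j, rec.env)]
        ):
            continue
        stratum = BOTH_GROWERS if (li == GROWER and lj == GROWER) else ANY_NON_GROWER
        rows.append(
            {
                "stratum": stratum,
                "n_sources": environments[rec.env].n_sources,
                "interaction_class": rec.interaction_class,
            }
        )
    long = pd.DataFrame(rows, columns=["stratum", "n_sources", "interaction_class"])
    table = (
        long.groupby(["stratum", "n_sources", "interaction_class"])
        .size()
        .rename("count")
        .reset_index()
    )
    return table


def class_enrichment(
    strata: pd.DataFrame,
    fdr: float = 0.05,
    bins: tuple[int, ...] | None = (1, 2, 4),
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per (stratum, class).

    The population is the pooled table (both strata) restricted to the chosen
    carbon-number bins; each stratum is the draw, each class the success
    state.  p = P[X >= observed] under the hypergeometric null; BH across all
    (stratum, class) tests.  Degenerate margins give p = 1."""
    sub = strata if bins is None else strata.loc[strata["n_sources"].isin(bins)]
    if len(sub) == 0 or sub["count"].sum() == 0:
        raise ValidationError("no interactions in the selected bins")
    pooled = sub.groupby("interaction_class")["count"].sum()
    M = int(pooled.sum())
    rows = []
    for stratum, grp in sub.groupby("stratum"):
        by_class = grp.groupby("interaction_class")["count"].sum()
        N = int(by_class.sum())
        for cls in pooled.index:
            K = int(pooled.get(cls, 0))
            k = int(by_class.get(cls, 0))
            if K == 0 or N == 0:
                p = 1.0
            else:
                p = float(stats.hypergeom.sf(k - 1, M, K, N))
            expected = N * K / M
            rows.append(
                {
                    "stratum": stratum,
                    "interaction_class": cls,
                    "observed": k,
                    "expected": expected,
                    "obs_over_exp": (k / expected) if expected > 0 else np.nan,
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["q"] < fdr
    return out
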