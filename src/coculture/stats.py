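"""Community-level statistics.

Four families of tests ask whether interaction outcomes vary systematically:

* Monte-Carlo chi-square heterogeneity of class counts across carbon sources
  or bacterial pairs;
* pairwise PERMANOVA of per-environment theta profiles between biochemical
  categories of carbon sources;
* a rank-based species enrichment test (adapted from gene-set enrichment):
  is the mean rank of a species' pairs, when all pairs are ranked by theta,
  biased relative to random same-size pair subsets;
* Spearman rank trend between the number of carbon sources and theta.

All Monte-Carlo p-values use the add-one estimator (1 + #{null >= obs}) /
(1 + iterations), so they are bounded below by the resolution floor and never
zero.  One master seed drives everything; each procedure derives a stable
sub-seed from its identity.
"""

from __future__ import annotations

import hashlib
import warnings
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ValidationError

try:  # importlib.resources for the packaged category table
    from importlib.resources import files as _files
except ImportError:  # pragma: no cover
    _files = None


def subseed(master: int, *tokens) -> int:
    """Stable sub-seed (< 2**31) derived from a master seed and a test
    identity, so permuting the order of analyses never changes any result."""
    h = hashlib.sha256(("/".join([str(master), *map(str, tokens)])).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def default_category_partition() -> dict[str, str]:
    """Biochemical category per carbon source for the standard 16-source
    panel (sugars, sugar alcohols, carboxylate ions, amino acids, nucleic
    acids)."""
    path = _files("coculture").joinpath("data/carbon_categories.csv")
    df = pd.read_csv(path)
    return dict(zip(df["source"], df["category"]))


# ---------------------------------------------------------------------------
# Monte-Carlo chi-square
# ---------------------------------------------------------------------------

def chisq_mc(
    table: pd.DataFrame, iters: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo chi-square heterogeneity test on a class-count table.

    Rows are grouping levels (carbon sources or pairs), columns interaction
    classes.  The observed Pearson statistic is compared with tables drawn
    with fixed row totals and pooled column probabilities (the convention of
    R's simulated chi-square test).  Zero-margin rows/columns are dropped
    with a warning.  Returns (statistic, p) with the add-one estimator."""
    if iters < 1:
        raise ValidationError("iters must be >= 1")
    X = np.asarray(table, dtype=float)
    if X.size == 0:
        raise ValidationError("empty table")
    row_ok = X.sum(axis=1) > 0
    col_ok = X.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn("dropping zero-margin rows/columns", stacklevel=2)
        X = X[row_ok][:, col_ok]
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("table needs at least 2 rows and 2 columns")
    rows = X.sum(axis=1)
    total = X.sum()
    p_cols = X.sum(axis=0) / total
    expected = np.outer(rows, p_cols)
    obs_stat = float(((X - expected) ** 2 / expected).sum())

    rng = np.random.default_rng(seed)
    ge = 0
    chunk = 20_000
    n_int = rows.astype(int)
    for start in range(0, iters, chunk):
        m = min(chunk, iters - start)
        sims = rng.multinomial(n_int[None, :].repeat(m, axis=0), p_cols).astype(float)
        # the statistic of each simulated table uses its own fitted margins,
        # exactly as the observed statistic does
        col_sim = sims.sum(axis=1) / total  # [m, cols]
        e_sim = rows[None, :, None] * col_sim[:, None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(e_sim > 0, (sims - e_sim) ** 2 / e_sim, 0.0)
        stats_sim = contrib.sum(axis=(1, 2))
        ge += int((stats_sim >= obs_stat - 1e-12).sum())
    p = (1 + ge) / (1 + iters)
    return obs_stat, float(p)


def class_count_table(classes: pd.DataFrame, by: str) -> pd.DataFrame:
    """Count interaction classes per carbon source env (``by='env'``) or per
    bacterial pair (``by='pair'``)."""
    df = classes.copy()
    if by == "pair":
        df["level"] = df["species_i"] + "-" + df["species_j"]
    elif by == "env":
        df["level"] = df["env"]
    else:
        raise ValidationError("by must be 'env' or 'pair'")
    return pd.crosstab(df["level"], df["interaction_class"])


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _pseudo_f(sq_dist: np.ndarray, groups: np.ndarray) -> float:
    """PERMANOVA pseudo-F from a squared Euclidean distance matrix and group
    labels: F = (SS_between/(a-1)) / (SS_within/(N-a))."""
    n = len(groups)
    labels = np.unique(groups)
    a = len(labels)
    ss_total = sq_dist[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in labels:
        idx = np.flatnonzero(groups == g)
        if idx.size > 1:
            sub = sq_dist[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    points: np.ndarray,
    groups: np.ndarray,
    perms: int = 10_000,
    seed: int = 0,
    exhaustive_limit: int = 20_000,
) -> tuple[float, float]:
    """Two-group (or multi-group) PERMANOVA on Euclidean distances.

    Enumerates all distinct label assignments exactly when there are at most
    ``exhaustive_limit`` of them (two-group case); otherwise permutes labels
    ``perms`` times with the add-one p estimator.  Returns (pseudo-F, p)."""
    points = np.asarray(points, dtype=float)
    groups = np.asarray(groups)
    if points.ndim == 1:
        points = points[:, None]
    diff = points[:, None, :] - points[None, :, :]
    sq = (diff**2).sum(axis=-1)
    f_obs = _pseudo_f(sq, groups)
    labels, counts = np.unique(groups, return_counts=True)
    n = len(groups)
    if len(labels) == 2 and comb(n, int(counts[0])) <= exhaustive_limit:
        k = int(counts[0])
        ge = 0
        total = 0
        for idx in combinations(range(n), k):
            g = np.full(n, labels[1], dtype=groups.dtype)
            g[list(idx)] = labels[0]
            if _pseudo_f(sq, g) >= f_obs - 1e-12:
                ge += 1
            total += 1
        return f_obs, ge / total
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(perms):
        g = rng.permutation(groups)
        if _pseudo_f(sq, g) >= f_obs - 1e-12:
            ge += 1
    return f_obs, (1 + ge) / (1 + perms)


def pairwise_permanova(
    theta_matrix: pd.DataFrame,
    partition: dict[str, str],
    perms: int = 10_000,
    seed: int = 0,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Pairwise PERMANOVA between biochemical categories of carbon sources.

    ``theta_matrix`` has one row per single-carbon-source environment (index
    = the source name) and one column per bacterial pair, holding theta.
    Categories with fewer than two environments are skipped with a warning.
    BH correction across category pairs."""
    cats = {}
    for src in theta_matrix.index:
        if src not in partition:
            raise ValidationError(f"carbon source {src!r} missing from partition")
        cats.setdefault(partition[src], []).append(src)
    usable = {c: srcs for c, srcs in cats.items() if len(srcs) >= 2}
    skipped = sorted(set(cats) - set(usable))
    if skipped:
        warnings.warn(f"categories with < 2 environments skipped: {skipped}", stacklevel=2)
    rows = []
    for c1, c2 in combinations(sorted(usable), 2):
        srcs = usable[c1] + usable[c2]
        pts = theta_matrix.loc[srcs].to_numpy()
        grp = np.array([c1] * len(usable[c1]) + [c2] * len(usable[c2]))
        f, p = permanova(pts, grp, perms=perms, seed=subseed(seed, "permanova", c1, c2))
        rows.append({"category_1": c1, "category_2": c2, "pseudo_F": f, "p": p})
    out = pd.DataFrame(rows, columns=["category_1", "category_2", "pseudo_F", "p"])
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out["significant"] = out["q"] < fdr
    return out


# ---------------------------------------------------------------------------
# Species rank enrichment
# ---------------------------------------------------------------------------

def species_rank_enrichment(
    theta_by_pair: pd.DataFrame,
    perms: int = 10_000,
    seed: int = 0,
    fdr: float = 0.05,
    exhaustive_limit: int = 50_000,
) -> pd.DataFrame:
    """Rank-bias test per species, adapted from gene-set enrichment.

    ``theta_by_pair`` has columns species_i, species_j, theta (one value per
    pair, typically the pair average over single-source environments).  All
    pairs are ranked by theta (mid-ranks for ties); the statistic for a
    species is the mean rank of the pairs containing it.  The two-sided p
    compares it against the distribution of mean ranks of random same-size
    pair subsets -- enumerated exactly when feasible, else by Monte Carlo
    with the add-one estimator.  BH across species."""
    theta = theta_by_pair["theta"].to_numpy(dtype=float)
    n = len(theta)
    if n == 0:
        raise ValidationError("no pairs")
    ranks = stats.rankdata(theta)
    species = sorted(set(theta_by_pair["species_i"]) | set(theta_by_pair["species_j"]))
    members = {
        s: np.flatnonzero(
            (theta_by_pair["species_i"] == s) | (theta_by_pair["species_j"] == s)
        )
        for s in species
    }
    rows = []
    for s in species:
        idx = members[s]
        k = idx.size
        if k == 0:
            continue
        obs = float(ranks[idx].mean())
        if comb(n, k) <= exhaustive_limit:
            null = np.array(
                [ranks[list(c)].mean() for c in combinations(range(n), k)]
            )
            lo = float((null <= obs + 1e-12).mean())
            hi = float((null >= obs - 1e-12).mean())
            p = min(1.0, 2 * min(lo, hi))
        else:
            rng = np.random.default_rng(subseed(seed, "rank_enrichment", s))
            null = np.array(
                [ranks[rng.choice(n, size=k, replace=False)].mean() for _ in range(perms)]
            )
            lo = (1 + int((null <= obs + 1e-12).sum())) / (1 + perms)
            hi = (1 + int((null >= obs - 1e-12).sum())) / (1 + perms)
            p = min(1.0, 2 * min(lo, hi))
        rows.append(
            {
                "species": s,
                "n_pairs": k,
                "mean_rank": obs,
                "expected_rank": (n + 1) / 2,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["q"] < fdr
    return out


# ---------------------------------------------------------------------------
# Rank-correlation trend
# ---------------------------------------------------------------------------

def spearman_trend(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties, two-sided t
    approximation).  Constant input yields (nan, nan)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need equal-length inputs with >= 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
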