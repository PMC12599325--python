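"""Domain types, tabular IO, detection-floor handling and yield summaries.

The central data structure is a long-format "culture table": one row per
replicate endpoint measurement of fluorescent cell density (cells/ml) for a
mono-culture (``partner`` empty) or a co-culture (``partner`` set), in one
growth environment.  All downstream statistics consume either this table or
per-culture yield summaries derived from it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

#: Lower reporting limit for fluorescent cell density (cells/ml).  Densities
#: below this are set to it before any analysis; the value is the published
#: constant derived from the 90th percentile of densities observed without a
#: carbon source.
DETECTION_FLOOR = 4.57e5

CULTURE_COLUMNS = ["focal", "partner", "env", "replicate", "density"]
ENVIRONMENT_COLUMNS = ["env", "carbon_sources", "total_mg_per_ml"]


class SchemaError(ValueError):
    """A table is missing required columns."""


class ValidationError(ValueError):
    """A table has the right shape but invalid contents."""


@dataclass(frozen=True)
class Environment:
    """A growth environment: a set of carbon sources sharing a fixed total
    concentration (mg/ml), split equally between the sources when mixed.
    ``n_sources == 0`` encodes the no-carbon control."""

    env_id: str
    carbon_sources: frozenset[str] = frozenset()
    total_concentration: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "carbon_sources", frozenset(self.carbon_sources))
        if self.total_concentration < 0:
            raise ValidationError("total_concentration must be >= 0")

    @property
    def n_sources(self) -> int:
        return len(self.carbon_sources)

    @property
    def per_source_concentration(self) -> float:
        """Concentration of each individual source (equal split)."""
        if self.n_sources == 0:
            return 0.0
        return self.total_concentration / self.n_sources


@dataclass
class PipelineConfig:
    """Run-wide constants: detection floor, FDR, master seed and Monte-Carlo
    iteration counts.  One master seed is used; every stochastic procedure
    derives a stable sub-seed from it (see :func:`coculture.stats.subseed`)."""

    detection_floor: float = DETECTION_FLOOR
    fdr: float = 0.05
    seed: int = 0
    chisq_iterations: int = 100_000
    permanova_permutations: int = 10_000
    enrichment_permutations: int = 10_000
    welch: bool = True
    cluster_axis: str = "species"  # or "environment"
    enrichment_bins: tuple[int, ...] = (1, 2, 4)

    def __post_init__(self) -> None:
        if not (0 < self.fdr < 1):
            raise ValidationError("fdr must be in (0, 1)")
        if self.detection_floor <= 0:
            raise ValidationError("detection_floor must be > 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "enrichment_bins" in data:
            data["enrichment_bins"] = tuple(data["enrichment_bins"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["enrichment_bins"] = list(self.enrichment_bins)
        return d


# ---------------------------------------------------------------------------
# Table IO
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing columns {missing}")


def validate_culture_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a culture table in place-free fashion.

    Mono-cultures are rows with an empty ``partner``.  Densities must be
    non-negative reals and (focal, partner, env, replicate) must be unique.
    """
    _require_columns(df, CULTURE_COLUMNS, "culture table")
    out = df.loc[:, CULTURE_COLUMNS].copy()
    out["partner"] = out["partner"].fillna("").astype(str)
    out["focal"] = out["focal"].astype(str)
    out["env"] = out["env"].astype(str)
    out["replicate"] = out["replicate"].astype(int)
    out["density"] = pd.to_numeric(out["density"], errors="raise").astype(float)
    if (out["density"] < 0).any():
        bad = out.loc[out["density"] < 0].iloc[0]
        raise ValidationError(f"negative density for {bad['focal']}/{bad['env']}")
    if out["density"].isna().any():
        raise ValidationError("missing density values")
    dup = out.duplicated(subset=["focal", "partner", "env", "replicate"])
    if dup.any():
        bad = out.loc[dup].iloc[0]
        raise ValidationError(
            f"duplicate replicate {bad['replicate']} for "
            f"({bad['focal']}, {bad['partner']!r}, {bad['env']})"
        )
    return out


def read_culture_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV/TSV culture table (columns focal, partner, env, replicate,
    density) into a validated DataFrame."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"focal": str, "partner": str, "env": str})
    return validate_culture_table(df)


def write_culture_table(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, CULTURE_COLUMNS].to_csv(path, index=False)


def read_environment_table(path: str | Path) -> dict[str, Environment]:
    """Read an environment definition table: env, semicolon-separated
    carbon_sources, total_mg_per_ml."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"env": str, "carbon_sources": str})
    _require_columns(df, ENVIRONMENT_COLUMNS, "environment table")
    envs: dict[str, Environment] = {}
    for row in df.itertuples(index=False):
        sources = frozenset(
            s for s in str(row.carbon_sources or "").split(";") if s and s != "nan"
        )
        if row.env in envs:
            raise ValidationError(f"duplicate environment id {row.env!r}")
        envs[str(row.env)] = Environment(str(row.env), sources, float(row.total_mg_per_ml))
    return envs


def write_environment_table(envs: Mapping[str, Environment], path: str | Path) -> None:
    rows = [
        {
            "env": e.env_id,
            "carbon_sources": ";".join(sorted(e.carbon_sources)),
            "total_mg_per_ml": e.total_concentration,
        }
        for e in envs.values()
    ]
    pd.DataFrame(rows, columns=ENVIRONMENT_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Detection floor and yield summaries
# ---------------------------------------------------------------------------

def apply_detection_floor(df: pd.DataFrame, floor: float = DETECTION_FLOOR) -> pd.DataFrame:
    """Replace densities below ``floor`` by ``floor``; a boolean ``floored``
    column records which values were raised.  Idempotent."""
    if floor <= 0:
        raise ValidationError("floor must be > 0")
    out = df.copy()
    below = out["density"] < floor
    out["floored"] = below.to_numpy() | out.get("floored", False)
    out.loc[below, "density"] = floor
    return out


def summarize_yields(df: pd.DataFrame) -> pd.DataFrame:
    """Per-culture summaries of floored replicate densities.

    Returns one row per (focal, partner, env) with the replicate count, the
    arithmetic mean density, and the mean and unbiased variance of the log10
    densities (NaN variance when only one replicate is present).
    """
    if len(df) == 0:
        raise ValidationError("empty culture table")
    g = df.groupby(["focal", "partner", "env"], sort=True)["density"]
    out = g.agg(
        n_reps="count",
        mean_density="mean",
        mean_log10=lambda x: np.log10(x).mean(),
        var_log10=lambda x: np.log10(x).var(ddof=1) if len(x) > 1 else np.nan,
    ).reset_index()
    return out


def mono_summaries(yields: pd.DataFrame) -> pd.DataFrame:
    """Subset of yield summaries for mono-cultures (empty partner)."""
    return yields.loc[yields["partner"] == ""].reset_index(drop=True)


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered species pair in canonical (sorted) order."""
    return (a, b) if a <= b else (b, a)
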