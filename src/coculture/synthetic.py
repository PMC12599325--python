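"""Synthetic datasets with known ground truth.

Two generators produce tables in the standard culture-table schema:

* :func:`generate_planted_dataset` plants known log2 interaction effects on
  top of chosen mono-culture densities, with lognormal replicate noise
  (additive Gaussian on log10 density) -- the tool for unit-testing the
  inference chain, since the truth is recorded alongside.

* :func:`generate_resource_dataset` runs a mechanistic batch consumer-
  resource simulation: species take up carbon sources they can use, convert
  a fraction to biomass and re-secrete the remainder as a shared carbon
  by-product pool that any species may consume (cross-feeding).  Total
  carbon is fixed and split equally between the sources of an environment,
  so single-source media starve most species (whose partners may then feed
  them by-products: facilitation) while diverse media let everyone grow and
  contest the same fixed carbon pool (competition).  This is an engineered
  stand-in for the experimental system, not a fitted model of it.

The default study design mirrors the experimental one: 8 species, 28 pairs,
32 environments (16 single sources, random mixtures of 2, 4, 8 and 16 with
equal mass split, one no-carbon control), biological triplicates, lognormal
replicate noise, and the 4.57e5 cells/ml detection floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CULTURE_COLUMNS,
    DETECTION_FLOOR,
    Environment,
    ValidationError,
    apply_detection_floor,
    canonical_pair,
    validate_culture_table,
)

#: The 16-source carbon panel (common names), used as the default resource
#: set so biochemical-category analyses apply to simulated data directly.
CARBON_SOURCES = (
    "Glucose", "Ribose", "Cellobiose", "Raffinose",
    "Glycerol", "Mannitol", "Sorbitol",
    "Acetate", "Citrate", "Succinate",
    "Alanine", "Glutamine", "Isoleucine", "Proline", "Serine",
    "Uridine",
)

DEFAULT_SPECIES = tuple(f"S{i+1}" for i in range(8))

#: Inoculum densities (cells/ml): 2000 cells/ul preculture, 10 ul into
#: 190 ul medium for mono-cultures; 5 ul of each strain for co-cultures.
MONO_INOCULUM = 1.0e5
CO_INOCULUM = 5.0e4


# ---------------------------------------------------------------------------
# Environment design
# ---------------------------------------------------------------------------

def design_environments(
    sources: tuple[str, ...] = CARBON_SOURCES,
    total: float = 1.0,
    seed: int = 1,
) -> dict[str, Environment]:
    """The 32-environment design: every single source, nested random
    mixtures of 2, 4, 8 and 16 (8 + 4 + 2 + 1 of them), and a no-carbon
    control.  Mixtures are formed by randomly permuting the sources and
    merging consecutive blocks, so each size level nests the previous one."""
    if len(sources) != 16:
        raise ValidationError("the standard design requires 16 carbon sources")
    rng = np.random.default_rng(seed)
    perm = [sources[i] for i in rng.permutation(len(sources))]
    envs: dict[str, Environment] = {}
    for s in sources:
        envs[s] = Environment(s, frozenset({s}), total)
    for level in (2, 4, 8, 16):
        n_mix = 16 // level
        for b in range(n_mix):
            block = perm[b * level : (b + 1) * level]
            env_id = f"mix{level}_{b + 1}"
            envs[env_id] = Environment(env_id, frozenset(block), total)
    envs["none"] = Environment("none", frozenset(), total)
    return envs


# ---------------------------------------------------------------------------
# Planted-effect generator
# ---------------------------------------------------------------------------

@dataclass
class PlantedEffectConfig:
    """Ground-truth specification for the planted-effect generator.

    ``effects`` maps (species_i, species_j, env) -- pair in canonical order --
    to the true effect pair (E_true_ij, E_true_ji) in log2 units;
    ``mono_means`` maps (species, env) to the true mono-culture mean density.
    ``noise_sd_log10 = 0`` yields deterministic tables."""

    species: tuple[str, ...]
    environments: tuple[str, ...]
    effects: dict[tuple[str, str, str], tuple[float, float]]
    mono_means: dict[tuple[str, str], float]
    noise_sd_log10: float = 0.05
    n_reps: int = 3
    seed: int = 1
    floor: float = DETECTION_FLOOR

    def __post_init__(self) -> None:
        if self.noise_sd_log10 < 0:
            raise ValidationError("noise_sd_log10 must be >= 0")
        if any(m <= 0 for m in self.mono_means.values()):
            raise ValidationError("mono-culture means must be positive")


def implied_class(e_ij: float, e_ji: float) -> str:
    from .calls import classify_pair

    sym = {1: "+", 0: "0", -1: "-"}
    return classify_pair(sym[int(np.sign(e_ij))], sym[int(np.sign(e_ji))])


def generate_planted_dataset(
    config: PlantedEffectConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit (culture table, truth table).

    Mono replicates are 10^(log10 mono_mean + eps); co replicates are
    10^(log10(mono_mean * 2^E_true) + eps), eps ~ N(0, noise_sd_log10).
    Densities are floored.  The truth table records the planted effects and
    the class implied by their signs."""
    rng = np.random.default_rng(config.seed)
    rows = []
    noise = config.noise_sd_log10

    def reps(mean: float) -> np.ndarray:
        eps = rng.normal(0.0, noise, config.n_reps) if noise > 0 else np.zeros(config.n_reps)
        return 10 ** (np.log10(mean) + eps)

    for (sp, env), mean in sorted(config.mono_means.items()):
        for r, d in enumerate(reps(mean), start=1):
            rows.append((sp, "", env, r, d))

    truth_rows = []
    for (i, j, env), (e_ij, e_ji) in sorted(config.effects.items()):
        if (i, j) != canonical_pair(i, j):
            raise ValidationError(f"effect key ({i}, {j}) not in canonical order")
        for focal, partner, e in ((i, j, e_ij), (j, i, e_ji)):
            mono = config.mono_means[(focal, env)]
            for r, d in enumerate(reps(mono * 2.0**e), start=1):
                rows.append((focal, partner, env, r, d))
        truth_rows.append(
            {
                "species_i": i,
                "species_j": j,
                "env": env,
                "E_true_ij": e_ij,
                "E_true_ji": e_ji,
                "true_class": implied_class(e_ij, e_ji),
            }
        )
    culture = pd.DataFrame(rows, columns=CULTURE_COLUMNS)
    culture = apply_detection_floor(validate_culture_table(culture), config.floor)
    return culture, pd.DataFrame(truth_rows)


def planted_environments(config: PlantedEffectConfig) -> dict[str, Environment]:
    """Single-source environments named after themselves, for running the
    pipeline on planted tables."""
    return {e: Environment(e, frozenset({e}), 1.0) for e in config.environments}


def default_planted_config(
    n_pair_envs: int = 100,
    magnitudes: tuple[float, ...] = (0.0, 1.0, 1.5),
    noise_sd_log10: float = 0.05,
    n_reps: int = 3,
    seed: int = 1,
    mono_mean: float = 1.0e7,
) -> PlantedEffectConfig:
    """A generic planted design: ``n_pair_envs`` independent pair-environment
    cells, each unidirectional true effect drawn uniformly from the signed
    magnitude set {0, +-1, +-1.5} (uniform over the five values)."""
    rng = np.random.default_rng(seed)
    signed = sorted({float(s * m) for m in magnitudes for s in (1, -1)})
    species = ("A", "B")
    envs = tuple(f"env{k+1:03d}" for k in range(n_pair_envs))
    effects = {}
    mono_means = {}
    for env in envs:
        e_ij = float(rng.choice(signed))
        e_ji = float(rng.choice(signed))
        effects[("A", "B", env)] = (e_ij, e_ji)
        mono_means[("A", env)] = mono_mean
        mono_means[("B", env)] = mono_mean
    return PlantedEffectConfig(
        species=species,
        environments=envs,
        effects=effects,
        mono_means=mono_means,
        noise_sd_log10=noise_sd_log10,
        n_reps=n_reps,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Resource-explicit batch simulator
# ---------------------------------------------------------------------------

@dataclass
class ResourceModelConfig:
    """Parameters of the batch consumer-resource model.

    Arrays are indexed [species, resource]; the resource axis covers the
    carbon sources plus any by-product pools (``byproduct_resource``).
    Units: uptake in mg per cell per hour, yield in cells per mg consumed,
    densities in cells/ml, resources in mg/ml, time in hours.
    ``byproduct_fraction`` is the share of consumed carbon re-secreted into
    the by-product pool (mass balance: consumed = assimilated + secreted)."""

    species: tuple[str, ...]
    resources: tuple[str, ...]
    uptake: np.ndarray
    yield_cells_per_mg: np.ndarray
    byproduct_fraction: np.ndarray
    byproduct_resource: str | None = "byproduct"
    horizon_h: float = 72.0
    dt_h: float = 0.05
    mono_inoculum: float = MONO_INOCULUM
    co_inoculum: float = CO_INOCULUM
    noise_sd_log10: float = 0.05
    n_reps: int = 3
    seed: int = 1
    floor: float = DETECTION_FLOOR

    def __post_init__(self) -> None:
        self.uptake = np.asarray(self.uptake, dtype=float)
        self.yield_cells_per_mg = np.asarray(self.yield_cells_per_mg, dtype=float)
        self.byproduct_fraction = np.asarray(self.byproduct_fraction, dtype=float)
        shape = (len(self.species), len(self.resources))
        for name, arr in (
            ("uptake", self.uptake),
            ("yield_cells_per_mg", self.yield_cells_per_mg),
            ("byproduct_fraction", self.byproduct_fraction),
        ):
            if arr.shape != shape:
                raise ValidationError(f"{name} must have shape {shape}")
            if (arr < 0).any():
                raise ValidationError(f"{name} must be non-negative")
        if (self.byproduct_fraction >= 1).any():
            raise ValidationError("byproduct_fraction must be < 1")
        if self.byproduct_resource is not None:
            if self.byproduct_resource not in self.resources:
                raise ValidationError("byproduct_resource must be listed in resources")
            bp = self.resources.index(self.byproduct_resource)
            if self.byproduct_fraction[:, bp].any():
                raise ValidationError("the by-product pool cannot itself be re-secreted")

    def species_index(self, name: str) -> int:
        return self.species.index(name)


def _initial_resources(config: ResourceModelConfig, env: Environment) -> np.ndarray:
    r0 = np.zeros(len(config.resources))
    for src in env.carbon_sources:
        if src not in config.resources:
            raise ValidationError(f"environment source {src!r} not in the resource set")
        r0[config.resources.index(src)] = env.per_source_concentration
    return r0


def _simulate_batch(
    config: ResourceModelConfig,
    env: Environment,
    communities: list[tuple[str, ...]],
    check_mass_balance: bool = False,
) -> np.ndarray:
    """Simulate all ``communities`` (1- or 2-species tuples) in one
    environment simultaneously.  Returns final densities with shape
    [community, member] (NaN padding for mono-cultures).

    Per step, each species demands uptake * density * dt of every resource;
    over-subscribed resources are shared pro rata to demand, consumed carbon
    splits into biomass (yield applies to the assimilated fraction) and
    secretion into the by-product pool.  Deterministic; densities
    non-decreasing; primary resources non-increasing."""
    n_comm = len(communities)
    n_sp = len(config.species)
    n_res = len(config.resources)
    bp_idx = (
        config.resources.index(config.byproduct_resource)
        if config.byproduct_resource is not None
        else None
    )
    member = np.zeros((n_comm, n_sp), dtype=bool)
    x = np.zeros((n_comm, n_sp))
    for c, comm in enumerate(communities):
        if not 1 <= len(comm) <= 2:
            raise ValidationError("communities must have 1 or 2 species")
        inoc = config.mono_inoculum if len(comm) == 1 else config.co_inoculum
        for sp in comm:
            s = config.species_index(sp)
            if member[c, s]:
                raise ValidationError("duplicate species in a community")
            member[c, s] = True
            x[c, s] = inoc

    r = np.tile(_initial_resources(config, env), (n_comm, 1))
    u = config.uptake[None, :, :]
    gamma = config.yield_cells_per_mg[None, :, :]
    beta = config.byproduct_fraction[None, :, :]
    assimilated_mass = np.zeros((n_comm, n_sp))  # mg/ml carbon into biomass
    initial_total = r.sum(axis=1).copy()

    n_steps = int(round(config.horizon_h / config.dt_h))
    active = x * member
    for _ in range(n_steps):
        demand = u * active[:, :, None] * config.dt_h  # [comm, sp, res]
        tot_demand = demand.sum(axis=1)  # [comm, res]
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(tot_demand > 0, np.minimum(1.0, r / tot_demand), 0.0)
        consumed = demand * scale[:, None, :]
        r = r - consumed.sum(axis=1)
        np.maximum(r, 0.0, out=r)
        secreted = (beta * consumed).sum(axis=(1, 2))  # [comm]
        if bp_idx is not None:
            r[:, bp_idx] += secreted
        gain_mass = ((1.0 - beta) * consumed).sum(axis=2)  # [comm, sp]
        assimilated_mass += gain_mass
        active = active + (gamma * (1.0 - beta) * consumed).sum(axis=2)
        if r.sum() == 0.0:
            break

    if check_mass_balance:
        final_total = r.sum(axis=1) + assimilated_mass.sum(axis=1)
        ref = np.maximum(initial_total, 1e-30)
        if np.any(np.abs(final_total - initial_total) > 1e-9 * np.maximum(ref, 1.0)):
            raise AssertionError("carbon mass balance violated")

    out = np.full((n_comm, 2), np.nan)
    for c, comm in enumerate(communities):
        for k, sp in enumerate(comm):
            out[c, k] = active[c, config.species_index(sp)]
    return out


def resource_batch_dynamics(
    config: ResourceModelConfig,
    env: Environment,
    community: tuple[str, ...],
    check_mass_balance: bool = True,
) -> dict[str, float]:
    """Final densities (cells/ml) of a 1- or 2-species batch culture after
    the configured horizon.  Deterministic given the configuration."""
    final = _simulate_batch(config, env, [tuple(community)], check_mass_balance)
    return {sp: float(final[0, k]) for k, sp in enumerate(community)}


def default_resource_config(seed: int = 1, noise_sd_log10: float = 0.05) -> ResourceModelConfig:
    """Eight specialist species on the standard 16-source panel.

    Each species can use a random 4-6 of the 16 sources (seeded draw,
    jittered rates around 1e-9 mg/cell/h), converts carbon at 5e8 cells/mg
    and re-secretes 30% of consumed source carbon into a shared by-product
    pool that every species can eat.  These rates give ~0.35/h effective
    growth and full carbon consumption well inside the 72 h horizon."""
    rng = np.random.default_rng(seed)
    species = DEFAULT_SPECIES
    resources = CARBON_SOURCES + ("byproduct",)
    n_sp, n_res = len(species), len(resources)
    uptake = np.zeros((n_sp, n_res))
    for s in range(n_sp):
        k = int(rng.integers(4, 7))
        usable = rng.choice(16, size=k, replace=False)
        uptake[s, usable] = 1.0e-9 * 10 ** rng.normal(0.0, 0.15, size=k)
    uptake[:, -1] = 1.0e-9 * 10 ** rng.normal(0.0, 0.15, size=n_sp)  # by-product
    gamma = np.full((n_sp, n_res), 5.0e8)
    beta = np.full((n_sp, n_res), 0.3)
    beta[:, -1] = 0.0
    return ResourceModelConfig(
        species=species,
        resources=resources,
        uptake=uptake,
        yield_cells_per_mg=gamma,
        byproduct_fraction=beta,
        noise_sd_log10=noise_sd_log10,
        seed=seed,
    )


def generate_resource_dataset(
    config: ResourceModelConfig,
    environments: dict[str, Environment] | None = None,
) -> tuple[pd.DataFrame, dict[str, Environment]]:
    """Simulate the full study design: every species mono-culture and every
    pair co-culture in every environment, with lognormal replicate noise and
    the detection floor applied.  Returns (culture table, environments)."""
    if environments is None:
        environments = design_environments(
            tuple(r for r in config.resources if r != config.byproduct_resource),
            seed=config.seed,
        )
    rng = np.random.default_rng(config.seed)
    communities: list[tuple[str, ...]] = [(sp,) for sp in config.species]
    for a in range(len(config.species)):
        for b in range(a + 1, len(config.species)):
            communities.append((config.species[a], config.species[b]))

    rows = []
    for env_id in sorted(environments):
        env = environments[env_id]
        final = _simulate_batch(config, env, communities)
        for c, comm in enumerate(communities):
            for k, sp in enumerate(comm):
                partner = comm[1 - k] if len(comm) == 2 else ""
                mean = max(final[c, k], 1.0)  # log-noise needs a positive base
                for rep in range(1, config.n_reps + 1):
                    eps = (
                        rng.normal(0.0, config.noise_sd_log10)
                        if config.noise_sd_log10 > 0
                        else 0.0
                    )
                    rows.append((sp, partner, env_id, rep, 10 ** (np.log10(mean) + eps)))
    culture = pd.DataFrame(rows, columns=CULTURE_COLUMNS)
    culture = apply_detection_floor(validate_culture_table(culture), config.floor)
    return culture, environments
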