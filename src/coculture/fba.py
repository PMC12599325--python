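"""Flux balance analysis and carbon-containing by-product counting.

Given a stoichiometric model with a biomass objective, flux balance analysis
(FBA) maximises biomass production at steady state (S v = 0 within flux
bounds).  Because the optimal flux vector is generally non-unique, the
by-product count is restricted to reactions *essential for the optimum*:
reactions whose individual removal lowers the optimal biomass by more than a
threshold (default 1%).  Possible by-products are then the carbon-containing
metabolites participating in reactions that both carry nonzero flux and are
essential, excluding the supplied carbon source and the biomass
pseudo-metabolite.  Essentiality depends only on optimal values, never on
which particular optimal flux vector the solver returned.

Models can be built in code, loaded from a plain JSON toy format, or read
from SBML (level 3 FBC) through cobrapy.  The linear programs themselves are
solved by cobrapy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import cobra
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import ValidationError
from .stats import spearman_trend


@dataclass(frozen=True)
class Metabolite:
    id: str
    carbon: int = 0  # carbon atoms per molecule

    def __post_init__(self) -> None:
        if self.carbon < 0:
            raise ValidationError("carbon count must be >= 0")


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: dict[str, float]  # metabolite id -> coefficient (<0 consumed)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValidationError(f"reaction {self.id}: lower bound above upper bound")


@dataclass
class MetabolicModel:
    """A stoichiometric model plus the annotations the by-product rule needs:
    carbon counts per metabolite, the biomass reaction, and which metabolite
    is the supplied carbon source.  Exchange reactions are the
    single-metabolite reactions."""

    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction: str
    carbon_source: str | None = None
    biomass_metabolite: str | None = None

    def __post_init__(self) -> None:
        met_ids = {m.id for m in self.metabolites}
        if len(met_ids) != len(self.metabolites):
            raise ValidationError("duplicate metabolite ids")
        for r in self.reactions:
            unknown = set(r.stoichiometry) - met_ids
            if unknown:
                raise ValidationError(f"reaction {r.id} references unknown {unknown}")
        if self.biomass_reaction not in {r.id for r in self.reactions}:
            raise ValidationError(f"biomass reaction {self.biomass_reaction!r} not found")
        if self.carbon_source is not None and self.carbon_source not in met_ids:
            raise ValidationError(f"carbon source {self.carbon_source!r} not a metabolite")

    @property
    def carbon_of(self) -> dict[str, int]:
        return {m.id: m.carbon for m in self.metabolites}

    def exchange_reactions(self) -> list[str]:
        return [r.id for r in self.reactions if len(r.stoichiometry) == 1]

    def source_exchange(self) -> str | None:
        """Exchange reaction whose sole metabolite is the supplied source."""
        if self.carbon_source is None:
            return None
        for r in self.reactions:
            if set(r.stoichiometry) == {self.carbon_source}:
                return r.id
        return None


def model_from_dict(data: dict) -> MetabolicModel:
    return MetabolicModel(
        id=data["id"],
        metabolites=[Metabolite(m["id"], int(m.get("carbon", 0))) for m in data["metabolites"]],
        reactions=[
            Reaction(
                r["id"],
                {k: float(v) for k, v in r["stoichiometry"].items()},
                float(r.get("lower_bound", 0.0)),
                float(r.get("upper_bound", 1000.0)),
            )
            for r in data["reactions"]
        ],
        biomass_reaction=data["biomass_reaction"],
        carbon_source=data.get("carbon_source"),
        biomass_metabolite=data.get("biomass_metabolite"),
    )


def read_model_json(path: str | Path) -> MetabolicModel:
    return model_from_dict(json.loads(Path(path).read_text()))


def write_model_json(model: MetabolicModel, path: str | Path) -> None:
    data = {
        "id": model.id,
        "metabolites": [{"id": m.id, "carbon": m.carbon} for m in model.metabolites],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
            }
            for r in model.reactions
        ],
        "biomass_reaction": model.biomass_reaction,
        "carbon_source": model.carbon_source,
        "biomass_metabolite": model.biomass_metabolite,
    }
    Path(path).write_text(json.dumps(data, indent=2))


def read_model_sbml(
    path: str | Path, carbon_source: str | None = None, biomass_reaction: str | None = None
) -> MetabolicModel:
    """Load an SBML (level 3 FBC) model via cobrapy; carbon counts come from
    the metabolite formulae."""
    cm = cobra.io.read_sbml_model(str(path))
    if biomass_reaction is None:
        objs = [r.id for r in cm.reactions if r.objective_coefficient]
        if len(objs) != 1:
            raise ValidationError("cannot infer a unique biomass reaction from SBML")
        biomass_reaction = objs[0]
    mets = [Metabolite(m.id, int(m.elements.get("C", 0))) for m in cm.metabolites]
    rxns = [
        Reaction(
            r.id,
            {m.id: float(c) for m, c in r.metabolites.items()},
            float(r.lower_bound),
            float(r.upper_bound),
        )
        for r in cm.reactions
    ]
    return MetabolicModel(cm.id or Path(path).stem, mets, rxns, biomass_reaction, carbon_source)


def to_cobra(model: MetabolicModel) -> cobra.Model:
    cm = cobra.Model(model.id)
    cmets = {m.id: cobra.Metabolite(m.id) for m in model.metabolites}
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cm.add_reactions([cr])
        cr.add_metabolites({cmets[k]: v for k, v in r.stoichiometry.items()})
    cm.objective = model.biomass_reaction
    return cm


class InfeasibleModel(RuntimeError):
    """The steady-state LP has no feasible flux vector."""


def fba_optimize(model: MetabolicModel) -> tuple[pd.Series, float]:
    """Maximise biomass flux; returns (flux vector, optimal biomass).

    The objective value is unique even when the flux vector is not.  An
    infeasible LP raises :class:`InfeasibleModel`; an unbounded one raises
    ``ValidationError``."""
    cm = to_cobra(model)
    sol = cm.optimize()
    if sol.status == "infeasible":
        raise InfeasibleModel(f"model {model.id} is infeasible")
    if sol.status != "optimal":
        raise ValidationError(f"model {model.id}: solver status {sol.status!r}")
    return sol.fluxes, float(sol.objective_value)


def essential_for_optimum(
    model: MetabolicModel, threshold: float = 0.01
) -> set[str]:
    """Reactions whose removal decreases the optimal biomass by more than
    ``threshold`` (default 1%).

    The supplied source's exchange reaction and the biomass reaction are
    always included.  A zero-biomass baseline returns an empty set with a
    warning."""
    cm = to_cobra(model)
    baseline = cm.slim_optimize(error_value=None)
    if baseline is None:
        raise InfeasibleModel(f"model {model.id} is infeasible")
    if baseline <= 0:
        warnings.warn(f"model {model.id}: baseline biomass is 0", stacklevel=2)
        return set()
    essential: set[str] = set()
    always = {model.biomass_reaction}
    src_ex = model.source_exchange()
    if src_ex is not None:
        always.add(src_ex)
    for r in model.reactions:
        if r.id in always:
            essential.add(r.id)
            continue
        with cm:
            rxn = cm.reactions.get_by_id(r.id)
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
            reduced = cm.slim_optimize(error_value=0.0)
        if reduced < (1 - threshold) * baseline:
            essential.add(r.id)
    return essential


@dataclass
class ByproductReport:
    model_id: str
    carbon_source: str | None
    byproducts: list[str] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.byproducts)


def count_carbon_byproducts(
    model: MetabolicModel,
    fluxes: pd.Series,
    essential: set[str],
    rel_tol: float = 1e-9,
) -> ByproductReport:
    """Carbon-containing metabolites in reactions that carry nonzero flux and
    are essential for the optimum, excluding the supplied source and the
    biomass pseudo-metabolite."""
    carbon = model.carbon_of
    vmax = float(np.max(np.abs(fluxes.to_numpy()))) if len(fluxes) else 0.0
    tol = rel_tol * vmax
    excluded = {model.carbon_source, model.biomass_metabolite}
    mets: set[str] = set()
    for r in model.reactions:
        if r.id not in essential:
            continue
        if abs(float(fluxes.get(r.id, 0.0))) <= tol:
            continue
        for met in r.stoichiometry:
            if carbon.get(met, 0) >= 1 and met not in excluded:
                mets.add(met)
    return ByproductReport(model.id, model.carbon_source, sorted(mets))


def byproduct_report(model: MetabolicModel, threshold: float = 0.01) -> ByproductReport:
    """Full pipeline on one model: FBA, essentiality scan, by-product count."""
    fluxes, _ = fba_optimize(model)
    essential = essential_for_optimum(model, threshold=threshold)
    return count_carbon_byproducts(model, fluxes, essential)


def byproduct_theta_correlation(
    reports: pd.DataFrame,
    theta_bar_env: pd.Series,
    grew: pd.DataFrame | None = None,
    min_points: int = 3,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-species Spearman correlation between the rank of the environment
    average theta and the predicted by-product count.

    ``reports`` has columns species, source, count; ``theta_bar_env`` maps
    carbon source to the environment-average theta.  ``grew`` optionally
    restricts each species to sources where growth above the detection floor
    was verified (columns species, source).  Species with fewer than
    ``min_points`` usable sources, or constant counts, are skipped."""
    if grew is not None:
        key = pd.MultiIndex.from_frame(grew[["species", "source"]])
        mask = pd.MultiIndex.from_frame(reports[["species", "source"]]).isin(key)
        reports = reports.loc[mask]
    rows = []
    for species, grp in reports.groupby("species"):
        usable = grp.loc[grp["source"].isin(theta_bar_env.index)]
        if len(usable) < min_points:
            rows.append({"species": species, "n_sources": len(usable),
                         "rho": np.nan, "p": np.nan, "skipped": "too few sources"})
            continue
        theta_rank = theta_bar_env.loc[usable["source"]].rank().to_numpy()
        counts = usable["count"].to_numpy(dtype=float)
        if np.ptp(counts) == 0 or np.ptp(theta_rank) == 0:
            rows.append({"species": species, "n_sources": len(usable),
                         "rho": np.nan, "p": np.nan, "skipped": "constant input"})
            continue
        rho, p = spearman_trend(theta_rank, counts)
        rows.append({"species": species, "n_sources": len(usable),
                     "rho": rho, "p": p, "skipped": ""})
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = multipletests(out.loc[tested, "p"].to_numpy(),
                                             method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Toy model builders (used by tests, docs and the acceptance script)
# ---------------------------------------------------------------------------

def linear_chain_model(uptake: float = 10.0) -> MetabolicModel:
    """A -> B -> biomass with a single route; every reaction essential."""
    return MetabolicModel(
        id="chain",
        metabolites=[Metabolite("A", 6), Metabolite("B", 6)],
        reactions=[
            Reaction("EX_A", {"A": 1.0}, 0.0, uptake),
            Reaction("r1", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
            Reaction("biomass", {"B": -1.0}, 0.0, 1000.0),
        ],
        biomass_reaction="biomass",
        carbon_source="A",
    )


def parallel_routes_model(cap1: float = 1000.0, cap2: float = 1000.0,
                          uptake: float = 10.0) -> MetabolicModel:
    """A -> B via two parallel routes with separate capacities; essentiality
    of each branch depends on whether the other can carry the demand."""
    return MetabolicModel(
        id="parallel",
        metabolites=[Metabolite("A", 6), Metabolite("B", 6)],
        reactions=[
            Reaction("EX_A", {"A": 1.0}, 0.0, uptake),
            Reaction("route1", {"A": -1.0, "B": 1.0}, 0.0, cap1),
            Reaction("route2", {"A": -1.0, "B": 1.0}, 0.0, cap2),
            Reaction("biomass", {"B": -1.0}, 0.0, 1000.0),
        ],
        biomass_reaction="biomass",
        carbon_source="A",
    )


def branched_secretion_model(uptake: float = 10.0) -> MetabolicModel:
    """Glucose-like source split into a biomass branch and an obligatory
    secreted by-product (acetate-like), plus an inert cofactor cycle without
    carbon.  Hand enumeration: essential active carbon metabolites are
    B and P; the source G is excluded."""
    return MetabolicModel(
        id="branched",
        metabolites=[
            Metabolite("G", 6),
            Metabolite("B", 3),
            Metabolite("P", 2),
            Metabolite("NAD", 0),
            Metabolite("NADH", 0),
        ],
        reactions=[
            Reaction("EX_G", {"G": 1.0}, 0.0, uptake),
            # split: each G yields one biomass precursor and one by-product
            Reaction("split", {"G": -1.0, "B": 1.0, "P": 1.0, "NAD": -1.0, "NADH": 1.0},
                     0.0, 1000.0),
            Reaction("regen", {"NADH": -1.0, "NAD": 1.0}, 0.0, 1000.0),
            Reaction("EX_P", {"P": -1.0}, 0.0, 1000.0),
            Reaction("biomass", {"B": -1.0}, 0.0, 1000.0),
        ],
        biomass_reaction="biomass",
        carbon_source="G",
    )
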