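"""Constraint-based metabolic core.

Implements the stoichiometric model container, model I/O (community JSON
dialect and SBML-FBC, read through cobrapy), growth-environment application,
and the three linear programs every downstream stage builds on:

* **FBA** — maximize the model objective c'v subject to steady state S·v = 0
  and flux bounds l ≤ v ≤ u.
* **pFBA** — among flux states attaining the FBA optimum, the one minimizing
  total absolute flux Σ|v|; used to uniquify the reference flux state.
* **FVA** — per-reaction minimum/maximum attainable flux, optionally with the
  global objective fixed at a stated optimum.

All LPs are solved with scipy's HiGHS interface, which is deterministic for a
fixed problem. Infinite bounds are capped at ±``BOUND_CAP`` before solving
(standard practice) and the original bounds are kept on the model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .errors import ConfigurationError, FormatError, InfeasibleError, UnboundedError
from .gpr import GprNode, gpr_genes, parse_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "EnvironmentSpec",
    "FluxState",
    "FluxRange",
    "read_model",
    "write_model",
    "fba",
    "pfba_reference",
    "fva",
]

#: cap substituted for infinite bounds inside the LPs
BOUND_CAP = 1e4
#: relative tolerance used when re-imposing a previously computed optimum
FIX_TOL = 1e-9


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str = "c"
    name: str = ""


@dataclass
class Reaction:
    """A (possibly reversible) reaction with bounds, GPR and objective weight.

    ``metabolites`` maps metabolite id → stoichiometric coefficient (negative
    for substrates, positive for products). Exchange pseudo-reactions are
    written in the export convention: ``A ->`` with coefficient −1, so uptake
    is a negative flux.
    """

    id: str
    metabolites: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gene_reaction_rule: str = ""
    objective_coefficient: float = 0.0
    name: str = ""
    subsystem: str = ""

    @property
    def gpr(self) -> GprNode | None:
        return parse_gpr(self.gene_reaction_rule)

    @property
    def genes(self) -> frozenset[str]:
        return gpr_genes(self.gpr)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class MetabolicModel:
    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._rxn_index = {r.id: r for r in self.reactions}
        self._met_ids = {m.id for m in self.metabolites}

    def reaction(self, rid: str) -> Reaction:
        try:
            return self._rxn_index[rid]
        except KeyError:
            raise KeyError(f"model {self.id!r} has no reaction {rid!r}") from None

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def genes(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for r in self.reactions:
            out |= r.genes
        return out

    @property
    def objective(self) -> dict[str, float]:
        return {r.id: r.objective_coefficient for r in self.reactions if r.objective_coefficient}

    def validate(self, require_objective: bool = True) -> None:
        """Check structural invariants; raises :class:`FormatError` naming the culprit."""
        if len(self._met_ids) != len(self.metabolites):
            raise FormatError(f"model {self.id!r}: duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise FormatError(f"model {self.id!r}: duplicate reaction ids")
        for r in self.reactions:
            missing = set(r.metabolites) - self._met_ids
            if missing:
                raise FormatError(
                    f"reaction {r.id!r} references undeclared metabolites: {sorted(missing)}"
                )
            if r.lower_bound > r.upper_bound:
                raise FormatError(
                    f"reaction {r.id!r}: lower bound {r.lower_bound} > upper bound {r.upper_bound}"
                )
            r.gpr  # noqa: B018 - raises FormatError on a malformed rule
        if require_objective and not self.objective:
            raise FormatError(f"model {self.id!r} has no reaction with a nonzero objective")

    def stoichiometric_matrix(self) -> tuple[sparse.csr_matrix, list[str], list[str]]:
        """Sparse S (metabolites × reactions) plus row/column id orderings."""
        met_ids = [m.id for m in self.metabolites]
        met_pos = {m: i for i, m in enumerate(met_ids)}
        rows, cols, vals = [], [], []
        for j, r in enumerate(self.reactions):
            for met, coef in r.metabolites.items():
                rows.append(met_pos[met])
                cols.append(j)
                vals.append(float(coef))
        S = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(met_ids), len(self.reactions))
        )
        return S, met_ids, self.reaction_ids

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=[replace(r, metabolites=dict(r.metabolites)) for r in self.reactions],
            notes=dict(self.notes),
        )


@dataclass
class EnvironmentSpec:
    """Growth-environment overrides applied on top of a model's default bounds.

    ``exchange_bounds`` maps reaction id → (lower, upper); ``None`` keeps the
    model's bound. ``nutrient_pools`` caps uptake through designated
    reserve-exchange reactions (reaction id → maximal uptake rate, applied as
    lower bound = −cap). ``atp_maintenance`` forces at least that flux through
    the named maintenance reaction.
    """

    exchange_bounds: dict[str, tuple[float | None, float | None]] = field(default_factory=dict)
    oxygen_allowed: bool = True
    oxygen_exchange: str = "EX_o2_e"
    nutrient_pools: dict[str, float] = field(default_factory=dict)
    atp_maintenance: float = 0.0
    atp_maintenance_reaction: str = "ATPM"

    def apply(self, model: MetabolicModel) -> MetabolicModel:
        out = model.copy()
        for rid, (lb, ub) in self.exchange_bounds.items():
            try:
                rxn = out.reaction(rid)
            except KeyError:
                raise ConfigurationError(
                    f"environment overrides unknown reaction {rid!r}"
                ) from None
            if lb is not None:
                rxn.lower_bound = float(lb)
            if ub is not None:
                rxn.upper_bound = float(ub)
        for rid, cap in self.nutrient_pools.items():
            if cap < 0:
                raise ConfigurationError(f"nutrient pool cap for {rid!r} must be >= 0")
            try:
                rxn = out.reaction(rid)
            except KeyError:
                raise ConfigurationError(
                    f"nutrient pool references unknown reaction {rid!r}"
                ) from None
            rxn.lower_bound = -float(cap)
        if not self.oxygen_allowed:
            try:
                rxn = out.reaction(self.oxygen_exchange)
                rxn.lower_bound = max(rxn.lower_bound, 0.0)
            except KeyError:
                pass  # model has no oxygen exchange; anaerobiosis is vacuous
        if self.atp_maintenance > 0:
            try:
                rxn = out.reaction(self.atp_maintenance_reaction)
            except KeyError:
                raise ConfigurationError(
                    f"atp_maintenance > 0 but reaction "
                    f"{self.atp_maintenance_reaction!r} is absent"
                ) from None
            rxn.lower_bound = float(self.atp_maintenance)
        return out


@dataclass
class FluxState:
    """One steady-state flux distribution and the objective value it attains."""

    fluxes: pd.Series
    objective_value: float

    def __getitem__(self, rid: str) -> float:
        return float(self.fluxes[rid])

    def to_frame(self) -> pd.DataFrame:
        return self.fluxes.rename("flux").to_frame()


@dataclass
class FluxRange:
    """Per-reaction attainable [lower, upper] flux under stated constraints."""

    frame: pd.DataFrame  # columns: lower, upper; index: reaction id

    def __post_init__(self) -> None:
        # guard against tiny solver inversions
        lo = self.frame[["lower", "upper"]].min(axis=1)
        hi = self.frame[["lower", "upper"]].max(axis=1)
        self.frame = pd.DataFrame({"lower": lo, "upper": hi})

    @property
    def lower(self) -> pd.Series:
        return self.frame["lower"]

    @property
    def upper(self) -> pd.Series:
        return self.frame["upper"]

    @property
    def midpoint(self) -> pd.Series:
        return (self.frame["lower"] + self.frame["upper"]) / 2.0

    def __getitem__(self, rid: str) -> tuple[float, float]:
        row = self.frame.loc[rid]
        return float(row["lower"]), float(row["upper"])


# ---------------------------------------------------------------------------
# model I/O
# ---------------------------------------------------------------------------

def _from_cobra(cm) -> MetabolicModel:
    mets = [Metabolite(m.id, m.compartment or "c", m.name or "") for m in cm.metabolites]
    rxns = []
    for r in cm.reactions:
        rxns.append(
            Reaction(
                id=r.id,
                metabolites={m.id: float(c) for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gene_reaction_rule=r.gene_reaction_rule or "",
                objective_coefficient=float(r.objective_coefficient),
                name=r.name or "",
                subsystem=r.subsystem or "",
            )
        )
    notes = dict(cm.notes) if cm.notes else {}
    return MetabolicModel(id=cm.id or "model", metabolites=mets, reactions=rxns, notes=notes)


def read_model(path: str | Path, fmt: str | None = None) -> MetabolicModel:
    """Read a metabolic model from ``model-json`` or ``sbml-fbc``.

    ``fmt`` is inferred from the extension when omitted (.json vs .xml/.sbml).
    """
    import cobra.io as cio

    path = Path(path)
    if fmt is None:
        fmt = "model-json" if path.suffix.lower() == ".json" else "sbml-fbc"
    if fmt not in ("model-json", "sbml-fbc"):
        raise ConfigurationError(f"unknown model format {fmt!r}")
    try:
        if fmt == "model-json":
            cm = cio.load_json_model(str(path))
        else:
            cm = cio.read_sbml_model(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    model = _from_cobra(cm)
    model.validate(require_objective=False)
    return model


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write the model in the community JSON dialect (lossless round-trip)."""
    mets_by_id = {m.id: m for m in model.metabolites}
    doc = {
        "id": model.id,
        "version": "1",
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": {k: r.metabolites[k] for k in sorted(r.metabolites)},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gene_reaction_rule,
                "objective_coefficient": r.objective_coefficient,
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
        "genes": [{"id": g, "name": g} for g in sorted(model.genes)],
        "compartments": {
            c: c for c in sorted({m.compartment for m in model.metabolites})
        },
        "notes": model.notes,
    }
    del mets_by_id
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=False) + "\n")


# ---------------------------------------------------------------------------
# linear programming
# ---------------------------------------------------------------------------

ExtraConstraint = tuple[Mapping[str, float], float | None, float | None]


class _Lp:
    """Assembled LP data for one (model, environment) pair."""

    def __init__(self, model: MetabolicModel, env: EnvironmentSpec | None):
        self.model = env.apply(model) if env is not None else model.copy()
        self.S, self.met_ids, self.rxn_ids = self.model.stoichiometric_matrix()
        self.pos = {rid: j for j, rid in enumerate(self.rxn_ids)}
        self.lb = np.array(
            [max(r.lower_bound, -BOUND_CAP) for r in self.model.reactions]
        )
        self.ub = np.array(
            [min(r.upper_bound, BOUND_CAP) for r in self.model.reactions]
        )
        self.n = len(self.rxn_ids)
        self.m = len(self.met_ids)

    def coef_vector(self, objective: Mapping[str, float]) -> np.ndarray:
        c = np.zeros(self.n)
        for rid, w in objective.items():
            if rid not in self.pos:
                raise KeyError(f"objective references unknown reaction {rid!r}")
            c[self.pos[rid]] = float(w)
        return c

    def solve(
        self,
        maximize: Mapping[str, float] | np.ndarray,
        extra: Sequence[ExtraConstraint] = (),
        minimize: bool = False,
    ) -> tuple[np.ndarray, float]:
        """Optimize a linear objective over the flux polytope; returns (v, value)."""
        c = maximize if isinstance(maximize, np.ndarray) else self.coef_vector(maximize)
        A_ub_rows, b_ub = [], []
        A_eq_rows, b_eq = [self.S], [np.zeros(self.m)]
        for coeffs, lo, hi in extra:
            row = sparse.csr_matrix(self.coef_vector(coeffs))
            if lo is not None and hi is not None and math.isclose(lo, hi, rel_tol=0, abs_tol=0):
                A_eq_rows.append(row)
                b_eq.append(np.array([lo]))
                continue
            if hi is not None:
                A_ub_rows.append(row)
                b_ub.append(hi)
            if lo is not None:
                A_ub_rows.append(-row)
                b_ub.append(-lo)
        A_eq = sparse.vstack(A_eq_rows, format="csr")
        beq = np.concatenate(b_eq)
        A_ub = sparse.vstack(A_ub_rows, format="csr") if A_ub_rows else None
        bub = np.array(b_ub) if b_ub else None
        sign = 1.0 if minimize else -1.0
        res = linprog(
            sign * c,
            A_ub=A_ub,
            b_ub=bub,
            A_eq=A_eq,
            b_eq=beq,
            bounds=list(zip(self.lb, self.ub)),
            method="highs",
        )
        if res.status == 2:
            raise InfeasibleError(
                "LP infeasible for model "
                f"{self.model.id!r}; check environment bounds (e.g. ATP maintenance "
                "versus maximal producible ATP) and expression-derived caps"
            )
        if res.status == 3:
            raise UnboundedError(f"LP unbounded for model {self.model.id!r}")
        if res.status != 0:
            raise InfeasibleError(f"LP solver failure (status {res.status}): {res.message}")
        return res.x, float(c @ res.x)

    def min_total_flux(
        self, extra: Sequence[ExtraConstraint] = ()
    ) -> np.ndarray:
        """Minimize Σ|v| via the standard v/t split; returns the flux vector."""
        n = self.n
        # variables: [v (n), t (n)]; minimize sum t; t >= |v|
        c = np.concatenate([np.zeros(n), np.ones(n)])
        eye = sparse.identity(n, format="csr")
        A_ub_rows = [
            sparse.hstack([eye, -eye], format="csr"),   # v - t <= 0
            sparse.hstack([-eye, -eye], format="csr"),  # -v - t <= 0
        ]
        b_ub = [np.zeros(n), np.zeros(n)]
        A_eq_rows = [sparse.hstack([self.S, sparse.csr_matrix((self.m, n))], format="csr")]
        b_eq = [np.zeros(self.m)]
        for coeffs, lo, hi in extra:
            row = self.coef_vector(coeffs)
            wide = sparse.csr_matrix(np.concatenate([row, np.zeros(n)]))
            if hi is not None:
                A_ub_rows.append(wide)
                b_ub.append(np.array([hi]))
            if lo is not None:
                A_ub_rows.append(-wide)
                b_ub.append(np.array([-lo]))
        bounds = list(zip(self.lb, self.ub)) + [(0.0, BOUND_CAP)] * n
        res = linprog(
            c,
            A_ub=sparse.vstack(A_ub_rows, format="csr"),
            b_ub=np.concatenate(b_ub),
            A_eq=sparse.vstack(A_eq_rows, format="csr"),
            b_eq=np.concatenate(b_eq),
            bounds=bounds,
            method="highs",
        )
        if res.status != 0:
            raise InfeasibleError(
                f"parsimonious LP failed (status {res.status}): {res.message}"
            )
        return res.x[: self.n]


def _fix_constraint(
    objective: Mapping[str, float], value: float, tol: float = FIX_TOL
) -> ExtraConstraint:
    """One-sided constraint pinning a maximization objective at its optimum."""
    slack = tol * max(abs(value), 1.0)
    return (objective, value - slack, None)


def fba(
    model: MetabolicModel,
    env: EnvironmentSpec | None = None,
    objective: Mapping[str, float] | None = None,
) -> FluxState:
    """Flux balance analysis: maximize the (model or supplied) objective."""
    lp = _Lp(model, env)
    obj = dict(objective) if objective is not None else lp.model.objective
    if not obj:
        raise ConfigurationError(f"model {model.id!r} has no objective to maximize")
    v, z = lp.solve(obj)
    return FluxState(pd.Series(v, index=lp.rxn_ids, name="flux"), z)


def pfba_reference(
    model: MetabolicModel,
    env: EnvironmentSpec | None = None,
    objective: Mapping[str, float] | None = None,
    fix_tol: float = FIX_TOL,
) -> FluxState:
    """Parsimonious FBA: the minimum-Σ|v| flux state at the FBA optimum.

    The optimum itself is unique; Σ|v| at the optimum is unique; the returned
    vertex is the deterministic HiGHS solution of the split LP.
    """
    lp = _Lp(model, env)
    obj = dict(objective) if objective is not None else lp.model.objective
    if not obj:
        raise ConfigurationError(f"model {model.id!r} has no objective to maximize")
    _, z = lp.solve(obj)
    v = lp.min_total_flux(extra=[_fix_constraint(obj, z, fix_tol)])
    return FluxState(pd.Series(v, index=lp.rxn_ids, name="flux"), z)


def fva(
    model: MetabolicModel,
    env: EnvironmentSpec | None = None,
    fix_objective_at: float | None = None,
    objective: Mapping[str, float] | None = None,
    reactions: Iterable[str] | None = None,
    extra_constraints: Sequence[ExtraConstraint] = (),
    fix_tol: float = FIX_TOL,
) -> FluxRange:
    """Flux variability analysis: per-reaction [min, max] attainable flux.

    With ``fix_objective_at`` set, the (model or supplied) objective is first
    pinned to that value, so the ranges describe the optimal face only.
    """
    lp = _Lp(model, env)
    extra = list(extra_constraints)
    if fix_objective_at is not None:
        obj = dict(objective) if objective is not None else lp.model.objective
        if not obj:
            raise ConfigurationError(
                "fix_objective_at given but the model has no objective"
            )
        extra.append(_fix_constraint(obj, float(fix_objective_at), fix_tol))
    rids = list(reactions) if reactions is not None else lp.rxn_ids
    lo, hi = [], []
    for rid in rids:
        if rid not in lp.pos:
            raise KeyError(f"FVA requested for unknown reaction {rid!r}")
        unit = np.zeros(lp.n)
        unit[lp.pos[rid]] = 1.0
        _, vmax = lp.solve(unit, extra=extra)
        _, vmin_neg = lp.solve(unit, extra=extra, minimize=True)
        lo.append(vmin_neg)
        hi.append(vmax)
    return FluxRange(pd.DataFrame({"lower": lo, "upper": hi}, index=rids))
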