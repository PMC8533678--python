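"""Gene-expression flux balance analysis (gx-FBA).

Integrates a differential-expression table into a constraint-based metabolic
model: each reaction receives an expression ratio C (treated/control) by
propagating per-gene fold changes through its GPR rule, and the stress flux
state is found by maximizing similarity between flux changes and those
expression changes.

Construction, for a model with reference environment ``ref_env`` and stress
environment ``stress_env``:

1. ``v_ref``  — parsimonious FBA reference flux state in ``ref_env``.
2. ``v_mean`` — per-reaction midpoint of the *unconstrained* FVA range in
   ``stress_env`` (no objective fixed): the "mean possible flux" used to
   normalize the objective so abundant and scarce reactions are comparable.
3. ``T``      — the constrained reaction set: reactions with a non-empty GPR
   touched by at least one significant gene, a combined ratio C ≠ 1, no
   up/down direction conflict among their significant genes, and
   |v_mean| ≥ ε.
4. For each reaction i ∈ T with direction d_i (sign of v_ref, falling back
   to the sign of v_mean when the reference flux is zero):
   * expression cap:   d_i·v_i ≤ C_i · max(|v_ref,i|, |v_mean,i|)
   * no direction flip: d_i·v_i ≥ 0
   * objective weight: log2(C_i) · d_i / |v_mean,i|
5. Maximize Z = Σ_{i∈T} w_i·v_i subject to steady state and the stress
   bounds; then fix Z at its optimum (relative tolerance 1e-6) and compute
   post-optimal FVA bounds (the stress flux ranges the classifier consumes)
   and a parsimonious representative stress flux state.

Genes with status ``ns`` are neutral throughout (value 1, no bound, no
objective term); secretion bounds are never modified. All policies (GPR
aggregation rules, ε, the cap) are explicit parameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dge import DETable
from .errors import InfeasibleError, UnboundedError
from .gpr import evaluate_gpr, gpr_genes
from .metnet import (
    EnvironmentSpec,
    FluxRange,
    FluxState,
    MetabolicModel,
    fva,
    pfba_reference,
)
from .metnet import _Lp, _fix_constraint  # internal LP plumbing shared on purpose

__all__ = [
    "ReactionRatioTable",
    "GxFbaProblem",
    "GxFbaResult",
    "reaction_ratios",
    "build_gxfba",
    "solve_gxfba",
]

logger = logging.getLogger(__name__)

_DUAL = {"min": "max", "max": "min", "mean": "mean"}


@dataclass
class ReactionRatioTable:
    """Per-reaction expression ratio C and membership in the constrained set."""

    frame: pd.DataFrame  # columns: C, in_T, conflict, n_significant_genes

    def ratio(self, rid: str) -> float:
        return float(self.frame.loc[rid, "C"])

    @property
    def constrained(self) -> list[str]:
        return list(self.frame.index[self.frame["in_T"]])


@dataclass
class GxFbaProblem:
    model: MetabolicModel            # stress-env applied, expression caps added
    stress_env: EnvironmentSpec
    v_ref: FluxState
    v_mean: pd.Series
    ratios: ReactionRatioTable
    T: list[str]
    direction: pd.Series             # +1/-1 per reaction in T
    objective: dict[str, float]      # log2(C)*d/|v_mean| per reaction in T
    epsilon: float
    diagnostics: dict = field(default_factory=dict)


@dataclass
class GxFbaResult:
    Z_star: float
    stress_flux: FluxState
    stress_range: FluxRange
    diagnostics: dict

    def to_frame(self, problem: GxFbaProblem) -> pd.DataFrame:
        """Reaction-level report: v_ref, C, T membership and stress bounds."""
        idx = problem.v_ref.fluxes.index
        return pd.DataFrame(
            {
                "v_ref": problem.v_ref.fluxes,
                "C": problem.ratios.frame["C"].reindex(idx),
                "in_T": problem.ratios.frame["in_T"].reindex(idx).fillna(False),
                "stress_lower": self.stress_range.lower.reindex(idx),
                "stress_upper": self.stress_range.upper.reindex(idx),
            },
            index=idx,
        )


def reaction_ratios(
    de: DETable,
    model: MetabolicModel,
    and_rule: str = "min",
    or_rule: str = "max",
    ratio_tol: float = 1e-9,
) -> ReactionRatioTable:
    """Map gene fold changes to per-reaction expression ratios via GPRs.

    Significant genes contribute 2^log2fc; non-significant and absent genes
    are neutral (1). AND combines with ``and_rule`` (complex semantics: the
    limiting subunit), OR with ``or_rule`` (isozyme semantics: the dominant
    isozyme). A reaction is excluded from the constrained set T when its GPR
    is empty, no significant gene touches it, C = 1, or its significant genes
    conflict in direction: both up- and down-regulated genes appear and the
    combined ratio lands on opposite sides of 1 depending on whether the
    chosen rules or their duals (min↔max swapped) are applied.
    """
    sig = de.frame[de.frame["status"].isin(["up", "down"])]
    gene_values = {g: float(2.0 ** lfc) for g, lfc in sig["log2fc"].items()}
    up_genes = set(sig.index[sig["status"] == "up"])
    down_genes = set(sig.index[sig["status"] == "down"])

    records = []
    for rxn in model.reactions:
        ast = rxn.gpr
        if ast is None:
            records.append((rxn.id, np.nan, False, False, 0))
            continue
        genes = gpr_genes(ast)
        sig_here = genes & (up_genes | down_genes)
        C = evaluate_gpr(ast, gene_values, and_rule, or_rule)
        conflict = False
        if (genes & up_genes) and (genes & down_genes):
            C_dual = evaluate_gpr(ast, gene_values, _DUAL[and_rule], _DUAL[or_rule])
            conflict = (C - 1.0) * (C_dual - 1.0) < -(ratio_tol**2)
        in_T = (
            bool(sig_here)
            and not conflict
            and abs(C - 1.0) > ratio_tol
        )
        records.append((rxn.id, C, in_T, conflict, len(sig_here)))
    frame = pd.DataFrame(
        records, columns=["reaction", "C", "in_T", "conflict", "n_significant_genes"]
    ).set_index("reaction")
    return ReactionRatioTable(frame)


def build_gxfba(
    model: MetabolicModel,
    ref_env: EnvironmentSpec,
    stress_env: EnvironmentSpec,
    de: DETable,
    and_rule: str = "min",
    or_rule: str = "max",
    epsilon: float = 1e-6,
    cap_relaxation: float = 1.0,
) -> GxFbaProblem:
    """Assemble the expression-similarity LP for the stress state.

    ``cap_relaxation`` multiplies every expression-derived cap; raise it above
    1 if the capped problem turns out infeasible for a given model/environment
    combination.
    """
    v_ref = pfba_reference(model, ref_env)
    stress_free = fva(model, stress_env, fix_objective_at=None)
    v_mean = stress_free.midpoint
    ratios = reaction_ratios(de, model, and_rule=and_rule, or_rule=or_rule)

    small_vmean = [
        rid for rid in ratios.constrained if abs(float(v_mean[rid])) < epsilon
    ]
    T = [rid for rid in ratios.constrained if rid not in set(small_vmean)]

    stress_model = stress_env.apply(model)
    direction = {}
    objective = {}
    for rid in T:
        vr = float(v_ref.fluxes[rid])
        vm = float(v_mean[rid])
        d = math.copysign(1.0, vr) if abs(vr) >= epsilon else math.copysign(1.0, vm)
        direction[rid] = d
        C = ratios.ratio(rid)
        objective[rid] = math.log2(C) * d / abs(vm)
        cap = cap_relaxation * C * max(abs(vr), abs(vm))
        rxn = stress_model.reaction(rid)
        if d > 0:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
            rxn.upper_bound = min(rxn.upper_bound, cap)
        else:
            rxn.upper_bound = min(rxn.upper_bound, 0.0)
            rxn.lower_bound = max(rxn.lower_bound, -cap)
        if rxn.lower_bound > rxn.upper_bound:  # cap collided with model bounds
            rxn.lower_bound = rxn.upper_bound = 0.0

    # feasibility probe with the caps in place
    try:
        _Lp(stress_model, None).solve(np.zeros(len(stress_model.reactions)))
    except InfeasibleError as exc:
        raise InfeasibleError(
            "stress LP infeasible after applying expression bounds; consider "
            "raising cap_relaxation in the run configuration"
        ) from exc

    diagnostics = {
        "n_reactions": len(model.reactions),
        "n_constrained": len(T),
        "n_conflicts": int(ratios.frame["conflict"].sum()),
        "n_empty_gpr": int(ratios.frame["C"].isna().sum()),
        "n_small_vmean_excluded": len(small_vmean),
    }
    return GxFbaProblem(
        model=stress_model,
        stress_env=stress_env,
        v_ref=v_ref,
        v_mean=v_mean,
        ratios=ratios,
        T=T,
        direction=pd.Series(direction, dtype=float),
        objective=objective,
        epsilon=epsilon,
        diagnostics=diagnostics,
    )


def solve_gxfba(problem: GxFbaProblem, z_tol: float = 1e-6) -> GxFbaResult:
    """Maximize expression similarity, then bound every flux at that optimum.

    Returns the optimal similarity Z*, post-optimal per-reaction flux ranges
    (FVA with Z fixed at Z* within relative ``z_tol``) and a parsimonious
    representative stress flux state. With an empty constrained set the
    objective is identically zero and the ranges equal the plain
    stress-environment FVA.
    """
    lp = _Lp(problem.model, None)
    if problem.objective:
        try:
            v, z_star = lp.solve(problem.objective)
        except UnboundedError:
            culprits = [
                rid
                for rid, w in problem.objective.items()
                if w > 0 and problem.model.reaction(rid).upper_bound >= 1e4
            ]
            raise UnboundedError(
                f"gx-FBA objective unbounded; suspect reactions: {culprits}"
            ) from None
        extra = [_fix_constraint(problem.objective, z_star, z_tol / 2)]
    else:
        z_star = 0.0
        extra = []

    rng = fva(problem.model, None, extra_constraints=extra)
    flux = lp.min_total_flux(extra=extra)
    state = FluxState(pd.Series(flux, index=lp.rxn_ids, name="flux"), z_star)

    z_check = sum(w * float(state.fluxes[rid]) for rid, w in problem.objective.items())
    diagnostics = dict(problem.diagnostics)
    diagnostics.update(Z_star=z_star, Z_recomputed=z_check)
    if abs(z_check - z_star) > z_tol * max(abs(z_star), 1.0):
        logger.warning(
            "parsimonious stress flux attains Z=%g, expected %g", z_check, z_star
        )
    return GxFbaResult(
        Z_star=z_star, stress_flux=state, stress_range=rng, diagnostics=diagnostics
    )
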