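"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written *without* reusing the package's code
paths: LP questions are answered by enumerating polytope vertices, the
four-way flux-category rules are transcribed directly, and GPR rules are
evaluated by Python's own boolean-operator machinery over value-wrapping
objects. Slow and simple on purpose; only usable at toy scale.
"""

from __future__ import annotations

import re
from itertools import combinations, product

import numpy as np


def enumerate_vertices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    """All vertices of {v : S v = 0, lb <= v <= ub} (bounded, small n only)."""
    S = np.asarray(S, dtype=float)
    m, n = S.shape
    rank = np.linalg.matrix_rank(S)
    free = n - rank
    verts: list[np.ndarray] = []
    for idx in combinations(range(n), free):
        rest = [j for j in range(n) if j not in idx]
        A = S[:, rest]
        for vals in product(*[(lb[j], ub[j]) for j in idx]):
            fixed = np.array(vals, dtype=float)
            b = -S[:, list(idx)] @ fixed
            sol, *_ = np.linalg.lstsq(A, b, rcond=None)
            v = np.empty(n)
            v[list(idx)] = fixed
            v[rest] = sol
            if np.max(np.abs(S @ v)) > 1e-8:
                continue
            if np.any(v < lb - 1e-9) or np.any(v > ub + 1e-9):
                continue
            verts.append(np.clip(v, lb, ub))
    if not verts:
        return np.empty((0, n))
    arr = np.array(verts)
    # dedupe
    uniq = [arr[0]]
    for v in arr[1:]:
        if all(np.max(np.abs(v - u)) > 1e-7 for u in uniq):
            uniq.append(v)
    return np.array(uniq)


def model_polytope(model) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Dense S, capped bounds and reaction order for a package model."""
    S, _, rxn_ids = model.stoichiometric_matrix()
    lb = np.array([max(r.lower_bound, -1e4) for r in model.reactions])
    ub = np.array([min(r.upper_bound, 1e4) for r in model.reactions])
    return S.toarray(), lb, ub, rxn_ids


def brute_fba(model, objective: dict[str, float]) -> tuple[float, np.ndarray]:
    """Max of a linear objective over the flux polytope by vertex enumeration."""
    S, lb, ub, rxn_ids = model_polytope(model)
    verts = enumerate_vertices(S, lb, ub)
    c = np.zeros(len(rxn_ids))
    for rid, w in objective.items():
        c[rxn_ids.index(rid)] = w
    vals = verts @ c
    best = int(np.argmax(vals))
    return float(vals[best]), verts[best]


def brute_fva(
    model, objective: dict[str, float] | None, fix_at: float | None, tol: float = 1e-7
) -> dict[str, tuple[float, float]]:
    """Per-reaction flux ranges via vertex enumeration.

    With ``fix_at`` set, only vertices attaining that objective value stay:
    the extreme points of the optimal face are polytope vertices.
    """
    S, lb, ub, rxn_ids = model_polytope(model)
    verts = enumerate_vertices(S, lb, ub)
    if fix_at is not None:
        c = np.zeros(len(rxn_ids))
        for rid, w in (objective or {}).items():
            c[rxn_ids.index(rid)] = w
        verts = verts[np.abs(verts @ c - fix_at) <= tol * max(abs(fix_at), 1.0)]
    return {
        rid: (float(verts[:, j].min()), float(verts[:, j].max()))
        for j, rid in enumerate(rxn_ids)
    }


def classify_one(v_ref: float, lo: float, hi: float, eps: float) -> str:
    """Direct transcription of the four category rules."""
    carries_no_flux_unstressed = abs(v_ref) < eps
    cannot_carry_flux_stressed = abs(lo) < eps and abs(hi) < eps
    if carries_no_flux_unstressed and cannot_carry_flux_stressed:
        return "no_flux"
    if hi < v_ref - eps:  # stress upper bound below the unstressed flux
        return "down"
    if lo > v_ref + eps:  # stress lower bound above the unstressed flux
        return "up"
    return "ambiguous"  # unstressed flux falls between the bounds


class _Val:
    """Value wrapper whose & / | implement the chosen AND / OR semantics."""

    def __init__(self, x, and_fn, or_fn):
        self.x, self.and_fn, self.or_fn = x, and_fn, or_fn

    def __and__(self, other):
        return _Val(self.and_fn(self.x, other.x), self.and_fn, self.or_fn)

    def __or__(self, other):
        return _Val(self.or_fn(self.x, other.x), self.and_fn, self.or_fn)


def eval_rule_independent(rule, values, and_fn=min, or_fn=max, neutral=1.0):
    """Evaluate a GPR rule via Python's own expression evaluator."""
    expr = re.sub(r"\band\b", "&", rule, flags=re.IGNORECASE)
    expr = re.sub(r"\bor\b", "|", expr, flags=re.IGNORECASE)
    genes = set(re.findall(r"\b(?!and\b|or\b)\w+\b", rule, flags=re.IGNORECASE))
    ns = {g: _Val(float(values.get(g, neutral)), and_fn, or_fn) for g in genes}
    return eval(expr, {"__builtins__": {}}, ns).x  # noqa: S307 - test oracle
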