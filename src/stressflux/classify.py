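"""Four-way classification of reaction fluxes under stress.

Given the unstressed reference flux of every reaction and the [lower, upper]
flux bounds returned by the expression-constrained stress optimization, each
reaction falls into exactly one of four categories:

* ``no_flux``   — carries no flux unstressed and cannot carry flux under
  stress (|v_ref| < ε and max(|L|, |U|) < ε);
* ``down``      — the stress upper bound lies below the unstressed flux
  (U < v_ref − ε), so the flux must decrease;
* ``up``        — the stress lower bound lies above the unstressed flux
  (L > v_ref + ε), so the flux must increase;
* ``ambiguous`` — the unstressed flux falls inside [L, U]; no regulation
  direction is forced by the expression data.

``no_flux`` is checked first because its definition overlaps ``ambiguous``
when everything is zero. Comparisons are signed by default (bounds against
the signed unstressed flux); a magnitude mode is available for sensitivity
analysis on reversible reactions, where the two conventions disagree.

The module also builds cross-condition summaries: per-reaction medians over
many conditions ("generic response"), pairwise category-overlap tables, and
a pathway color-map export (green up / red down / yellow ambiguous; no-flux
reactions omitted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError
from .metnet import FluxRange, FluxState

__all__ = [
    "LABELS",
    "ReactionClassification",
    "GenericResponse",
    "classify_reactions",
    "generic_response",
    "overlap_table",
    "category_counts",
    "export_pathway_colors",
]

logger = logging.getLogger(__name__)

LABELS = ("up", "down", "ambiguous", "no_flux")

COLORS = {"up": "#00FF00", "down": "#FF0000", "ambiguous": "#FFFF00"}


@dataclass
class ReactionClassification:
    frame: pd.DataFrame  # columns: label, v_ref, lower, upper; index: reaction
    epsilon: float

    @property
    def labels(self) -> pd.Series:
        return self.frame["label"]

    @property
    def counts(self) -> dict[str, int]:
        vc = self.frame["label"].value_counts()
        return {lab: int(vc.get(lab, 0)) for lab in LABELS}

    @property
    def total(self) -> int:
        return len(self.frame)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.rename_axis("reaction").to_csv(path, sep="\t")


@dataclass
class GenericResponse:
    """Elementwise medians across conditions plus their classification."""

    median_reference: pd.Series
    median_range: FluxRange
    classification: ReactionClassification


def classify_reactions(
    v_ref: FluxState | pd.Series,
    stress: FluxRange,
    epsilon: float = 1e-6,
    magnitude: bool = False,
) -> ReactionClassification:
    """Label every reaction ``no_flux`` / ``down`` / ``up`` / ``ambiguous``."""
    if epsilon < 0:
        raise ConfigurationError(f"epsilon must be >= 0, got {epsilon}")
    ref = v_ref.fluxes if isinstance(v_ref, FluxState) else v_ref
    missing = set(ref.index).symmetric_difference(stress.frame.index)
    if missing:
        raise FormatError(
            f"reference fluxes and stress ranges disagree on reactions: {sorted(missing)[:5]}"
        )
    ref = ref.reindex(stress.frame.index)
    lo = stress.lower.to_numpy(dtype=float)
    hi = stress.upper.to_numpy(dtype=float)
    v = ref.to_numpy(dtype=float)
    if magnitude:
        cmp_v = np.abs(v)
        cmp_lo = np.minimum(np.abs(lo), np.abs(hi))
        cmp_hi = np.maximum(np.abs(lo), np.abs(hi))
    else:
        cmp_v, cmp_lo, cmp_hi = v, lo, hi
    no_flux = (np.abs(v) < epsilon) & (np.maximum(np.abs(lo), np.abs(hi)) < epsilon)
    down = cmp_hi < cmp_v - epsilon
    up = cmp_lo > cmp_v + epsilon
    label = np.where(no_flux, "no_flux", np.where(down, "down", np.where(up, "up", "ambiguous")))
    frame = pd.DataFrame(
        {"label": label, "v_ref": v, "lower": lo, "upper": hi}, index=stress.frame.index
    )
    return ReactionClassification(frame, epsilon=float(epsilon))


def generic_response(
    results: Sequence[tuple[FluxState, FluxRange]],
    epsilon: float = 1e-6,
    magnitude: bool = False,
) -> GenericResponse:
    """Median reference flux and stress bounds across conditions, classified.

    The median with an even number of conditions is the mean of the two
    middle values, so for a single condition the medians are that condition's
    own values.
    """
    if len(results) == 0:
        raise ConfigurationError("generic_response needs at least one condition")
    index = results[0][1].frame.index
    refs, los, his = [], [], []
    for state, rng in results:
        fx = state.fluxes if isinstance(state, FluxState) else state
        if set(fx.index) != set(index) or set(rng.frame.index) != set(index):
            raise FormatError("conditions do not share a reaction vocabulary")
        refs.append(fx.reindex(index).to_numpy(dtype=float))
        los.append(rng.lower.reindex(index).to_numpy(dtype=float))
        his.append(rng.upper.reindex(index).to_numpy(dtype=float))
    med_ref = pd.Series(np.median(refs, axis=0), index=index, name="flux")
    med_rng = FluxRange(
        pd.DataFrame(
            {"lower": np.median(los, axis=0), "upper": np.median(his, axis=0)},
            index=index,
        )
    )
    cls = classify_reactions(med_ref, med_rng, epsilon=epsilon, magnitude=magnitude)
    return GenericResponse(med_ref, med_rng, cls)


def overlap_table(
    a: ReactionClassification, b: ReactionClassification
) -> pd.DataFrame:
    """4×4 contingency of labels: rows = condition A, columns = condition B."""
    if set(a.frame.index) != set(b.frame.index):
        raise FormatError("classifications do not share a reaction vocabulary")
    bl = b.labels.reindex(a.frame.index)
    table = pd.crosstab(a.labels, bl).reindex(index=LABELS, columns=LABELS, fill_value=0)
    table.index.name = "a"
    table.columns.name = "b"
    return table.astype(int)


def category_counts(c: ReactionClassification) -> pd.Series:
    """One summary row: up, down, ambiguous, no_flux and their total."""
    counts = c.counts
    row = {lab: counts[lab] for lab in LABELS}
    row["total"] = sum(counts.values())
    return pd.Series(row, dtype=int)


def export_pathway_colors(
    c: ReactionClassification,
    pathway_map: Mapping[str, str],
    path: str | Path,
) -> pd.DataFrame:
    """Write a (pathway id, hex color) TSV for pathway-map painting.

    Up-regulated reactions are green, down-regulated red, ambiguous yellow;
    no-flux reactions are omitted. Reactions absent from ``pathway_map`` are
    logged and skipped; an empty map yields an empty file with a warning.
    """
    rows = []
    if not pathway_map:
        logger.warning("empty reaction→pathway map; writing an empty color file")
    for rid, label in c.labels.items():
        if label == "no_flux":
            continue
        if rid not in pathway_map:
            logger.warning("reaction %s has no pathway id; skipped", rid)
            continue
        rows.append((pathway_map[rid], COLORS[label]))
    out = pd.DataFrame(rows, columns=["pathway_id", "color"])
    out.to_csv(path, sep="\t", index=False)
    return out
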