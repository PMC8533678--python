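"""Seeded synthetic inputs for every pipeline stage.

Two generators:

* :func:`simulate_counts` — negative-binomial RNA-seq count matrices with a
  planted differential-expression signal. The defaults emulate the study
  design the pipeline targets: ~3,900 expressed genes, four control and four
  treated replicates, ~18% of genes differentially expressed with absolute
  fold changes concentrated in 3.5–30 and 58% of them up-regulated, library
  sizes of ten million reads with a 20% coefficient of variation.
* :func:`generate_toy_model` — small metabolic networks (a linear chain, a
  branched network with routes of unequal yield, and a chain with a futile
  cycle) with known analytic FBA optima recorded in the model notes, standing
  in for a genome-scale model at desk scale. Every variant has an exchange
  reaction, an objective reaction and at least one multi-gene GPR.

:func:`generate_condition_set` fabricates per-condition DE tables over a toy
model's genes, emulating a panel of stress transcriptomes for the
generic-response machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dge import CountMatrix, DETable
from .errors import ConfigurationError
from .metnet import MetabolicModel, Metabolite, Reaction

__all__ = [
    "SimCountSpec",
    "PlantedTruth",
    "ToyNetworkSpec",
    "simulate_counts",
    "generate_toy_model",
    "generate_condition_set",
]

TOY_VARIANTS = ("chain", "branched", "reversible")


@dataclass
class SimCountSpec:
    """Parameters of the synthetic count-matrix generator.

    The negative binomial is parameterized by its mean μ and a single common
    dispersion φ, variance = μ + φμ². Planted |log2 fold changes| are uniform
    on [log2(fc_low), log2(fc_high)], signed up with probability ``up_share``.
    """

    n_genes: int = 3898
    n_reps_per_group: int = 4
    library_size_mean: float = 1e7
    library_size_cv: float = 0.2
    dispersion: float = 0.1
    de_fraction: float = 0.182
    fc_low: float = 3.5
    fc_high: float = 30.0
    up_share: float = 0.58
    abundance_sigma: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError(f"n_genes must be positive, got {self.n_genes}")
        if self.n_reps_per_group < 1:
            raise ConfigurationError(
                f"n_reps_per_group must be positive, got {self.n_reps_per_group}"
            )
        if self.library_size_mean <= 0:
            raise ConfigurationError(
                f"library_size_mean must be positive, got {self.library_size_mean}"
            )
        if self.library_size_cv < 0:
            raise ConfigurationError(
                f"library_size_cv must be >= 0, got {self.library_size_cv}"
            )
        if self.dispersion < 0:
            raise ConfigurationError(f"dispersion must be >= 0, got {self.dispersion}")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ConfigurationError(
                f"de_fraction must lie in [0, 1], got {self.de_fraction}"
            )
        if not (1.0 < self.fc_low <= self.fc_high):
            raise ConfigurationError(
                f"need 1 < fc_low <= fc_high, got fc_low={self.fc_low}, fc_high={self.fc_high}"
            )
        if not (0.0 <= self.up_share <= 1.0):
            raise ConfigurationError(f"up_share must lie in [0, 1], got {self.up_share}")

    @property
    def n_de(self) -> int:
        return int(round(self.de_fraction * self.n_genes))


@dataclass
class PlantedTruth:
    """Ground truth of the planted signal: per-gene status and true log2 FC."""

    frame: pd.DataFrame  # columns: status, true_log2fc; index: gene

    @property
    def counts(self) -> dict[str, int]:
        vc = self.frame["status"].value_counts()
        return {k: int(vc.get(k, 0)) for k in ("up", "down", "ns")}

    def to_tsv(self, path: str | Path) -> None:
        self.frame.rename_axis("gene").to_csv(path, sep="\t")


@dataclass
class ToyNetworkSpec:
    variant: str = "chain"
    uptake_bound: float = 10.0
    atp_maintenance: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.variant not in TOY_VARIANTS:
            raise ConfigurationError(
                f"unknown toy-network variant {self.variant!r}; choose from {TOY_VARIANTS}"
            )
        if self.uptake_bound <= 0:
            raise ConfigurationError(
                f"uptake_bound must be positive, got {self.uptake_bound}"
            )
        if self.atp_maintenance < 0:
            raise ConfigurationError(
                f"atp_maintenance must be >= 0, got {self.atp_maintenance}"
            )


def simulate_counts(spec: SimCountSpec) -> tuple[CountMatrix, PlantedTruth]:
    """Draw a seeded count matrix with planted differential expression.

    Per-gene relative abundances are log-normal; library sizes are log-normal
    around ``library_size_mean`` (so TMM has real work to do); treated-group
    means of the planted DE genes are the control means scaled by
    2^(true log2 FC). Identical specs reproduce identical matrices.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, reps = spec.n_genes, spec.n_reps_per_group
    genes = [f"gene_{i + 1:05d}" for i in range(n)]
    samples = [f"control_{j + 1}" for j in range(reps)] + [
        f"treated_{j + 1}" for j in range(reps)
    ]
    design = pd.Series(["control"] * reps + ["treated"] * reps, index=samples)

    abundance = rng.lognormal(mean=0.0, sigma=spec.abundance_sigma, size=n)
    abundance /= abundance.sum()

    n_de = spec.n_de
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    n_up = int(round(spec.up_share * n_de))
    lfc = np.zeros(n)
    status = np.full(n, "ns", dtype=object)
    if n_de:
        mags = rng.uniform(math.log2(spec.fc_low), math.log2(spec.fc_high), size=n_de)
        signs = np.concatenate([np.ones(n_up), -np.ones(n_de - n_up)])
        lfc[de_idx] = mags * signs
        status[de_idx[:n_up]] = "up"
        status[de_idx[n_up:]] = "down"

    if spec.library_size_cv > 0:
        sigma2 = math.log1p(spec.library_size_cv**2)
        mu = math.log(spec.library_size_mean) - sigma2 / 2.0
        lib = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=2 * reps)
    else:
        lib = np.full(2 * reps, spec.library_size_mean)

    treated_abundance = abundance * 2.0**lfc
    mean = np.empty((n, 2 * reps))
    mean[:, :reps] = abundance[:, None] * lib[:reps]
    mean[:, reps:] = treated_abundance[:, None] * lib[reps:]

    if spec.dispersion > 0:
        r = 1.0 / spec.dispersion
        p = r / (r + mean)
        counts = rng.negative_binomial(r, p)
    else:
        counts = rng.poisson(mean)

    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), design)
    truth = PlantedTruth(
        pd.DataFrame({"status": status, "true_log2fc": lfc}, index=genes)
    )
    return cm, truth


def _chain_reactions(uptake: float, maintenance: float) -> list[Reaction]:
    return [
        Reaction("EX_a", {"a_c": -1.0}, -uptake, 0.0, name="A exchange"),
        Reaction("R1", {"a_c": -1.0, "b_c": 1.0}, 0.0, 1000.0, "g1"),
        Reaction("R2", {"b_c": -1.0, "c_c": 1.0}, 0.0, 1000.0, "g2 and g3"),
        Reaction("ATPM", {"b_c": -1.0}, maintenance, 1000.0, name="maintenance drain"),
        Reaction(
            "BIOMASS", {"c_c": -1.0}, 0.0, 1000.0, objective_coefficient=1.0,
            name="biomass sink",
        ),
    ]


def generate_toy_model(spec: ToyNetworkSpec) -> MetabolicModel:
    """Build one of the three documented toy networks.

    The analytic FBA optimum of each variant is recorded in
    ``model.notes["fba_optimum"]``:

    * ``chain``      — A → B → C with a maintenance drain on B;
      optimum = uptake − maintenance.
    * ``branched``   — A converts to B via a yield-1 route (``HI``) or a
      yield-0.5 route (``LO``); optimum = uptake − maintenance, all flux on
      ``HI``.
    * ``reversible`` — the chain plus a futile cycle B ↔ D of bound 5; the
      cycle never affects the optimum, and its reactions have FVA width equal
      to the cycle bound at the fixed optimum.
    """
    spec.validate()
    u, m = float(spec.uptake_bound), float(spec.atp_maintenance)
    mets = [Metabolite("a_c"), Metabolite("b_c"), Metabolite("c_c")]
    if spec.variant == "chain":
        rxns = _chain_reactions(u, m)
    elif spec.variant == "branched":
        mets = [Metabolite("a_c"), Metabolite("b_c")]
        rxns = [
            Reaction("EX_a", {"a_c": -1.0}, -u, 0.0, name="A exchange"),
            Reaction("HI", {"a_c": -1.0, "b_c": 1.0}, 0.0, 1000.0, "g2", name="yield-1 route"),
            Reaction(
                "LO", {"a_c": -1.0, "b_c": 0.5}, 0.0, 1000.0, "g4 or g5",
                name="yield-0.5 route",
            ),
            Reaction("ATPM", {"b_c": -1.0}, m, 1000.0, name="maintenance drain"),
            Reaction(
                "BIOMASS", {"b_c": -1.0}, 0.0, 1000.0, objective_coefficient=1.0,
                name="biomass sink",
            ),
        ]
    else:  # reversible
        mets = mets + [Metabolite("d_c")]
        cycle_bound = 5.0
        rxns = _chain_reactions(u, m) + [
            Reaction("CYC1", {"b_c": -1.0, "d_c": 1.0}, -cycle_bound, cycle_bound, "g6"),
            Reaction("CYC2", {"d_c": -1.0, "b_c": 1.0}, 0.0, cycle_bound, "g7"),
        ]
    model = MetabolicModel(
        id=f"toy_{spec.variant}",
        metabolites=mets,
        reactions=rxns,
        notes={
            "variant": spec.variant,
            "uptake_bound": u,
            "atp_maintenance": m,
            "fba_optimum": u - m,
            "seed": spec.seed,
        },
    )
    model.validate()
    return model


def generate_condition_set(
    model: MetabolicModel,
    n_conditions: int,
    seed: int,
    de_prob: float = 0.5,
    fc_low: float = 3.5,
    fc_high: float = 30.0,
    always_up: Sequence[str] = (),
    always_down: Sequence[str] = (),
) -> list[tuple[DETable, str]]:
    """Synthetic per-condition DE tables over the model's GPR genes.

    Each condition marks each model gene significant with probability
    ``de_prob`` (at least one gene is always significant), drawing |log2 FC|
    uniform on [log2(fc_low), log2(fc_high)] with random sign. Genes listed
    in ``always_up``/``always_down`` are planted with that status in *every*
    condition — the hook for generic-response recovery experiments.
    """
    if n_conditions < 1:
        raise ConfigurationError(f"n_conditions must be >= 1, got {n_conditions}")
    genes = sorted(model.genes)
    if not genes:
        raise ConfigurationError(
            f"model {model.id!r} has no gene associations; cannot build condition DE tables"
        )
    unknown = (set(always_up) | set(always_down)) - set(genes)
    if unknown:
        raise ConfigurationError(f"planted genes absent from the model: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    lo, hi = math.log2(fc_low), math.log2(fc_high)
    out = []
    for i in range(n_conditions):
        sig = rng.random(len(genes)) < de_prob
        if not sig.any():
            sig[rng.integers(len(genes))] = True
        mags = rng.uniform(lo, hi, size=len(genes))
        signs = np.where(rng.random(len(genes)) < 0.5, 1.0, -1.0)
        lfc = np.where(sig, mags * signs, 0.0)
        for g in always_up:
            j = genes.index(g)
            sig[j], lfc[j] = True, abs(mags[j])
        for g in always_down:
            j = genes.index(g)
            sig[j], lfc[j] = True, -abs(mags[j])
        status = np.where(~sig, "ns", np.where(lfc > 0, "up", "down"))
        frame = pd.DataFrame(
            {
                "log2fc": lfc,
                "fold_change_signed": np.where(
                    lfc == 0, 1.0, np.sign(lfc) * 2.0 ** np.abs(lfc)
                ),
                "p_value": np.where(sig, 1e-3, 0.5),
                "status": status,
            },
            index=pd.Index(genes, name="gene"),
        )
        out.append((DETable(frame), f"condition_{i + 1}"))
    return out
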