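"""Differential gene expression between control and treated groups.

The stage mirrors the classical count-based RNA-seq workflow: between-sample
TMM normalization (trimmed mean of M-values), a single common negative
binomial dispersion estimated by conditional maximum likelihood, and the NB
exact conditional test on normalized group sums. Significance is called at a
raw p-value cutoff (default α = 0.05, no multiple-testing correction; an
optional Benjamini–Hochberg flag is available but off by default).

Fold changes are reported both as log2 values and in the signed convention
common in microbial stress-response tables: +FC for up-regulated genes and
−FC for down-regulated ones, where FC = 2^|log2FC|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import rankdata

from .errors import ConfigurationError, FormatError

__all__ = [
    "CountMatrix",
    "NormFactors",
    "DETable",
    "DESummary",
    "tmm_factors",
    "estimate_common_dispersion",
    "exact_test",
    "summarize_de",
    "top_regulated",
]

GROUPS = ("control", "treated")


@dataclass
class CountMatrix:
    """Gene × sample integer counts plus the sample → group design.

    ``counts`` is a DataFrame (rows = genes, columns = samples); ``design``
    maps every sample id to ``"control"`` or ``"treated"``.
    """

    counts: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64, copy=False)
        self.design = self.design.reindex(self.counts.columns)
        self.validate()

    def validate(self) -> None:
        if self.counts.index.has_duplicates:
            raise FormatError("duplicate gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise FormatError("duplicate sample ids in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("count matrix contains negative entries")
        if self.design.isna().any():
            missing = list(self.design.index[self.design.isna()])
            raise FormatError(f"samples without a group assignment: {missing}")
        bad = set(self.design.unique()) - set(GROUPS)
        if bad:
            raise FormatError(f"unknown groups {sorted(bad)}; expected {GROUPS}")
        for g in GROUPS:
            if (self.design == g).sum() < 1:
                raise FormatError(f"no samples assigned to group {g!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def samples_in(self, group: str) -> list[str]:
        return list(self.design.index[self.design == group])

    def drop_all_zero_genes(self) -> "CountMatrix":
        keep = self.counts.sum(axis=1) > 0
        return CountMatrix(self.counts.loc[keep], self.design.copy())

    # --- I/O -------------------------------------------------------------
    def to_tsv(self, counts_path: str | Path, design_path: str | Path) -> None:
        self.counts.rename_axis("gene").to_csv(counts_path, sep="\t")
        self.design.rename("group").rename_axis("sample").to_csv(design_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, design_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        design = pd.read_csv(design_path, sep="\t", index_col=0)["group"]
        return cls(counts, design)


@dataclass
class NormFactors:
    """Per-sample TMM scaling factors, geometric mean 1."""

    factors: pd.Series
    reference_sample: str

    def effective_sizes(self, counts: CountMatrix) -> pd.Series:
        return counts.library_sizes * self.factors


@dataclass
class DETable:
    """Per-gene differential-expression calls (treated vs control)."""

    frame: pd.DataFrame  # columns: log2fc, fold_change_signed, p_value, status
    alpha: float = 0.05

    REQUIRED = ("log2fc", "fold_change_signed", "p_value", "status")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise FormatError(f"DE table missing column {col!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)

    def genes_with_status(self, status: str) -> pd.DataFrame:
        return self.frame[self.frame["status"] == status]

    def to_tsv(self, path: str | Path) -> None:
        self.frame.rename_axis("gene").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, alpha: float = 0.05) -> "DETable":
        return cls(pd.read_csv(path, sep="\t", index_col="gene"), alpha=alpha)


@dataclass
class DESummary:
    n_total: int
    n_de: int
    n_up: int
    n_down: int
    pct_de: float
    pct_up_of_de: float
    pct_down_of_de: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("Mapped genes", self.n_total, 100.0),
            ("Differentially expressed genes", self.n_de, self.pct_de),
            ("Up-regulated", self.n_up, self.pct_up_of_de),
            ("Down-regulated", self.n_down, self.pct_down_of_de),
        ]
        return pd.DataFrame(rows, columns=["quantity", "count", "percent"])


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Weighted doubly-trimmed mean of M-values of one sample vs the reference.

    M = log2 relative-abundance ratio, A = average log2 abundance; genes are
    trimmed symmetrically by M (default 30% per tail) and by A (default 5%),
    the surviving M-values averaged with inverse approximate binomial
    variance weights, and the result returned on the linear scale.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2((obs / n_obs) / (ref / n_ref))
        a = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(m) & np.isfinite(a) & (a > -1e10)
    m, a, v = m[fin], a[fin], v[fin]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.nansum(m[keep] / v[keep]) / np.nansum(1.0 / v[keep])
    return float(2.0**f) if np.isfinite(f) else 1.0


def tmm_factors(
    counts: CountMatrix, trim_m: float = 0.3, trim_a: float = 0.05
) -> NormFactors:
    """TMM normalization factors against an automatically chosen reference.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of that quantity across samples. Factors are rescaled
    to geometric mean 1, so effective library size = library size × factor.
    """
    for name, t in (("trim_m", trim_m), ("trim_a", trim_a)):
        if not (0.0 <= t < 0.5):
            raise ConfigurationError(f"{name} must lie in [0, 0.5), got {t}")
    if len(counts.sample_ids) < 2:
        raise ConfigurationError("TMM requires at least two samples")
    lib = counts.library_sizes.to_numpy(dtype=float)
    if (lib <= 0).any():
        bad = [s for s, tot in counts.library_sizes.items() if tot <= 0]
        raise FormatError(f"samples with all-zero counts: {bad}")
    mat = counts.counts.to_numpy(dtype=float)
    mat = mat[mat.sum(axis=1) > 0]  # drop all-zero genes; column sums unchanged
    f75 = np.quantile(mat / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair(mat[:, j], mat[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
            for j in range(mat.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(
        pd.Series(factors, index=counts.sample_ids, name="tmm_factor"),
        reference_sample=counts.sample_ids[ref_idx],
    )


# ---------------------------------------------------------------------------
# common dispersion
# ---------------------------------------------------------------------------

def _adjusted_counts(counts: CountMatrix, norm: NormFactors) -> pd.DataFrame:
    """Counts rescaled to the geometric-mean effective library size."""
    eff = norm.effective_sizes(counts)
    target = float(np.exp(np.mean(np.log(eff))))
    return counts.counts * (target / eff)


def _group_cond_loglik(y: np.ndarray, phi: float) -> float:
    """Conditional NB log-likelihood of replicate rows given their row sums.

    For n iid NB(mean μ, dispersion φ) replicates the distribution of the
    vector given its sum is negative hypergeometric and free of μ, which makes
    it the natural criterion for a common dispersion. φ → 0 recovers the
    multinomial (Poisson) limit.
    """
    n = y.shape[1]
    z = y.sum(axis=1)
    if phi <= 0:
        # symmetric multinomial limit
        return float(
            np.sum(gammaln(z + 1) - gammaln(y + 1).sum(axis=1) - z * np.log(n))
        )
    r = 1.0 / phi
    per_cell = gammaln(y + r) - gammaln(r) - gammaln(y + 1)
    denom = gammaln(z + n * r) - gammaln(n * r) - gammaln(z + 1)
    return float(np.sum(per_cell.sum(axis=1) - denom))


def estimate_common_dispersion(
    counts: CountMatrix,
    norm: NormFactors,
    grid_max: float = 5.0,
    grid_step: float = 1e-3,
) -> float:
    """Single common NB dispersion φ by conditional maximum likelihood.

    The conditional likelihood is profiled on [0, ``grid_max``]: a coarse
    geometric bracket first, then a uniform grid with step ``grid_step``
    inside the bracket. Returns 0.0 for underdispersed (sub-Poisson) data.
    """
    reps = {g: len(counts.samples_in(g)) for g in GROUPS}
    if max(reps.values()) < 2:
        raise ConfigurationError(
            "common dispersion needs >= 2 replicates in at least one group; "
            "supply a fixed dispersion via configuration instead"
        )
    adj = _adjusted_counts(counts, norm)
    groups = [
        adj[counts.samples_in(g)].to_numpy(dtype=float)
        for g in GROUPS
        if len(counts.samples_in(g)) >= 2
    ]

    def loglik(phi: float) -> float:
        return sum(_group_cond_loglik(y, phi) for y in groups)

    coarse = np.concatenate([[0.0], np.geomspace(1e-3, grid_max, 60)])
    vals = np.array([loglik(p) for p in coarse])
    best = int(np.argmax(vals))
    lo = coarse[max(best - 1, 0)]
    hi = coarse[min(best + 1, len(coarse) - 1)]
    if hi <= lo:
        return float(coarse[best])
    fine = np.arange(lo, hi + grid_step, grid_step)
    fvals = np.array([loglik(p) for p in fine])
    phi = float(fine[int(np.argmax(fvals))])
    return max(phi, 0.0)


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

def _nb_logpmf(k: np.ndarray, mean: float, r: float | None) -> np.ndarray:
    """NB (or Poisson when ``r`` is None) log pmf with mean parameterization."""
    if mean <= 0:
        out = np.full_like(k, -np.inf, dtype=float)
        out[k == 0] = 0.0
        return out
    if r is None:  # Poisson limit
        return k * np.log(mean) - mean - gammaln(k + 1)
    logp = np.log(r) - np.log(r + mean)
    logq = np.log(mean) - np.log(r + mean)
    return gammaln(k + r) - gammaln(r) - gammaln(k + 1) + r * logp + k * logq


def _double_tail_p(s1: int, s2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact conditional NB test on two group sums.

    Conditions on the total s = s1 + s2; sums the probabilities of all splits
    no more likely than the observed one (double-tail rule). φ = 0 reduces to
    the conditional binomial (Poisson) exact test.
    """
    s = s1 + s2
    if s == 0:
        return 1.0
    mu = s / (n1 + n2)
    k = np.arange(s + 1)
    if phi <= 0:
        lp = _nb_logpmf(k, n1 * mu, None) + _nb_logpmf(s - k, n2 * mu, None)
    else:
        lp = _nb_logpmf(k, n1 * mu, n1 / phi) + _nb_logpmf(s - k, n2 * mu, n2 / phi)
    total = logsumexp(lp)
    obs = lp[s1]
    tail = lp[lp <= obs + 1e-10]
    return float(min(1.0, np.exp(logsumexp(tail) - total)))


def exact_test(
    counts: CountMatrix,
    norm: NormFactors,
    dispersion: float,
    alpha: float = 0.05,
    fdr: bool = False,
    prior_count: float = 0.5,
) -> DETable:
    """NB exact conditional test of treated vs control per gene.

    Counts are first scaled to a common effective library size; group sums of
    these pseudo-counts (rounded to integers) enter the exact conditional
    test. ``fdr=True`` switches the significance call to Benjamini–Hochberg
    adjusted p-values at the same α (the raw p-values stay in the table).
    """
    if not (0.0 < alpha < 1.0):
        raise ConfigurationError(f"alpha must lie in (0, 1), got {alpha}")
    if dispersion < 0:
        raise ConfigurationError(f"dispersion must be >= 0, got {dispersion}")
    adj = _adjusted_counts(counts, norm)
    ctrl = counts.samples_in("control")
    trt = counts.samples_in("treated")
    n1, n2 = len(ctrl), len(trt)
    s1 = np.rint(adj[ctrl].sum(axis=1).to_numpy()).astype(np.int64)
    s2 = np.rint(adj[trt].sum(axis=1).to_numpy()).astype(np.int64)

    pvals = np.ones(len(s1))
    # identical totals share one p-value computation
    cache: dict[tuple[int, int], float] = {}
    for i, (a, b) in enumerate(zip(s1, s2)):
        key = (int(a), int(b))
        if key not in cache:
            cache[key] = _double_tail_p(key[0], key[1], n1, n2, dispersion)
        pvals[i] = cache[key]

    mean1 = s1 / n1
    mean2 = s2 / n2
    log2fc = np.log2(mean2 + prior_count) - np.log2(mean1 + prior_count)
    fc_signed = np.sign(log2fc) * 2.0 ** np.abs(log2fc)
    fc_signed[log2fc == 0] = 1.0

    crit = pvals
    if fdr:
        from statsmodels.stats.multitest import multipletests

        crit = multipletests(pvals, method="fdr_bh")[1]
    status = np.where(
        (crit < alpha) & (log2fc > 0),
        "up",
        np.where((crit < alpha) & (log2fc < 0), "down", "ns"),
    )
    frame = pd.DataFrame(
        {
            "log2fc": log2fc,
            "fold_change_signed": fc_signed,
            "p_value": pvals,
            "status": status,
        },
        index=counts.counts.index,
    )
    return DETable(frame, alpha=alpha)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_de(table: DETable, n_mapped: int | None = None) -> DESummary:
    """Tally DE calls the way stress-response result tables print them.

    ``pct_de`` is rounded to one decimal of the mapped-gene total; the up and
    down shares are whole percentages of the DE genes.
    """
    n_genes = len(table.frame)
    if n_mapped is None:
        n_mapped = n_genes
    if n_mapped < n_genes:
        raise ConfigurationError(
            f"n_mapped ({n_mapped}) smaller than the number of genes in the table ({n_genes})"
        )
    n_up = int((table.frame["status"] == "up").sum())
    n_down = int((table.frame["status"] == "down").sum())
    n_de = n_up + n_down
    pct_de = round(100.0 * n_de / n_mapped, 1) if n_mapped else 0.0
    pct_up = round(100.0 * n_up / n_de) if n_de else 0.0
    pct_down = round(100.0 * n_down / n_de) if n_de else 0.0
    return DESummary(
        n_total=int(n_mapped),
        n_de=n_de,
        n_up=n_up,
        n_down=n_down,
        pct_de=float(pct_de),
        pct_up_of_de=float(pct_up),
        pct_down_of_de=float(pct_down),
    )


def top_regulated(
    table: DETable, n: int, direction: Literal["up", "down"]
) -> pd.DataFrame:
    """Top-``n`` genes of one direction by |signed fold change|.

    Ties are broken by gene id (lexicographic) so rankings are deterministic.
    Returns the full sorted list when fewer than ``n`` genes qualify.
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    if direction not in ("up", "down"):
        raise ConfigurationError(f"direction must be 'up' or 'down', got {direction!r}")
    sub = table.genes_with_status(direction).copy()
    sub["_mag"] = sub["fold_change_signed"].abs()
    # deterministic sort: magnitude descending, then gene id ascending
    sub = (
        sub.rename_axis("gene")
        .reset_index()
        .sort_values(by=["_mag", "gene"], ascending=[False, True], kind="mergesort")
        .set_index("gene")
        .drop(columns="_mag")
    )
    return sub.head(n)
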