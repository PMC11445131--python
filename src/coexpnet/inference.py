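"""Mutual-information co-expression network inference with DPI pruning.

The estimator is a plug-in (maximum-likelihood) mutual information over a
joint histogram of equal-frequency (quantile) bin assignments, i.e. a
fixed-partition MI without adaptive refinement.  Because binning depends
only on ranks, the estimate is invariant under strictly monotone
transforms of either variable.  Units are nats; downstream stages consume
only the edge *ranking*, which is unit-invariant.

Indirect interactions are pruned with the Data Processing Inequality
(DPI): in every gene triangle the weakest edge is presumed indirect and
removed (up to a tolerance), then the k strongest surviving edges are
retained so networks of different strata are size-matched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .networks import Network

DEFAULT_TOP_K = 10_000


@dataclass
class InferenceConfig:
    """Settings for one network inference run.

    Parameters
    ----------
    k : int
        Number of strongest edges retained (size-matching across strata).
    n_bins : int or "auto"
        Quantile bins for the MI histogram; "auto" uses
        ``floor(sqrt(n_samples))`` clamped to [2, 20].
    dpi_tolerance : float
        DPI tolerance epsilon >= 0; 0 prunes on strict inequality only.
    dpi_enabled : bool
        Whether to apply DPI pruning before top-k retention.
    """

    k: int = DEFAULT_TOP_K
    n_bins: int | str = "auto"
    dpi_tolerance: float = 0.0
    dpi_enabled: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.n_bins != "auto" and (not isinstance(self.n_bins, int) or self.n_bins < 2):
            raise ValueError(f"n_bins must be 'auto' or an integer >= 2, got {self.n_bins!r}")
        if self.dpi_tolerance < 0:
            raise ValueError(f"dpi_tolerance must be >= 0, got {self.dpi_tolerance}")


def auto_bins(n_samples: int) -> int:
    """floor(sqrt(n)) clamped to [2, 20], and to n // 4 so at least four
    samples fall in every bin (small strata fall back to 2 bins)."""
    return int(min(20, max(2, min(math.isqrt(n_samples), n_samples // 4))))


def quantile_bin(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin assignment from average ranks.

    Average ranks are cut into ``n_bins`` equal-width rank intervals; a
    tie group (one shared average rank) always lands in a single bin, and
    a group whose members would span a cut boundary goes to the lower
    bin.  A constant vector collapses into one occupied bin.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    r = rankdata(x, method="average")
    bins = np.floor((r - 1.0) * n_bins / n).astype(np.intp)
    return np.clip(bins, 0, n_bins - 1)


def _mi_from_joint(joint: np.ndarray) -> float:
    """Plug-in MI in nats from a joint count table."""
    n = joint.sum()
    p = joint / n
    pi = p.sum(axis=1, keepdims=True)
    pj = p.sum(axis=0, keepdims=True)
    mask = p > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (pi * pj))
    return float(terms[mask].sum())


def mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int | str = "auto") -> float:
    """Plug-in MI (nats) between two expression vectors.

    Symmetric in its arguments and >= 0 up to floating-point rounding.
    Requires at least ``4 * n_bins`` samples so every bin can be
    populated; a constant vector occupies a single bin and yields 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be 1-D of equal length, got {x.shape} vs {y.shape}")
    b = auto_bins(x.size) if n_bins == "auto" else int(n_bins)
    if x.size < 4 * b:
        raise ValueError(f"need at least {4 * b} samples for {b} bins, got {x.size}")
    bx = quantile_bin(x, b)
    by = quantile_bin(y, b)
    joint = np.zeros((b, b))
    np.add.at(joint, (bx, by), 1.0)
    return max(0.0, _mi_from_joint(joint))


@dataclass
class MITable:
    """Symmetric gene x gene MI table; NaN marks absent entries.

    The diagonal is undefined and always NaN.
    """

    genes: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        g = len(self.genes)
        if self.values.shape != (g, g):
            raise ValueError(f"values must be {g}x{g}, got {self.values.shape}")

    def copy(self) -> "MITable":
        return MITable(list(self.genes), self.values.copy())


def mi_matrix(matrix: pd.DataFrame, cfg: InferenceConfig | None = None) -> MITable:
    """All-pairs MI for a genes x samples expression matrix.

    Each gene's samples are quantile-binned once, then joint histograms
    for every pair are accumulated by one-hot matrix products (a single
    BLAS call per gene row).  Entry (i, j) equals
    ``mutual_information(row_i, row_j)`` exactly.
    """
    cfg = cfg or InferenceConfig()
    genes = [str(g) for g in matrix.index]
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to build an MI table")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene identifiers in expression matrix")
    values = np.asarray(matrix.to_numpy(), dtype=float)
    n_genes, n_samples = values.shape
    b = auto_bins(n_samples) if cfg.n_bins == "auto" else int(cfg.n_bins)
    if n_samples < 4 * b:
        raise ValueError(f"need at least {4 * b} samples for {b} bins, got {n_samples}")

    bins = np.empty((n_genes, n_samples), dtype=np.intp)
    for g in range(n_genes):
        bins[g] = quantile_bin(values[g], b)

    # one-hot encode: onehot[g] is (n_samples, b)
    onehot = np.zeros((n_genes, n_samples, b), dtype=np.float64)
    rows = np.repeat(np.arange(n_genes), n_samples)
    cols = np.tile(np.arange(n_samples), n_genes)
    onehot[rows, cols, bins.ravel()] = 1.0
    flat = np.ascontiguousarray(onehot.transpose(1, 0, 2).reshape(n_samples, n_genes * b))

    mi = np.full((n_genes, n_genes), np.nan)
    inv_n = 1.0 / n_samples
    marg = onehot.sum(axis=1) * inv_n  # (n_genes, b) marginal bin probabilities
    for i in range(n_genes - 1):
        # joint[j, :, :] = counts table between gene i and gene j
        joint = (onehot[i].T @ flat).reshape(b, n_genes, b).transpose(1, 0, 2)
        joint = joint[i + 1 :] * inv_n
        outer = marg[i][None, :, None] * marg[i + 1 :][:, None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = joint * np.log(joint / outer)
        row = np.nansum(np.where(joint > 0, terms, 0.0), axis=(1, 2))
        row = np.maximum(row, 0.0)
        mi[i, i + 1 :] = row
        mi[i + 1 :, i] = row
    return MITable(genes, mi)


def dpi_prune(table: MITable, tolerance: float = 0.0) -> MITable:
    """Data Processing Inequality pruning with mark-then-sweep semantics.

    For every triple (i, j, k) with all three MIs present in the *input*
    table, edge (i, j) is removed iff
    ``MI(i,j) < min(MI(i,k), MI(j,k)) * (1 - tolerance)``.
    All removals are evaluated against the input, so the result does not
    depend on gene enumeration order; ties survive (strict inequality).
    """
    if tolerance < 0:
        raise ValueError(f"tolerance must be >= 0, got {tolerance}")
    m = table.values
    n = m.shape[0]
    a = np.where(np.isnan(m), -np.inf, m)
    np.fill_diagonal(a, -np.inf)
    out = m.copy()
    scale = 1.0 - tolerance
    for i in range(n):
        # t[j, k] = min(MI(i,k), MI(j,k)); -inf wherever either is absent
        t = np.minimum(a[i][None, :], a)
        t[:, i] = -np.inf  # k must differ from i (t[j, j] is already -inf)
        best = t.max(axis=1)
        with np.errstate(invalid="ignore"):
            drop = ~np.isnan(m[i]) & (m[i] < scale * best)
        out[i, drop] = np.nan
        out[drop, i] = np.nan
    return MITable(list(table.genes), out)


def top_k_edges(table: MITable, k: int, name: str = "network") -> Network:
    """Retain the k strongest present entries as a canonical edge list.

    Ties at the cutoff are broken deterministically by canonical pair
    lexicographic order, so the result is reproducible across platforms.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    m = table.values
    iu, ju = np.triu_indices(m.shape[0], k=1)
    present = ~np.isnan(m[iu, ju])
    if not present.any():
        raise ValueError("MI table has no present entries")
    iu, ju, w = iu[present], ju[present], m[iu, ju][present]
    ranked = sorted(
        ((table.genes[i], table.genes[j]) if table.genes[i] < table.genes[j]
         else (table.genes[j], table.genes[i]), wij)
        for i, j, wij in zip(iu, ju, w)
    )
    ranked.sort(key=lambda pw: -pw[1])  # stable: lexicographic within equal weight
    net = Network(name)
    for (ga, gb), wij in ranked[: min(k, len(ranked))]:
        net.add(ga, gb, wij)
    return net


def infer_network(
    matrix: pd.DataFrame, cfg: InferenceConfig | None = None, name: str = "network"
) -> Network:
    """Full inference for one stratum: MI table -> (DPI) -> top-k edges."""
    cfg = cfg or InferenceConfig()
    table = mi_matrix(matrix, cfg)
    if cfg.dpi_enabled:
        table = dpi_prune(table, cfg.dpi_tolerance)
    return top_k_edges(table, cfg.k, name=name)
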