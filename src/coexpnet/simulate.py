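"""Synthetic RNA-seq cohort with planted co-expression modules.

Emulates the design of a sex- and age-stratified bulk muscle cohort: six
strata (sex F/M x age group Y/M/E) with configurable sample sizes,
negative-binomial counts with library-size variation, and latent-factor
induced co-expression modules that are either shared across strata or
active in a single stratum.

Generative mechanism, per module m and sample s of a stratum where m is
active: a latent factor z_ms ~ N(0, 1) shifts the log-mean of every gene
g in the module, mu_gs = libsize_s * exp(log m_g + beta * z_ms); counts
are NB(mean=mu_gs, dispersion) drawn as a gamma-Poisson mixture
(variance mu + mu^2 / dispersion).  Genes outside any active module are
independent given the library size, so the only excess dependence is the
planted module structure.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .networks import Network, Pair, canonical_pair

#: Stratum labels in fixed column order: sex (F/M) then age group
#: Y (young, 20-39), M (middle-aged, 40-59), E (elderly, 60-70+).
STRATA: tuple[str, ...] = ("FY", "FM", "FE", "MY", "MM", "ME")

#: Cohort design of the emulated muscle study: per-stratum sample counts
#: (803 samples in total).
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "FY": 39, "FM": 134, "FE": 87, "MY": 93, "MM": 245, "ME": 205,
}


class ConfigurationError(ValueError):
    """A simulation parameter is out of its valid range."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    beta is the latent-factor loading on the log scale (0 = no planted
    co-expression); dispersion is the NB size parameter (larger = closer
    to Poisson); base_mean_log_range bounds the log of per-gene baseline
    means; libsize_sigma is the log-normal sd of per-sample library-size
    factors; stratum_specific_fraction is the fraction of modules active
    in exactly one stratum (the rest are active everywhere).
    """

    n_genes: int = 300
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_modules: int = 6
    module_size: int = 20
    beta: float = 1.5
    dispersion: float = 10.0
    base_mean_log_range: tuple[float, float] = (math.log(50.0), math.log(2000.0))
    libsize_sigma: float = 0.2
    stratum_specific_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError(f"n_genes must be >= 1, got {self.n_genes}")
        unknown = set(self.group_sizes) - set(STRATA)
        if unknown:
            raise ConfigurationError(f"group_sizes has unknown strata: {sorted(unknown)}")
        if any(v < 0 for v in self.group_sizes.values()):
            raise ConfigurationError(f"group_sizes must be >= 0: {self.group_sizes}")
        if self.n_modules < 0:
            raise ConfigurationError(f"n_modules must be >= 0, got {self.n_modules}")
        if self.n_modules and self.module_size < 2:
            raise ConfigurationError(f"module_size must be >= 2, got {self.module_size}")
        if self.n_modules * self.module_size > self.n_genes:
            raise ConfigurationError(
                f"n_modules * module_size = {self.n_modules * self.module_size} "
                f"exceeds n_genes = {self.n_genes}"
            )
        if self.dispersion <= 0:
            raise ConfigurationError(f"dispersion must be > 0, got {self.dispersion}")
        if not (0.0 <= self.stratum_specific_fraction <= 1.0):
            raise ConfigurationError(
                f"stratum_specific_fraction must be in [0, 1], "
                f"got {self.stratum_specific_fraction}"
            )
        lo, hi = self.base_mean_log_range
        if not lo <= hi:
            raise ConfigurationError(f"base_mean_log_range must satisfy lo <= hi, got {lo}, {hi}")
        if self.libsize_sigma < 0:
            raise ConfigurationError(f"libsize_sigma must be >= 0, got {self.libsize_sigma}")


@dataclass
class GroundTruth:
    """Planted module structure behind a synthetic cohort."""

    module_assignments: dict[str, int | None]
    module_activity: dict[int, set[str]]
    true_pairs: dict[str, set[Pair]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_assignments": {
                g: m for g, m in self.module_assignments.items() if m is not None
            },
            "module_activity": {str(m): sorted(s) for m, s in self.module_activity.items()},
            "true_pairs": {
                s: sorted([a, b] for a, b in pairs) for s, pairs in self.true_pairs.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            module_assignments={g: int(m) for g, m in payload["module_assignments"].items()},
            module_activity={int(m): set(s) for m, s in payload["module_activity"].items()},
            true_pairs={
                s: {canonical_pair(a, b) for a, b in pairs}
                for s, pairs in payload["true_pairs"].items()
            },
        )

    def module_gene_sets(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {m: set() for m in self.module_activity}
        for gene, module in self.module_assignments.items():
            if module is not None:
                out[module].add(gene)
        return out


def _stream(seed: int, *keys: object) -> np.random.Generator:
    """Independent RNG stream from the root seed and a fixed key path.

    Keys are hashed so adding a stratum or module never perturbs the
    draws of another stream.
    """
    tag = "|".join(str(k) for k in keys)
    digest = hashlib.sha256(tag.encode()).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**63, *words]))


def gene_names(n_genes: int) -> list[str]:
    """Zero-padded synthetic symbols ("G000001"), lexicographically sorted."""
    return [f"G{i + 1:06d}" for i in range(n_genes)]


def _plan_modules(cfg: SimulationConfig) -> tuple[dict[str, int | None], dict[int, set[str]]]:
    """Assign genes to modules (leading blocks) and modules to strata.

    The first ``round(stratum_specific_fraction * n_modules)`` modules are
    stratum-specific, cycling FY, FM, ... in order; the rest are active in
    every stratum.  Deterministic by construction.
    """
    names = gene_names(cfg.n_genes)
    assignments: dict[str, int | None] = {g: None for g in names}
    activity: dict[int, set[str]] = {}
    n_specific = round(cfg.stratum_specific_fraction * cfg.n_modules)
    for m in range(cfg.n_modules):
        block = names[m * cfg.module_size : (m + 1) * cfg.module_size]
        for g in block:
            assignments[g] = m
        if m < n_specific:
            activity[m] = {STRATA[m % len(STRATA)]}
        else:
            activity[m] = set(STRATA)
    return assignments, activity


def generate_dataset(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate one cohort.

    Returns
    -------
    counts : DataFrame
        Non-negative integer genes x samples matrix; column count equals
        the sum of group sizes, columns grouped by stratum in the fixed
        order FY, FM, FE, MY, MM, ME.
    metadata : DataFrame
        One row per sample: SAMPID, SEX, AGE_GROUP.
    truth : GroundTruth
        Planted modules, their active strata, and the within-module gene
        pairs per stratum (the "true" co-expression edges).
    """
    names = gene_names(cfg.n_genes)
    assignments, activity = _plan_modules(cfg)
    module_genes: dict[int, np.ndarray] = {
        m: np.array([i for i, g in enumerate(names) if assignments[g] == m])
        for m in activity
    }

    lo, hi = cfg.base_mean_log_range
    base_log_mean = _stream(cfg.seed, "baseline").uniform(lo, hi, size=cfg.n_genes)

    blocks: list[np.ndarray] = []
    sample_ids: list[str] = []
    meta_rows: list[tuple[str, str, str]] = []
    for stratum in STRATA:
        n_s = int(cfg.group_sizes.get(stratum, 0))
        if n_s == 0:
            continue
        ids = [f"{stratum}-{i + 1:04d}" for i in range(n_s)]
        sample_ids.extend(ids)
        meta_rows.extend((sid, stratum[0], stratum[1]) for sid in ids)

        libsize = (
            np.exp(_stream(cfg.seed, "libsize", stratum).normal(0.0, cfg.libsize_sigma, n_s))
            if cfg.libsize_sigma > 0
            else np.ones(n_s)
        )
        log_mu = np.tile(base_log_mean[:, None], (1, n_s))
        for m, strata_active in activity.items():
            if stratum not in strata_active or len(module_genes[m]) == 0:
                continue
            z = _stream(cfg.seed, "factor", stratum, m).standard_normal(n_s)
            log_mu[module_genes[m], :] += cfg.beta * z[None, :]
        mu = np.exp(log_mu) * libsize[None, :]

        noise = _stream(cfg.seed, "counts", stratum)
        lam = noise.gamma(shape=cfg.dispersion, scale=mu / cfg.dispersion)
        blocks.append(noise.poisson(lam).astype(np.int64))

    if not blocks:
        raise ConfigurationError("group_sizes: all strata are empty")
    counts = pd.DataFrame(np.hstack(blocks), index=names, columns=sample_ids)
    counts.index.name = "gene_id"
    metadata = pd.DataFrame(meta_rows, columns=["SAMPID", "SEX", "AGE_GROUP"])

    true_pairs: dict[str, set[Pair]] = {s: set() for s in STRATA}
    for m, strata_active in activity.items():
        genes = sorted(names[i] for i in module_genes[m])
        pairs = {canonical_pair(a, b) for a, b in combinations(genes, 2)}
        for s in strata_active:
            true_pairs[s] |= pairs
    truth = GroundTruth(assignments, activity, true_pairs)
    return counts, metadata, truth


def module_recall(network: Network, truth: GroundTruth, stratum: str) -> float:
    """Fraction of a stratum's true within-module pairs present as edges."""
    if stratum not in truth.true_pairs:
        raise KeyError(f"unknown stratum {stratum!r}")
    true = truth.true_pairs[stratum]
    if not true:
        raise ValueError(f"recall undefined: stratum {stratum!r} has no true pairs")
    return len(network.pairs & true) / len(true)


# -- file export ---------------------------------------------------------


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def write_counts_gct(counts: pd.DataFrame, path: str | Path) -> None:
    """GCT v1.2: '#1.2' line, dimensions line, then Name/Description table."""
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{counts.shape[0]}\t{counts.shape[1]}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, counts.columns)) + "\n")
        for gene, row in counts.iterrows():
            fh.write(f"{gene}\tna\t" + "\t".join(str(int(v)) for v in row) + "\n")


def write_metadata_tsv(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)
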