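"""Count-matrix loading, gene filtering, quantile normalization, and the
six-way sex x age-group split.

The preprocessing order mirrors the study design: filter genes on the
*full* cohort (one shared gene universe), quantile-normalize the whole
matrix, then split into the six strata.  Filtering before splitting
keeps the six networks on an identical gene namespace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import STRATA

logger = logging.getLogger(__name__)

#: GTEx-style decade brackets mapped to the three study age groups:
#: Young 20-39, Middle-aged 40-59, Elderly 60+.  Overridable per run.
DEFAULT_AGE_BRACKETS: dict[str, str] = {
    "20-29": "Y", "30-39": "Y",
    "40-49": "M", "50-59": "M",
    "60-69": "E", "70-79": "E",
}

_SEX_CODES = {"F": "F", "M": "M", "2": "F", "1": "M", "FEMALE": "F", "MALE": "M"}


class FormatError(ValueError):
    """Malformed input file or inconsistent identifiers."""


@dataclass
class FilterConfig:
    """Gene-filtering thresholds applied to raw counts.

    A gene is retained iff its mean count across all samples is at least
    ``mean_threshold`` AND its fraction of zero counts is at most
    ``max_zero_fraction``.
    """

    mean_threshold: float = 10.0
    max_zero_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.mean_threshold < 0:
            raise ValueError(f"mean_threshold must be >= 0, got {self.mean_threshold}")
        if not (0.0 <= self.max_zero_fraction <= 1.0):
            raise ValueError(
                f"max_zero_fraction must be in [0, 1], got {self.max_zero_fraction}"
            )


def _validate_matrix(counts: pd.DataFrame, source: str) -> None:
    dup_genes = counts.index[counts.index.duplicated()].unique().tolist()
    if dup_genes:
        raise FormatError(f"{source}: duplicate gene ids: {dup_genes[:5]}")
    dup_samples = counts.columns[counts.columns.duplicated()].unique().tolist()
    if dup_samples:
        raise FormatError(f"{source}: duplicate sample ids: {dup_samples[:5]}")
    if (counts.to_numpy() < 0).any():
        raise FormatError(f"{source}: negative values in count matrix")


def read_counts(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a gene x sample count matrix (TSV or GCT v1.2)."""
    path = Path(path)
    if dialect == "tsv":
        counts = pd.read_csv(path, sep="\t", index_col=0)
    elif dialect == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(f"{path}: expected GCT version line '#1.2', got {version!r}")
            dims = fh.readline().split("\t")
            try:
                n_rows, n_cols = int(dims[0]), int(dims[1])
            except (IndexError, ValueError):
                raise FormatError(f"{path}: malformed GCT dimensions line") from None
        counts = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        if "Description" in counts.columns:
            counts = counts.drop(columns="Description")
        if counts.shape != (n_rows, n_cols):
            raise FormatError(
                f"{path}: GCT header declares {n_rows}x{n_cols}, body is "
                f"{counts.shape[0]}x{counts.shape[1]}"
            )
    else:
        raise ValueError(f"dialect must be 'tsv' or 'gct', got {dialect!r}")
    counts.index = counts.index.astype(str)
    counts.index.name = "gene_id"
    counts.columns = counts.columns.astype(str)
    _validate_matrix(counts, str(path))
    return counts


def read_metadata(
    path: str | Path, age_brackets: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a sample-attribute table (SAMPID, SEX, AGE or AGE_GROUP).

    Sex accepts F/M, Female/Male, or the 1=male / 2=female numeric
    coding; ages accept direct group labels (Y/M/E), decade brackets
    ("50-59"), or numeric years.
    """
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"SAMPID", "SEX"}
    if not required.issubset(meta.columns):
        raise FormatError(f"{path}: metadata must have columns SAMPID and SEX")
    if "AGE_GROUP" not in meta.columns and "AGE" not in meta.columns:
        raise FormatError(f"{path}: metadata must have an AGE or AGE_GROUP column")
    dup = meta["SAMPID"][meta["SAMPID"].duplicated()].tolist()
    if dup:
        raise FormatError(f"{path}: duplicate sample ids: {dup[:5]}")

    sex = meta["SEX"].str.strip().str.upper().map(_SEX_CODES)
    bad = meta.loc[sex.isna(), "SAMPID"].tolist()
    if bad:
        raise FormatError(f"{path}: unmapped SEX value for samples {bad[:5]}")

    brackets = age_brackets if age_brackets is not None else DEFAULT_AGE_BRACKETS
    raw_age = meta["AGE_GROUP"] if "AGE_GROUP" in meta.columns else meta["AGE"]
    age_group = []
    for sampid, value in zip(meta["SAMPID"], raw_age.astype(str).str.strip()):
        if value in {"Y", "M", "E"}:
            age_group.append(value)
        elif value in brackets:
            age_group.append(brackets[value])
        elif value.isdigit():
            years = int(value)
            bracket = f"{10 * (years // 10)}-{10 * (years // 10) + 9}"
            if bracket not in brackets:
                raise FormatError(f"{path}: age {years} of sample {sampid} maps to no group")
            age_group.append(brackets[bracket])
        else:
            raise FormatError(f"{path}: unmapped age value {value!r} for sample {sampid}")
    out = pd.DataFrame(
        {"SAMPID": meta["SAMPID"].str.strip(), "SEX": sex, "AGE_GROUP": age_group}
    )
    return out


def load_dataset(
    counts_path: str | Path,
    metadata_path: str | Path,
    dialect: str = "tsv",
    age_brackets: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load counts and metadata, aligning samples.

    Samples present in the counts but absent from the metadata are
    dropped with a warning; metadata rows without a counts column are
    ignored.  The returned matrix columns follow the counts-file order.
    """
    counts = read_counts(counts_path, dialect=dialect)
    meta = read_metadata(metadata_path, age_brackets=age_brackets)
    known = set(meta["SAMPID"])
    missing = [s for s in counts.columns if s not in known]
    if missing:
        logger.warning(
            "dropping %d sample(s) absent from metadata: %s%s",
            len(missing), missing[:5], "..." if len(missing) > 5 else "",
        )
        counts = counts.drop(columns=missing)
    if counts.shape[1] == 0:
        raise FormatError("no samples remain after aligning counts with metadata")
    meta = meta.set_index("SAMPID").loc[list(counts.columns)].reset_index()
    return counts, meta


def filter_genes(counts: pd.DataFrame, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Drop genes with low mean count or too many zero counts.

    Both rules are evaluated on the same input matrix; gene order is
    preserved.  Raises if no gene survives.
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("count matrix is empty")
    cfg = cfg or FilterConfig()
    values = counts.to_numpy(dtype=float)
    mean_ok = values.mean(axis=1) >= cfg.mean_threshold
    zero_ok = (values == 0).mean(axis=1) <= cfg.max_zero_fraction
    keep = mean_ok & zero_ok
    if not keep.any():
        raise ValueError(
            f"no genes pass the filters (mean >= {cfg.mean_threshold}, "
            f"zero fraction <= {cfg.max_zero_fraction})"
        )
    return counts.loc[keep]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean-of-sorted-columns reference.

    After normalization every column's sorted value multiset is the same
    reference distribution and within-column rank order is preserved.
    Tied values within a column receive the mean of the reference values
    at their tied rank positions, so the output does not depend on sort
    stability.  A single-column matrix is returned unchanged.
    """
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise FormatError("expression matrix contains non-finite values")
    n_genes, n_cols = values.shape
    if n_cols < 1:
        raise ValueError("matrix must have at least one column")
    if n_cols == 1:
        return matrix.copy()
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_cols):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        # mean of reference over each tie block
        _, inverse, counts_per = np.unique(col[order], return_inverse=True, return_counts=True)
        block_means = np.bincount(inverse, weights=reference) / counts_per
        out[order, j] = block_means[inverse]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def split_groups(
    matrix: pd.DataFrame, meta: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Split columns into the six sex x age-group strata.

    Every sample lands in exactly one stratum; empty strata are allowed
    (and logged).  Keys are the labels FY, FM, FE, MY, MM, ME.
    """
    lookup = meta.set_index("SAMPID")
    unknown = [s for s in matrix.columns if s not in lookup.index]
    if unknown:
        raise FormatError(f"samples without metadata: {unknown[:5]}")
    strata: dict[str, list[str]] = {s: [] for s in STRATA}
    for sample in matrix.columns:
        row = lookup.loc[sample]
        label = f"{row['SEX']}{row['AGE_GROUP']}"
        if label not in strata:
            raise FormatError(f"sample {sample}: unmapped stratum {label!r}")
        strata[label].append(sample)
    out = {}
    for label, samples in strata.items():
        if not samples:
            logger.info("stratum %s is empty", label)
        out[label] = matrix[samples]
    return out
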