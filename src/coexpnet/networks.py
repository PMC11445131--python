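"""Canonical edge-list container shared by every stage of the pipeline.

A co-expression network here is a set of *unordered* gene pairs with
mutual-information weights.  Every comparison downstream (overlaps,
conserved/unique sets, null models) identifies an edge by its pair of
endpoint genes only, so the container enforces one canonical form at
construction: ``gene_a < gene_b`` lexicographically, no self-pairs, no
duplicate pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

Pair = tuple[str, str]


def canonical_pair(gene_a: str, gene_b: str) -> Pair:
    """Return the unordered pair in canonical (lexicographic) order.

    Raises
    ------
    ValueError
        If the two genes are identical (self-pairs carry no
        co-expression information and are never valid edges).
    """
    if gene_a == gene_b:
        raise ValueError(f"self-pair is not a valid edge: {gene_a!r}")
    return (gene_a, gene_b) if gene_a < gene_b else (gene_b, gene_a)


@dataclass(frozen=True)
class Edge:
    """One undirected interaction with its MI weight in nats."""

    gene_a: str
    gene_b: str
    weight: float = math.nan

    def __post_init__(self) -> None:
        a, b = canonical_pair(self.gene_a, self.gene_b)
        object.__setattr__(self, "gene_a", a)
        object.__setattr__(self, "gene_b", b)

    @property
    def pair(self) -> Pair:
        return (self.gene_a, self.gene_b)


@dataclass
class Network:
    """A named co-expression network stored as ``pair -> weight``.

    ``edges`` maps canonical pairs to MI weights; pair identity (not the
    weight) defines membership.  ``genes`` is derived: every gene is an
    endpoint of at least one edge, so isolated genes do not exist.
    """

    name: str
    edges: dict[Pair, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: Pair) -> bool:
        return tuple(pair) in self.edges

    def __iter__(self) -> Iterator[Pair]:
        return iter(self.edges)

    @property
    def pairs(self) -> set[Pair]:
        return set(self.edges)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def add(self, gene_a: str, gene_b: str, weight: float = math.nan) -> None:
        self.edges[canonical_pair(gene_a, gene_b)] = float(weight)

    @classmethod
    def from_pairs(
        cls,
        name: str,
        pairs: Iterable[Pair] | Mapping[Pair, float],
        default_weight: float = math.nan,
    ) -> "Network":
        net = cls(name)
        if isinstance(pairs, Mapping):
            for (a, b), w in pairs.items():
                net.add(a, b, w)
        else:
            for a, b in pairs:
                net.add(a, b, default_weight)
        return net

    # -- serialization ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Edge table sorted by descending weight then canonical pair."""
        rows = sorted(
            ((a, b, w) for (a, b), w in self.edges.items()),
            key=lambda r: (-r[2] if r[2] == r[2] else 0.0, r[0], r[1]),
        )
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "mi"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    def write_sif(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for a, b, _ in self.to_frame().itertuples(index=False):
                fh.write(f"{a}\tmi\t{b}\n")

    @classmethod
    def read_tsv(cls, path: str | Path, name: str | None = None) -> "Network":
        frame = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
        expected = {"gene_a", "gene_b", "mi"}
        if not expected.issubset(frame.columns):
            raise ValueError(
                f"{path}: edgelist must have columns {sorted(expected)}, "
                f"found {list(frame.columns)}"
            )
        net = cls(name if name is not None else Path(path).stem)
        for a, b, w in frame[["gene_a", "gene_b", "mi"]].itertuples(index=False):
            net.add(a, b, w)
        return net
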