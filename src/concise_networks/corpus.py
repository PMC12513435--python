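"""Path corpora and trigram count tables.

A path corpus is a collection of trajectories through a system: each
trajectory is a sequence of node labels, optionally carrying an integer
or real weight (e.g. a pre-aggregated itinerary count).  Second-order
evidence about a node ``j`` is tabulated as trigrams ``i -> j -> k``:
for every center ``j`` we store a matrix ``A`` of observation counts
with rows indexed by successors ``k`` and columns by predecessors ``i``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PathCorpus",
    "TrigramCounts",
    "load_path_corpus",
    "extract_trigram_counts",
    "top_transit_nodes",
    "write_trigram_tsv",
    "read_trigram_tsv",
]


@dataclass
class PathCorpus:
    """Trajectories with positive weights.

    Parameters
    ----------
    trajectories
        List of ``(labels, weight)`` pairs.  Labels are opaque strings;
        weights default to 1 and multiply every trigram contribution.
    """

    trajectories: list[tuple[tuple[str, ...], float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for seq, w in self.trajectories:
            if len(seq) < 1:
                raise ValueError("every trajectory must contain at least one node")
            if w <= 0:
                raise ValueError(f"trajectory weight must be positive, got {w!r}")

    @property
    def node_universe(self) -> set[str]:
        return {label for seq, _ in self.trajectories for label in seq}

    def __len__(self) -> int:
        return len(self.trajectories)


@dataclass
class TrigramCounts:
    """Observation counts of trigrams through one center node.

    ``A[k, i]`` is the (weighted) number of observed two-step paths
    ``predecessors[i] -> center -> successors[k]``.  Only observed
    predecessors are stored, so every column has a positive sum.
    Label orderings are sorted for reproducible matrix layouts.
    """

    center: str
    predecessors: tuple[str, ...]
    successors: tuple[str, ...]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (len(self.successors), len(self.predecessors)):
            raise ValueError(
                f"A has shape {self.A.shape}, expected "
                f"({len(self.successors)}, {len(self.predecessors)})"
            )
        if np.any(self.A < 0):
            raise ValueError("trigram counts must be nonnegative")
        colsums = self.A.sum(axis=0)
        if np.any(colsums <= 0):
            bad = [p for p, s in zip(self.predecessors, colsums) if s <= 0]
            raise ValueError(f"predecessor columns with zero counts: {bad}")

    @property
    def total(self) -> float:
        """Total (weighted) trigram count through the center."""
        return float(self.A.sum())

    @property
    def n(self) -> np.ndarray:
        """Per-predecessor observation counts ``n_i`` (column sums of A)."""
        return self.A.sum(axis=0)


def load_path_corpus(file: str | Path, weighted: bool = False) -> PathCorpus:
    """Read a plain-text path file, one trajectory per line.

    Tokens are whitespace-separated node labels; with ``weighted`` the
    first token of each line is a positive numeric weight.
    """
    file = Path(file)
    trajectories: list[tuple[tuple[str, ...], float]] = []
    with file.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            weight = 1.0
            if weighted:
                try:
                    weight = float(tokens[0])
                except ValueError:
                    raise ValueError(
                        f"{file}:{lineno}: expected a numeric weight, got {tokens[0]!r}"
                    ) from None
                if weight <= 0:
                    raise ValueError(f"{file}:{lineno}: weight must be positive")
                tokens = tokens[1:]
            if not tokens:
                raise ValueError(f"{file}:{lineno}: no node labels on line")
            trajectories.append((tuple(tokens), weight))
    if not trajectories:
        logger.warning("path file %s contains no trajectories", file)
    return PathCorpus(trajectories)


def extract_trigram_counts(
    corpus: PathCorpus, exclude_returns: bool = False
) -> dict[str, TrigramCounts]:
    """Tabulate per-center trigram counts from a corpus.

    Every consecutive triple ``(i, j, k)`` contributes its trajectory
    weight to ``A^j[k, i]``.  With ``exclude_returns``, return transits
    ``i -> j -> i`` are dropped (used when studying nodes as transit
    hubs rather than round-trip endpoints).  Centers with no surviving
    triples are absent from the result.
    """
    acc: dict[str, dict[tuple[str, str], float]] = {}
    for seq, w in corpus.trajectories:
        for i, j, k in zip(seq, seq[1:], seq[2:]):
            if exclude_returns and i == k:
                continue
            bucket = acc.setdefault(j, {})
            bucket[(k, i)] = bucket.get((k, i), 0.0) + w
    return {center: _to_counts(center, pairs) for center, pairs in acc.items()}


def _to_counts(center: str, pairs: Mapping[tuple[str, str], float]) -> TrigramCounts:
    predecessors = tuple(sorted({i for _, i in pairs}))
    successors = tuple(sorted({k for k, _ in pairs}))
    pidx = {p: c for c, p in enumerate(predecessors)}
    sidx = {s: r for r, s in enumerate(successors)}
    A = np.zeros((len(successors), len(predecessors)))
    for (k, i), count in pairs.items():
        A[sidx[k], pidx[i]] = count
    return TrigramCounts(center, predecessors, successors, A)


def top_transit_nodes(counts: Mapping[str, TrigramCounts], m: int) -> list[str]:
    """The ``m`` centers with the largest total trigram count.

    Ordered by total descending; ties broken lexicographically by label.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    if m > len(counts):
        logger.warning(
            "requested %d transit nodes but only %d centers observed", m, len(counts)
        )
        m = len(counts)
    ranked = sorted(counts.items(), key=lambda item: (-item[1].total, item[0]))
    return [center for center, _ in ranked[:m]]


def write_trigram_tsv(counts: Mapping[str, TrigramCounts], file: str | Path) -> None:
    """Write trigram counts as a four-column TSV (center, predecessor, successor, count)."""
    rows = []
    for center in sorted(counts):
        tc = counts[center]
        for r, k in enumerate(tc.successors):
            for c, i in enumerate(tc.predecessors):
                if tc.A[r, c] > 0:
                    rows.append((center, i, k, tc.A[r, c]))
    df = pd.DataFrame(rows, columns=["center", "predecessor", "successor", "count"])
    df.to_csv(file, sep="\t", index=False)


def read_trigram_tsv(file: str | Path) -> dict[str, TrigramCounts]:
    """Read trigram counts written by :func:`write_trigram_tsv`."""
    df = pd.read_csv(file, sep="\t", dtype={"center": str, "predecessor": str, "successor": str})
    expected = ["center", "predecessor", "successor", "count"]
    if list(df.columns) != expected:
        raise ValueError(f"expected columns {expected}, got {list(df.columns)}")
    out: dict[str, TrigramCounts] = {}
    for center, group in df.groupby("center", sort=True):
        pairs = {
            (row.successor, row.predecessor): float(row.count_)
            for row in group.rename(columns={"count": "count_"}).itertuples()
        }
        out[str(center)] = _to_counts(str(center), pairs)
    return out
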