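"""Shared domain containers: parcellated time series, connectivity
matrices, edge masks, and network-strength scores.

Node identifiers are 1-based atlas labels externally (files, masks) and
mapped to 0-based positions internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SYMMETRY_TOL = 1e-12


@dataclass
class NodeTimeSeries:
    """One run's parcellated signal: T timepoints x N nodes."""

    values: np.ndarray
    node_ids: tuple[int, ...]
    repetition_time: float = 1.0
    subject: str | None = None
    run: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.node_ids = tuple(int(i) for i in self.node_ids)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D T x N array")
        T, N = self.values.shape
        if N != len(self.node_ids):
            raise ValueError(f"{N} columns but {len(self.node_ids)} node ids")
        if N < 2:
            raise ValueError("need at least 2 nodes")
        if T < 3:
            raise ValueError("need at least 3 timepoints")
        if np.isnan(self.values).any():
            raise ValueError("time series contains missing values")
        if len(set(self.node_ids)) != N:
            raise ValueError("node ids must be unique")
        if list(self.node_ids) != sorted(self.node_ids):
            raise ValueError("node ids must be sorted")
        if self.repetition_time <= 0:
            raise ValueError("repetition time must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=[str(i) for i in self.node_ids])

    @classmethod
    def from_file(cls, path, repetition_time: float = 1.0, subject=None, run=None) -> "NodeTimeSeries":
        """Read a T x N table (TSV/CSV, header row = 1-based node labels)."""
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        table = pd.read_csv(path, sep=sep)
        return cls(
            values=table.to_numpy(dtype=float),
            node_ids=tuple(int(c) for c in table.columns),
            repetition_time=repetition_time,
            subject=subject,
            run=run,
        )

    def write(self, path) -> None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        self.to_frame().to_csv(path, sep=sep, index=False)


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N edge-weight matrix on the r or z scale, zero diagonal."""

    values: np.ndarray
    scale: str
    node_ids: tuple[int, ...]
    subject: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.node_ids = tuple(int(i) for i in self.node_ids)
        if self.scale not in ("r", "z"):
            raise ValueError("scale must be 'r' or 'z'")
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("matrix must be square")
        if n != len(self.node_ids):
            raise ValueError("node id count does not match matrix dimension")
        if not np.allclose(self.values, self.values.T, atol=SYMMETRY_TOL, rtol=0):
            raise ValueError("matrix is not symmetric")
        if np.abs(np.diag(self.values)).max(initial=0.0) > SYMMETRY_TOL:
            raise ValueError("diagonal must be zero")
        if self.scale == "r":
            off = self.values[~np.eye(n, dtype=bool)]
            if off.size and (np.abs(off) > 1 + 1e-12).any():
                raise ValueError("r-scale entries must lie in [-1, 1]")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def index_of(self, node_id: int) -> int:
        return self.node_ids.index(int(node_id))

    def to_frame(self) -> pd.DataFrame:
        labels = [str(i) for i in self.node_ids]
        return pd.DataFrame(self.values, index=labels, columns=labels)

    @classmethod
    def from_file(cls, path, scale: str, subject=None) -> "ConnectivityMatrix":
        table = pd.read_csv(path, index_col=0)
        return cls(
            values=table.to_numpy(dtype=float),
            scale=scale,
            node_ids=tuple(int(c) for c in table.columns),
            subject=subject,
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path)


def _canonical_edges(edges) -> frozenset[tuple[int, int]]:
    canon = set()
    for i, j in edges:
        i, j = int(i), int(j)
        if i == j:
            raise ValueError(f"self-pair ({i}, {j}) is not a valid edge")
        canon.add((min(i, j), max(i, j)))
    return frozenset(canon)


@dataclass(frozen=True)
class NetworkMask:
    """A fixed set of unordered node pairs with a polarity label."""

    edges: frozenset = field(default_factory=frozenset)
    polarity: str = "high"
    atlas_size: int = 268

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", _canonical_edges(self.edges))
        if self.polarity not in ("high", "low"):
            raise ValueError("polarity must be 'high' or 'low'")
        for i, j in self.edges:
            if not (1 <= i <= self.atlas_size and 1 <= j <= self.atlas_size):
                raise ValueError(f"edge ({i}, {j}) outside 1..{self.atlas_size}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def nodes(self) -> set[int]:
        return {n for e in self.edges for n in e}

    @classmethod
    def from_edgelist(cls, path, polarity: str, atlas_size: int = 268) -> "NetworkMask":
        """Read a 3-column edge-list TSV (node_i, node_j, weight), 1-based ids."""
        table = pd.read_csv(path, sep="\t")
        if table.shape[1] < 2:
            raise ValueError(f"{path}: edge list needs at least two columns")
        if table.shape[1] >= 3:
            w = table.iloc[:, 2].to_numpy(dtype=float)
            if not np.allclose(w, 1.0):
                import warnings

                warnings.warn(
                    f"{path}: non-unit edge weights present; treated as binary membership",
                    stacklevel=2,
                )
        pairs = list(zip(table.iloc[:, 0].astype(int), table.iloc[:, 1].astype(int)))
        return cls(edges=frozenset(pairs), polarity=polarity, atlas_size=atlas_size)

    @classmethod
    def from_dense(cls, matrix: np.ndarray, polarity: str) -> "NetworkMask":
        """Build from a dense binary adjacency matrix (symmetrized, zero diag)."""
        m = np.asarray(matrix, dtype=float)
        n = m.shape[0]
        if m.shape != (n, n):
            raise ValueError("dense mask must be square")
        if not np.allclose(m, m.T):
            raise ValueError("dense mask must be symmetric")
        if np.abs(np.diag(m)).max(initial=0.0) > 0:
            raise ValueError("dense mask must have zero diagonal")
        rows, cols = np.nonzero(np.triu(m, k=1))
        return cls(edges=frozenset(zip(rows + 1, cols + 1)), polarity=polarity, atlas_size=n)

    def write_edgelist(self, path) -> None:
        rows = sorted(self.edges)
        pd.DataFrame(rows, columns=["node_i", "node_j"]).assign(weight=1).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class StrengthScores:
    """Per-subject network strength: mean masked z for each polarity and
    their difference (combined = high - low)."""

    subject: str
    high: float
    low: float

    @property
    def combined(self) -> float:
        return self.high - self.low
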