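"""Reading, validation, and preprocessing of undirected networks.

The canonical object analysed throughout the package is a connected,
undirected network with non-negative edge weights and no self-loops,
represented by a dense symmetric adjacency matrix plus an ordered list
of node labels.  Raw inputs (edge lists or dense adjacency matrices,
possibly directed, weighted, or fragmented) are brought into this form
by :func:`preprocess`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import networkx as nx
from scipy.sparse import csgraph
from scipy.sparse import csr_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "NetworkFormatError",
    "NetworkValidationError",
    "EmptyInputError",
    "TooSmallError",
    "read_network",
    "write_network",
    "preprocess",
]


class NetworkFormatError(ValueError):
    """Input file does not conform to the declared format."""


class NetworkValidationError(ValueError):
    """Adjacency data violates a network invariant (e.g. negative weight)."""


class EmptyInputError(ValueError):
    """Input file contains no edges / no matrix."""


class TooSmallError(ValueError):
    """Largest connected component has fewer than 3 nodes."""


@dataclass(frozen=True)
class Network:
    """An undirected network with non-negative weights.

    Parameters
    ----------
    adjacency : (N, N) ndarray
        Symmetric non-negative matrix with zero diagonal.
    node_labels : tuple of str
        Original node identifiers, in internal index order.
    weighted : bool
        If False, every nonzero weight must equal 1.
    """

    adjacency: np.ndarray
    node_labels: tuple[str, ...]
    weighted: bool = False

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        object.__setattr__(self, "adjacency", A)
        object.__setattr__(self, "node_labels", tuple(str(x) for x in self.node_labels))
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise NetworkFormatError(f"adjacency must be square, got shape {A.shape}")
        if len(self.node_labels) != A.shape[0]:
            raise NetworkValidationError("label count does not match adjacency size")
        if np.any(A < 0):
            raise NetworkValidationError("negative edge weights are not allowed")
        if not np.allclose(A, A.T):
            raise NetworkValidationError("adjacency must be symmetric (use preprocess)")
        if np.any(np.diag(A) != 0):
            raise NetworkValidationError("self-loops are not allowed (use preprocess)")
        if not self.weighted:
            nz = A[A != 0]
            if nz.size and not np.all(nz == 1):
                raise NetworkValidationError(
                    "unweighted network has weights other than 1"
                )

    # -- derived quantities -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))

    @property
    def degrees(self) -> np.ndarray:
        """Binary degree d_i (number of neighbours), regardless of weighting."""
        return (self.adjacency > 0).sum(axis=1).astype(int)

    @property
    def strengths(self) -> np.ndarray:
        """Weighted degree s_i = row sum of the adjacency matrix."""
        return self.adjacency.sum(axis=1)

    def content_hash(self) -> int:
        """Stable hash of the adjacency content (below 2**31), used to derive
        per-network sub-seeds so identical networks get identical analyses."""
        import zlib

        data = np.ascontiguousarray(self.adjacency).tobytes()
        return zlib.crc32(data) & 0x7FFFFFFF

    def neighbour_sets(self) -> list[set[int]]:
        return [set(np.flatnonzero(self.adjacency[i] > 0)) for i in range(self.n_nodes)]

    def is_connected(self) -> bool:
        if self.n_nodes == 0:
            return False
        n_comp, _ = csgraph.connected_components(
            csr_matrix(self.adjacency), directed=False
        )
        return n_comp == 1

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(range(self.n_nodes))
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        G.add_weighted_edges_from(
            (int(i), int(j), float(self.adjacency[i, j])) for i, j in zip(ii, jj)
        )
        return G

    @classmethod
    def from_networkx(
        cls,
        G: nx.Graph,
        labels: Sequence[str] | None = None,
        weighted: bool | None = None,
    ) -> "Network":
        nodes = list(G.nodes())
        A = nx.to_numpy_array(G, nodelist=nodes, weight="weight")
        if labels is None:
            labels = [str(v) for v in nodes]
        if weighted is None:
            nz = A[A != 0]
            weighted = bool(nz.size and not np.all(nz == 1))
        return cls(A, tuple(labels), weighted)

    def with_adjacency(self, A: np.ndarray, weighted: bool | None = None) -> "Network":
        return Network(A, self.node_labels, self.weighted if weighted is None else weighted)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _tokenize(line: str) -> list[str]:
    line = line.strip()
    if "," in line:
        return [t.strip() for t in line.split(",") if t.strip() != ""]
    return line.split()


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _read_edgelist(path: Path) -> Network:
    rows: list[tuple[str, str, float]] = []
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise EmptyInputError(f"{path}: no edges found")
    any_weight_col = False
    for k, ln in enumerate(lines):
        toks = _tokenize(ln)
        if len(toks) not in (2, 3):
            raise NetworkFormatError(
                f"{path}: line {k + 1} has {len(toks)} columns (expected 2 or 3)"
            )
        if k == 0 and len(toks) == 3 and not _is_number(toks[2]):
            continue  # header row detected by non-numeric weight column
        if len(toks) == 3:
            w = float(toks[2])
            if w < 0:
                raise NetworkValidationError(f"{path}: negative weight on line {k + 1}")
            any_weight_col = True
        else:
            w = 1.0
        rows.append((toks[0], toks[1], w))
    if not rows:
        raise EmptyInputError(f"{path}: no edges found")

    labels: list[str] = []
    index: dict[str, int] = {}
    for u, v, _ in rows:
        for x in (u, v):
            if x not in index:
                index[x] = len(labels)
                labels.append(x)
    n = len(labels)
    A = np.zeros((n, n))
    seen: set[tuple[int, int]] = set()
    for u, v, w in rows:
        i, j = index[u], index[v]
        key = (min(i, j), max(i, j))
        if key in seen:
            logger.warning("duplicate edge %s-%s: keeping last-seen weight %g", u, v, w)
        seen.add(key)
        A[i, j] = w
        A[j, i] = w
    np.fill_diagonal(A, 0.0)
    nz = A[A != 0]
    weighted = bool(any_weight_col and nz.size and not np.all(nz == 1))
    if not weighted:
        A = (A > 0).astype(float)
    return Network(np.maximum(A, A.T), tuple(labels), weighted)


def _read_adjacency(path: Path) -> Network:
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise EmptyInputError(f"{path}: empty adjacency file")
    table = [_tokenize(ln) for ln in lines]
    labels: list[str] | None = None
    # header row: any non-numeric token in the first row
    if any(not _is_number(t) for t in table[0]):
        header = table[0]
        body = table[1:]
    else:
        header = None
        body = table
    if not body:
        raise EmptyInputError(f"{path}: adjacency file has a header but no rows")
    n_rows = len(body)
    # rows carry a leading label column when the body is one column wider
    # than square, or when the first cell is non-numeric
    row_labels = None
    has_label_col = not _is_number(body[0][0]) or (
        header is not None and len(header) == n_rows + 1 and len(body[0]) == n_rows + 1
    )
    if has_label_col:
        row_labels = [r[0] for r in body]
        body = [r[1:] for r in body]
    if header is not None:
        labels = header[1:] if len(header) == n_rows + 1 else header
    try:
        A = np.array([[float(x) for x in r] for r in body])
    except ValueError as exc:
        raise NetworkFormatError(f"{path}: non-numeric cell in adjacency body") from exc
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise NetworkFormatError(
            f"{path}: adjacency matrix is not square (shape {A.shape})"
        )
    if np.any(A < 0):
        raise NetworkValidationError(f"{path}: negative weight in adjacency matrix")
    if labels is None:
        labels = row_labels if row_labels is not None else [str(i) for i in range(A.shape[0])]
    nz = A[A != 0]
    weighted = bool(nz.size and not np.all(nz == 1))
    A = np.maximum(A, A.T)
    np.fill_diagonal(A, 0.0)
    return Network(A, tuple(labels), weighted)


def read_network(path: str | Path, format: str | None = None) -> Network:
    """Read a network from an edge list or a dense adjacency matrix.

    Parameters
    ----------
    path : path
        Text file.  Edge lists have 2 or 3 whitespace/comma-separated
        columns (source, target, optional weight); adjacency files are
        dense CSV/TSV matrices with optional label header row/column.
    format : {"edgelist", "adjacency"}, optional
        Autodetected from content when omitted: a square all-numeric
        table wider than 3 columns is an adjacency matrix, otherwise
        an edge list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        with open(path) as fh:
            first = ""
            for ln in fh:
                if ln.strip() and not ln.lstrip().startswith("#"):
                    first = ln
                    break
        ncols = len(_tokenize(first))
        format = "edgelist" if ncols in (2, 3) else "adjacency"
    if format == "edgelist":
        return _read_edgelist(path)
    if format == "adjacency":
        return _read_adjacency(path)
    raise ValueError(f"unknown format {format!r}")


def write_network(net: Network, path: str | Path, format: str = "edgelist") -> None:
    """Write a network as an edge list or dense labelled adjacency CSV."""
    path = Path(path)
    if format == "edgelist":
        with open(path, "w") as fh:
            ii, jj = np.nonzero(np.triu(net.adjacency, 1))
            for i, j in zip(ii, jj):
                if net.weighted:
                    fh.write(
                        f"{net.node_labels[i]} {net.node_labels[j]} "
                        f"{float(net.adjacency[i, j])!r}\n"
                    )
                else:
                    fh.write(f"{net.node_labels[i]} {net.node_labels[j]}\n")
    elif format == "adjacency":
        with open(path, "w") as fh:
            fh.write("node," + ",".join(net.node_labels) + "\n")
            for i, lab in enumerate(net.node_labels):
                fh.write(lab + "," +
                         ",".join(repr(float(x)) for x in net.adjacency[i]) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess(net: Network | np.ndarray, binarize: bool = True,
               labels: Sequence[str] | None = None,
               weighted: bool | None = None) -> Network:
    """Bring a network into the canonical analysed form.

    Symmetrizes with ``A <- max(A, A^T)`` (a one-directional weighted edge
    keeps its weight), zeroes the diagonal, optionally binarizes, and keeps
    only the largest connected component (ties broken by the component
    containing the smallest node index).  Node ordering is preserved.

    Accepts either a :class:`Network` or a raw (possibly directed)
    adjacency matrix with optional ``labels``.

    Raises
    ------
    TooSmallError
        If the resulting component has fewer than 3 nodes.
    """
    if isinstance(net, Network):
        raw, node_labels, w = net.adjacency, net.node_labels, net.weighted
    else:
        raw = np.asarray(net, dtype=float)
        if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
            raise NetworkFormatError(f"adjacency must be square, got {raw.shape}")
        if np.any(raw < 0):
            raise NetworkValidationError("negative edge weights are not allowed")
        node_labels = tuple(labels) if labels is not None else tuple(
            str(i) for i in range(raw.shape[0]))
        nz = raw[raw != 0]
        w = bool(nz.size and not np.all(nz == 1)) if weighted is None else weighted
    A = np.maximum(raw, raw.T).astype(float)
    np.fill_diagonal(A, 0.0)
    weighted = w
    net = Network(A, node_labels, weighted)
    if binarize:
        A = (A > 0).astype(float)
        weighted = False
    n_comp, comp = csgraph.connected_components(csr_matrix(A), directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp, minlength=n_comp)
        best = max(
            range(n_comp),
            key=lambda c: (sizes[c], -int(np.flatnonzero(comp == c)[0])),
        )
        keep = np.flatnonzero(comp == best)
        A = A[np.ix_(keep, keep)]
        labels = tuple(net.node_labels[i] for i in keep)
    else:
        labels = net.node_labels
    if A.shape[0] < 3:
        raise TooSmallError(
            f"largest connected component has {A.shape[0]} nodes (< 3); "
            "centrality comparison is undefined"
        )
    nz = A[A != 0]
    if weighted and nz.size and np.all(nz == 1):
        weighted = False
    return Network(A, labels, weighted)
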