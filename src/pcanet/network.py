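"""Data model and I/O for partially observed friendship networks.

The central object is :class:`PartialNetwork`: an undirected simple graph in
which every node carries a *respondent* flag and every unordered pair of nodes
(a *dyad*) is classified as

* ``observed_present`` -- an observed friendship (an edge),
* ``observed_absent``  -- a pair known not to be friends, or
* ``unobserved``       -- a pair whose friendship status was never observed.

The observation design modelled here is the one produced by downloading the
friend lists of a set of survey respondents: every dyad with at least one
respondent endpoint is observed, and every nonrespondent-nonrespondent dyad is
unobserved.  Consequently a valid :class:`PartialNetwork` can never contain an
edge between two nonrespondents; such edges in input files are rejected as a
violation of the observation structure rather than silently reclassified.

:class:`Network` is the fully observed counterpart used for ground-truth
networks from the synthetic generator and for completed (imputed) networks; it
may carry nonrespondent-nonrespondent edges and marks a subset of its edges as
imputed.

Each node also carries a *sociability covariate*: its observed number of
friendships with respondents.  This quantity is always recomputed from the
edge list at construction time, so it can never drift out of sync with the
edges.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "OBSERVED_PRESENT",
    "OBSERVED_ABSENT",
    "UNOBSERVED",
    "NetworkValidationError",
    "UnknownNodeError",
    "SelfLoopError",
    "DuplicateEdgeError",
    "NonrespondentEdgeError",
    "BoundaryWarning",
    "NodeRecord",
    "PartialNetwork",
    "Network",
    "BoundarySpec",
    "QuadrantSummary",
    "apply_boundary",
    "boundary_table",
    "quadrant_summary",
    "degree_distribution",
    "read_network",
    "read_complete_network",
    "write_network",
    "to_graphml",
    "round_half_away",
    "as_percent",
    "unobserved_dyad_count",
]

# Dyad status labels.
OBSERVED_PRESENT = "observed_present"
OBSERVED_ABSENT = "observed_absent"
UNOBSERVED = "unobserved"


class NetworkValidationError(ValueError):
    """Base class for all input-validation failures."""


class UnknownNodeError(NetworkValidationError):
    """An edge references a node id absent from the node table."""


class SelfLoopError(NetworkValidationError):
    """An edge connects a node to itself."""


class DuplicateEdgeError(NetworkValidationError):
    """The same unordered pair appears more than once in the edge list."""


class NonrespondentEdgeError(NetworkValidationError):
    """An edge joins two nonrespondents, which the observation design forbids."""


class BoundaryWarning(UserWarning):
    """Raised when a boundary threshold retains no nonrespondents."""


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (the convention used for all
    reported percentages and mean degrees)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def as_percent(proportion: float | None, ndigits: int = 1) -> float | None:
    """Proportion -> printed percentage (one decimal, half away from zero)."""
    if proportion is None:
        return None
    return round_half_away(100.0 * proportion, ndigits)


def unobserved_dyad_count(n_nonrespondents: int) -> int:
    """Number of unobserved dyads implied by ``n`` nonrespondents: C(n, 2)."""
    return math.comb(int(n_nonrespondents), 2)


@dataclass(frozen=True)
class NodeRecord:
    """A single node: id, respondent flag, sociability covariate and optional
    attributes that are carried through but never used in computation.

    ``soc_covariate`` is the node's observed degree counting only respondent
    neighbours.  It is recomputed from the edge list whenever a network is
    constructed.
    """

    node_id: str
    is_respondent: bool
    soc_covariate: int = 0
    age: float | None = None
    city: str | None = None


def _canonical_pair(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


class _BaseNetwork:
    """Shared machinery for :class:`PartialNetwork` and :class:`Network`.

    Nodes are stored in lexicographic id order; that order defines the index
    used by every array-valued accessor (adjacency matrix, flag vectors).
    """

    _allow_nonrespondent_edges: bool = False

    def __init__(
        self,
        nodes: Iterable[NodeRecord],
        edges: Iterable[tuple[str, str]],
    ) -> None:
        records = sorted(nodes, key=lambda r: r.node_id)
        ids = [r.node_id for r in records]
        if len(set(ids)) != len(ids):
            dupes = pd.Series(ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise NetworkValidationError(f"duplicate node ids: {dupes}")
        self._ids: list[str] = ids
        self._index: dict[str, int] = {nid: k for k, nid in enumerate(ids)}
        self._is_resp = np.array([r.is_respondent for r in records], dtype=bool)

        edge_idx = self._validate_edges(edges)
        self._edge_idx = edge_idx  # (E, 2) int array, row-wise i < j, sorted
        soc = self._compute_soc()
        self._records: dict[str, NodeRecord] = {
            r.node_id: replace(r, soc_covariate=int(soc[self._index[r.node_id]]))
            for r in records
        }
        self._soc = soc
        self._edge_set: set[tuple[str, str]] | None = None

    # -- validation ------------------------------------------------------

    def _validate_edges(self, edges: Iterable[tuple[str, str]]) -> np.ndarray:
        rows = []
        for u, v in edges:
            iu = self._index.get(u)
            iv = self._index.get(v)
            if iu is None or iv is None:
                missing = u if iu is None else v
                raise UnknownNodeError(f"edge ({u}, {v}) references unknown node {missing!r}")
            if iu == iv:
                raise SelfLoopError(f"self-loop on node {u!r}")
            rows.append((iu, iv) if iu < iv else (iv, iu))
        if not rows:
            return np.empty((0, 2), dtype=np.int64)
        arr = np.array(rows, dtype=np.int64)
        order = np.lexsort((arr[:, 1], arr[:, 0]))
        arr = arr[order]
        dup = np.all(arr[1:] == arr[:-1], axis=1) if len(arr) > 1 else np.zeros(0, bool)
        if dup.any():
            k = int(np.flatnonzero(dup)[0])
            u, v = self._ids[arr[k, 0]], self._ids[arr[k, 1]]
            raise DuplicateEdgeError(f"duplicate edge ({u}, {v})")
        if not self._allow_nonrespondent_edges:
            both_nonresp = ~self._is_resp[arr[:, 0]] & ~self._is_resp[arr[:, 1]]
            if both_nonresp.any():
                k = int(np.flatnonzero(both_nonresp)[0])
                u, v = self._ids[arr[k, 0]], self._ids[arr[k, 1]]
                raise NonrespondentEdgeError(
                    f"edge ({u}, {v}) joins two nonrespondents; nonrespondent-"
                    "nonrespondent dyads are unobserved and cannot carry edges"
                )
        return arr

    def _compute_soc(self) -> np.ndarray:
        """Observed degree counting respondent neighbours only."""
        soc = np.zeros(len(self._ids), dtype=np.int64)
        if len(self._edge_idx):
            a, b = self._edge_idx[:, 0], self._edge_idx[:, 1]
            np.add.at(soc, a, self._is_resp[b].astype(np.int64))
            np.add.at(soc, b, self._is_resp[a].astype(np.int64))
        return soc

    # -- basic accessors -------------------------------------------------

    @property
    def node_ids(self) -> list[str]:
        """Node ids in lexicographic order."""
        return list(self._ids)

    @property
    def nodes(self) -> list[NodeRecord]:
        return [self._records[nid] for nid in self._ids]

    @property
    def records(self) -> Mapping[str, NodeRecord]:
        return dict(self._records)

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Observed-present dyads as canonical (min, max) id pairs."""
        if self._edge_set is None:
            self._edge_set = {
                (self._ids[i], self._ids[j]) for i, j in self._edge_idx
            }
        return set(self._edge_set)

    def edge_list(self) -> list[tuple[str, str]]:
        """Edges sorted lexicographically (deterministic output order)."""
        return [(self._ids[i], self._ids[j]) for i, j in self._edge_idx]

    @property
    def n_nodes(self) -> int:
        return len(self._ids)

    @property
    def n_edges(self) -> int:
        return len(self._edge_idx)

    @property
    def n_resp(self) -> int:
        return int(self._is_resp.sum())

    @property
    def n_nonresp(self) -> int:
        return int((~self._is_resp).sum())

    def is_respondent(self, node_id: str) -> bool:
        return bool(self._is_resp[self._index[node_id]])

    def respondents(self) -> list[str]:
        return [nid for nid, r in zip(self._ids, self._is_resp) if r]

    def nonrespondents(self) -> list[str]:
        return [nid for nid, r in zip(self._ids, self._is_resp) if not r]

    def respondent_flags(self) -> dict[str, bool]:
        return {nid: bool(f) for nid, f in zip(self._ids, self._is_resp)}

    def soc_covariate(self, node_id: str) -> int:
        return int(self._soc[self._index[node_id]])

    def soc_covariates(self) -> dict[str, int]:
        return {nid: int(s) for nid, s in zip(self._ids, self._soc)}

    def has_edge(self, u: str, v: str) -> bool:
        return _canonical_pair(u, v) in self.edges

    def degrees(self) -> dict[str, int]:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        if len(self._edge_idx):
            np.add.at(deg, self._edge_idx[:, 0], 1)
            np.add.at(deg, self._edge_idx[:, 1], 1)
        return {nid: int(d) for nid, d in zip(self._ids, deg)}

    def adjacency_matrix(self) -> sparse.csr_matrix:
        """Symmetric 0/1 adjacency in lexicographic node order."""
        n = self.n_nodes
        if not len(self._edge_idx):
            return sparse.csr_matrix((n, n))
        a, b = self._edge_idx[:, 0], self._edge_idx[:, 1]
        data = np.ones(2 * len(a))
        return sparse.csr_matrix(
            (data, (np.concatenate([a, b]), np.concatenate([b, a]))), shape=(n, n)
        )

    # internal: quadrant edge counts
    def _edge_quadrants(self) -> tuple[int, int, int]:
        if not len(self._edge_idx):
            return 0, 0, 0
        ra = self._is_resp[self._edge_idx[:, 0]]
        rb = self._is_resp[self._edge_idx[:, 1]]
        rr = int((ra & rb).sum())
        rn = int((ra ^ rb).sum())
        nn = int((~ra & ~rb).sum())
        return rr, rn, nn


class PartialNetwork(_BaseNetwork):
    """A partially observed network: all dyads with a respondent endpoint are
    observed, all nonrespondent-nonrespondent dyads are unobserved."""

    _allow_nonrespondent_edges = False

    def dyad_status(self, u: str, v: str) -> str:
        """Classify the unordered pair (u, v)."""
        if u == v:
            raise SelfLoopError(f"({u}, {v}) is not a dyad")
        if u not in self._index or v not in self._index:
            missing = u if u not in self._index else v
            raise UnknownNodeError(f"unknown node {missing!r}")
        if not self.is_respondent(u) and not self.is_respondent(v):
            return UNOBSERVED
        return OBSERVED_PRESENT if self.has_edge(u, v) else OBSERVED_ABSENT

    @property
    def n_dyads(self) -> int:
        return math.comb(self.n_nodes, 2)

    @property
    def n_unobserved_dyads(self) -> int:
        return unobserved_dyad_count(self.n_nonresp)

    @property
    def n_observed_present(self) -> int:
        return self.n_edges

    @property
    def n_observed_absent(self) -> int:
        return self.n_dyads - self.n_unobserved_dyads - self.n_edges

    def unobserved_dyads(self) -> list[tuple[str, str]]:
        """All nonrespondent-nonrespondent pairs, lexicographically ordered."""
        nonresp = self.nonrespondents()
        return [
            (nonresp[i], nonresp[j])
            for i in range(len(nonresp))
            for j in range(i + 1, len(nonresp))
        ]

    def observed_graph(self) -> "Network":
        """The observed network with every unobserved dyad treated as absent."""
        return Network(self.nodes, self.edge_list())


class Network(_BaseNetwork):
    """A fully observed undirected simple network with respondent flags.

    ``imputed_edges`` marks the subset of edges that were filled in by
    imputation (empty for ground-truth networks from the generator).
    """

    _allow_nonrespondent_edges = True

    def __init__(
        self,
        nodes: Iterable[NodeRecord],
        edges: Iterable[tuple[str, str]],
        imputed_edges: Iterable[tuple[str, str]] = (),
    ) -> None:
        super().__init__(nodes, edges)
        imputed = {_canonical_pair(u, v) for u, v in imputed_edges}
        stray = imputed - self.edges
        if stray:
            raise NetworkValidationError(
                f"imputed edges not present in edge set: {sorted(stray)[:3]}"
            )
        self.imputed_edges: set[tuple[str, str]] = imputed


@dataclass(frozen=True)
class BoundarySpec:
    """Degree-based relational boundary: a nonrespondent is retained iff it
    has at least ``min_respondent_friends`` observed respondent friends."""

    min_respondent_friends: int

    def __post_init__(self) -> None:
        if self.min_respondent_friends < 1:
            raise ValueError("min_respondent_friends must be a positive integer")


def apply_boundary(net: _BaseNetwork, spec: BoundarySpec | int) -> _BaseNetwork:
    """Retain all respondents plus the nonrespondents meeting the boundary.

    Edges incident to removed nodes are dropped.  Sociability covariates are
    unchanged by construction: they count friendships with respondents, none
    of whom are removed (they are nevertheless recomputed and therefore
    guaranteed consistent).  Works on both partial and complete networks; for
    a complete network the nonrespondent-nonrespondent edges among retained
    nodes are kept.
    """
    if isinstance(spec, int):
        spec = BoundarySpec(spec)
    k = spec.min_respondent_friends
    keep = {
        r.node_id
        for r in net.nodes
        if r.is_respondent or r.soc_covariate >= k
    }
    if not any(not net._records[nid].is_respondent for nid in keep):
        warnings.warn(
            f"boundary k={k} retains no nonrespondents "
            "(k exceeds the maximum observed degree with respondents)",
            BoundaryWarning,
            stacklevel=2,
        )
    records = [r for r in net.nodes if r.node_id in keep]
    edges = [(u, v) for u, v in net.edge_list() if u in keep and v in keep]
    if isinstance(net, Network):
        imputed = [(u, v) for u, v in net.imputed_edges if u in keep and v in keep]
        return Network(records, edges, imputed)
    return PartialNetwork(records, edges)


def boundary_table(net: _BaseNetwork, thresholds: Sequence[int]) -> pd.DataFrame:
    """Tabulate the consequences of candidate boundary thresholds.

    One row per threshold ``k``: the percentage of respondents ``k``
    corresponds to, the number of nonrespondents retained, the number of
    respondent-nonrespondent edges retained, and the number of unobserved
    nonrespondent-nonrespondent dyads implied (``C(n_retained, 2)``).
    """
    if not len(thresholds):
        raise ValueError("thresholds must be nonempty")
    if any(int(k) < 1 for k in thresholds):
        raise ValueError("thresholds must be positive")
    n_resp = net.n_resp
    nonresp_soc = np.array(
        [r.soc_covariate for r in net.nodes if not r.is_respondent], dtype=np.int64
    )
    rows = []
    for k in thresholds:
        k = int(k)
        retained = nonresp_soc[nonresp_soc >= k]
        rows.append(
            {
                "k": k,
                "pct_of_respondents": round_half_away(100.0 * k / n_resp, 1)
                if n_resp
                else float("nan"),
                "n_nonresp_retained": int(retained.size),
                "edges_rn_retained": int(retained.sum()),
                "unobserved_dyads_nn": unobserved_dyad_count(retained.size),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class QuadrantSummary:
    """Edge counts, densities and mean degrees for the observed quadrants.

    Densities are proportions in [0, 1]; ``None`` marks quantities whose
    denominator is empty (e.g. respondent-respondent density with fewer than
    two respondents).  Use :func:`as_percent` at the reporting layer.
    """

    n_resp: int
    n_nonresp: int
    edges_rr: int
    edges_rn: int
    density_rr: float | None
    density_rn: float | None
    unobserved_dyads_nn: int
    mean_degree_resp_total: float | None
    mean_degree_resp_resp: float | None
    mean_degree_resp_nonresp: float | None
    mean_degree_nonresp_observed: float | None

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["density_rr_pct"] = as_percent(self.density_rr)
        d["density_rn_pct"] = as_percent(self.density_rn)
        return d


def quadrant_summary(net: PartialNetwork) -> QuadrantSummary:
    """Summarise the observed quadrants of a partially observed network."""
    rr, rn, _ = net._edge_quadrants()
    n_r, n_n = net.n_resp, net.n_nonresp
    dyads_rr = math.comb(n_r, 2)
    dyads_rn = n_r * n_n
    return QuadrantSummary(
        n_resp=n_r,
        n_nonresp=n_n,
        edges_rr=rr,
        edges_rn=rn,
        density_rr=(rr / dyads_rr) if dyads_rr else None,
        density_rn=(rn / dyads_rn) if dyads_rn else None,
        unobserved_dyads_nn=unobserved_dyad_count(n_n),
        mean_degree_resp_total=((2 * rr + rn) / n_r) if n_r else None,
        mean_degree_resp_resp=(2 * rr / n_r) if n_r else None,
        mean_degree_resp_nonresp=(rn / n_r) if n_r else None,
        mean_degree_nonresp_observed=(rn / n_n) if n_n else None,
    )


def degree_distribution(
    net: _BaseNetwork, role: str, bin_width: int = 10
) -> pd.DataFrame:
    """Histogram of degrees for one role, binned into half-open intervals
    ``[b, b + bin_width)``.

    Degrees count all present edges, so on a completed network imputed edges
    contribute; on a partial network only observed edges exist.  Bins from 0
    through the maximum observed degree are included (empty bins have count
    0), and counts sum to the number of nodes of the requested role.
    """
    if role not in ("respondent", "nonrespondent"):
        raise ValueError("role must be 'respondent' or 'nonrespondent'")
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    want_resp = role == "respondent"
    deg = net.degrees()
    values = np.array(
        [deg[r.node_id] for r in net.nodes if r.is_respondent == want_resp],
        dtype=np.int64,
    )
    if values.size == 0:
        return pd.DataFrame({"bin_start": [], "count": []}).astype(
            {"bin_start": np.int64, "count": np.int64}
        )
    n_bins = int(values.max() // bin_width) + 1
    starts = np.arange(n_bins, dtype=np.int64) * bin_width
    counts = np.bincount(values // bin_width, minlength=n_bins)
    return pd.DataFrame({"bin_start": starts, "count": counts.astype(np.int64)})


# ---------------------------------------------------------------------------
# File I/O.  Node table: CSV with columns node_id,is_respondent[,age,city];
# edge list: CSV with columns source,target[,imputed].
# ---------------------------------------------------------------------------


def _read_node_table(node_table_path) -> list[NodeRecord]:
    df = pd.read_csv(node_table_path, dtype={"node_id": str})
    for col in ("node_id", "is_respondent"):
        if col not in df.columns:
            raise NetworkValidationError(f"node table missing column {col!r}")
    if df["node_id"].duplicated().any():
        dupes = sorted(df.loc[df["node_id"].duplicated(), "node_id"].unique())
        raise NetworkValidationError(f"duplicate node ids in node table: {dupes}")
    records = []
    for row in df.itertuples(index=False):
        age = getattr(row, "age", None)
        city = getattr(row, "city", None)
        records.append(
            NodeRecord(
                node_id=str(row.node_id),
                is_respondent=_parse_bool(row.is_respondent),
                age=None if age is None or pd.isna(age) else float(age),
                city=None if city is None or pd.isna(city) else str(city),
            )
        )
    return records


def _parse_bool(x) -> bool:
    if isinstance(x, str):
        s = x.strip().lower()
        if s in ("1", "true", "t", "yes"):
            return True
        if s in ("0", "false", "f", "no"):
            return False
        raise NetworkValidationError(f"cannot parse respondent flag {x!r}")
    return bool(int(x))


def _read_edge_list(edge_list_path) -> pd.DataFrame:
    df = pd.read_csv(edge_list_path, dtype={"source": str, "target": str})
    for col in ("source", "target"):
        if col not in df.columns:
            raise NetworkValidationError(f"edge list missing column {col!r}")
    return df


def read_network(node_table_path, edge_list_path) -> PartialNetwork:
    """Read a partially observed network from a node table and an edge list.

    Validation failures each raise a distinct error: :class:`UnknownNodeError`,
    :class:`SelfLoopError`, :class:`DuplicateEdgeError` and
    :class:`NonrespondentEdgeError`.
    """
    records = _read_node_table(node_table_path)
    df = _read_edge_list(edge_list_path)
    edges = list(zip(df["source"], df["target"]))
    return PartialNetwork(records, edges)


def read_complete_network(node_table_path, edge_list_path) -> Network:
    """Read a completed network; an optional ``imputed`` edge column marks
    which edges were filled in by imputation."""
    records = _read_node_table(node_table_path)
    df = _read_edge_list(edge_list_path)
    edges = list(zip(df["source"], df["target"]))
    imputed: list[tuple[str, str]] = []
    if "imputed" in df.columns:
        mask = df["imputed"].astype(int).astype(bool)
        imputed = list(zip(df.loc[mask, "source"], df.loc[mask, "target"]))
    return Network(records, edges, imputed)


def write_network(net: _BaseNetwork, node_table_path, edge_list_path) -> None:
    """Write a network back to CSV, losslessly (inverse of the readers).

    Nodes and edges are written in lexicographic order.  Optional ``age`` and
    ``city`` columns appear only when at least one node carries the value.
    Complete networks always include the ``imputed`` edge column.
    """
    records = net.nodes
    node_df = pd.DataFrame(
        {
            "node_id": [r.node_id for r in records],
            "is_respondent": [int(r.is_respondent) for r in records],
        }
    )
    if any(r.age is not None for r in records):
        node_df["age"] = [r.age for r in records]
    if any(r.city is not None for r in records):
        node_df["city"] = [r.city for r in records]
    node_df.to_csv(node_table_path, index=False)

    pairs = net.edge_list()
    edge_df = pd.DataFrame(pairs, columns=["source", "target"]).astype(str)
    if not pairs:
        edge_df = pd.DataFrame({"source": [], "target": []})
    if isinstance(net, Network):
        imputed = net.imputed_edges
        edge_df["imputed"] = [int(p in imputed) for p in pairs]
    edge_df.to_csv(edge_list_path, index=False)


def to_graphml(net: _BaseNetwork, path) -> None:
    """Export to GraphML with a boolean node attribute ``is_respondent`` and,
    for completed networks, a boolean edge attribute ``imputed``."""
    import networkx as nx

    g = nx.Graph()
    for r in net.nodes:
        g.add_node(r.node_id, is_respondent=bool(r.is_respondent))
    imputed = net.imputed_edges if isinstance(net, Network) else set()
    for u, v in net.edge_list():
        g.add_edge(u, v, imputed=bool((u, v) in imputed))
    nx.write_graphml(g, path)
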