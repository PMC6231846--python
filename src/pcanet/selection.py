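"""Peer change agent (PCA) selection: eigenvector centrality and KPP-Pos.

Two selection algorithms suited to information diffusion are provided.

*Eigenvector centrality* scores each node by the principal eigenvector of
the adjacency matrix (influence via unrestricted walks); the m
highest-scoring nodes form the PCA set.  Scores are computed by power
iteration on the spectrally shifted operator A + I: the shift leaves the
eigenvectors unchanged but makes the dominant eigenvalue strictly largest
in modulus, which is required for convergence on bipartite graphs (whose
adjacency spectra are symmetric about zero).

*Keyplayer positive (KPP-Pos)* is set-based: it maximises the
distance-weighted reach

    D_R(S) = (sum over j not in S of 1 / d(S, j)) / n,

where d(S, j) is the shortest-path distance from j to the nearest member of
S and 1/inf = 0 for unreachable nodes.  Members contribute through the
normalisation only (Borgatti's convention).  The optimal set need not
consist of the individually highest-scoring nodes, so the search is greedy
seeding followed by seeded improvement-only swap sweeps.

Selections across an ensemble of imputed networks are aggregated into
per-node selection counts, and a *sufficiency cutoff* converts the counts
into the sPCA set: the count threshold whose set size is closest to the
target m (ties resolved toward the higher threshold, i.e. the smaller set).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .imputation import ImputedEnsemble
from .network import Network, PartialNetwork

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "EmptyGraphError",
    "eigenvector_scores",
    "top_m",
    "kpp_fitness",
    "kpp_select",
    "aggregate_selections",
    "sufficiency_cutoff",
    "select_pcas",
]

_POWER_TOL = 1e-10
_POWER_MAXITER = 10_000


class EmptyGraphError(ValueError):
    """Selection requested on a graph with no nodes."""


@dataclass(frozen=True)
class SelectionConfig:
    """How to pick a PCA set: algorithm, target size m, keyplayer search
    effort and the master seed for all selection randomness."""

    algorithm: str = "eigenvector"
    m: int = 300
    kp_restarts: int = 1
    kp_max_sweeps: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("eigenvector", "keyplayer"):
            raise ValueError("algorithm must be 'eigenvector' or 'keyplayer'")
        if self.m < 1:
            raise ValueError("m must be >= 1")


def eigenvector_scores(net: Network | PartialNetwork) -> dict[str, float]:
    """Eigenvector centrality for every node, normalised to unit Euclidean
    length.

    Power iteration on A + I from a uniform start vector, with
    relative-change stopping at 1e-10 and at most 10,000 iterations.  Nodes
    outside the dominant component receive scores that decay to ~0.  On an
    edgeless graph the scores are uniform (every vector is an eigenvector of
    A + I); callers selecting from such a graph fall back to the id
    tie-break.
    """
    if isinstance(net, PartialNetwork):
        net = net.observed_graph()
    n = net.n_nodes
    if n == 0:
        raise EmptyGraphError("cannot score an empty graph")
    A = net.adjacency_matrix()
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(_POWER_MAXITER):
        y = A @ x + x  # (A + I) x : same eigenvectors, positive-shifted spectrum
        y /= np.linalg.norm(y)
        if np.linalg.norm(y - x) < _POWER_TOL:
            x = y
            break
        x = y
    return {nid: float(s) for nid, s in zip(net.node_ids, np.abs(x))}


def top_m(scores: Mapping[str, float], m: int) -> frozenset[str]:
    """The m highest-scoring node ids; boundary ties broken lexicographically."""
    if m > len(scores):
        raise ValueError(f"m={m} exceeds number of nodes {len(scores)}")
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return frozenset(nid for nid, _ in ranked[:m])


def _distance_matrix(net: Network) -> np.ndarray:
    """All-pairs shortest-path (hop) distances; inf for unreachable pairs."""
    A = net.adjacency_matrix()
    return shortest_path(A, directed=False, unweighted=True)


def _reach_fitness(dmin: np.ndarray, member_mask: np.ndarray) -> float:
    """D_R from per-node nearest-member distances; members excluded from the
    sum but included in the normalising n."""
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dmin) & (dmin > 0), 1.0 / dmin, 0.0)
    inv[member_mask] = 0.0
    return float(inv.sum() / len(dmin))


def kpp_fitness(net: Network, S: Iterable[str]) -> float:
    """Distance-weighted reach D_R(S) of a candidate keyplayer set."""
    members = sorted(set(S))
    if not members:
        raise ValueError("keyplayer set must be nonempty")
    index = {nid: k for k, nid in enumerate(net.node_ids)}
    midx = np.array([index[u] for u in members], dtype=np.int64)
    A = net.adjacency_matrix()
    d = shortest_path(A, directed=False, unweighted=True, indices=midx)
    dmin = d.min(axis=0) if d.ndim == 2 else d
    mask = np.zeros(net.n_nodes, dtype=bool)
    mask[midx] = True
    return _reach_fitness(dmin, mask)


def _greedy_seed(D: np.ndarray, m: int) -> tuple[list[int], np.ndarray, float]:
    """Iteratively add the node maximising the reach gain (ties -> smallest
    index, i.e. lexicographically first id)."""
    n = D.shape[0]
    members: list[int] = []
    member_mask = np.zeros(n, dtype=bool)
    dmin = np.full(n, np.inf)
    fitness = 0.0
    for _ in range(m):
        cand = np.flatnonzero(~member_mask)
        cand_dmin = np.minimum(dmin[None, :], D[cand, :])
        with np.errstate(divide="ignore"):
            inv = np.where(
                np.isfinite(cand_dmin) & (cand_dmin > 0), 1.0 / cand_dmin, 0.0
            )
        inv[:, member_mask] = 0.0
        inv[np.arange(len(cand)), cand] = 0.0
        fits = inv.sum(axis=1) / n
        best = int(np.argmax(fits))  # first max -> smallest candidate index
        v = int(cand[best])
        fitness = float(fits[best])
        members.append(v)
        member_mask[v] = True
        dmin = np.minimum(dmin, D[v, :])
    return members, dmin, fitness


def _swap_improve(
    D: np.ndarray,
    members: list[int],
    fitness: float,
    max_sweeps: int,
    rng: np.random.Generator,
) -> tuple[list[int], float]:
    """Improvement-only member<->nonmember swaps, best replacement per member,
    members visited in seeded random order; stops early on a sweep with no
    accepted swap."""
    n = D.shape[0]
    members = list(members)
    member_mask = np.zeros(n, dtype=bool)
    member_mask[members] = True
    for _ in range(max_sweeps):
        improved = False
        order = rng.permutation(len(members))
        for pos in order:
            u = members[pos]
            rest = [w for w in members if w != u]
            dmin_rest = (
                D[rest, :].min(axis=0) if rest else np.full(n, np.inf)
            )
            cand = np.flatnonzero(~member_mask)
            cand_dmin = np.minimum(dmin_rest[None, :], D[cand, :])
            with np.errstate(divide="ignore"):
                inv = np.where(
                    np.isfinite(cand_dmin) & (cand_dmin > 0), 1.0 / cand_dmin, 0.0
                )
            rest_mask = np.zeros(n, dtype=bool)
            rest_mask[rest] = True
            inv[:, rest_mask] = 0.0
            inv[np.arange(len(cand)), cand] = 0.0
            fits = inv.sum(axis=1) / n
            best = int(np.argmax(fits))
            if fits[best] > fitness + 1e-12:
                v = int(cand[best])
                member_mask[u] = False
                member_mask[v] = True
                members[pos] = v
                fitness = float(fits[best])
                improved = True
        if not improved:
            break
    return members, fitness


def kpp_select(
    net: Network,
    m: int,
    kp_restarts: int = 1,
    kp_max_sweeps: int = 4,
    seed: int = 0,
) -> frozenset[str]:
    """KPP-Pos set of size m: greedy seeding plus seeded swap hill-climbing,
    best of ``kp_restarts`` restarts.  Deterministic given the seed, and the
    returned set's fitness is never below the pure greedy seed's."""
    n = net.n_nodes
    if n == 0:
        raise EmptyGraphError("cannot select from an empty graph")
    if m > n:
        raise ValueError(f"m={m} exceeds number of nodes {n}")
    ids = net.node_ids
    if m == n:
        return frozenset(ids)
    D = _distance_matrix(net)
    greedy_members, _, greedy_fitness = _greedy_seed(D, m)
    best_members, best_fitness = list(greedy_members), greedy_fitness
    for r in range(kp_restarts):
        rng = np.random.default_rng([seed, r])
        if r == 0:
            start, start_fitness = greedy_members, greedy_fitness
        else:
            # diversify: later restarts hill-climb from a random seed set
            start = list(rng.choice(n, size=m, replace=False))
            mask = np.zeros(n, dtype=bool)
            mask[start] = True
            start_fitness = _reach_fitness(D[start, :].min(axis=0), mask)
        members, fitness = _swap_improve(D, start, start_fitness, kp_max_sweeps, rng)
        if fitness > best_fitness + 1e-12:
            best_members, best_fitness = members, fitness
    return frozenset(ids[k] for k in best_members)


def _select_on(net: Network, config: SelectionConfig, seed: int) -> frozenset[str]:
    if config.algorithm == "eigenvector":
        return top_m(eigenvector_scores(net), config.m)
    return kpp_select(
        net,
        config.m,
        kp_restarts=config.kp_restarts,
        kp_max_sweeps=config.kp_max_sweeps,
        seed=seed,
    )


def _member_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % 2**31)


def aggregate_selections(
    ensemble: ImputedEnsemble, config: SelectionConfig
) -> dict[str, int]:
    """counts[v] = number of ensemble networks on which v is selected.

    Nodes never selected are absent from the mapping (count 0).  Keyplayer
    randomness on member i uses a stream derived from (config.seed, i).
    """
    if len(ensemble) == 0:
        raise ValueError("ensemble must be nonempty")
    counts: dict[str, int] = {}
    for i, member in enumerate(ensemble):
        chosen = _select_on(member, config, _member_seed(config.seed, i))
        for v in chosen:
            counts[v] = counts.get(v, 0) + 1
    return counts


def sufficiency_cutoff(
    counts: Mapping[str, int], m_target: int, M: int
) -> tuple[int, frozenset[str]]:
    """Pick the count threshold whose selected-set size is closest to the
    target; among ties prefer the larger threshold (the smaller set).

    Scans integer thresholds t from M down to 1, where the set at t is
    {v : counts[v] >= t}.
    """
    if not counts:
        raise ValueError("counts must be nonempty")
    values = np.array(list(counts.values()))
    best_t, best_gap = None, None
    for t in range(M, 0, -1):
        s = int((values >= t).sum())
        gap = abs(s - m_target)
        if best_gap is None or gap < best_gap:  # strict: keeps the larger t on ties
            best_t, best_gap = t, gap
    spca = frozenset(v for v, c in counts.items() if c >= best_t)
    return best_t, spca


def _composition(node_set: Iterable[str], flags: Mapping[str, bool]) -> dict:
    ids = set(node_set)
    n_resp = sum(1 for v in ids if flags[v])
    return {
        "n": len(ids),
        "n_respondent": n_resp,
        "n_nonrespondent": len(ids) - n_resp,
    }


@dataclass(frozen=True)
class SelectionResult:
    """PCA selection on the observed network plus ensemble aggregation."""

    algorithm: str
    m: int
    M: int
    seed: int
    observed_set: frozenset[str]
    counts: dict[str, int]
    cutoff: int
    spca_set: frozenset[str]
    observed_composition: dict
    spca_composition: dict

    def to_json_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "m": self.m,
            "M": self.M,
            "seed": self.seed,
            "observed_set": sorted(self.observed_set),
            "counts": dict(sorted(self.counts.items())),
            "cutoff": self.cutoff,
            "spca_set": sorted(self.spca_set),
            "observed_composition": self.observed_composition,
            "spca_composition": self.spca_composition,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SelectionResult":
        return cls(
            algorithm=d["algorithm"],
            m=d["m"],
            M=d["M"],
            seed=d["seed"],
            observed_set=frozenset(d["observed_set"]),
            counts={k: int(v) for k, v in d["counts"].items()},
            cutoff=int(d["cutoff"]),
            spca_set=frozenset(d["spca_set"]),
            observed_composition=d["observed_composition"],
            spca_composition=d["spca_composition"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "SelectionResult":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


def select_pcas(
    partial_net: PartialNetwork,
    ensemble: ImputedEnsemble,
    config: SelectionConfig,
) -> SelectionResult:
    """Full selection for one algorithm: PCAs on the observed network (all
    unobserved dyads treated as absent), selection counts across the
    ensemble, and the sufficiency-cutoff sPCA set."""
    observed = _select_on(
        partial_net.observed_graph(), config, _member_seed(config.seed, len(ensemble))
    )
    counts = aggregate_selections(ensemble, config)
    cutoff, spca = sufficiency_cutoff(counts, config.m, len(ensemble))
    flags = partial_net.respondent_flags()
    return SelectionResult(
        algorithm=config.algorithm,
        m=config.m,
        M=len(ensemble),
        seed=config.seed,
        observed_set=observed,
        counts=counts,
        cutoff=cutoff,
        spca_set=spca,
        observed_composition=_composition(observed, flags),
        spca_composition=_composition(spca, flags),
    )
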