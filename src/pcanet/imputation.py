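"""Dyad-model estimation and multiple imputation of unobserved dyads.

The imputation model is a three-statistic exponential-family random graph
model: an edges (intercept) term, a *sociability* term (the sum of the two
endpoints' observed degrees with respondents), and a *selective mixing* term
(an indicator that exactly one endpoint is a respondent).  All three
statistics are dyad-independent, so the ERGM likelihood factorises over
dyads and the maximum-likelihood fit conditional on the observed dyads is
exactly a logistic regression of the dyad state on (intercept, soc_sum,
is_mixed) over the observed dyads; :func:`fit_dyad_model` exploits this
equivalence and estimation is therefore exact, not MCMC-based.

For the same reason, a random draw of the unobserved dyads from the fitted
model is a set of independent Bernoulli draws (:func:`impute_ensemble`).
The MCMC toggling procedure that general ERGM simulation would use is kept
as :func:`toggling_sampler`: Metropolis toggles restricted to the unobserved
dyads, whose stationary distribution is identical to the independent
scheme.  It serves as a fidelity check, not as the default path.

Sociability covariates are frozen at their observed values throughout:
the covariate is defined as degree *with respondents*, and imputation only
ever adds nonrespondent-nonrespondent edges, which cannot change it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .network import Network, PartialNetwork

__all__ = [
    "DyadModel",
    "ImputedEnsemble",
    "SeparationError",
    "SingularDesignError",
    "build_dyad_design",
    "fit_dyad_model",
    "impute_ensemble",
    "toggling_sampler",
    "imputation_diagnostics",
]


class SeparationError(RuntimeError):
    """The observed dyads are all present or all absent; the logistic MLE
    does not exist."""


class SingularDesignError(RuntimeError):
    """The design matrix over observed dyads is rank-deficient."""


@dataclass(frozen=True)
class DyadModel:
    """Fitted log-odds parameters of the three-term dyad model."""

    theta_edges: float
    theta_soc: float
    theta_mix: float
    se_edges: float
    se_soc: float
    se_mix: float
    n_obs_dyads: int

    def __post_init__(self) -> None:
        params = (self.theta_edges, self.theta_soc, self.theta_mix)
        ses = (self.se_edges, self.se_soc, self.se_mix)
        if not all(math.isfinite(p) for p in params):
            raise ValueError("dyad-model parameters must be finite")
        if not all(s > 0 and math.isfinite(s) for s in ses):
            raise ValueError("standard errors must be positive and finite")

    def predict_logit(self, soc_sum, is_mixed) -> np.ndarray:
        return (
            self.theta_edges
            + self.theta_soc * np.asarray(soc_sum, dtype=float)
            + self.theta_mix * np.asarray(is_mixed, dtype=float)
        )

    def predict_prob(self, soc_sum, is_mixed) -> np.ndarray:
        return expit(self.predict_logit(soc_sum, is_mixed))

    def to_json_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_json_dict(cls, d: dict) -> "DyadModel":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__})

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "DyadModel":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


def build_dyad_design(net: PartialNetwork) -> pd.DataFrame:
    """One row per dyad: response (1/0/NaN), soc_sum, is_mixed.

    The response follows the observation coding: observed existent ties are
    1, observed nonexistent ties are 0, unobserved (nonrespondent-
    nonrespondent) dyads are missing.  Missing-response rows are excluded
    from estimation but retained here for prediction.  Row count is always
    C(n, 2); dyads are in lexicographic (i, j) order.
    """
    ids = net.node_ids
    n = len(ids)
    is_resp = np.array([net.is_respondent(i) for i in ids], dtype=bool)
    soc = np.array([net.soc_covariate(i) for i in ids], dtype=np.int64)

    iu, ju = np.triu_indices(n, k=1)
    adj = np.zeros((n, n), dtype=bool)
    if net.n_edges:
        idx = {nid: k for k, nid in enumerate(ids)}
        e = np.array([(idx[u], idx[v]) for u, v in net.edge_list()], dtype=np.int64)
        adj[e[:, 0], e[:, 1]] = True
        adj[e[:, 1], e[:, 0]] = True

    response = adj[iu, ju].astype(float)
    unobserved = ~is_resp[iu] & ~is_resp[ju]
    response[unobserved] = np.nan
    return pd.DataFrame(
        {
            "node_i": np.asarray(ids, dtype=object)[iu],
            "node_j": np.asarray(ids, dtype=object)[ju],
            "response": response,
            "soc_sum": soc[iu] + soc[ju],
            "is_mixed": (is_resp[iu] ^ is_resp[ju]).astype(np.int8),
        }
    )


def fit_dyad_model(design: pd.DataFrame) -> DyadModel:
    """Maximum-likelihood logistic fit of the dyad model on observed dyads.

    Because the three statistics are dyad-independent, this logistic MLE
    coincides with the ERGM MLE conditional on the observed data.  Standard
    errors come from the observed-information matrix.
    """
    obs = design["response"].notna().to_numpy()
    y = design.loc[obs, "response"].to_numpy(dtype=float)
    if len(y) == 0 or y.min() == y.max():
        raise SeparationError(
            "observed dyads are all present or all absent; cannot estimate"
        )
    X = np.column_stack(
        [
            np.ones(len(y)),
            design.loc[obs, "soc_sum"].to_numpy(dtype=float),
            design.loc[obs, "is_mixed"].to_numpy(dtype=float),
        ]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(
            "design matrix is rank-deficient over observed dyads "
            "(e.g. every observed dyad is mixed, or soc_sum is constant)"
        )
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=200)
    params, bse = np.asarray(res.params), np.asarray(res.bse)
    if not (np.all(np.isfinite(params)) and np.all(np.isfinite(bse))):
        raise SeparationError("logistic fit did not converge to finite estimates")
    return DyadModel(
        theta_edges=float(params[0]),
        theta_soc=float(params[1]),
        theta_mix=float(params[2]),
        se_edges=float(bse[0]),
        se_soc=float(bse[1]),
        se_mix=float(bse[2]),
        n_obs_dyads=int(len(y)),
    )


def _unobserved_arrays(net: PartialNetwork):
    """Unobserved dyads as (id pairs, soc_sum, probability-model inputs)."""
    pairs = net.unobserved_dyads()
    soc = net.soc_covariates()
    soc_sum = np.array([soc[u] + soc[v] for u, v in pairs], dtype=np.float64)
    return pairs, soc_sum


@dataclass
class ImputedEnsemble:
    """M completed networks sharing the observed dyads.

    Members are materialised lazily from stored dyad indices; every member
    agrees with the base partial network on all observed dyads by
    construction.
    """

    base: PartialNetwork
    M: int
    seed: int
    unobserved_pairs: list[tuple[str, str]]
    member_dyad_indices: list[np.ndarray]
    imputed_edge_counts: list[int]

    def member(self, i: int) -> Network:
        idx = self.member_dyad_indices[i]
        imputed = [self.unobserved_pairs[k] for k in idx]
        return Network(
            self.base.nodes, self.base.edge_list() + imputed, imputed_edges=imputed
        )

    def __iter__(self):
        return (self.member(i) for i in range(self.M))

    def __len__(self) -> int:
        return self.M

    def to_frame(self) -> pd.DataFrame:
        """All imputed-present edges as rows (imputation, source, target)."""
        rows = []
        for m, idx in enumerate(self.member_dyad_indices):
            for k in idx:
                u, v = self.unobserved_pairs[k]
                rows.append((m, u, v))
        return pd.DataFrame(rows, columns=["imputation", "source", "target"])


def impute_ensemble(
    net: PartialNetwork, model: DyadModel, M: int = 100, seed: int = 0
) -> ImputedEnsemble:
    """Draw M completed networks from the fitted dyad model.

    Every unobserved dyad is nonrespondent-nonrespondent (is_mixed = 0), so
    it is imputed present independently with probability
    ``logistic(theta_edges + theta_soc * soc_sum)``.  Observed dyads are
    copied verbatim.  Per-imputation random streams are derived from the
    master seed by fixed offsets, so members are reproducible individually
    and under parallel execution.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    pairs, soc_sum = _unobserved_arrays(net)
    p = model.predict_prob(soc_sum, 0.0)
    members: list[np.ndarray] = []
    counts: list[int] = []
    for m in range(M):
        rng = np.random.default_rng([seed, m])
        hit = rng.random(len(pairs)) < p if len(pairs) else np.zeros(0, bool)
        idx = np.flatnonzero(hit)
        members.append(idx)
        counts.append(int(idx.size))
    return ImputedEnsemble(
        base=net,
        M=M,
        seed=seed,
        unobserved_pairs=pairs,
        member_dyad_indices=members,
        imputed_edge_counts=counts,
    )


def toggling_sampler(
    net: PartialNetwork, model: DyadModel, n_steps: int, seed: int = 0
) -> Network:
    """Metropolis toggling restricted to the unobserved dyads.

    Starting from the completion in which every unobserved dyad is absent,
    each step picks one unobserved dyad uniformly at random and proposes to
    toggle it; the acceptance ratio depends only on that dyad's log-odds
    (dyad independence), so the stationary distribution is identical to the
    independent-Bernoulli scheme of :func:`impute_ensemble`.  With
    ``n_steps=0`` the initial completion is returned unchanged.
    """
    pairs, soc_sum = _unobserved_arrays(net)
    logit = model.predict_logit(soc_sum, 0.0)
    state = np.zeros(len(pairs), dtype=bool)
    rng = np.random.default_rng(seed)
    if len(pairs) and n_steps > 0:
        choices = rng.integers(0, len(pairs), size=n_steps)
        accept_u = rng.random(n_steps)
        for t in range(n_steps):
            k = choices[t]
            # toggling on multiplies the density by exp(logit), off by exp(-logit)
            delta = -logit[k] if state[k] else logit[k]
            if math.log(accept_u[t]) < delta:
                state[k] = not state[k]
    imputed = [pairs[k] for k in np.flatnonzero(state)]
    return Network(
        net.nodes, net.edge_list() + imputed, imputed_edges=imputed
    )


def imputation_diagnostics(ens: ImputedEnsemble) -> dict:
    """Variability of the imputed-edge counts across the ensemble.

    ``max_deviation_pct`` is max_i |count_i - mean| / mean * 100, the
    diagnostic used to judge whether the number of imputations suffices;
    ``mean_imputed_nn_density`` is mean(count) / C(n_nonresp, 2).
    """
    if ens.M < 2:
        raise ValueError("diagnostics require at least 2 imputations")
    counts = np.array(ens.imputed_edge_counts, dtype=float)
    mean = counts.mean()
    n_unobs = len(ens.unobserved_pairs)
    return {
        "M": ens.M,
        "mean_imputed_edges": float(mean),
        "min_imputed_edges": int(counts.min()),
        "max_imputed_edges": int(counts.max()),
        "max_deviation_pct": float(np.abs(counts - mean).max() / mean * 100.0)
        if mean > 0
        else 0.0,
        "mean_imputed_nn_density": float(mean / n_unobs) if n_unobs else 0.0,
    }
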