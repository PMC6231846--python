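"""Sensitivity, stability and boundary-sensitivity of PCA selections.

*Sensitivity* measures how much imputation changes who gets selected: for
each respondent-status class, the proportion of ensemble sPCAs that were
also PCAs on the observed network (the sPCA side is the denominator).

*Stability* measures how concentrated the ensemble selection counts are:
mean, standard deviation and mode of counts, conditional on a node being
selected at least once, overall and by respondent status.

*Boundary effect* reports the minimum degree-with-respondents among the
selected nonrespondents; a minimum equal to the boundary threshold k flags
selections driven by the inclusion rule itself rather than network
position.

Every reported proportion carries its numerator/denominator pair, and
:func:`check_report_consistency` verifies that each proportion is
recomputable from them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import replace as dc_replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .network import NodeRecord, PartialNetwork, apply_boundary

__all__ = [
    "sensitivity",
    "stability_summary",
    "boundary_effect",
    "algorithm_overlap",
    "evaluate_selection",
    "check_report_consistency",
    "compare_boundaries",
    "imputation_benefit_report",
]


def _proportion(num: int, den: int) -> dict:
    return {
        "numerator": int(num),
        "denominator": int(den),
        "proportion": (num / den) if den else None,
    }


def sensitivity(
    observed_set: Iterable[str],
    spca_set: Iterable[str],
    respondent_flags: Mapping[str, bool],
) -> dict:
    """Per-status overlap of sPCAs with the observed-network PCA set.

    Denominator = sPCAs of that status; numerator = those also selected on
    the observed network.  Empty denominators report a missing proportion.
    """
    obs, spca = set(observed_set), set(spca_set)
    out = {}
    for label, want in (("respondent", True), ("nonrespondent", False)):
        status_spca = {v for v in spca if respondent_flags[v] == want}
        out[label] = _proportion(len(status_spca & obs), len(status_spca))
    out["overall"] = _proportion(len(spca & obs), len(spca))
    return out


def _stats(values: Sequence[int]) -> dict | None:
    if not values:
        return None
    arr = np.asarray(values, dtype=float)
    freq = Counter(values)
    top = max(freq.values())
    mode = min(v for v, c in freq.items() if c == top)  # smallest value on ties
    return {
        "n": len(values),
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if len(values) > 1 else None,
        "mode": int(mode),
    }


def stability_summary(
    counts: Mapping[str, int], respondent_flags: Mapping[str, bool]
) -> dict | None:
    """Selection-count statistics conditional on count >= 1, overall and by
    respondent status.  Returns None when no node was ever selected."""
    if not counts:
        raise ValueError("counts must be nonempty")
    selected = {v: c for v, c in counts.items() if c >= 1}
    if not selected:
        return None
    overall = [c for c in selected.values()]
    resp = [c for v, c in selected.items() if respondent_flags[v]]
    nonresp = [c for v, c in selected.items() if not respondent_flags[v]]
    return {
        "overall": _stats(overall),
        "respondent": _stats(resp),
        "nonrespondent": _stats(nonresp),
        "n_selected_at_least_once": len(selected),
    }


def boundary_effect(
    spca_set: Iterable[str],
    nodes: Mapping[str, NodeRecord] | PartialNetwork,
    boundary_k: int | None = None,
) -> dict | None:
    """Minimum degree-with-respondents among selected nonrespondents, with a
    flag for whether it sits exactly at the boundary threshold."""
    records = nodes.records if isinstance(nodes, PartialNetwork) else nodes
    socs = [
        records[v].soc_covariate
        for v in spca_set
        if not records[v].is_respondent
    ]
    if not socs:
        return None
    minimum = int(min(socs))
    return {
        "min_soc_covariate": minimum,
        "boundary_k": boundary_k,
        "at_boundary": (minimum == boundary_k) if boundary_k is not None else None,
    }


def algorithm_overlap(
    set_a: Iterable[str],
    set_b: Iterable[str],
    respondent_flags: Mapping[str, bool],
) -> dict:
    """Intersection/union sizes of two sPCA sets with respondent breakdown."""
    a, b = set(set_a), set(set_b)
    inter, union = a & b, a | b
    def split(s):
        nr = sum(1 for v in s if respondent_flags[v])
        return {"n": len(s), "n_respondent": nr, "n_nonrespondent": len(s) - nr}
    return {"intersection": split(inter), "union": split(union)}


def evaluate_selection(
    result,
    partial_net: PartialNetwork,
    boundary_k: int | None = None,
) -> dict:
    """Full per-algorithm evaluation report for one SelectionResult."""
    flags = partial_net.respondent_flags()
    report = {
        "algorithm": result.algorithm,
        "sensitivity": sensitivity(result.observed_set, result.spca_set, flags),
        "stability": stability_summary(result.counts, flags),
        "boundary_effect": boundary_effect(result.spca_set, partial_net, boundary_k),
        "cutoff": result.cutoff,
        "spca_composition": result.spca_composition,
        "observed_composition": result.observed_composition,
    }
    check_report_consistency(report)
    return report


def check_report_consistency(report: dict) -> None:
    """Assert every reported proportion is recomputable from its printed
    numerator/denominator pair (run on every evaluation report)."""
    def walk(node):
        if isinstance(node, dict):
            if set(node) >= {"numerator", "denominator", "proportion"}:
                num, den, p = node["numerator"], node["denominator"], node["proportion"]
                if den == 0:
                    assert p is None, "proportion must be missing for empty denominator"
                else:
                    assert abs(p - num / den) < 1e-12, "inconsistent proportion"
                assert num <= den, "numerator exceeds denominator"
            else:
                for v in node.values():
                    walk(v)
    walk(report)


def _jaccard(a: set, b: set) -> float | None:
    union = a | b
    return (len(a & b) / len(union)) if union else None


def compare_boundaries(
    raw_partial_net: PartialNetwork,
    k_values: Sequence[int],
    config,
    M: int = 20,
    seed: int = 0,
) -> dict:
    """Re-run boundary -> fit -> impute -> select -> evaluate for each k.

    Reports one evaluation per k plus the Jaccard overlap of sPCA sets
    between consecutive k values -- the boundary-sensitivity measure.
    ``config`` is a SelectionConfig shared across k.
    """
    from .imputation import build_dyad_design, fit_dyad_model, impute_ensemble
    from .selection import select_pcas

    if not len(k_values):
        raise ValueError("k_values must be nonempty")
    per_k = []
    spca_sets = []
    for k in k_values:
        bounded = apply_boundary(raw_partial_net, int(k))
        model = fit_dyad_model(build_dyad_design(bounded))
        ensemble = impute_ensemble(bounded, model, M=M, seed=seed)
        result = select_pcas(bounded, ensemble, config)
        per_k.append(
            {"k": int(k), "report": evaluate_selection(result, bounded, int(k))}
        )
        spca_sets.append(set(result.spca_set))
    overlaps = [
        {
            "k_from": int(k_values[i]),
            "k_to": int(k_values[i + 1]),
            "jaccard": _jaccard(spca_sets[i], spca_sets[i + 1]),
        }
        for i in range(len(k_values) - 1)
    ]
    return {"per_k": per_k, "consecutive_jaccard": overlaps}


def imputation_benefit_report(
    cfg, config, M: int = 10, n_seeds: int = 20, seed: int = 0
) -> dict:
    """On synthetic data with known ground truth, quantify what imputation
    buys: overlap of the ensemble sPCA set with the selection on the
    truth-completed network, versus the overlap of the observed-only
    selection with that same truth selection.

    Directional summary only (means across seeds); small-sample runs are
    noisy, so callers should report rather than hard-assert the direction.
    ``cfg`` is a GeneratorConfig, ``config`` a SelectionConfig.
    """
    from .imputation import build_dyad_design, fit_dyad_model, impute_ensemble
    from .selection import _select_on, select_pcas
    from .synth import generate_dataset, unmask

    rows = []
    for s in range(n_seeds):
        rep_seed = int(np.random.SeedSequence([seed, s]).generate_state(1)[0] % 2**31)
        rep_cfg = dc_replace(cfg, seed=rep_seed)
        partial, truth = generate_dataset(rep_cfg)
        truth_net = unmask(partial, truth.hidden_nn_edges)
        truth_set = _select_on(truth_net, config, rep_seed)
        model = fit_dyad_model(build_dyad_design(partial))
        ensemble = impute_ensemble(partial, model, M=M, seed=rep_seed)
        result = select_pcas(partial, ensemble, config)
        m = config.m
        rows.append(
            {
                "seed": rep_seed,
                "overlap_observed_vs_truth": len(set(result.observed_set) & truth_set) / m,
                "overlap_spca_vs_truth": len(set(result.spca_set) & truth_set)
                / max(len(result.spca_set), 1),
            }
        )
    obs = float(np.mean([r["overlap_observed_vs_truth"] for r in rows]))
    imp = float(np.mean([r["overlap_spca_vs_truth"] for r in rows]))
    return {
        "n_seeds": n_seeds,
        "mean_overlap_observed_vs_truth": obs,
        "mean_overlap_spca_vs_truth": imp,
        "imputation_at_least_as_good": imp >= obs,
        "per_seed": rows,
    }
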