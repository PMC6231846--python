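"""End-to-end orchestration: simulate -> boundary -> fit -> impute -> select
-> evaluate, as one reproducible run.

A run is driven by a single :class:`RunConfig` (usually loaded from YAML);
every artifact written to the run directory is stamped with the config hash
and master seed via ``manifest.json``, and a rerun with an identical config
produces byte-identical outputs.  Log lines carry no timestamps for exactly
that reason; they record dyad/edge counts after each stage so observation-
structure bugs surface immediately.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .evaluation import algorithm_overlap, evaluate_selection
from .imputation import (
    build_dyad_design,
    fit_dyad_model,
    impute_ensemble,
    imputation_diagnostics,
)
from .network import BoundarySpec, apply_boundary, quadrant_summary, read_network, write_network
from .selection import SelectionConfig, select_pcas
from .synth import GeneratorConfig, generate_dataset

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("pcanet.pipeline")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``generator`` (synthetic run) or both ``node_table`` and
    ``edge_list`` (file-based run) must be provided.  ``boundary_k`` applies
    the relational boundary; the same master ``seed`` drives imputation and
    selection (and, offset, the generator when present).
    """

    out_dir: str
    seed: int = 0
    boundary_k: int = 30
    M: int = 100
    m: int = 300
    algorithms: tuple[str, ...] = ("eigenvector", "keyplayer")
    kp_restarts: int = 1
    kp_max_sweeps: int = 4
    generator: GeneratorConfig | None = None
    node_table: str | None = None
    edge_list: str | None = None

    def __post_init__(self) -> None:
        if self.generator is None and (self.node_table is None or self.edge_list is None):
            raise ValueError(
                "config needs either a generator section or node_table+edge_list paths"
            )
        if self.M < 1 or self.m < 1:
            raise ValueError("M and m must be >= 1")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        gen = raw.pop("generator", None)
        if gen is not None:
            if "theta_true" in gen:
                gen["theta_true"] = tuple(gen["theta_true"])
            gen = GeneratorConfig(**gen)
        if "algorithms" in raw:
            raw["algorithms"] = tuple(raw["algorithms"])
        return cls(generator=gen, **raw)

    def to_canonical_yaml(self) -> str:
        """Canonical YAML of the scientific configuration.

        ``out_dir`` is excluded: where outputs land is not part of the run's
        identity, and excluding it keeps reruns byte-identical across
        directories.
        """

        def listify(x):
            if isinstance(x, dict):
                return {k: listify(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [listify(v) for v in x]
            return x

        d = asdict(self)
        d.pop("out_dir")
        return yaml.safe_dump(listify(d), sort_keys=True, default_flow_style=False)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical_yaml().encode()).hexdigest()


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(name, exc) from exc
        return inner
    return wrap


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Stage failures abort with the stage name and cause; outputs written
    before the failure are retained for debugging.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        (out / "config.yaml").write_text(cfg.to_canonical_yaml())
        manifest = {
            "config_sha256": cfg.config_hash(),
            "seed": cfg.seed,
            "pcanet_version": __version__,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

        # -- input --------------------------------------------------------
        if cfg.generator is not None:
            partial, _truth = _stage("simulate")(generate_dataset)(cfg.generator, out)
            logger.info(
                "simulate: %d nodes (%d respondents), %d observed edges",
                partial.n_nodes, partial.n_resp, partial.n_edges,
            )
        else:
            for p in (cfg.node_table, cfg.edge_list):
                if not Path(p).exists():
                    raise PipelineError("load", FileNotFoundError(p))
            partial = _stage("load")(read_network)(cfg.node_table, cfg.edge_list)
            logger.info(
                "load: %d nodes (%d respondents), %d observed edges",
                partial.n_nodes, partial.n_resp, partial.n_edges,
            )

        # -- boundary -----------------------------------------------------
        bounded = _stage("boundary")(apply_boundary)(
            partial, BoundarySpec(cfg.boundary_k)
        )
        qs = quadrant_summary(bounded)
        logger.info(
            "boundary k=%d: %d respondents, %d nonrespondents, %d RR edges, "
            "%d RN edges, %d unobserved NN dyads",
            cfg.boundary_k, qs.n_resp, qs.n_nonresp, qs.edges_rr, qs.edges_rn,
            qs.unobserved_dyads_nn,
        )
        write_network(bounded, out / "nodes.csv", out / "edges.csv")
        with open(out / "quadrants.json", "w") as fh:
            json.dump(qs.to_dict(), fh, indent=1, sort_keys=True)

        # -- fit ----------------------------------------------------------
        design = _stage("fit")(build_dyad_design)(bounded)
        model = _stage("fit")(fit_dyad_model)(design)
        model.save(out / "model.json")
        logger.info(
            "fit: theta=(%.4f, %.4f, %.4f) on %d observed dyads",
            model.theta_edges, model.theta_soc, model.theta_mix, model.n_obs_dyads,
        )

        # -- impute -------------------------------------------------------
        ensemble = _stage("impute")(impute_ensemble)(
            bounded, model, M=cfg.M, seed=cfg.seed
        )
        diag = imputation_diagnostics(ensemble) if cfg.M >= 2 else {"M": cfg.M}
        with open(out / "imputation_diagnostics.json", "w") as fh:
            json.dump(diag, fh, indent=1, sort_keys=True)
        ensemble.to_frame().to_csv(out / "ensemble.csv", index=False)
        logger.info(
            "impute: M=%d, mean imputed edges %.1f",
            cfg.M, float(sum(ensemble.imputed_edge_counts)) / cfg.M,
        )

        # -- select + evaluate -------------------------------------------
        results = {}
        for algorithm in cfg.algorithms:
            sel_cfg = SelectionConfig(
                algorithm=algorithm,
                m=min(cfg.m, bounded.n_nodes),
                kp_restarts=cfg.kp_restarts,
                kp_max_sweeps=cfg.kp_max_sweeps,
                seed=cfg.seed,
            )
            result = _stage(f"select[{algorithm}]")(select_pcas)(
                bounded, ensemble, sel_cfg
            )
            result.save(out / f"selection_{algorithm}.json")
            results[algorithm] = result
            logger.info(
                "select[%s]: cutoff=%d, |sPCA|=%d",
                algorithm, result.cutoff, len(result.spca_set),
            )

        evaluation = {
            alg: _stage(f"evaluate[{alg}]")(evaluate_selection)(
                res, bounded, cfg.boundary_k
            )
            for alg, res in results.items()
        }
        if len(results) == 2:
            a, b = list(results)
            evaluation["overlap_between_algorithms"] = algorithm_overlap(
                results[a].spca_set, results[b].spca_set, bounded.respondent_flags()
            )
        with open(out / "evaluation.json", "w") as fh:
            json.dump(evaluation, fh, indent=1, sort_keys=True)
        logger.info("done")
        return out
    finally:
        logger.removeHandler(handler)
        handler.close()
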