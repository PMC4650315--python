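"""Pipeline orchestration: stage sequencing, run manifests, reproducibility.

A run executes score -> null -> p-values/threshold -> robustness -> phase fit
over a hit table (and optionally a phase table), writing every stage's output
plus a flat key-value manifest that freezes the merged configuration, the
seeds used and the SHA-256 digests of the inputs, so that identical manifests
reproduce identical outputs for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .permutation import attach_pvalues, exact_null, shuffle_null, significance_threshold
from .phase import (
    CircularPhaseGLM,
    filter_and_pool_phases,
    load_phase_table,
    tf_combo_summary,
    tf_group_scores,
)
from .registry import (
    Registry,
    load_hit_matrix,
    load_registry,
    paper_registry,
    write_score_table,
)
from .robustness import robust_candidates
from .scoring import total_scores

__all__ = ["PipelineError", "RunManifest", "run_pipeline"]

logger = logging.getLogger("clockminer")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclasses.dataclass
class RunManifest:
    """Flat reproducibility record written once per output directory."""

    subcommand: str
    entries: dict = dataclasses.field(default_factory=dict)

    def record(self, key: str, value) -> None:
        self.entries[str(key)] = value

    def record_digest(self, key: str, path: str | Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.entries[f"digest.{key}"] = digest

    def write(self, out_dir: str | Path) -> Path:
        path = Path(out_dir) / "manifest.txt"
        lines = [
            f"subcommand\t{self.subcommand}",
            f"tool_version\t{__version__}",
            f"timestamp\t{datetime.datetime.now(datetime.timezone.utc).isoformat()}",
        ]
        lines += [f"{k}\t{v}" for k, v in sorted(self.entries.items())]
        path.write_text("\n".join(lines) + "\n")
        return path


DEFAULTS = {
    "level": 0.001,
    "null": {"iterations": 1000, "seed": 0, "exact": False},
    "robust": {"draws": 100, "iterations": 1000, "seed": 0, "exact": False, "enabled": True},
    "phase": {"enabled": False, "phases": None, "fdr_cutoff": 0.05, "max_iter": 500, "tol": 1e-10},
}


def _merged_config(config: dict) -> dict:
    merged = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULTS.items()}
    for key, value in config.items():
        if key in merged and isinstance(merged[key], dict) and isinstance(value, dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> Path:
    """Execute the staged analysis described by a config mapping or YAML file.

    Required config keys: ``hits`` (hit-table TSV) and ``out_dir`` (unless
    passed explicitly).  Optional: ``registry`` (YAML path; defaults to the
    built-in 19-dataset configuration), ``level``, ``null.*``, ``robust.*``
    and ``phase.*`` sections.  Returns the output directory.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = _merged_config(config)
    out_dir = Path(out_dir or cfg.get("out_dir") or ".")
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest("run")
    for key, value in cfg.items():
        if isinstance(value, dict):
            for k2, v2 in value.items():
                manifest.record(f"config.{key}.{k2}", v2)
        else:
            manifest.record(f"config.{key}", value)

    # -- scoring ------------------------------------------------------------
    stage = "score"
    try:
        if cfg.get("registry"):
            registry = load_registry(cfg["registry"])
            manifest.record_digest("registry", cfg["registry"])
        else:
            registry = paper_registry()
            manifest.record("config.registry", "<built-in>")
        hits_path = cfg.get("hits")
        if not hits_path:
            raise PipelineError(stage, "config key 'hits' (hit-table TSV path) is required")
        hits = load_hit_matrix(hits_path, registry)
        manifest.record_digest("hits", hits_path)
        scores = total_scores(hits, registry)
        logger.info("score: %d genes x %d datasets scored", len(scores), len(registry))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- permutation null ---------------------------------------------------
    stage = "null"
    try:
        ncfg = cfg["null"]
        if ncfg.get("exact"):
            null = exact_null(registry)
        else:
            null = shuffle_null(
                registry, n_iterations=int(ncfg["iterations"]), seed=int(ncfg["seed"])
            )
        level = float(cfg["level"])
        scores = attach_pvalues(scores, null, level=level)
        threshold = significance_threshold(null, level)
        np.savetxt(
            out_dir / "null_distribution.tsv",
            np.column_stack([null.support, null.tail_prob]),
            delimiter="\t",
            header="score\ttail_prob",
            comments="",
        )
        manifest.record("null.method", null.method)
        manifest.record("null.threshold", threshold)
        manifest.record("seed.null", ncfg["seed"])
        logger.info(
            "null: method=%s iterations=%d threshold(level=%g)=%g, %d significant genes",
            null.method, null.n_iterations, level, threshold,
            int(scores.table["significant"].sum()),
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- robustness ---------------------------------------------------------
    stage = "robust"
    rcfg = cfg["robust"]
    if rcfg.get("enabled", True):
        try:
            result = robust_candidates(
                hits,
                registry,
                n_draws=int(rcfg["draws"]),
                level=float(cfg["level"]),
                null_iterations=int(rcfg["iterations"]),
                seed=int(rcfg["seed"]),
                null_method="exact" if rcfg.get("exact") else "shuffle",
            )
            robust = result.robust_genes
            scores.table["robust"] = scores.table.index.isin(robust)
            with open(out_dir / "robust_genes.tsv", "w") as fh:
                fh.write("gene_id\n")
                for g in sorted(robust):
                    fh.write(f"{g}\n")
            with open(out_dir / "robustness_draws.tsv", "w") as fh:
                fh.write("alpha\tbeta\tgamma\tn_significant\n")
                for w, sig in zip(result.draws, result.per_draw_significant):
                    fh.write(f"{w.alpha:.10g}\t{w.beta:.10g}\t{w.gamma:.10g}\t{len(sig)}\n")
            manifest.record("seed.robust", rcfg["seed"])
            manifest.record("robust.n_robust", len(robust))
            logger.info("robust: %d draws -> %d robust genes", len(result.draws), len(robust))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    write_score_table(scores, out_dir / "score_table.tsv")

    # -- phase model --------------------------------------------------------
    stage = "phase-fit"
    pcfg = cfg["phase"]
    if pcfg.get("enabled") or pcfg.get("phases"):
        try:
            phase_path = pcfg.get("phases")
            if not phase_path:
                raise PipelineError(stage, "phase stage enabled but no 'phases' table given")
            records = load_phase_table(phase_path)
            manifest.record_digest("phases", phase_path)
            pooled = filter_and_pool_phases(records, fdr_cutoff=float(pcfg["fdr_cutoff"]))
            group_scores = tf_group_scores(hits, registry)
            model = CircularPhaseGLM.from_dataframe(pooled, group_scores)
            fit = model.fit(max_iter=int(pcfg["max_iter"]), tol=float(pcfg["tol"]))
            with open(out_dir / "phase_fit.tsv", "w") as fh:
                fh.write("parameter\testimate\tstd_err\n")
                for name, est in fit.params.items():
                    fh.write(f"{name}\t{est:.10g}\t{fit.bse.get(name, float('nan')):.10g}\n")
                fh.write(f"loglik\t{fit.loglik:.10g}\t\n")
                fh.write(f"n_obs\t{fit.nobs}\t\n")
                fh.write(f"converged\t{int(fit.converged)}\t\n")
            combos = tf_combo_summary(hits, registry, pooled)
            combos.to_csv(out_dir / "tf_combo_summary.tsv", sep="\t", index=False)
            manifest.record("phase.converged", fit.converged)
            logger.info(
                "phase-fit: n=%d converged=%s mu_ct=%.2f kappa=%.3f",
                fit.nobs, fit.converged, fit.mu_ct, fit.kappa,
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    manifest.write(out_dir)
    return out_dir
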