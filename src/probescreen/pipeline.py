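"""End-to-end screen orchestration and the filter-cascade report.

Stages: acquire probe-level data (simulate or load) → probe-level
normalization → model-based expression indices → the filter cascade
(differential SAM screen → GO keyword filter → probe-consistency f-ratio
filter, reorderable). Every stage writes its artifact to the output
directory; the run is summarised by a :class:`CascadeReport` that mirrors
the screen's funnel (total probe sets → SAM-significant → keyword-matched →
f-ratio-passing) and is byte-reproducible from config + seed.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field

import yaml

from . import io as psio
from .annotation import keyword_filter, load_annotations, write_annotations
from .fratio import FRatioFilter
from .mbei import ModelBasedIndex
from .normalize import normalize_probe_level
from .sam import SamScreen
from .simulate import SimulationConfig, generate_annotations, generate_dataset, write_truth

__all__ = ["CascadeReport", "PipelineError", "PipelineResult", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

DEFAULT_ORDER = ("sam", "gofilter", "fratio")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class CascadeReport:
    """Filter-funnel counts with the thresholds and seed that produced them."""

    stages: list                # [{"name", "n_in", "n_out"}, ...]
    thresholds: dict
    seed: int

    def to_json(self) -> str:
        payload = {"stages": self.stages, "thresholds": self.thresholds, "seed": self.seed}
        return json.dumps(payload, sort_keys=True, indent=2) + "\n"

    def to_text(self) -> str:
        lines = ["filter cascade"]
        for st in self.stages:
            lines.append(f"  {st['name']:<10} {st['n_in']:>8} -> {st['n_out']:>8}")
        lines.append("thresholds: " + ", ".join(
            f"{k}={v}" for k, v in sorted(self.thresholds.items())))
        lines.append(f"seed: {self.seed}")
        return "\n".join(lines) + "\n"


@dataclass
class PipelineResult:
    report: CascadeReport
    artifacts: dict = field(default_factory=dict)   # name -> path
    data: object = None                             # normalized ProbeLevelMatrix
    truth: object = None
    annotations: object = None
    expression: object = None                       # ExpressionIndexTable
    sam: object = None                              # fitted SamScreen
    f_ratios: object = None                         # FRatioFilter table
    surviving_ids: list = field(default_factory=list)


def load_config(source) -> dict:
    if isinstance(source, dict):
        return dict(source)
    with open(source) as handle:
        return yaml.safe_load(handle) or {}


def _stage(name: str, out_dir):
    """Context wrapper: log timing, convert failures into PipelineError."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                marker = os.path.join(out_dir, f"FAILED_{name}")
                with open(marker, "w") as handle:
                    handle.write(f"{exc}\n")
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - self.t0)
    return _Ctx()


def run_pipeline(config, out_dir, seed=None) -> PipelineResult:
    """Execute the full screen described by ``config`` into ``out_dir``.

    ``config`` is a dict (or path to a YAML document) with optional blocks
    ``simulate`` (SimulationConfig fields) or ``inputs`` (paths to matrix /
    probe_map / samples / annotations TSVs), plus ``normalize``, ``mbei``,
    ``sam``, ``gofilter``, ``fratio`` parameter blocks and ``order`` for the
    filter cascade. ``seed`` overrides the config seed. Fully deterministic:
    rerunning with the same config and seed reproduces every artifact
    byte-for-byte.
    """
    config = load_config(config)
    seed = int(config.get("seed", 0) if seed is None else seed)
    os.makedirs(out_dir, exist_ok=True)
    artifacts: dict = {}
    result = PipelineResult(report=None, artifacts=artifacts)

    # -- acquire ----------------------------------------------------------
    with _stage("acquire", out_dir):
        if "inputs" in config:
            paths = config["inputs"]
            data = psio.read_probe_level_matrix(
                paths["matrix"], paths["probe_map"], paths["samples"])
            annotations = (load_annotations(paths["annotations"])
                           if "annotations" in paths else None)
            truth = None
        else:
            sim_kwargs = dict(config.get("simulate", {}))
            ann_kwargs = dict(sim_kwargs.pop("annotations", {}) or {})
            ann_kwargs.update(config.get("annotations", {}))
            sim_kwargs["seed"] = seed
            sim_config = SimulationConfig(**sim_kwargs)
            data, truth = generate_dataset(sim_config)
            annotations = generate_annotations(truth, seed=seed + 1, **ann_kwargs)
            artifacts.update(psio.write_probe_level_matrix(data, out_dir))
            artifacts["truth"] = os.path.join(out_dir, "truth.tsv")
            write_truth(truth, artifacts["truth"])
            artifacts["annotations"] = os.path.join(out_dir, "annotations.tsv")
            write_annotations(annotations, artifacts["annotations"])
        result.truth, result.annotations = truth, annotations

    # -- normalize --------------------------------------------------------
    with _stage("normalize", out_dir):
        norm_kwargs = dict(config.get("normalize", {}))
        data = normalize_probe_level(data, **norm_kwargs)
        artifacts["normalized_matrix"] = os.path.join(out_dir, "normalized_matrix.tsv")
        psio.write_probe_matrix(data.intensities, artifacts["normalized_matrix"])
        result.data = data

    # -- expression indices ----------------------------------------------
    with _stage("mbei", out_dir):
        model = ModelBasedIndex(**config.get("mbei", {})).fit(data)
        expression = model.to_table()
        artifacts["expression"] = os.path.join(out_dir, "expression.tsv")
        psio.write_table(expression.theta, artifacts["expression"], index_name="probeset_id")
        artifacts["mbei_diagnostics"] = os.path.join(out_dir, "mbei_diagnostics.tsv")
        psio.write_table(expression.diagnostics(), artifacts["mbei_diagnostics"],
                         index_name="probeset_id")
        result.expression = expression

    # -- filter cascade ---------------------------------------------------
    sam_cfg = dict(config.get("sam", {}))
    sam_cfg.setdefault("group1", "GFPneg_P8")
    sam_cfg.setdefault("group2", "GFPpos_P8")
    sam_cfg.setdefault("seed", seed + 2)
    go_cfg = dict(config.get("gofilter", {}))
    fr_cfg = dict(config.get("fratio", {}))
    order = list(config.get("order", DEFAULT_ORDER))
    if sorted(order) != sorted(DEFAULT_ORDER):
        raise PipelineError(f"order must be a permutation of {DEFAULT_ORDER}, got {order}")

    candidates = list(expression.theta.index)
    stages = [{"name": "total", "n_in": len(candidates), "n_out": len(candidates)}]

    for name in order:
        n_in = len(candidates)
        with _stage(name, out_dir):
            if name == "sam":
                screen = SamScreen(**sam_cfg).fit(expression.theta, data.sample_groups)
                artifacts["sam_results"] = os.path.join(out_dir, "sam_results.tsv")
                psio.write_table(screen.result_.table, artifacts["sam_results"],
                                 index_name="probeset_id")
                artifacts["delta_table"] = os.path.join(out_dir, "delta_table.tsv")
                screen.result_.delta_table.to_csv(artifacts["delta_table"], sep="\t",
                                                  index=False, float_format=psio.FLOAT_FMT)
                called = set(screen.result_.called_ids)
                candidates = [c for c in candidates if c in called]
                result.sam = screen
            elif name == "gofilter":
                if annotations is None:
                    raise ValueError("keyword filter requires an annotation table")
                candidates = keyword_filter(annotations, candidates, **go_cfg)
            elif name == "fratio":
                fr = FRatioFilter(**fr_cfg).fit(data, probeset_ids=candidates)
                artifacts["fratio"] = os.path.join(out_dir, "fratio.tsv")
                psio.write_table(fr.f_ratios_, artifacts["fratio"], index_name="probeset_id")
                candidates = fr.transform(candidates)
                result.f_ratios = fr.f_ratios_
            path = os.path.join(out_dir, f"{name}_passing_ids.txt")
            with open(path, "w") as handle:
                handle.writelines(f"{c}\n" for c in candidates)
            artifacts[f"{name}_passing_ids"] = path
        stages.append({"name": name, "n_in": n_in, "n_out": len(candidates)})

    result.surviving_ids = candidates
    report = CascadeReport(
        stages=stages,
        thresholds={
            "fold_min": sam_cfg.get("fold_min", 2.0),
            "target_fdr": sam_cfg.get("target_fdr", 0.01),
            "n_permutations": sam_cfg.get("n_permutations", 800),
            "keyword": go_cfg.get("keyword", "GTP"),
            "fratio_cutoff": fr_cfg.get("cutoff", 1.0),
        },
        seed=seed,
    )
    result.report = report
    artifacts["report_json"] = os.path.join(out_dir, "cascade_report.json")
    with open(artifacts["report_json"], "w") as handle:
        handle.write(report.to_json())
    artifacts["report_txt"] = os.path.join(out_dir, "cascade_report.txt")
    with open(artifacts["report_txt"], "w") as handle:
        handle.write(report.to_text())
    logger.info("cascade: %s", " -> ".join(str(st["n_out"]) for st in stages))
    return result
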