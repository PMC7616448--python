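"""End-to-end pipeline orchestration: (simulate) -> score -> enrich -> compose.

A single :class:`RunConfig` (loadable from YAML or JSON) drives the run; the
seed propagates to every stochastic stage. Each run writes its result tables
plus a JSON manifest recording versions, parameters, input checksums and the
headline outputs, which is sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__ as _pkg_version
from . import io as _io
from .composition import compare_conditions, composition
from .data import CountMatrix, GeneSet
from .enrichment import DEFAULT_EVALUATION_KS, EnrichmentParams, consensus_robust, rank_markers, run_evaluation
from .genesets import load_ieg_panel
from .preprocess import filter_neuronal, log_normalize
from .scoring import ModuleScoreParams, ieg_positivity, module_score, presentation_score
from .simulate import SyntheticSpec, generate, write_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    output_dir: Path
    matrix: Path | None = None
    annotation: Path | None = None
    ieg_list: Path | None = None
    simulate: SyntheticSpec | None = None
    control: str = "control"
    treated: str = "treated"
    ks: tuple[int, ...] = DEFAULT_EVALUATION_KS
    n_hvg: int = 2000
    n_reps: int = 100
    alpha: float = 0.01
    n_intervals: int = 50
    genes_per_interval: int = 50
    n_bins: int = 24
    n_ctrl_per_gene: int = 100
    presentation_offset: float = 0.05
    min_markers_detected: int | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        for name in ("matrix", "annotation", "ieg_list"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))
        self.ks = tuple(int(k) for k in self.ks)

    def validate(self) -> None:
        """Aggregate every configuration problem into a single error report."""
        problems: list[str] = []
        if self.simulate is None:
            if self.matrix is None:
                problems.append("matrix: required when no synthetic spec is given")
            elif not self.matrix.exists():
                problems.append(f"matrix: path does not exist: {self.matrix}")
            if self.annotation is None:
                problems.append("annotation: required when no synthetic spec is given")
            elif not self.annotation.exists():
                problems.append(f"annotation: path does not exist: {self.annotation}")
        if self.ieg_list is not None and not self.ieg_list.exists():
            problems.append(f"ieg_list: path does not exist: {self.ieg_list}")
        if not self.ks:
            problems.append("ks: at least one marker threshold is required")
        if self.n_reps < 1:
            problems.append("n_reps: must be >= 1")
        if not 0 < self.alpha < 1:
            problems.append("alpha: must be in (0, 1)")
        if problems:
            raise ValueError("invalid configuration:\n  - " + "\n  - ".join(problems))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        sim = raw.pop("simulate", None)
        if sim is not None:
            if "clusters" in sim:
                sim["clusters"] = tuple((str(c), int(n)) for c, n in sim["clusters"])
            if "samples" in sim:
                sim["samples"] = tuple((str(s), str(c)) for s, c in sim["samples"])
            if "active_fraction" in sim:
                sim["active_fraction"] = {
                    (str(c), str(cond)): float(f)
                    for (c, cond), f in (
                        ((e["cluster"], e["condition"]), e["fraction"])
                        for e in sim["active_fraction"]
                    )
                }
            if "baseline_log_mean" in sim:
                sim["baseline_log_mean"] = tuple(sim["baseline_log_mean"])
            raw["simulate"] = SyntheticSpec(**sim)
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(config: RunConfig) -> tuple[CountMatrix, pd.DataFrame, GeneSet, dict]:
    checksums: dict[str, str] = {}
    if config.simulate is not None:
        spec = dataclasses.replace(config.simulate, seed=config.seed)
        dataset = generate(spec)
        data_dir = config.output_dir / "data"
        write_dataset(dataset, data_dir)
        matrix, ann, ieg = dataset.matrix, dataset.annotation, dataset.ieg
        checksums["matrix.mtx"] = _sha256(data_dir / "matrix.mtx")
    else:
        if config.matrix.is_dir():
            matrix = _io.read_10x_mtx(config.matrix)
            checksums[str(config.matrix)] = _sha256(
                next(p for p in (config.matrix / "matrix.mtx", config.matrix / "matrix.mtx.gz") if p.exists())
            )
        else:
            matrix = _io.read_dense_table(config.matrix)
            checksums[str(config.matrix)] = _sha256(config.matrix)
        ann = _io.read_annotation(config.annotation, matrix)
        checksums[str(config.annotation)] = _sha256(config.annotation)
        ieg = load_ieg_panel()
    if config.ieg_list is not None:
        ieg = _io.read_gene_set(config.ieg_list)
        checksums[str(config.ieg_list)] = _sha256(config.ieg_list)
    return matrix, ann, ieg, checksums


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    config.validate()
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": _pkg_version,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "seed": config.seed,
        "parameters": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
            if k != "simulate"
        },
        "synthetic": config.simulate is not None,
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    stage = "load"
    try:
        matrix, ann, ieg, checksums = _load_inputs(config)
        manifest["input_checksums"] = checksums
        if config.min_markers_detected is not None:
            matrix = filter_neuronal(matrix, min_markers_detected=config.min_markers_detected)
            ann = ann[ann["cell_id"].isin(matrix.cell_ids)].reset_index(drop=True)
        matrix = log_normalize(matrix)
        manifest["stages"]["load"] = {"n_genes": matrix.n_genes, "n_cells": matrix.n_cells}

        stage = "score"
        params = ModuleScoreParams(
            n_bins=config.n_bins,
            n_ctrl_per_gene=config.n_ctrl_per_gene,
            seed=config.seed,
            presentation_offset=config.presentation_offset,
        )
        scores = module_score(matrix, ieg, params)
        shown = presentation_score(scores)
        _io.write_table(
            pd.DataFrame(
                {"cell_id": scores.scores.index, "module_score": scores.scores.to_numpy(),
                 "presentation_score": shown.to_numpy()}
            ),
            out / "module_scores.tsv",
        )
        positivity = ieg_positivity(scores, ann)
        _io.write_table(positivity.rename_axis("cluster").reset_index(), out / "ieg_positivity.tsv")
        manifest["stages"]["score"] = {
            "n_feature_genes": len(scores.feature_genes),
            "n_control_genes": len(scores.control_genes),
            "mean_score": float(scores.scores.mean()),
        }

        stage = "enrich"
        ranking = rank_markers(matrix, ann)
        calls = {}
        enrich_summary = {}
        for k in config.ks:
            ep = EnrichmentParams(
                top_k_markers=k,
                n_hvg=config.n_hvg,
                n_intervals=config.n_intervals,
                genes_per_interval=config.genes_per_interval,
                n_reps=config.n_reps,
                alpha=config.alpha,
                seed=config.seed,
            )
            call, pool = run_evaluation(matrix, ann, ieg, ep, marker_ranking=ranking)
            calls[k] = call
            _io.write_table(
                call.table.reset_index(), out / f"active_calls_k{k}.tsv"
            )
            enrich_summary[str(k)] = {
                "pool_size": call.pool_size,
                "n_feature": call.n_feature,
                "n_active": int(call.table["active"].sum()),
            }
        manifest["stages"]["enrich"] = enrich_summary

        stage = "consensus"
        conditions = set(ann["condition"])
        if {config.control, config.treated} <= conditions:
            cons = consensus_robust(calls, ann, config.control, config.treated)
            _io.write_table(cons.per_evaluation, out / "consensus_per_evaluation.tsv")
            _io.write_table(cons.clusters, out / "robust_clusters.tsv")
            manifest["stages"]["consensus"] = {
                "robust_clusters": sorted(
                    cons.clusters.loc[cons.clusters["robust"], "cluster"].tolist()
                )
            }
        else:
            logger.warning("conditions %r/%r not both present; consensus skipped",
                           config.control, config.treated)
            manifest["stages"]["consensus"] = {"skipped": True}

        stage = "compose"
        comp = composition(ann)
        _io.write_table(comp, out / "composition.tsv")
        if {config.control, config.treated} <= conditions and all(
            ann[ann["condition"] == c]["sample"].nunique() >= 2
            for c in (config.control, config.treated)
        ):
            cmp_tab = compare_conditions(comp, config.control, config.treated)
            _io.write_table(cmp_tab, out / "composition_comparison.tsv")
            manifest["stages"]["compose"] = {
                "significant_clusters": sorted(
                    cmp_tab.loc[cmp_tab["significant"], "cluster"].tolist()
                )
            }
        else:
            manifest["stages"]["compose"] = {"comparison_skipped": True}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
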