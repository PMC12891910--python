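"""End-to-end orchestration: reads in, components + feature tables + models out.

Every run writes a self-describing output directory: a JSON echo of the
configuration (with tool version and input checksums), the stage
artifacts, and a machine-readable summary.  Stage timings go to the
logger only, so artifact files are byte-identical across reruns with the
same inputs and configuration.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import __version__
from . import io as _io
from .dbg import (
    build_graph,
    color_vectors,
    components_to_fasta,
    condensed_components,
    extract_colored_components,
    local_search,
)
from .features import FeatureTable, build_feature_table, calc_features
from .kmer_core import count_sample_file
from .ml import TrainedModel, cross_validate, fit, pca, predict, write_predictions_tsv
from .selection import (
    GroupLabels,
    auto_select_G,
    build_presence_matrix,
    select_chisq,
    select_stats,
    select_unique,
)

__all__ = ["PipelineConfig", "run_supervised", "run_unsupervised", "run_model"]

logger = logging.getLogger(__name__)

SUPERVISED_MODES = ("unique", "chisq", "stats", "colored")
MODEL_MODES = ("fit", "cv", "predict", "calc_features", "pca")


@dataclass
class PipelineConfig:
    mode: str
    out_dir: Path
    reads_dir: Path | None = None
    metadata: Path | None = None
    k: int = 31
    min_count: int = 2
    # selection parameters
    G: int | None = None  # None -> automatic
    alpha: float = 0.05
    top_n: int = 10000
    target_range: tuple[int, int] = (1000, 10000)
    # colored parameters
    colored_mode: str = "threshold"
    threshold: float = 0.9
    n_per_group: int = 100
    # local search parameters
    max_radius: int = 100
    branch_limit: int = 1
    max_component_size: int = 10000
    # condensation parameters
    initial_threshold: float = 1.0
    size_bounds: tuple[int, int] = (5, 10000)
    max_iterations: int = 10
    # model parameters
    n_trees: int = 100
    folds: int = 10
    seed: int = 0
    feature_mode: str = "breadth"
    n_components: int = 2
    # model-mode inputs
    features_tsv: Path | None = None
    components_fasta: Path | None = None
    model_path: Path | None = None
    extra: dict = field(default_factory=dict)

    def echo(self) -> dict[str, Any]:
        d: dict[str, Any] = {}
        for key, val in self.__dict__.items():
            if isinstance(val, Path):
                d[key] = str(val)
            elif isinstance(val, tuple):
                d[key] = list(val)
            else:
                d[key] = val
        d["tool_version"] = __version__
        return d


class _Stage:
    """Context logger for one pipeline stage (timings to stderr logger only)."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            logger.info("stage %s: done in %.1fs", self.name, dt)
        else:
            logger.error("stage %s: failed after %.1fs: %s", self.name, dt, exc)
        return False


def _write_config_echo(cfg: PipelineConfig, input_files: list[Path]) -> None:
    echo = cfg.echo()
    echo["input_checksums"] = {str(p): _io.file_sha256(p) for p in sorted(input_files)}
    _io.write_json(Path(cfg.out_dir) / "config.json", echo)


def _count_samples(cfg: PipelineConfig, sample_ids: list[str]):
    files = _io.find_sample_files(cfg.reads_dir, sample_ids)
    tables = {}
    with _Stage("count"):
        for sid in sample_ids:
            tables[sid] = count_sample_file(
                files[sid], k=cfg.k, min_count=cfg.min_count, sample_id=sid
            )
            logger.info("  sample %s: %d k-mers", sid, len(tables[sid]))
    return files, tables


def run_supervised(cfg: PipelineConfig) -> dict:
    """count -> select (per category, one-vs-rest) -> graph -> components ->
    contigs FASTA -> breadth + depth feature tables."""
    if cfg.mode not in SUPERVISED_MODES:
        raise ValueError(f"supervised mode must be one of {SUPERVISED_MODES}")
    if cfg.metadata is None or cfg.reads_dir is None:
        raise ValueError("supervised modes need --reads-dir and --metadata")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = GroupLabels.from_tsv(cfg.metadata)
    files, tables = _count_samples(cfg, labels.sample_ids)
    _write_config_echo(cfg, [Path(cfg.metadata), *files.values()])

    with _Stage("graph"):
        graph = build_graph(list(tables.values()))
        logger.info("  graph: %d nodes", len(graph))

    components = []
    summary: dict[str, Any] = {"mode": cfg.mode, "samples": len(tables), "graph_nodes": len(graph)}
    if cfg.mode == "colored":
        with _Stage("color"):
            colors = color_vectors(tables, labels)
        with _Stage("components"):
            components = extract_colored_components(
                graph,
                colors,
                mode=cfg.colored_mode,
                n_per_group=cfg.n_per_group,
                threshold=cfg.threshold,
            )
    else:
        with _Stage("presence"):
            presence = build_presence_matrix(tables, labels)
        selections = {}
        with _Stage("select"):
            for cat in labels.categories:
                if cfg.mode == "unique":
                    G = cfg.G if cfg.G is not None else auto_select_G(
                        presence, cat, cfg.target_range
                    )
                    sel = select_unique(presence, cat, G)
                    logger.info("  %s: G=%d, %d unique k-mers", cat, G, len(sel))
                elif cfg.mode == "chisq":
                    sel = select_chisq(presence, cat, alpha=cfg.alpha, top_n=cfg.top_n)
                    logger.info("  %s: %d chisq k-mers", cat, len(sel))
                else:
                    sel = select_stats(
                        tables, labels, cat, alpha=cfg.alpha, top_n=cfg.top_n
                    )
                    logger.info("  %s: %d stats k-mers", cat, len(sel))
                if len(sel) == 0:
                    logger.warning("  category %s: empty selection, skipped", cat)
                    continue
                selections[cat] = sel
                sel.write_tsv(out / f"selected_kmers_{cat}.tsv")
        with _Stage("components"):
            for cat, sel in selections.items():
                comps = local_search(
                    graph,
                    sel,
                    max_radius=cfg.max_radius,
                    branch_limit=cfg.branch_limit,
                    max_component_size=cfg.max_component_size,
                )
                logger.info("  %s: %d components", cat, len(comps))
                components.extend(comps)

    summary["components"] = len(components)
    summary["component_sizes"] = sorted(c.size for c in components)
    fasta_path = out / "components.fasta"
    with _Stage("contigs"):
        components_to_fasta(components, fasta_path)
    with _Stage("features"):
        for mode in ("breadth", "depth"):
            table = build_feature_table(components, tables, mode=mode)
            table.write_tsv(out / f"features_{mode}.tsv")
    summary["feature_table_shape"] = [len(components), len(tables)]
    _io.write_json(out / "summary.json", summary)
    return summary


def run_unsupervised(cfg: PipelineConfig) -> dict:
    """Joint graph -> condensed components -> contigs + feature tables."""
    if cfg.reads_dir is None:
        raise ValueError("unsupervised mode needs --reads-dir")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reads_dir = Path(cfg.reads_dir)
    sample_ids = sorted(
        {
            f.name[: -len(ext)]
            for f in reads_dir.iterdir()
            for ext in _io.READ_EXTENSIONS
            if f.name.endswith(ext)
        }
    )
    if not sample_ids:
        raise ValueError(f"no read files found in {reads_dir}")
    files, tables = _count_samples(cfg, sample_ids)
    _write_config_echo(cfg, list(files.values()))
    with _Stage("graph"):
        graph = build_graph(list(tables.values()))
    with _Stage("components"):
        components = condensed_components(
            graph,
            initial_threshold=cfg.initial_threshold,
            size_bounds=cfg.size_bounds,
            max_iterations=cfg.max_iterations,
        )
        logger.info("  %d components", len(components))
    fasta_path = out / "components.fasta"
    with _Stage("contigs"):
        components_to_fasta(components, fasta_path)
    with _Stage("features"):
        for mode in ("breadth", "depth"):
            build_feature_table(components, tables, mode=mode).write_tsv(
                out / f"features_{mode}.tsv"
            )
    summary = {
        "mode": "condense",
        "samples": len(tables),
        "graph_nodes": len(graph),
        "components": len(components),
        "feature_table_shape": [len(components), len(tables)],
    }
    _io.write_json(out / "summary.json", summary)
    return summary


def run_model(cfg: PipelineConfig) -> dict:
    """Dispatch fit / cv / predict / calc_features / pca on stored artifacts."""
    if cfg.mode not in MODEL_MODES:
        raise ValueError(f"model mode must be one of {MODEL_MODES}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"mode": cfg.mode}
    inputs: list[Path] = []

    if cfg.mode == "calc_features":
        if cfg.components_fasta is None or cfg.reads_dir is None:
            raise ValueError("calc_features needs --components and --reads-dir")
        reads_dir = Path(cfg.reads_dir)
        sample_ids = sorted(
            {
                f.name[: -len(ext)]
                for f in reads_dir.iterdir()
                for ext in _io.READ_EXTENSIONS
                if f.name.endswith(ext)
            }
        )
        files = _io.find_sample_files(reads_dir, sample_ids)
        inputs = [Path(cfg.components_fasta), *files.values()]
        with _Stage("calc_features"):
            for mode in ("breadth", "depth"):
                table = calc_features(
                    cfg.components_fasta,
                    {s: p for s, p in files.items()},
                    k=cfg.k,
                    mode=mode,
                    min_count=cfg.min_count,
                )
                table.write_tsv(out / f"features_{mode}.tsv")
        summary["feature_table_shape"] = list(table.shape)
    elif cfg.mode in ("fit", "cv"):
        if cfg.features_tsv is None or cfg.metadata is None:
            raise ValueError(f"{cfg.mode} needs --features and --metadata")
        inputs = [Path(cfg.features_tsv), Path(cfg.metadata)]
        table = FeatureTable.read_tsv(cfg.features_tsv, mode=cfg.feature_mode)
        labels = GroupLabels.from_tsv(cfg.metadata)
        if cfg.mode == "fit":
            with _Stage("fit"):
                model = fit(table, labels, n_trees=cfg.n_trees, seed=cfg.seed, k=cfg.k)
                model.save(out / "model.joblib")
            summary["categories"] = model.categories
            summary["n_features"] = len(model.feature_ids)
        else:
            with _Stage("cv"):
                metrics = cross_validate(
                    table, labels, folds=cfg.folds, seed=cfg.seed, n_trees=cfg.n_trees
                )
            _io.write_json(out / "metrics.json", metrics)
            summary["cv_mean"] = metrics["mean"]
    elif cfg.mode == "predict":
        if cfg.features_tsv is None or cfg.model_path is None:
            raise ValueError("predict needs --features and --model")
        inputs = [Path(cfg.features_tsv), Path(cfg.model_path)]
        table = FeatureTable.read_tsv(cfg.features_tsv, mode=cfg.feature_mode)
        model = TrainedModel.load(cfg.model_path)
        with _Stage("predict"):
            preds = predict(model, table)
        write_predictions_tsv(preds, model.categories, out / "predictions.tsv")
        summary["n_predicted"] = len(preds)
    else:  # pca
        if cfg.features_tsv is None:
            raise ValueError("pca needs --features")
        inputs = [Path(cfg.features_tsv)]
        table = FeatureTable.read_tsv(cfg.features_tsv, mode=cfg.feature_mode)
        with _Stage("pca"):
            result = pca(table, n_components=cfg.n_components)
        df = result.coordinates.copy()
        df.index.name = "sample_id"
        df.to_csv(out / "pca_coordinates.tsv", sep="\t", float_format="%.6f")
        summary["explained_variance_ratio"] = [
            float(v) for v in result.explained_variance_ratio
        ]
    _write_config_echo(cfg, inputs)
    _io.write_json(out / "summary.json", summary)
    return summary
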