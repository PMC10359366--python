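"""End-to-end orchestration: simulate -> build tensors -> train/eval -> compare.

A :class:`PipelineConfig` (YAML on disk) names the input files and collects
the feature, model, split and run settings. Every stage is a plain function
so the CLI stays a thin wrapper and tests can drive stages directly.

The baseline arm is the identical pipeline without spatial information: the
spatial column is removed from every flattened tensor (or zeroed, in
``zero`` mode) before training.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import features as ft
from .contacts import read_bedpe
from .errors import ConfigError, DataError
from .genome_io import (
    GeneRecord,
    read_expression_matrix,
    read_gene_table,
    read_tissue_mapping,
    transform_target,
    validate_tissue_mapping,
)
from .regression import ModelConfig, SplitSpec, chromosome_split, repeated_runs
from .signal_predictor import SyntheticTrackStore, track_predictor
from .synthetic_data import SynthConfig, generate, write_fixture

log = logging.getLogger(__name__)

ARMS = ("baseline", "spatial")


@dataclass
class PathsConfig:
    workdir: str = "spex_work"
    genes: str = ""
    contacts: str = ""
    tracks: str = ""
    expression: str = ""
    mapping: str = ""


@dataclass
class FeaturesConfig:
    k_per_side: int = 10
    lambdas: list[float] | None = None
    min_count: int = ft.MIN_COUNT
    linear_scope: int = ft.LINEAR_SCOPE
    resolution: int = 5000


@dataclass
class RunsConfig:
    n_runs: int = 10
    base_seed: int = 0
    experiment: str = "synthetic"
    factor: str = "synthetic"
    baseline_mode: str = "drop"  # 'drop' removes the spatial column, 'zero' zeroes it

    def __post_init__(self) -> None:
        if self.baseline_mode not in ("drop", "zero"):
            raise ConfigError(f"baseline_mode must be 'drop' or 'zero', got {self.baseline_mode!r}")
        if self.n_runs < 1:
            raise ConfigError("n_runs must be >= 1")


@dataclass
class PipelineConfig:
    paths: PathsConfig = field(default_factory=PathsConfig)
    features: FeaturesConfig = field(default_factory=FeaturesConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    runs: RunsConfig = field(default_factory=RunsConfig)
    simulate: SynthConfig = field(default_factory=SynthConfig)

    @property
    def workdir(self) -> Path:
        return Path(self.paths.workdir)


_SECTIONS = {
    "paths": PathsConfig,
    "features": FeaturesConfig,
    "model": ModelConfig,
    "split": SplitSpec,
    "runs": RunsConfig,
    "simulate": SynthConfig,
}


def _build_section(cls, payload: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ConfigError(f"unknown keys in [{cls.__name__}]: {sorted(unknown)}")
    coerced = dict(payload)
    for f in dataclasses.fields(cls):
        if f.name in coerced and isinstance(coerced[f.name], list) and f.name in (
            "excluded_chroms", "count_choices", "count_weights", "loop_distance",
        ):
            coerced[f.name] = tuple(coerced[f.name])
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [{cls.__name__}] section: {exc}") from exc


def config_from_dict(payload: dict) -> PipelineConfig:
    unknown = set(payload) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = payload.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"config section {name!r} must be a mapping")
        if name == "simulate" and "chrom_lengths" in section:
            section = dict(section)
            section["chrom_lengths"] = {
                str(k): int(v) for k, v in section["chrom_lengths"].items()
            }
        kwargs[name] = _build_section(cls, section)
    return PipelineConfig(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    try:
        payload = yaml.safe_load(Path(path).read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(payload, dict):
        raise ConfigError(f"{path}: top level must be a mapping of sections")
    return config_from_dict(payload)


def run_simulate(config: PipelineConfig, overwrite: bool = False) -> dict[str, Path]:
    """Generate the synthetic fixture into ``workdir/fixture`` and point the
    pipeline's input paths at it."""
    outdir = config.workdir / "fixture"
    paths = write_fixture(generate(config.simulate), outdir, overwrite=overwrite)
    config.paths.genes = str(paths["genes.bed"])
    config.paths.contacts = str(paths["contacts.bedpe"])
    config.paths.tracks = str(paths["tracks.h5"])
    config.paths.expression = str(paths["expression.tsv"])
    config.paths.mapping = str(paths["mapping.tsv"])
    config.features.resolution = config.simulate.resolution
    config.features.k_per_side = config.simulate.k_per_side
    return paths


def _require_file(path: str, what: str) -> Path:
    if not path:
        raise DataError(f"no {what} file configured (paths.{what})")
    p = Path(path)
    if not p.is_file():
        raise DataError(f"{what} file {p} not found")
    return p


@dataclass
class TensorStats:
    n_genes: int
    n_fallback: int

    @property
    def fallback_rate(self) -> float:
        return self.n_fallback / self.n_genes if self.n_genes else float("nan")


def run_build_tensors(config: PipelineConfig, force: bool = False) -> tuple[Path, TensorStats]:
    """Build one tensor per gene and archive them; skipped when the archive
    already exists unless ``force``. Logs the fallback rate."""
    archive = config.workdir / "tensors.h5"
    genes = read_gene_table(_require_file(config.paths.genes, "genes"), format="bed6")
    if archive.exists() and not force:
        log.info("tensor archive %s exists; skipping build", archive)
        tensors = ft.read_tensor_archive(archive)
        n_fb = sum(t.used_fallback for t in tensors.values())
        return archive, TensorStats(len(tensors), n_fb)
    cs = read_bedpe(_require_file(config.paths.contacts, "contacts"),
                    config.features.resolution)
    store = SyntheticTrackStore.load(_require_file(config.paths.tracks, "tracks"))
    predictor = track_predictor(store)
    basis = ft.decay_basis(config.features.k_per_side, config.features.lambdas)
    tensors = []
    n_fb = 0
    for gene in genes:
        t = ft.build_gene_tensor(
            gene, cs, predictor, basis,
            linear_scope=config.features.linear_scope,
            min_count=config.features.min_count,
            chrom_length=store.chrom_length(gene.chrom),
        )
        n_fb += t.used_fallback
        tensors.append(t)
    config.workdir.mkdir(parents=True, exist_ok=True)
    ft.write_tensor_archive(tensors, archive)
    stats = TensorStats(len(tensors), n_fb)
    log.info(
        "built %d tensors (%d fallback, rate %.1f%%) -> %s",
        stats.n_genes, stats.n_fallback, 100 * stats.fallback_rate, archive,
    )
    return archive, stats


def assemble_matrix(
    tensors: dict[str, ft.FeatureTensor],
    gene_ids: Sequence[str],
    arm: str = "spatial",
    baseline_mode: str = "drop",
) -> tuple[np.ndarray, dict]:
    """Stack flattened tensors into a genes x features matrix.

    The baseline arm removes (``drop``) or zeroes (``zero``) the spatial
    column of every track before flattening, so it carries no spatial
    information; the layout metadata records which was done.
    """
    if arm not in ARMS:
        raise ConfigError(f"arm must be one of {ARMS}, got {arm!r}")
    rows = []
    k = None
    for gid in gene_ids:
        if gid not in tensors:
            raise KeyError(f"gene {gid!r} missing from tensor archive")
        t = tensors[gid]
        k = t.k_per_side
        m = t.matrix
        if arm == "baseline":
            m = m[:, :-1] if baseline_mode == "drop" else np.column_stack(
                [m[:, :-1], np.zeros(m.shape[0])]
            )
        rows.append(m.ravel(order="C"))
    X = np.vstack(rows)
    layout = {
        "order": "track-major",
        "k_per_side": k,
        "arm": arm,
        "baseline_mode": baseline_mode if arm == "baseline" else None,
        "n_features": X.shape[1],
    }
    return X, layout


def run_train_eval(config: PipelineConfig, arm: str) -> tuple[Path, pd.DataFrame]:
    """Train ``runs.n_runs`` times on the train chromosomes and score the
    held-out chromosome; write one metrics row per run."""
    if arm not in ARMS:
        raise ConfigError(f"arm must be one of {ARMS}, got {arm!r}")
    genes = read_gene_table(_require_file(config.paths.genes, "genes"), format="bed6")
    em = read_expression_matrix(_require_file(config.paths.expression, "expression"))
    mapping = read_tissue_mapping(_require_file(config.paths.mapping, "mapping"))
    validate_tissue_mapping(mapping, em)
    if config.runs.experiment not in mapping:
        raise DataError(
            f"experiment {config.runs.experiment!r} not in tissue mapping"
        )
    tissue = mapping[config.runs.experiment]
    archive = config.workdir / "tensors.h5"
    if not archive.exists():
        raise DataError(f"tensor archive {archive} not found; run build-tensors first")
    tensors = ft.read_tensor_archive(archive)

    expr = em.column(tissue)
    usable = [g for g in genes if g.gene_id in expr.index and g.gene_id in tensors]
    if len(usable) < len(genes):
        log.info("dropped %d genes without expression or tensor", len(genes) - len(usable))
    train_ids, test_ids = chromosome_split(usable, config.split)
    X_train, layout = assemble_matrix(tensors, train_ids, arm, config.runs.baseline_mode)
    X_test, _ = assemble_matrix(tensors, test_ids, arm, config.runs.baseline_mode)
    y_train = transform_target(expr.loc[train_ids].to_numpy())
    y_test = transform_target(expr.loc[test_ids].to_numpy())

    rows = repeated_runs(
        X_train, y_train, X_test, y_test,
        cfg=config.model,
        n_runs=config.runs.n_runs,
        base_seed=config.runs.base_seed,
    )
    df = pd.DataFrame(rows)
    df.insert(0, "experiment", config.runs.experiment)
    df.insert(1, "factor", config.runs.factor)
    df.insert(2, "label", arm)
    config.workdir.mkdir(parents=True, exist_ok=True)
    out = config.workdir / f"metrics_{arm}.tsv"
    df.to_csv(out, sep="\t", index=False)
    log.info("%s arm: mean SCC %.4f over %d runs -> %s",
             arm, df["scc"].mean(), len(df), out)
    return out, df


def run_two_arm_experiment(
    synth_cfg: SynthConfig,
    workdir: str | Path,
    n_runs: int = 10,
    base_seed: int = 0,
    model: ModelConfig | None = None,
) -> dict:
    """Generate a synthetic dataset, build tensors once, then train both
    arms ``n_runs`` times each and compare them with a Welch test.

    Returns the per-arm metric tables, the mean-SCC improvement
    (spatial - baseline) and the Welch (t, p) across runs.
    """
    from .evaluation import welch_test

    config = PipelineConfig()
    config.paths.workdir = str(workdir)
    config.simulate = synth_cfg
    config.runs.n_runs = n_runs
    config.runs.base_seed = base_seed
    if model is not None:
        config.model = model
    run_simulate(config, overwrite=True)
    _, stats = run_build_tensors(config)
    _, df_base = run_train_eval(config, "baseline")
    _, df_spat = run_train_eval(config, "spatial")
    t, p = welch_test(df_spat["scc"].to_numpy(), df_base["scc"].to_numpy())
    return {
        "config": config,
        "tensor_stats": stats,
        "baseline": df_base,
        "spatial": df_spat,
        "mean_baseline_scc": float(df_base["scc"].mean()),
        "mean_spatial_scc": float(df_spat["scc"].mean()),
        "improvement": float(df_spat["scc"].mean() - df_base["scc"].mean()),
        "welch_t": t,
        "welch_p": p,
    }


def run_compare(metric_files: Sequence[str | Path], outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Join metric tables from both arms and write the per-experiment and
    per-factor-group Welch/Bonferroni comparison reports."""
    from .evaluation import grouped_comparison

    frames = [pd.read_csv(p, sep="\t") for p in metric_files]
    if not frames:
        raise DataError("no metric files given")
    runs = pd.concat(frames, ignore_index=True)
    labels = set(runs["label"])
    if not {"baseline", "spatial"} <= labels:
        raise DataError(f"need both arms, found labels {sorted(labels)}")
    per_exp, per_group = grouped_comparison(runs)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    per_exp.to_csv(outdir / "comparison_per_experiment.tsv", sep="\t", index=False)
    per_group.to_csv(outdir / "comparison_per_group.tsv", sep="\t", index=False)
    return {"per_experiment": per_exp, "per_group": per_group}
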