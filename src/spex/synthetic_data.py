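"""Download-free synthetic datasets with the structure the pipeline assumes.

The generator emits a gene/TSS table, binned intra-chromosomal contacts
with integer counts at a fixed resolution, a per-track signal store, and an
expression matrix in which the (log-space) target of gene ``g`` is

    y(g) = beta_lin * s_lin(g) + beta_sp * s_sp(g) + eps,   eps ~ N(0, noise_sd)

where ``s_lin`` is the standardised mean predicted signal over the gene's
+-20 kb window and ``s_sp`` the standardised summed predicted signal over
the gene's *planted qualifying* loop anchors -- anchors of loops whose
count is at least 2 and which lie entirely outside the +-20 kb linear
scope. Genes without a qualifying loop have ``s_sp = 0``. Loop counts mix
in 1s, and some genes get decoy loops inside the linear scope, so the
pipeline's filters are exercised end to end: neither kind may ever reach a
spatial feature.

TSSs are placed at least 30 kb apart and planted distal anchors avoid every
gene's TSS anchor window, so the truth record is the complete list of
spatial regions any gene should select.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as ft
from .contacts import Contact, ContactSet, write_bedpe
from .errors import ConfigError, DataError
from .genome_io import (
    DEFAULT_PSEUDOCOUNT,
    ExpressionMatrix,
    GeneRecord,
    write_expression_matrix,
    write_gene_table,
    write_tissue_mapping,
)
from .signal_predictor import SyntheticTrackStore, track_predictor

log = logging.getLogger(__name__)

MIN_TSS_SPACING = 30_000
#: clearance so every window, context and anchor bin fits the chromosome
EDGE_MARGIN = 25_000


def _default_chroms() -> dict[str, int]:
    # five chromosomes sized to host 2000 genes at >= 30 kb TSS spacing
    return {c: 13_000_000 for c in ("chr1", "chr2", "chr3", "chr7", "chr8")}


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe the reference experiment: 2000 genes on five
    chromosomes, 20 tracks, 5 kb contact resolution, half the genes given
    distal loops 30-300 kb away, loop counts mixing 1s (below the count
    threshold) with qualifying counts, equal linear and spatial effect
    sizes and moderate noise.
    """

    n_genes: int = 2000
    chrom_lengths: dict[str, int] = field(default_factory=_default_chroms)
    n_tracks: int = 20
    k_per_side: int = 10
    resolution: int = 5000
    loop_prob: float = 0.5
    n_loops: int = 2
    loop_distance: tuple[int, int] = (30_000, 300_000)
    count_choices: tuple[int, ...] = (1, 2, 3, 4, 5)
    count_weights: tuple[float, ...] = (0.25, 0.25, 0.2, 0.15, 0.15)
    decoy_inside_prob: float = 0.5
    beta_lin: float = 1.0
    beta_sp: float = 1.0
    noise_sd: float = 0.5
    n_tissues: int = 1
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    block_size: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_tracks < 1 or self.resolution < 1:
            raise ConfigError("n_genes, n_tracks and resolution must be positive")
        if not 0 <= self.loop_prob <= 1:
            raise ConfigError("loop_prob must lie in [0, 1]")
        if self.loop_distance[0] <= ft.LINEAR_SCOPE:
            raise ConfigError(
                f"planted loop distances must exceed the {ft.LINEAR_SCOPE} bp "
                f"linear scope, got {self.loop_distance}"
            )
        if len(self.count_choices) != len(self.count_weights):
            raise ConfigError("count_choices and count_weights must align")
        if self.resolution % self.block_size != 0 or self.resolution % 200 != 0:
            raise ConfigError("resolution must be a multiple of 200 and block_size")


@dataclass
class SyntheticDataset:
    """A generated dataset plus the truth record that explains it."""

    config: SynthConfig
    genes: list[GeneRecord]
    contacts: ContactSet
    store: SyntheticTrackStore
    expression: ExpressionMatrix
    mapping: dict[str, str]
    truth: pd.DataFrame  # indexed by gene_id


def _place_tss(cfg: SynthConfig, rng: np.random.Generator) -> list[GeneRecord]:
    chroms = list(cfg.chrom_lengths)
    per_chrom = {c: 0 for c in chroms}
    for i in range(cfg.n_genes):
        per_chrom[chroms[i % len(chroms)]] += 1
    genes: list[GeneRecord] = []
    gid = 0
    for chrom in chroms:
        n = per_chrom[chrom]
        if n == 0:
            continue
        length = cfg.chrom_lengths[chrom]
        usable = length - 2 * EDGE_MARGIN - cfg.loop_distance[1]
        spacing = usable / n
        if spacing < MIN_TSS_SPACING:
            raise ConfigError(
                f"{chrom} (length {length}) cannot host {n} TSSs at "
                f">= {MIN_TSS_SPACING} bp spacing plus loop room; "
                f"use larger chromosomes or fewer genes"
            )
        jitter_max = int(spacing) - MIN_TSS_SPACING
        for j in range(n):
            tss = EDGE_MARGIN + int(j * spacing)
            if jitter_max > 0:
                tss += int(rng.integers(0, jitter_max))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneRecord(f"G{gid:05d}", chrom, tss, strand))
            gid += 1
    return genes


def _forbidden_bins(genes: list[GeneRecord], resolution: int) -> dict[str, set[int]]:
    """Bin starts whose anchor would overlap some gene's TSS window
    [tss, tss + resolution) -- planted distal anchors must avoid these."""
    out: dict[str, set[int]] = {}
    for g in genes:
        bins = out.setdefault(g.chrom, set())
        first = (g.tss - resolution) // resolution + 1
        last = (g.tss + resolution - 1) // resolution
        for k in range(first, last + 1):
            bins.add(k * resolution)
    return out


def generate(cfg: SynthConfig | None = None) -> SyntheticDataset:
    """Generate a complete dataset; all randomness flows from ``cfg.seed``."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)

    genes = _place_tss(cfg, rng)
    forbidden = _forbidden_bins(genes, cfg.resolution)
    res = cfg.resolution

    # block-constant, non-negative track signal
    data = {}
    for chrom, length in cfg.chrom_lengths.items():
        n_blocks = -(-length // cfg.block_size)
        data[chrom] = rng.gamma(2.0, 1.0, size=(cfg.n_tracks, n_blocks))
    store = SyntheticTrackStore(data, block_size=cfg.block_size, seed=cfg.seed)
    predictor = track_predictor(store)

    contacts: list[Contact] = []
    qualifying: dict[str, list[int]] = {}
    for g in genes:
        length = cfg.chrom_lengths[g.chrom]
        b1 = (g.tss // res) * res
        qualifying[g.gene_id] = []
        if rng.random() < cfg.loop_prob:
            used: set[int] = set()
            for _ in range(cfg.n_loops):
                b2 = None
                for _attempt in range(100):
                    d = int(rng.integers(cfg.loop_distance[0], cfg.loop_distance[1] + 1))
                    direction = -1 if rng.random() < 0.5 else 1
                    cand = ((g.tss + direction * d) // res) * res
                    if cand < 0 or cand + res > length or cand in used:
                        continue
                    if cand in forbidden[g.chrom]:
                        continue
                    # paranoia: planted anchors must sit outside the scope
                    if cand < g.tss + ft.LINEAR_SCOPE and cand + res > g.tss - ft.LINEAR_SCOPE:
                        continue
                    b2 = cand
                    break
                if b2 is None:
                    raise ConfigError(
                        f"could not place a loop anchor for {g.gene_id} on "
                        f"{g.chrom}; use larger chromosomes"
                    )
                used.add(b2)
                count = int(rng.choice(cfg.count_choices, p=cfg.count_weights))
                contacts.append(Contact(g.chrom, b1, b1 + res, b2, b2 + res, count))
                if count >= ft.MIN_COUNT:
                    qualifying[g.gene_id].append(b2)
        if rng.random() < cfg.decoy_inside_prob:
            # decoy with a qualifying count but inside the linear scope
            b2d = ((g.tss + ft.LINEAR_SCOPE // 2) // res) * res
            if (
                0 <= b2d
                and b2d + res <= length
                and b2d + res <= g.tss + ft.LINEAR_SCOPE
                and b2d != b1
                and b2d not in forbidden[g.chrom] - {b1}
            ):
                contacts.append(Contact(g.chrom, b1, b1 + res, b2d, b2d + res, 3))
    contact_set = ContactSet(res, contacts)

    # truth signals through the same averaging predictor the pipeline uses,
    # but from the *planted* loop list, never from contact selection
    raw_lin = np.empty(len(genes))
    raw_sp = np.zeros(len(genes))
    has_loop = np.zeros(len(genes), dtype=bool)
    n_regions = np.zeros(len(genes), dtype=int)
    for i, g in enumerate(genes):
        grid = ft.build_bin_grid(g, chrom_length=cfg.chrom_lengths[g.chrom])
        sig = ft.window_signal(grid, predictor)
        raw_lin[i] = sig.mean()
        anchors = sorted(set(qualifying[g.gene_id]))
        n_regions[i] = len(anchors)
        if anchors:
            has_loop[i] = True
            raw_sp[i] = sum(
                predictor.predict_bins(g.chrom, b, b + res).sum() for b in anchors
            )

    s_lin = _standardise(raw_lin)
    s_sp = np.zeros(len(genes))
    if has_loop.sum() >= 2:
        s_sp[has_loop] = _standardise(raw_sp[has_loop])

    tissue_names = [f"tissue{t + 1}" for t in range(cfg.n_tissues)]
    noise = rng.normal(0.0, cfg.noise_sd, size=(len(genes), cfg.n_tissues)) \
        if cfg.noise_sd > 0 else np.zeros((len(genes), cfg.n_tissues))
    y = (cfg.beta_lin * s_lin + cfg.beta_sp * s_sp)[:, None] + noise
    values = np.exp(y) - cfg.pseudocount
    if np.any(values < 0):
        raise DataError("synthetic expression fell below zero; lower noise_sd")
    expression = ExpressionMatrix([g.gene_id for g in genes], tissue_names, values)

    truth = pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "tss": [g.tss for g in genes],
            "strand": [g.strand for g in genes],
            "has_qualifying_loop": has_loop,
            "n_qualifying_regions": n_regions,
            "qualifying_anchors": [
                ",".join(str(b) for b in sorted(set(qualifying[g.gene_id])))
                for g in genes
            ],
            "raw_lin": raw_lin,
            "raw_sp": raw_sp,
            "s_lin": s_lin,
            "s_sp": s_sp,
        },
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )
    for t, name in enumerate(tissue_names):
        truth[f"noise_{name}"] = noise[:, t]
        truth[f"log_target_{name}"] = y[:, t]

    mapping = {"synthetic": tissue_names[0]}
    return SyntheticDataset(cfg, genes, contact_set, store, expression, mapping, truth)


def _standardise(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


FIXTURE_FILES = (
    "genes.bed",
    "contacts.bedpe",
    "tracks.h5",
    "expression.tsv",
    "mapping.tsv",
    "truth.tsv",
)


def write_fixture(ds: SyntheticDataset, outdir: str | Path, overwrite: bool = False) -> dict[str, Path]:
    """Write the dataset in exactly the formats the pipeline reads, plus the
    truth record and a checksum manifest. Refuses to clobber a non-empty
    directory unless ``overwrite`` is set."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise DataError(f"{outdir} is not empty; pass overwrite=True to replace it")
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / name for name in FIXTURE_FILES}
    write_gene_table(ds.genes, paths["genes.bed"], format="bed6")
    write_bedpe(ds.contacts, paths["contacts.bedpe"])
    ds.store.save(paths["tracks.h5"])
    write_expression_matrix(ds.expression, paths["expression.tsv"])
    write_tissue_mapping(ds.mapping, paths["mapping.tsv"])
    ds.truth.to_csv(paths["truth.tsv"], sep="\t")
    manifest = outdir / "manifest.tsv"
    with manifest.open("w") as fh:
        fh.write("file\tsha256\tbytes\n")
        for name in FIXTURE_FILES:
            digest = hashlib.sha256(paths[name].read_bytes()).hexdigest()
            fh.write(f"{name}\t{digest}\t{paths[name].stat().st_size}\n")
    paths["manifest.tsv"] = manifest
    log.info("wrote synthetic fixture to %s (%d genes, %d contacts)",
             outdir, len(ds.genes), len(ds.contacts))
    return paths
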