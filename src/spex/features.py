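"""Per-gene feature tensors: decay-weighted TSS-window features plus one
spatial column from contact-selected distal regions.

The local part follows the classic promoter-window construction: the signal
of every track is predicted in 200 bp bins over the window centred on the
TSS (200 bins, 100 per side, so +-20 kb -- the same 20 kb "linear scope"
that bounds conventional sequence-adjacent features) and compressed with
exponential distance decays, ``K`` scales per side, giving ``2K`` features
per track. At full scale (2002 tracks) the window holds 2002 x 200 =
400,400 raw values and the decay transform leaves 2002 x 20 = 40,040
features.

The spatial part selects contacts anchored in ``[tss, tss + resolution)``
whose other anchor lies entirely outside the +-20 kb linear scope and whose
count is at least 2, sums the predicted signal over the selected regions
into a single extra column, and falls back to the unweighted window sum
(no decay transform) when no contact qualifies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np

from .contacts import ContactSet, _overlaps
from .errors import DataError
from .genome_io import GeneRecord
from .signal_predictor import BIN_SIZE, PredictorContract

log = logging.getLogger(__name__)

WINDOW = 40_000  # total TSS window, bp (100 bins of 200 bp per side)
N_BINS = WINDOW // BIN_SIZE  # 200 bins, 100 per side
LINEAR_SCOPE = 20_000  # half-width of the region counted as "linearly close"
MIN_COUNT = 2  # minimum contact count for a qualifying loop


@dataclass(frozen=True)
class BinGrid:
    """The 200-bin tiling of the +-20 kb window around one TSS.

    ``starts`` are genomic bin starts ordered 5'->3' relative to the gene's
    strand, so index 0 is always the most upstream bin; for minus-strand
    genes the genomic order is reversed. ``valid`` flags bins that lie
    inside the chromosome; bins truncated off the chromosome start carry
    zero signal and are logged.
    """

    chrom: str
    tss: int
    strand: str
    starts: np.ndarray  # (N_BINS,) genomic bin starts, 5'->3' order
    valid: np.ndarray  # (N_BINS,) bool
    bin_size: int = BIN_SIZE

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    @property
    def truncated(self) -> bool:
        return not bool(self.valid.all())


def build_bin_grid(
    gene: GeneRecord,
    window: int = WINDOW,
    bin_size: int = BIN_SIZE,
    chrom_length: int | None = None,
) -> BinGrid:
    """Tile ``[tss - window/2, tss + window/2)`` into ``window / bin_size``
    bins ordered 5'->3' along the gene."""
    half = window // 2
    genomic_starts = gene.tss - half + bin_size * np.arange(window // bin_size)
    valid = genomic_starts >= 0
    if chrom_length is not None:
        valid &= genomic_starts + bin_size <= chrom_length
    if gene.strand == "-":
        genomic_starts = genomic_starts[::-1].copy()
        valid = valid[::-1].copy()
    if not valid.all():
        log.info(
            "gene %s: %d/%d window bins fall outside %s and carry zero signal",
            gene.gene_id, int((~valid).sum()), len(valid), gene.chrom,
        )
    return BinGrid(gene.chrom, gene.tss, gene.strand, genomic_starts, valid, bin_size)


def window_signal(grid: BinGrid, predictor: PredictorContract) -> np.ndarray:
    """Predicted signal over the grid, columns in the grid's 5'->3' order.

    Missing (truncated) bins are zero-filled.
    """
    order = np.argsort(grid.starts)  # back to genomic order
    g_starts = grid.starts[order]
    g_valid = grid.valid[order]
    out = np.zeros((predictor.n_tracks, grid.n_bins))
    if g_valid.any():
        lo = int(g_starts[g_valid][0])
        hi = int(g_starts[g_valid][-1]) + grid.bin_size
        pred = predictor.predict_bins(grid.chrom, lo, hi)
        idx = ((g_starts[g_valid] - lo) // grid.bin_size).astype(int)
        out[:, np.nonzero(g_valid)[0]] = pred[:, idx]
    # restore 5'->3' order
    inverse = np.empty_like(order)
    inverse[order] = np.arange(len(order))
    return out[:, inverse]


@dataclass(frozen=True)
class DecayBasis:
    """Exponential distance-decay weights over the window bins.

    Row ``k`` (k < K) applies ``exp(-d / lambda_k)`` to upstream bins only;
    row ``K + k`` to downstream bins only; ``d`` is the distance from the
    bin centre to the TSS in bp. All weights lie in [0, 1].
    """

    k_per_side: int
    lambdas: np.ndarray  # (K,) decay lengths, bp
    weights: np.ndarray  # (2K, N_BINS)


def default_lambdas(k_per_side: int = 10, bin_size: int = BIN_SIZE) -> np.ndarray:
    """Geometric ladder of decay lengths, one bin to ~window scale:
    ``lambda_k = bin_size * 2**(k-1)``."""
    return bin_size * 2.0 ** np.arange(k_per_side)


def decay_basis(
    k_per_side: int = 10,
    lambdas: Sequence[float] | None = None,
    n_bins: int = N_BINS,
    bin_size: int = BIN_SIZE,
) -> DecayBasis:
    if lambdas is None:
        lambdas = default_lambdas(k_per_side, bin_size)
    lambdas = np.asarray(lambdas, dtype=float)
    if len(lambdas) != k_per_side:
        raise ValueError(f"expected {k_per_side} decay lengths, got {len(lambdas)}")
    if np.any(lambdas <= 0):
        raise ValueError("decay lengths must be positive")
    half = n_bins // 2
    # bin centre distance to TSS in 5'->3' order; bins 0..half-1 upstream
    centres = (np.arange(n_bins) - half) * bin_size + bin_size / 2.0
    d = np.abs(centres)
    weights = np.zeros((2 * k_per_side, n_bins))
    for k, lam in enumerate(lambdas):
        w = np.exp(-d / lam)
        weights[k, :half] = w[:half]  # upstream rows
        weights[k_per_side + k, half:] = w[half:]  # downstream rows
    return DecayBasis(k_per_side, lambdas, weights)


def linear_features(signal: np.ndarray, basis: DecayBasis) -> np.ndarray:
    """Compress an ``F x n_bins`` window signal into ``F x 2K`` decay
    features: ``out[f, k] = sum_j weights[k, j] * signal[f, j]``."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 2 or signal.shape[1] != basis.weights.shape[1]:
        raise ValueError(
            f"signal shape {signal.shape} incompatible with basis over "
            f"{basis.weights.shape[1]} bins"
        )
    return signal @ basis.weights.T


@dataclass
class SpatialSelection:
    """Distal regions spatially close to one TSS, or the fallback marker."""

    regions: list[tuple[str, int, int]]
    used_fallback: bool


def select_spatial_regions(
    cs: ContactSet,
    gene: GeneRecord,
    linear_scope: int = LINEAR_SCOPE,
    min_count: int = MIN_COUNT,
) -> SpatialSelection:
    """Select contact anchors spatially close to the TSS.

    A contact qualifies when (a) one anchor overlaps the anchor window
    ``[tss, tss + resolution)``, (b) its count is at least ``min_count``,
    and (c) the *other* anchor lies entirely outside the linear scope
    ``[tss - linear_scope, tss + linear_scope)``. The other anchors of all
    qualifying contacts, deduplicated and sorted, are the selected regions.
    An empty selection sets ``used_fallback`` and signals that the gene's
    own window must stand in for the missing spatial regions.
    """
    tss = gene.tss
    win_lo, win_hi = tss, tss + cs.resolution
    scope_lo, scope_hi = tss - linear_scope, tss + linear_scope
    regions: set[tuple[str, int, int]] = set()
    for c in cs.query_anchored(gene.chrom, win_lo, win_hi):
        if c.count < min_count:
            continue
        a1, a2 = c.anchors()
        for near, other in ((a1, a2), (a2, a1)):
            if not _overlaps(near[0], near[1], win_lo, win_hi):
                continue
            if _overlaps(other[0], other[1], scope_lo, scope_hi):
                continue
            regions.add((gene.chrom, other[0], other[1]))
    return SpatialSelection(sorted(regions), used_fallback=not regions)


def spatial_feature(
    sel: SpatialSelection,
    predictor: PredictorContract,
    grid: BinGrid,
    window_sig: np.ndarray | None = None,
) -> np.ndarray:
    """Sum predicted signal over the selected regions into one F-vector.

    Regions are subdivided into 200 bp bins (truncated to the largest
    contained multiple of the bin size, logged when trimming occurs). In
    fallback mode the vector is the unweighted sum of the gene's own
    200-bin window signal -- no exponential transform is applied.
    """
    if sel.used_fallback:
        if window_sig is None:
            window_sig = window_signal(grid, predictor)
        return window_sig.sum(axis=1)
    vec = np.zeros(predictor.n_tracks)
    for chrom, start, end in sel.regions:
        n = (end - start) // predictor.bin_size
        if n == 0:
            log.warning("region %s:%d-%d shorter than one bin, skipped", chrom, start, end)
            continue
        snapped_end = start + n * predictor.bin_size
        if snapped_end != end:
            log.info(
                "region %s:%d-%d truncated to %d for 200 bp binning",
                chrom, start, end, snapped_end,
            )
        try:
            pred = predictor.predict_bins(chrom, start, snapped_end)
        except Exception as exc:
            raise DataError(
                f"predictor failed on region {chrom}:{start}-{snapped_end}: {exc}"
            ) from exc
        vec += pred.sum(axis=1)
    return vec


@dataclass
class FeatureTensor:
    """One gene's ``F x (2K + 1)`` feature matrix.

    Columns ``0 .. 2K-1`` are the decay features (K upstream then K
    downstream scales); the last column is the spatial feature.
    """

    gene_id: str
    matrix: np.ndarray
    k_per_side: int
    resolution: int
    used_fallback: bool
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise DataError(f"tensor {self.gene_id}: matrix must be 2-D")
        if self.matrix.shape[1] != 2 * self.k_per_side + 1:
            raise DataError(
                f"tensor {self.gene_id}: expected {2 * self.k_per_side + 1} "
                f"columns, got {self.matrix.shape[1]}"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise DataError(f"tensor {self.gene_id}: non-finite entries")

    @property
    def n_tracks(self) -> int:
        return self.matrix.shape[0]

    def flatten(self) -> np.ndarray:
        """Track-major flattening: each track's 2K+1 columns contiguous."""
        return self.matrix.ravel(order="C")


def assemble_tensor(
    lin: np.ndarray,
    sp: np.ndarray,
    gene_id: str,
    k_per_side: int,
    resolution: int,
    used_fallback: bool,
) -> FeatureTensor:
    """Stack ``F x 2K`` decay features and the spatial F-vector into the
    final ``F x (2K + 1)`` tensor (spatial column last)."""
    lin = np.asarray(lin, dtype=float)
    sp = np.asarray(sp, dtype=float)
    if lin.ndim != 2 or sp.ndim != 1 or lin.shape[0] != sp.shape[0]:
        raise DataError(
            f"tensor {gene_id}: row mismatch (linear {lin.shape}, spatial {sp.shape})"
        )
    if lin.shape[1] != 2 * k_per_side:
        raise DataError(
            f"tensor {gene_id}: expected {2 * k_per_side} decay columns, "
            f"got {lin.shape[1]}"
        )
    matrix = np.column_stack([lin, sp])
    return FeatureTensor(gene_id, matrix, k_per_side, resolution, used_fallback)


def build_gene_tensor(
    gene: GeneRecord,
    cs: ContactSet,
    predictor: PredictorContract,
    basis: DecayBasis,
    linear_scope: int = LINEAR_SCOPE,
    min_count: int = MIN_COUNT,
    chrom_length: int | None = None,
) -> FeatureTensor:
    """Full per-gene pipeline: grid -> signal -> decay features -> spatial
    selection -> spatial feature -> tensor."""
    grid = build_bin_grid(gene, chrom_length=chrom_length)
    sig = window_signal(grid, predictor)
    lin = linear_features(sig, basis)
    sel = select_spatial_regions(cs, gene, linear_scope=linear_scope, min_count=min_count)
    sp = spatial_feature(sel, predictor, grid, window_sig=sig)
    return assemble_tensor(
        lin, sp, gene.gene_id, basis.k_per_side, cs.resolution, sel.used_fallback
    )


def write_tensor_archive(tensors: Iterable[FeatureTensor], path: str | Path) -> None:
    """Persist tensors to a gene-keyed HDF5 archive (exact round trip)."""
    tensors = list(tensors)
    ids = [t.gene_id for t in tensors]
    if len(set(ids)) != len(ids):
        dup = sorted({g for g in ids if ids.count(g) > 1})
        raise DataError(f"duplicate gene keys in archive: {dup}")
    with h5py.File(path, "w") as fh:
        if tensors:
            fh.attrs["n_tracks"] = tensors[0].n_tracks
            fh.attrs["k_per_side"] = tensors[0].k_per_side
            fh.attrs["resolution"] = tensors[0].resolution
        fh.attrs["n_tensors"] = len(tensors)
        for t in tensors:
            ds = fh.create_dataset(t.gene_id, data=t.matrix, track_times=False)
            ds.attrs["k_per_side"] = t.k_per_side
            ds.attrs["resolution"] = t.resolution
            ds.attrs["used_fallback"] = t.used_fallback


def read_tensor_archive(
    path: str | Path, gene_ids: Sequence[str] | None = None
) -> dict[str, FeatureTensor]:
    """Load tensors back; a requested gene missing from the archive raises a
    KeyError naming it."""
    out: dict[str, FeatureTensor] = {}
    with h5py.File(path, "r") as fh:
        keys = list(fh.keys()) if gene_ids is None else list(gene_ids)
        for gid in keys:
            if gid not in fh:
                raise KeyError(f"gene {gid!r} not in tensor archive {path}")
            ds = fh[gid]
            out[gid] = FeatureTensor(
                gene_id=gid,
                matrix=ds[()],
                k_per_side=int(ds.attrs["k_per_side"]),
                resolution=int(ds.attrs["resolution"]),
                used_fallback=bool(ds.attrs["used_fallback"]),
            )
    return out
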