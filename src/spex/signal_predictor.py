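"""The epigenomic signal-predictor contract and a synthetic implementation.

Any signal source -- a trained sequence-to-epigenome CNN, or the synthetic
track store shipped here -- is used through one contract: given a genomic
interval whose length is a multiple of 200 bp, return an ``F x n_bins``
matrix where column ``j`` is the predicted signal of every track over the
200 bp bin ``[start + 200 j, start + 200 (j+1))``. Each bin is predicted
from a 2000 bp context window centred on it; the contract is deterministic.

The synthetic predictor averages a stored per-base track over the context
window, which gives every aggregation step downstream a closed-form oracle.
At chromosome edges the context is truncated to the available bases; no
padding value is invented.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np

from .errors import DataError

log = logging.getLogger(__name__)

BIN_SIZE = 200
CONTEXT = 2000
#: number of epigenomic tracks in a full-scale run (ENCODE/Roadmap panel)
FULL_SCALE_TRACKS = 2002


class PredictorContract:
    """Abstract interface mapping genomic intervals to per-bin signal.

    Subclasses define :attr:`n_tracks` and implement :meth:`predict_bins`.
    """

    n_tracks: int
    bin_size: int = BIN_SIZE
    context: int = CONTEXT

    def predict_bins(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Return an ``(n_tracks, (end - start) // 200)`` signal matrix."""
        raise NotImplementedError

    def _check_interval(self, chrom: str, start: int, end: int) -> int:
        if start >= end:
            raise ValueError(f"empty interval [{start}, {end}) on {chrom}")
        if (end - start) % self.bin_size != 0:
            raise ValueError(
                f"interval length {end - start} is not a multiple of {self.bin_size}"
            )
        return (end - start) // self.bin_size


class SyntheticTrackStore:
    """Per-chromosome, per-track non-negative signal arrays.

    Values are stored block-wise: ``value(track, x) = data[track, x // block_size]``,
    i.e. the signal is constant within each block. ``block_size=1`` is the
    per-base layout; larger blocks keep full-genome stores small while all
    base-pair query semantics stay exact.
    """

    def __init__(
        self,
        data: Mapping[str, np.ndarray],
        block_size: int = 1,
        seed: int | None = None,
    ):
        if block_size < 1:
            raise ValueError(f"block_size must be >= 1, got {block_size}")
        self.block_size = int(block_size)
        self.seed = seed
        self.data: dict[str, np.ndarray] = {}
        n_tracks = None
        for chrom, arr in data.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.ndim != 2:
                raise DataError(f"{chrom}: track array must be 2-D (F x n_blocks)")
            if not np.all(np.isfinite(arr)):
                raise DataError(f"{chrom}: non-finite track values")
            if n_tracks is None:
                n_tracks = arr.shape[0]
            elif arr.shape[0] != n_tracks:
                raise DataError("all chromosomes must have the same track count")
            self.data[chrom] = arr
        if n_tracks is None:
            raise DataError("track store is empty")
        self.n_tracks = int(n_tracks)

    def chrom_length(self, chrom: str) -> int:
        """Number of bases covered on ``chrom``."""
        return self.data[chrom].shape[1] * self.block_size

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base signal ``(n_tracks, end - start)`` over ``[start, end)``."""
        if chrom not in self.data:
            raise DataError(f"unknown chromosome {chrom!r} in track store")
        if not (0 <= start < end <= self.chrom_length(chrom)):
            raise ValueError(
                f"[{start}, {end}) outside {chrom} "
                f"(length {self.chrom_length(chrom)})"
            )
        bs = self.block_size
        if bs == 1:
            return self.data[chrom][:, start:end]
        blocks = self.data[chrom][:, start // bs : (end - 1) // bs + 1]
        expanded = np.repeat(blocks, bs, axis=1)
        off = start - (start // bs) * bs
        return expanded[:, off : off + (end - start)]

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            fh.attrs["block_size"] = self.block_size
            fh.attrs["n_tracks"] = self.n_tracks
            if self.seed is not None:
                fh.attrs["seed"] = self.seed
            for chrom, arr in self.data.items():
                fh.create_dataset(
                    chrom, data=arr, compression="gzip", shuffle=True,
                    track_times=False,  # same seed => byte-identical file
                )

    @classmethod
    def load(cls, path: str | Path) -> "SyntheticTrackStore":
        with h5py.File(path, "r") as fh:
            block_size = int(fh.attrs["block_size"])
            seed = int(fh.attrs["seed"]) if "seed" in fh.attrs else None
            data = {chrom: fh[chrom][()] for chrom in fh.keys()}
        return cls(data, block_size=block_size, seed=seed)


class TrackAveragingPredictor(PredictorContract):
    """Predictor whose bin value is the mean stored signal over the 2000 bp
    context window centred on the bin (truncated at chromosome edges)."""

    def __init__(self, store: SyntheticTrackStore):
        self.store = store
        self.n_tracks = store.n_tracks

    def predict_bins(self, chrom: str, start: int, end: int) -> np.ndarray:
        n_bins = self._check_interval(chrom, start, end)
        if chrom not in self.store.data:
            raise DataError(f"unknown chromosome {chrom!r}")
        length = self.store.chrom_length(chrom)
        if start < 0 or end > length:
            raise ValueError(f"[{start}, {end}) outside {chrom} (length {length})")
        flank = (self.context - self.bin_size) // 2  # 900 bp each side
        lo = max(0, start - flank)
        hi = min(length, end + flank)
        v = self.store.values(chrom, lo, hi)
        csum = np.concatenate(
            [np.zeros((self.n_tracks, 1)), np.cumsum(v, axis=1)], axis=1
        )
        out = np.empty((self.n_tracks, n_bins), dtype=np.float64)
        for j in range(n_bins):
            w_lo = max(0, start + j * self.bin_size - flank)
            w_hi = min(length, start + (j + 1) * self.bin_size + flank)
            s = csum[:, w_hi - lo] - csum[:, w_lo - lo]
            out[:, j] = s / (w_hi - w_lo)
        return out


def track_predictor(store: SyntheticTrackStore) -> TrackAveragingPredictor:
    """Wrap a :class:`SyntheticTrackStore` in the predictor contract."""
    return TrackAveragingPredictor(store)
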