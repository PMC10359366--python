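"""Binned intra-chromosomal chromatin contacts and anchor-interval queries.

A :class:`ContactSet` holds pairwise contacts at one fixed bin resolution
(the Hi-C / ChIA-PET matrix resolution). Contacts are stored symmetrically
(``start1 <= start2``); identical pairs are merged by summing their counts,
matching the upper-triangle convention of cooler matrices. Interval overlap
is half-open throughout (``a < end and start < b``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .errors import DataError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Contact:
    """One binned intra-chromosomal contact with an observed count."""

    chrom: str
    start1: int
    end1: int
    start2: int
    end2: int
    count: int

    def anchors(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (self.start1, self.end1), (self.start2, self.end2)


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


class ContactSet:
    """Resolution-tagged collection of contacts indexed by chromosome.

    Parameters
    ----------
    resolution : bin width in bp; every anchor must span exactly this width
        and start on a multiple of it.
    contacts : iterable of :class:`Contact`. Anchors are normalised so that
        anchor1 <= anchor2 and duplicate pairs are merged by summing counts.
    """

    def __init__(self, resolution: int, contacts: Iterable[Contact] = ()):
        if resolution <= 0:
            raise DataError(f"resolution must be positive, got {resolution}")
        self.resolution = int(resolution)
        merged: dict[tuple[str, int, int], int] = {}
        for c in contacts:
            c = self._validate(c)
            key = (c.chrom, c.start1, c.start2)
            merged[key] = merged.get(key, 0) + c.count
        self._by_chrom: dict[str, list[Contact]] = {}
        res = self.resolution
        for (chrom, s1, s2), count in sorted(merged.items()):
            self._by_chrom.setdefault(chrom, []).append(
                Contact(chrom, s1, s1 + res, s2, s2 + res, count)
            )
        # per-chromosome anchor arrays for vectorised interval queries
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, lst in self._by_chrom.items():
            self._index[chrom] = (
                np.array([c.start1 for c in lst], dtype=np.int64),
                np.array([c.start2 for c in lst], dtype=np.int64),
            )

    def _validate(self, c: Contact) -> Contact:
        res = self.resolution
        if c.count < 1:
            raise DataError(f"contact {c}: count must be >= 1")
        for s, e in c.anchors():
            if e - s != res:
                raise DataError(
                    f"contact {c}: anchor width {e - s} != resolution {res}"
                )
            if s % res != 0:
                raise DataError(f"contact {c}: bin start {s} not a multiple of {res}")
        if c.start1 > c.start2:
            c = Contact(c.chrom, c.start2, c.end2, c.start1, c.end1, c.count)
        return c

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __iter__(self) -> Iterator[Contact]:
        for chrom in sorted(self._by_chrom):
            yield from self._by_chrom[chrom]

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def query_anchored(self, chrom: str, a: int, b: int) -> list[Contact]:
        """Contacts with either anchor overlapping the half-open ``[a, b)``.

        Each contact is returned once even when both anchors overlap.
        An unknown chromosome yields an empty result (logged), not an error.
        """
        if a >= b:
            raise ValueError(f"empty query interval [{a}, {b})")
        if chrom not in self._by_chrom:
            log.debug("query on unknown chromosome %s -> empty", chrom)
            return []
        s1, s2 = self._index[chrom]
        res = self.resolution
        hit = ((s1 < b) & (a < s1 + res)) | ((s2 < b) & (a < s2 + res))
        lst = self._by_chrom[chrom]
        return [lst[i] for i in np.nonzero(hit)[0]]


def read_bedpe(
    path: str | Path, resolution: int, on_trans: str = "drop"
) -> ContactSet:
    """Read binned contacts from a BEDPE file (count in column 7).

    Inter-chromosomal rows are dropped with a logged count by default
    (``on_trans='drop'``) or rejected (``on_trans='error'``).
    """
    if on_trans not in ("drop", "error"):
        raise ValueError(f"on_trans must be 'drop' or 'error', got {on_trans!r}")
    path = Path(path)
    contacts: list[Contact] = []
    n_trans = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise DataError(f"{path}:{lineno}: expected >= 7 BEDPE columns")
            chrom1, s1, e1, chrom2, s2, e2, count_s = fields[:7]
            if chrom1 != chrom2:
                if on_trans == "error":
                    raise DataError(
                        f"{path}:{lineno}: inter-chromosomal contact "
                        f"{chrom1} x {chrom2}"
                    )
                n_trans += 1
                continue
            try:
                start1, end1 = int(s1), int(e1)
                start2, end2 = int(s2), int(e2)
                count = int(count_s)
            except ValueError:
                raise DataError(f"{path}:{lineno}: non-integer field") from None
            if count <= 0:
                raise DataError(f"{path}:{lineno}: count {count} must be >= 1")
            if end1 - start1 != resolution or end2 - start2 != resolution:
                raise DataError(
                    f"{path}:{lineno}: anchor width != resolution {resolution}"
                )
            contacts.append(Contact(chrom1, start1, end1, start2, end2, count))
    if n_trans:
        log.info("dropped %d inter-chromosomal contacts from %s", n_trans, path)
    return ContactSet(resolution, contacts)


def write_bedpe(cs: ContactSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for c in cs:
            fh.write(
                f"{c.chrom}\t{c.start1}\t{c.end1}\t{c.chrom}\t{c.start2}\t"
                f"{c.end2}\t{c.count}\n"
            )


def read_cool(path: str | Path, chrom: str, a: int, b: int) -> ContactSet:
    """Adapter: extract contacts anchored in ``[a, b)`` of one chromosome
    from a single-resolution ``.cool`` file into a :class:`ContactSet`.

    Requires the optional :mod:`cooler` dependency.
    """
    try:
        import cooler  # noqa: PLC0415
    except ImportError as exc:
        raise ImportError(
            "the cooler package is required for .cool input; "
            "install it or convert the matrix to BEDPE"
        ) from exc
    clr = cooler.Cooler(str(path))
    res = int(clr.binsize)
    df = clr.matrix(balance=False, as_pixels=True, join=True).fetch(
        (chrom, a, b), chrom
    )
    contacts = [
        Contact(chrom, int(r.start1), int(r.end1), int(r.start2), int(r.end2), int(r["count"]))
        for _, r in df.iterrows()
        if r.chrom1 == r.chrom2 and int(r["count"]) >= 1
    ]
    return ContactSet(res, contacts)
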