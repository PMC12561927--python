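"""Genomic interval algebra.

All coordinates are 0-based half-open ``[start, end)``. Intervals of zero or
negative length are rejected on construction. A :class:`RegionSet` is the
universal currency of the pipeline: a sorted table of intervals per chromosome
with opaque attribute columns carried along untouched.

Overlap is always defined as sharing at least one base: ``[a, b)`` and
``[c, d)`` overlap iff ``a < d and c < b``. Touching intervals (``b == c``) do
not overlap but *are* coalesced by :func:`merge_regions` with ``gap=0``,
matching the adjacency rule of the standard merge tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ValidationError

_CORE_COLS = ["chrom", "start", "end"]


@dataclass
class GenomicInterval:
    """A single 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome must be non-empty")
        if self.start < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValidationError(
                f"interval must satisfy start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class RegionSet:
    """A sorted collection of genomic intervals with attribute columns.

    The backing store is a pandas DataFrame with columns ``chrom``, ``start``,
    ``end`` plus any number of extra attribute columns. Rows are kept sorted by
    (chrom, start, end); the positional row index is the region index used by
    all per-region outputs.
    """

    def __init__(self, df: pd.DataFrame | None = None, name: str = ""):
        if df is None:
            df = pd.DataFrame(columns=_CORE_COLS)
        missing = [c for c in _CORE_COLS if c not in df.columns]
        if missing:
            raise ValidationError(f"RegionSet frame missing columns: {missing}")
        df = df.reset_index(drop=True)
        if len(df):
            starts = df["start"].to_numpy()
            ends = df["end"].to_numpy()
            if (starts < 0).any():
                raise ValidationError("negative interval start")
            if (starts >= ends).any():
                bad = int(np.argmax(starts >= ends))
                raise ValidationError(
                    f"interval with start >= end at row {bad}: "
                    f"[{starts[bad]}, {ends[bad]})"
                )
            df = df.sort_values(_CORE_COLS, kind="mergesort").reset_index(drop=True)
        self._df = df
        self.name = name
        self._trees: dict[str, IntervalTree] | None = None
        self._chrom_arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None

    # -- construction ------------------------------------------------------
    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple], name: str = "") -> "RegionSet":
        rows = list(tuples)
        df = pd.DataFrame(rows, columns=_CORE_COLS[: len(rows[0])] if rows else _CORE_COLS)
        return cls(df, name=name)

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval], name: str = "") -> "RegionSet":
        records = []
        for iv in intervals:
            rec = {"chrom": iv.chrom, "start": iv.start, "end": iv.end}
            rec.update(iv.attrs)
            records.append(rec)
        return cls(pd.DataFrame(records, columns=None if records else _CORE_COLS), name=name)

    # -- basic protocol ----------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        extra = [c for c in self._df.columns if c not in _CORE_COLS]
        for row in self._df.itertuples(index=False):
            d = row._asdict()
            yield GenomicInterval(
                d["chrom"], int(d["start"]), int(d["end"]),
                attrs={k: d[k] for k in extra},
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        a = self._df[_CORE_COLS].reset_index(drop=True)
        b = other._df[_CORE_COLS].reset_index(drop=True)
        return a.equals(b)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._df["chrom"].unique().tolist())

    @property
    def region_ids(self) -> pd.Series:
        df = self._df
        return df["chrom"].astype(str) + ":" + df["start"].astype(str) + "-" + df["end"].astype(str)

    def lengths(self) -> np.ndarray:
        return (self._df["end"] - self._df["start"]).to_numpy()

    def is_disjoint(self) -> bool:
        """True if no two intervals on the same chromosome overlap."""
        for _, g in self._df.groupby("chrom", sort=False):
            s = g["start"].to_numpy()
            e = g["end"].to_numpy()
            if len(s) > 1 and (s[1:] < e[:-1]).any():
                return False
        return True

    # -- internal indexes --------------------------------------------------
    def _arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, row indices) for one chromosome, in sorted order."""
        if self._chrom_arrays is None:
            self._chrom_arrays = {}
            for c, g in self._df.groupby("chrom", sort=False):
                self._chrom_arrays[c] = (
                    g["start"].to_numpy(np.int64),
                    g["end"].to_numpy(np.int64),
                    g.index.to_numpy(np.int64),
                )
        empty = (np.empty(0, np.int64),) * 3
        return self._chrom_arrays.get(chrom, empty)

    def _tree(self, chrom: str) -> IntervalTree:
        if self._trees is None:
            self._trees = {}
            for c, g in self._df.groupby("chrom", sort=False):
                self._trees[c] = IntervalTree.from_tuples(
                    zip(g["start"].tolist(), g["end"].tolist(), g.index.tolist())
                )
        return self._trees.get(chrom, IntervalTree())

    def subset(self, row_indices) -> "RegionSet":
        return RegionSet(self._df.iloc[np.asarray(row_indices)].copy(), name=self.name)


@dataclass
class TssTable:
    """Transcription start sites: (gene_id, chrom, tss position, strand).

    Multiple TSS per gene are allowed. Positions are 0-based.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene_id", "chrom", "tss", "strand"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"TSS table missing columns: {missing}")
        if len(self.df) and (self.df["tss"].to_numpy() < 0).any():
            raise ValidationError("TSS positions must be non-negative")
        self.df = (
            self.df.sort_values(["chrom", "tss", "gene_id"], kind="mergesort")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def merge_regions(*sets: RegionSet, gap: int = 0, name: str = "merged") -> RegionSet:
    """Union of all inputs with intervals closer than or equal to ``gap`` coalesced.

    With the default ``gap=0`` touching intervals ([a,b) and [b,c)) merge; a
    1 bp separation does not. The output is minimal: no further merge is
    possible, so intervals are pairwise non-touching per chromosome.
    """
    if gap < 0:
        raise ValidationError("gap must be >= 0")
    frames = [s.df[_CORE_COLS] for s in sets if len(s)]
    if not frames:
        return RegionSet(name=name)
    df = pd.concat(frames, ignore_index=True).sort_values(_CORE_COLS, kind="mergesort")
    out_rows = []
    for chrom, g in df.groupby("chrom", sort=True):
        starts = g["start"].to_numpy(np.int64)
        ends = g["end"].to_numpy(np.int64)
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e + gap:
                cur_e = max(cur_e, e)
            else:
                out_rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out_rows.append((chrom, cur_s, cur_e))
    return RegionSet(pd.DataFrame(out_rows, columns=_CORE_COLS), name=name)


def overlaps_any(regions: RegionSet, other: RegionSet) -> np.ndarray:
    """Boolean per region of ``regions``: does it share >= 1 bp with ``other``?"""
    hit = np.zeros(len(regions), dtype=bool)
    if not len(regions) or not len(other):
        return hit
    disjoint_fast = other.is_disjoint()
    for chrom, g in regions.df.groupby("chrom", sort=False):
        qs = g["start"].to_numpy(np.int64)
        qe = g["end"].to_numpy(np.int64)
        idx = g.index.to_numpy()
        if disjoint_fast:
            os_, oe, _ = other._arrays(chrom)
            if not len(os_):
                continue
            lo = np.searchsorted(oe, qs, side="right")
            hi = np.searchsorted(os_, qe, side="left")
            hit[idx] = hi > lo
        else:
            tree = other._tree(chrom)
            if not tree:
                continue
            for j, (s, e) in enumerate(zip(qs, qe)):
                if tree.overlaps(int(s), int(e)):
                    hit[idx[j]] = True
    return hit


def consensus_filter(master: RegionSet, sample_sets: Sequence[RegionSet], k: int) -> RegionSet:
    """Keep master regions supported by >= k sample sets (>= 1 bp overlap each).

    The returned set carries a ``support`` attribute column with the number of
    sample sets contributing at least one overlapping interval.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > len(sample_sets):
        raise ValidationError(
            f"k={k} exceeds the number of sample sets ({len(sample_sets)})"
        )
    support = np.zeros(len(master), dtype=np.int64)
    for s in sample_sets:
        support += overlaps_any(master, s).astype(np.int64)
    keep = support >= k
    df = master.df.loc[keep, _CORE_COLS].copy()
    df["support"] = support[keep]
    return RegionSet(df, name=master.name)


def subtract_overlapping(query: RegionSet, blacklist: RegionSet) -> RegionSet:
    """Remove (whole, untrimmed) query regions overlapping any blacklist interval."""
    if not len(blacklist):
        return RegionSet(query.df.copy(), name=query.name)
    hit = overlaps_any(query, blacklist)
    return RegionSet(query.df.loc[~hit].copy(), name=query.name)


def overlap_join(a: RegionSet, b: RegionSet, min_frac_of_b: float = 0.0) -> pd.DataFrame:
    """All (a, b) interval pairs overlapping >= 1 bp and >= min_frac_of_b * len(b).

    Returns a DataFrame with columns ``a_index``, ``b_index``, ``overlap`` (bp),
    sorted by (a_index, b_index). An a-interval may appear in many pairs.
    """
    if not (0.0 <= min_frac_of_b <= 1.0):
        raise ValidationError("min_frac_of_b must be in [0, 1]")
    pairs: list[tuple[int, int, int]] = []
    for chrom, g in a.df.groupby("chrom", sort=False):
        tree = b._tree(chrom)
        if not tree:
            continue
        for ai, s, e in zip(g.index, g["start"].to_numpy(), g["end"].to_numpy()):
            for iv in tree.overlap(int(s), int(e)):
                ov = min(e, iv.end) - max(s, iv.begin)
                if ov >= 1 and ov >= min_frac_of_b * (iv.end - iv.begin):
                    pairs.append((int(ai), int(iv.data), int(ov)))
    out = pd.DataFrame(pairs, columns=["a_index", "b_index", "overlap"])
    return out.sort_values(["a_index", "b_index"], kind="mergesort").reset_index(drop=True)


def closest_tss(regions: RegionSet, tss: TssTable) -> pd.DataFrame:
    """Nearest TSS to each region *start*, upstream or downstream.

    Distance is signed: ``tss_position - region.start`` (negative when the TSS
    lies left of the region start). Ties on absolute distance break toward the
    smaller coordinate, then the lexicographically smaller gene_id. Regions on
    chromosomes without any TSS get gene_id None and distance NaN.

    Returns a DataFrame indexed like ``regions.df`` with columns ``gene_id``
    and ``distance``.
    """
    gene = np.full(len(regions), None, dtype=object)
    dist = np.full(len(regions), np.nan)
    by_chrom = {c: g for c, g in tss.df.groupby("chrom", sort=False)}
    for chrom, g in regions.df.groupby("chrom", sort=False):
        t = by_chrom.get(chrom)
        if t is None or not len(t):
            continue
        # one representative per position: the lexicographically smallest gene
        t2 = t.sort_values(["tss", "gene_id"], kind="mergesort").drop_duplicates("tss")
        pos = t2["tss"].to_numpy(np.int64)
        genes = t2["gene_id"].to_numpy(object)
        starts = g["start"].to_numpy(np.int64)
        j = np.searchsorted(pos, starts)
        left = np.clip(j - 1, 0, len(pos) - 1)
        right = np.clip(j, 0, len(pos) - 1)
        dl = np.abs(starts - pos[left])
        dr = np.abs(starts - pos[right])
        # tie (dl == dr) -> smaller coordinate, i.e. the left candidate
        use_left = dl <= dr
        best = np.where(use_left, left, right)
        gene[g.index.to_numpy()] = genes[best]
        dist[g.index.to_numpy()] = pos[best] - starts
    return pd.DataFrame({"gene_id": gene, "distance": dist})


def point_to_region_distance(point: int, region: GenomicInterval, chrom: str | None = None) -> int:
    """Distance from a 0-based point to a region: 0 when contained, else
    distance to the nearest *included* base (``start`` or ``end - 1``)."""
    if chrom is not None and chrom != region.chrom:
        raise ValidationError(
            f"point on {chrom} but region on {region.chrom}: distance undefined"
        )
    if region.start <= point < region.end:
        return 0
    return int(min(abs(point - region.start), abs(point - (region.end - 1))))


def points_to_regions_distance(points: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Vectorized broadcast form of :func:`point_to_region_distance`.

    ``points`` shape (n,), ``starts``/``ends`` shape (m,) -> (n, m) distances.
    """
    p = np.asarray(points)[:, None]
    s = np.asarray(starts)[None, :]
    e = np.asarray(ends)[None, :]
    d = np.minimum(np.abs(p - s), np.abs(p - (e - 1)))
    inside = (s <= p) & (p < e)
    return np.where(inside, 0, d)
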