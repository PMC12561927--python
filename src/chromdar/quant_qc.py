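"""Quantification and quality control.

Fragments (paired-end read pairs collapsed to a single interval) are the
counting unit. A fragment increments every consensus region it overlaps by at
least 1 bp; because consensus regions are merged and therefore disjoint, a
fragment is counted once per region it touches, and once in total in the FRiP
numerator regardless of how many regions it spans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .intervals import RegionSet, TssTable, overlaps_any


@dataclass
class CountExperiment:
    """Region x sample integer counts plus sample metadata."""

    regions: RegionSet
    counts: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.regions), len(self.samples)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.regions)} regions x {len(self.samples)} samples"
            )
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def lib_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subset_regions(self, keep: np.ndarray) -> "CountExperiment":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountExperiment(
            regions=self.regions.subset(keep),
            counts=self.counts[keep],
            samples=self.samples.copy(),
        )


def count_fragments(
    fragments: Mapping[str, RegionSet],
    regions: RegionSet,
    meta: pd.DataFrame,
) -> CountExperiment:
    """Count per-sample fragments in a merged region set.

    ``fragments`` maps sample_id -> fragment RegionSet. Records per sample the
    total fragment count and the number of fragments overlapping >= 1 region
    (the FRiP numerator) in the returned metadata.
    """
    if not regions.is_disjoint():
        raise ValidationError("count_fragments requires merged (disjoint) regions")
    missing = [s for s in meta["sample_id"] if s not in fragments]
    if missing:
        raise ValidationError(f"fragment sets missing for samples: {missing}")
    R = len(regions)
    counts = np.zeros((R, len(meta)), dtype=np.int64)
    n_frag, n_in = [], []
    for j, sample_id in enumerate(meta["sample_id"]):
        frag = fragments[sample_id]
        in_any = np.zeros(len(frag), dtype=bool)
        for chrom, g in frag.df.groupby("chrom", sort=False):
            rs, re_, ridx = regions._arrays(chrom)
            if not len(rs):
                continue
            qs = g["start"].to_numpy(np.int64)
            qe = g["end"].to_numpy(np.int64)
            lo = np.searchsorted(re_, qs, side="right")
            hi = np.searchsorted(rs, qe, side="left")
            hits = hi > lo
            for l, h in zip(lo[hits], hi[hits]):
                counts[ridx[l:h], j] += 1
            in_any[np.asarray(g.index, dtype=int)] = hits
        n_frag.append(len(frag))
        n_in.append(int(in_any.sum()))
    samples = meta.copy()
    samples["n_fragments"] = n_frag
    samples["n_fragments_in_regions"] = n_in
    return CountExperiment(regions=regions, counts=counts, samples=samples)


def frip(experiment: CountExperiment, floor: float = 0.2) -> pd.DataFrame:
    """Fraction of fragments in regions per sample, with a quality flag.

    A fragment spanning several regions counts once in the numerator. Samples
    below ``floor`` are flagged (a warning-level metric, not a hard filter).
    """
    cols = ("n_fragments", "n_fragments_in_regions")
    if any(c not in experiment.samples.columns for c in cols):
        raise ValidationError(
            "FRiP requires an experiment built by count_fragments "
            "(per-sample fragment totals are not stored in a count matrix)"
        )
    n = experiment.samples["n_fragments"].to_numpy(float)
    if (n <= 0).any():
        raise ValidationError("FRiP undefined for samples with zero fragments")
    value = experiment.samples["n_fragments_in_regions"].to_numpy(float) / n
    return pd.DataFrame({
        "sample_id": experiment.samples["sample_id"],
        "frip": value,
        "below_floor": value < floor,
    })


def log2_cpm(experiment: CountExperiment, prior: float = 0.5,
             lib_sizes: np.ndarray | None = None) -> np.ndarray:
    """log2 counts-per-million with a prior count.

    ``log2((count + prior) / (lib_size + 2 * prior) * 1e6)``. With prior 0 the
    anti-logged columns sum to 1e6 exactly.
    """
    libs = experiment.lib_sizes.astype(float) if lib_sizes is None else np.asarray(lib_sizes, float)
    if (libs <= 0).any():
        raise ValidationError("library sizes must be positive")
    return np.log2((experiment.counts + prior) / (libs + 2.0 * prior) * 1e6)


def filter_low_accessibility(
    experiment: CountExperiment,
    drop_chroms: Sequence[str] = ("chrY",),
    prior: float = 0.5,
) -> tuple[CountExperiment, dict]:
    """Drop regions with mean log2-cpm < 0 (strict) or on excluded chromosomes.

    Returns the filtered experiment and a report of how many regions each rule
    removed (a region failing both rules is attributed to both counters).
    """
    mean_lcpm = log2_cpm(experiment, prior=prior).mean(axis=1)
    low = mean_lcpm < 0.0
    on_drop = experiment.regions.df["chrom"].isin(set(drop_chroms)).to_numpy()
    keep = ~(low | on_drop)
    report = {
        "n_input": experiment.n_regions,
        "n_low_accessibility": int(low.sum()),
        "n_dropped_chrom": int(on_drop.sum()),
        "n_kept": int(keep.sum()),
    }
    return experiment.subset_regions(keep), report


def tss_enrichment(
    fragments: RegionSet,
    tss: TssTable,
    flank: int = 1000,
    window: int = 100,
) -> float:
    """TSS enrichment score for one sample.

    Aggregate per-base fragment depth is accumulated over ``[tss - flank,
    tss + flank)`` across all TSS, flipped for minus-strand TSS so downstream
    is consistent. The profile is partitioned into ``2 * flank / window``
    windows; each window's score is its mean depth divided by the mean depth of
    the two terminal windows, and the score is the maximum over windows.
    """
    if flank % window != 0:
        raise ValidationError("flank must be divisible by window")
    if not len(tss):
        raise ValidationError("TSS table is empty")
    width = 2 * flank
    depth = np.zeros(width, dtype=np.float64)
    by_chrom = {c: g for c, g in fragments.df.groupby("chrom", sort=False)}
    for row in tss.df.itertuples(index=False):
        g = by_chrom.get(row.chrom)
        if g is None:
            continue
        lo, hi = row.tss - flank, row.tss + flank
        fs = g["start"].to_numpy(np.int64)
        fe = g["end"].to_numpy(np.int64)
        sel = (fs < hi) & (fe > lo)
        if not sel.any():
            continue
        diff = np.zeros(width + 1)
        a = np.clip(fs[sel] - lo, 0, width)
        b = np.clip(fe[sel] - lo, 0, width)
        np.add.at(diff, a, 1.0)
        np.add.at(diff, b, -1.0)
        local = np.cumsum(diff[:-1])
        if row.strand == "-":
            local = local[::-1]
        depth += local
    means = depth.reshape(-1, window).mean(axis=1)
    background = 0.5 * (means[0] + means[-1])
    if background <= 0:
        raise ValidationError("zero flank depth: TSS enrichment undefined")
    return float(np.max(means / background))


def sample_correlation(log2cpm: np.ndarray, sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Pearson correlation across all pairs of samples (columns)."""
    x = np.asarray(log2cpm, float)
    if x.shape[0] < 2:
        raise ValidationError("need >= 2 regions for sample correlation")
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr[np.ix_(sd == 0, np.arange(x.shape[1]))] = np.nan
    corr[np.ix_(np.arange(x.shape[1]), sd == 0)] = np.nan
    np.fill_diagonal(corr, 1.0)
    ids = list(sample_ids) if sample_ids is not None else list(range(x.shape[1]))
    return pd.DataFrame(corr, index=ids, columns=ids)


def pca_factor_association(
    log2cpm: np.ndarray,
    meta: pd.DataFrame,
    n_pcs: int = 5,
    factors: Sequence[str] = ("treatment", "individual", "time"),
) -> pd.DataFrame:
    """PCA on region-centered log2-cpm plus per-(PC, factor) one-way F-tests.

    Returns one row per (PC, factor) with the PC's variance explained, the
    one-way model's R-squared, F statistic and p-value.
    """
    from scipy import stats

    x = np.asarray(log2cpm, float)
    centered = x - x.mean(axis=1, keepdims=True)
    if np.allclose(centered, 0):
        raise ValidationError("constant matrix: PCA undefined")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = vt.T * s  # samples x components
    var_explained = s**2 / np.sum(s**2)
    n_pcs = min(n_pcs, scores.shape[1])
    rows = []
    n = scores.shape[0]
    for pc in range(n_pcs):
        y = scores[:, pc]
        for factor in factors:
            if factor not in meta.columns:
                continue
            labels = meta[factor].astype(str).to_numpy()
            levels = pd.unique(labels)
            k = len(levels)
            if k < 2 or n <= k:
                continue
            grand = y.mean()
            ss_tot = np.sum((y - grand) ** 2)
            ss_between = sum(
                (labels == lv).sum() * (y[labels == lv].mean() - grand) ** 2
                for lv in levels
            )
            ss_within = ss_tot - ss_between
            df1, df2 = k - 1, n - k
            if ss_tot <= 0:
                continue
            r2 = ss_between / ss_tot
            if ss_within <= 0:
                f, p = np.inf, 0.0
            else:
                f = (ss_between / df1) / (ss_within / df2)
                p = float(stats.f.sf(f, df1, df2))
            rows.append({
                "pc": pc + 1, "factor": factor,
                "variance_explained": float(var_explained[pc]),
                "r2": float(r2), "f": float(f), "p": p,
            })
    return pd.DataFrame(rows)
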