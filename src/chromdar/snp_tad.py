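"""GWAS SNP integration.

SNPs are 0-based points; a SNP overlaps a region iff ``start <= pos < end``.
SNP-to-region distance comparisons are scoped to topologically associating
domains (TADs): every (SNP, region) pair sharing at least one TAD contributes
one distance, DAR-pair and CAR-pair distance pools are compared by a two-sided
Wilcoxon rank-sum test (exact enumeration when both pools have <= 8 members
and no ties, normal approximation with tie and continuity corrections
otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .intervals import RegionSet, overlap_join, points_to_regions_distance
from .io import SNPRecord
from .enrichment import EnrichmentResult, enrichment_from_counts


@dataclass
class TadSet:
    """Topologically associating domains; nesting/overlap is permitted."""

    regions: RegionSet

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class DistanceComparison:
    dar_distances: np.ndarray
    car_distances: np.ndarray
    statistic: float   # rank-sum W of the DAR pool
    p: float
    method: str


def _snps_frame(snps: list[SNPRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.rsid, s.chrom, s.pos0, s.trait) for s in snps],
        columns=["rsid", "chrom", "pos0", "trait"],
    )


def _snp_regionset(snps: list[SNPRecord]) -> RegionSet:
    df = _snps_frame(snps)
    df["start"] = df["pos0"]
    df["end"] = df["pos0"] + 1
    return RegionSet(df[["chrom", "start", "end", "rsid", "trait"]])


def snp_region_overlap(snps: list[SNPRecord], regions: RegionSet) -> pd.DataFrame:
    """(snp, region) pairs where the SNP position falls inside a region.

    Columns: rsid, trait, chrom, pos0, region_index, region_id. Against a
    merged region set each SNP hits at most one region.
    """
    rows = []
    ids = regions.region_ids.to_numpy()
    by_chrom: dict[str, list[SNPRecord]] = {}
    for s in snps:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, chrom_snps in by_chrom.items():
        tree = regions._tree(chrom)
        if not tree:
            continue
        for s in chrom_snps:
            for iv in tree.overlap(s.pos0, s.pos0 + 1):
                rows.append((s.rsid, s.trait, s.chrom, s.pos0,
                             int(iv.data), ids[int(iv.data)]))
    return pd.DataFrame(
        rows, columns=["rsid", "trait", "chrom", "pos0", "region_index", "region_id"]
    ).sort_values(["trait", "rsid", "region_index"], kind="mergesort").reset_index(drop=True)


def snp_enrichment(
    dar: RegionSet,
    car: RegionSet,
    snps: list[SNPRecord],
    fisher_switch: int = 10,
    contrast: tuple = (),
) -> dict[str, EnrichmentResult]:
    """Per-trait DAR-vs-CAR enrichment of SNP-overlapping regions.

    A region is a hit when it contains >= 1 SNP of the trait. Traits with zero
    SNPs are skipped.
    """
    if not len(dar) or not len(car):
        raise ValidationError("SNP enrichment needs non-empty DAR and CAR sets")
    results: dict[str, EnrichmentResult] = {}
    df = _snps_frame(snps)
    for trait, g in df.groupby("trait", sort=True):
        if not len(g):
            continue
        trait_snps = [SNPRecord(r.rsid, r.chrom, int(r.pos0), trait)
                      for r in g.itertuples(index=False)]
        a = len(set(snp_region_overlap(trait_snps, dar)["region_index"]))
        c = len(set(snp_region_overlap(trait_snps, car)["region_index"]))
        results[trait] = enrichment_from_counts(
            a, len(dar) - a, c, len(car) - c,
            track=f"SNP_{trait}", category_group="snp",
            fisher_switch=fisher_switch, contrast=contrast,
        )
    return results


def assign_to_tads(items: RegionSet | list[SNPRecord], tads: TadSet) -> pd.DataFrame:
    """Item -> TAD assignments.

    SNPs map to every TAD containing their position; regions map to every TAD
    they overlap by >= 1 bp. Items with no containing TAD are absent from the
    result (flagged unassigned by omission). Columns: item_index, tad_index.
    """
    if isinstance(items, RegionSet):
        item_set = items
    else:
        item_set = _snp_regionset(items)
    pairs = overlap_join(item_set, tads.regions, min_frac_of_b=0.0)
    return pairs.rename(columns={"a_index": "item_index", "b_index": "tad_index"})[
        ["item_index", "tad_index"]
    ]


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum test of x vs y.

    Exact enumeration when both samples have <= 8 members and the pooled data
    are tie-free; otherwise the normal approximation with tie correction and
    continuity correction. Returns (W, p, method) where W is the rank-sum
    statistic of x: U1 + n1*(n1+1)/2.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(x) <= 8 and len(y) <= 8 and no_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        method = "normal-approximation"
    w = float(res.statistic) + len(x) * (len(x) + 1) / 2.0
    return w, float(res.pvalue), method


def tad_distance_test(
    snps: list[SNPRecord],
    regions: RegionSet,
    labels: np.ndarray,
    tads: TadSet,
) -> DistanceComparison:
    """Wilcoxon comparison of SNP-to-DAR vs SNP-to-CAR distances within TADs.

    ``labels`` is a per-region array of "DAR"/"CAR". Each (SNP, region) pair
    sharing >= 1 TAD contributes one distance (pairs duplicated across nested
    TADs are de-duplicated).
    """
    labels = np.asarray(labels)
    if len(labels) != len(regions):
        raise ValidationError("labels must align with regions")
    snp_points = _snp_regionset(snps)  # sorted; item indices refer to this set
    snp_tads = assign_to_tads(snp_points, tads)
    region_tads = assign_to_tads(regions, tads)
    if not len(snp_tads) or not len(region_tads):
        raise ValidationError("no SNP-containing TAD with assigned regions")
    pairs = snp_tads.merge(region_tads, on="tad_index", suffixes=("_snp", "_region"))
    pairs = pairs.drop_duplicates(["item_index_snp", "item_index_region"])
    if not len(pairs):
        raise ValidationError("no (SNP, region) pairs share a TAD")
    snp_pos = snp_points.df["start"].to_numpy()
    starts = regions.df["start"].to_numpy()
    ends = regions.df["end"].to_numpy()
    si = pairs["item_index_snp"].to_numpy()
    ri = pairs["item_index_region"].to_numpy()
    d = np.minimum(np.abs(snp_pos[si] - starts[ri]),
                   np.abs(snp_pos[si] - (ends[ri] - 1)))
    inside = (starts[ri] <= snp_pos[si]) & (snp_pos[si] < ends[ri])
    d = np.where(inside, 0, d)
    is_dar = labels[ri] == "DAR"
    dar_d = d[is_dar]
    car_d = d[~is_dar]
    if len(dar_d) == 0 or len(car_d) == 0:
        raise ValidationError("one of the DAR/CAR distance pools is empty")
    w, p, method = rank_sum_test(dar_d, car_d)
    return DistanceComparison(dar_distances=dar_d, car_distances=car_d,
                              statistic=w, p=p, method=method)


def effectsize_comparison(
    log2fc: pd.DataFrame,
    reference: str = "TRZ",
) -> pd.DataFrame:
    """Absolute drug effect sizes at SNP-overlapping regions vs a reference drug.

    ``log2fc`` has one row per region and one column per treatment (same region
    universe throughout). Each non-reference column is compared to the
    reference by a two-sided Wilcoxon rank-sum test on |log2FC|.
    """
    if reference not in log2fc.columns:
        raise ValidationError(f"reference treatment {reference!r} missing")
    ref = np.abs(log2fc[reference].to_numpy(float))
    rows = []
    for col in log2fc.columns:
        if col == reference:
            continue
        x = np.abs(log2fc[col].to_numpy(float))
        w, p, method = rank_sum_test(x, ref)
        rows.append({"treatment": col, "reference": reference, "n": len(x),
                     "median_abs_log2fc": float(np.median(x)),
                     "reference_median": float(np.median(ref)),
                     "w": w, "p": p, "method": method})
    return pd.DataFrame(rows)


def permutation_overlap_test(
    query: RegionSet,
    reference: RegionSet,
    chrom_sizes: dict[str, int],
    b: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[int, np.ndarray, float]:
    """Permutation test of region-set overlap.

    Statistic: number of query regions overlapping >= 1 reference region. Each
    permutation re-places every query region uniformly at random on its own
    chromosome, preserving its length (placed regions may overlap each other).
    p = (1 + #{permutation >= observed}) / (b + 1).
    """
    if b < 1:
        raise ValidationError("need >= 1 permutation")
    missing = [c for c in query.chroms if c not in chrom_sizes]
    if missing:
        raise ValidationError(f"chrom_sizes missing query chromosomes: {missing}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    from .intervals import merge_regions, overlaps_any

    ref = merge_regions(reference)
    observed = int(overlaps_any(query, ref).sum())
    perm = np.zeros(b, dtype=np.int64)
    for chrom, g in query.df.groupby("chrom", sort=True):
        size = chrom_sizes[chrom]
        lengths = (g["end"] - g["start"]).to_numpy(np.int64)
        if (lengths > size).any():
            raise ValidationError(f"query region longer than chromosome {chrom}")
        rs, re_, _ = ref._arrays(chrom)
        starts = rng.integers(0, size - lengths + 1, size=(b, len(lengths)))
        if not len(rs):
            continue
        ends = starts + lengths
        lo = np.searchsorted(re_, starts, side="right")
        hi = np.searchsorted(rs, ends, side="left")
        perm += (hi > lo).sum(axis=1)
    p = (1.0 + float((perm >= observed).sum())) / (b + 1.0)
    return observed, perm, p
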