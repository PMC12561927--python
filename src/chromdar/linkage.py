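"""Multi-omic linkage.

Regions are paired with genes through the nearest TSS (measured from the
region start) within a window; drug-response effect sizes (the median log2
fold change across the anthracycline-class treatments at a timepoint) are then
correlated across phenotypes (chromatin accessibility, histone-mark
enrichment, gene expression) by Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .intervals import RegionSet, TssTable, closest_tss, overlap_join, overlaps_any


def link_regions_to_genes(
    regions: RegionSet,
    tss: TssTable,
    expressed: set[str] | None,
    window: int,
) -> pd.DataFrame:
    """One nearest-TSS link per region, kept iff |distance| <= window and the
    gene is expressed.

    Columns: region_index, region_id, gene_id, distance (signed bp from region
    start to the TSS), window.
    """
    if window <= 0:
        raise ValidationError("window must be positive")
    nearest = closest_tss(regions, tss)
    ids = regions.region_ids.to_numpy()
    out = pd.DataFrame({
        "region_index": np.arange(len(regions)),
        "region_id": ids,
        "gene_id": nearest["gene_id"],
        "distance": nearest["distance"],
    })
    out = out[out["gene_id"].notna() & (out["distance"].abs() <= window)]
    if expressed is not None:
        out = out[out["gene_id"].isin(expressed)]
    out = out.copy()
    out["window"] = window
    out["distance"] = out["distance"].astype(int)
    return out.reset_index(drop=True)


def region_set_overlap_fraction(a: RegionSet, b: RegionSet) -> tuple[int, float]:
    """(number, fraction) of a-regions overlapping any b-region by >= 1 bp."""
    if not len(a):
        raise ValidationError("empty query set: overlap fraction undefined")
    n = int(overlaps_any(a, b).sum())
    return n, n / len(a)


def best_histone_partner(regions: RegionSet, histone: RegionSet) -> pd.DataFrame:
    """Per region, the histone region with the largest overlap (ties -> lower
    coordinate). Columns: region_index, histone_index, overlap."""
    pairs = overlap_join(regions, histone, min_frac_of_b=0.0)
    if not len(pairs):
        return pd.DataFrame(columns=["region_index", "histone_index", "overlap"])
    starts = histone.df["start"].to_numpy()
    pairs = pairs.assign(b_start=starts[pairs["b_index"]])
    pairs = pairs.sort_values(
        ["a_index", "overlap", "b_start"],
        ascending=[True, False, True], kind="mergesort",
    ).drop_duplicates("a_index")
    return pairs.rename(columns={"a_index": "region_index", "b_index": "histone_index"})[
        ["region_index", "histone_index", "overlap"]
    ].reset_index(drop=True)


def median_response(
    contrast_table: pd.DataFrame,
    time: str,
    treatments: list[str],
) -> pd.Series:
    """Per-region median log2FC over the given treatments at one timepoint.

    ``contrast_table`` is a long table with columns region_id, treatment, time,
    log2fc. Regions missing from any treatment's table are excluded.
    """
    if not treatments:
        raise ValidationError("need >= 1 treatment")
    t = contrast_table[
        (contrast_table["time"].astype(str) == str(time))
        & (contrast_table["treatment"].isin(treatments))
    ]
    wide = t.pivot_table(index="region_id", columns="treatment", values="log2fc")
    wide = wide.dropna()
    missing = [trt for trt in treatments if trt not in wide.columns]
    if missing:
        raise ValidationError(f"no contrast results for treatments {missing} at time {time}")
    return wide[treatments].median(axis=1)


@dataclass
class CorrelationReport:
    phenotypes: tuple[str, str]
    time: str
    rho: float
    p: float
    n: int
    method: str


def cross_phenotype_correlation(
    x: pd.Series | np.ndarray,
    y: pd.Series | np.ndarray,
    phenotypes: tuple[str, str] = ("", ""),
    time: str = "",
    method: str = "spearman",
) -> CorrelationReport:
    """Correlation of paired per-region (or per-pair) drug-response effects.

    Spearman by default (average ranks for ties; exact permutation p for
    n <= 10, large-sample approximation otherwise); Pearson optional.
    """
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        joined = pd.concat([x.rename("x"), y.rename("y")], axis=1, join="inner").dropna()
        xv, yv = joined["x"].to_numpy(float), joined["y"].to_numpy(float)
    else:
        xv, yv = np.asarray(x, float), np.asarray(y, float)
        ok = np.isfinite(xv) & np.isfinite(yv)
        xv, yv = xv[ok], yv[ok]
    n = len(xv)
    if n < 3:
        raise ValidationError("need >= 3 complete pairs")
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        raise ValidationError("constant vector: correlation undefined")
    if method == "pearson":
        rho, p = stats.pearsonr(xv, yv)
    elif method == "spearman":
        rho, p = stats.spearmanr(xv, yv)
        if n <= 10:
            def _stat(a, b):
                return stats.spearmanr(a, b).statistic

            res = stats.permutation_test(
                (xv, yv), _stat, permutation_type="pairings",
                n_resamples=np.inf, alternative="two-sided",
            )
            p = float(res.pvalue)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return CorrelationReport(phenotypes=phenotypes, time=str(time),
                             rho=float(rho), p=float(p), n=n, method=method)
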