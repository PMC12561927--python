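"""DAR-vs-CAR feature enrichment.

Regions are annotated against feature tracks by overlap (>= 1 bp, optionally
also >= a fraction of the feature's length, e.g. 50% for transposable
elements). Enrichment is a 2x2 contingency test of (DAR/CAR) x (hit/miss):
Pearson chi-square (1 df, no continuity correction) unless any cell falls
below the Fisher switch count, in which case Fisher's exact test (two-sided by
summation of tables at most as probable as the observed one) is used.
Bonferroni correction is applied within feature-category groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .intervals import RegionSet, overlap_join


@dataclass
class FeatureTrack:
    """A named annotation track with its Bonferroni family and overlap rule."""

    name: str
    regions: RegionSet
    category_group: str = "features"
    min_frac: float = 0.0


@dataclass
class EnrichmentResult:
    track: str
    category_group: str
    dar_hit: int
    dar_miss: int
    car_hit: int
    car_miss: int
    odds_ratio: float
    test_used: str           # "chi-square" or "fisher"
    p: float
    p_adj: float = np.nan
    direction: str = ""
    degenerate: bool = False
    contrast: tuple = ()

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.dar_hit, self.dar_miss],
                         [self.car_hit, self.car_miss]])


def annotate_hits(regions: RegionSet, track: FeatureTrack) -> np.ndarray:
    """Boolean per region: does any feature interval overlap it by >= 1 bp and
    by >= min_frac of the feature's length?"""
    hits = np.zeros(len(regions), dtype=bool)
    if not len(track.regions):
        return hits
    pairs = overlap_join(regions, track.regions, min_frac_of_b=track.min_frac)
    if len(pairs):
        hits[pairs["a_index"].unique()] = True
    return hits


def _odds_ratio(a: int, b: int, c: int, d: int) -> tuple[float, bool]:
    """(dar_hit*car_miss)/(dar_miss*car_hit); infinite/zero cells flagged."""
    num, den = a * d, b * c
    if den == 0 and num == 0:
        return float("nan"), True
    if den == 0:
        return float("inf"), True
    if num == 0:
        return 0.0, True
    return num / den, False


def contingency_2x2(a: int, b: int, c: int, d: int, fisher_switch: int = 10) -> tuple[str, float]:
    """Chi-square (no continuity correction) with a Fisher switch below
    ``fisher_switch`` in any cell. Degenerate tables (an all-zero margin) give
    p = 1."""
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return "fisher", 1.0
    if table.min() < fisher_switch:
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return "fisher", float(p)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return "chi-square", float(p)


def enrichment_test(
    dar: RegionSet,
    car: RegionSet,
    track: FeatureTrack,
    fisher_switch: int = 10,
    contrast: tuple = (),
) -> EnrichmentResult:
    """2x2 DAR-vs-CAR enrichment of one feature track."""
    if not len(dar) or not len(car):
        raise ValidationError("enrichment test needs non-empty DAR and CAR sets")
    dar_hits = annotate_hits(dar, track)
    car_hits = annotate_hits(car, track)
    a = int(dar_hits.sum())
    b = len(dar) - a
    c = int(car_hits.sum())
    d = len(car) - c
    return enrichment_from_counts(a, b, c, d, track.name, track.category_group,
                                  fisher_switch=fisher_switch, contrast=contrast)


def enrichment_from_counts(
    dar_hit: int, dar_miss: int, car_hit: int, car_miss: int,
    track: str = "", category_group: str = "features",
    fisher_switch: int = 10, contrast: tuple = (),
) -> EnrichmentResult:
    if min(dar_hit, dar_miss, car_hit, car_miss) < 0:
        raise ValidationError("contingency counts must be non-negative")
    odds, degenerate = _odds_ratio(dar_hit, dar_miss, car_hit, car_miss)
    test_used, p = contingency_2x2(dar_hit, dar_miss, car_hit, car_miss, fisher_switch)
    direction = "enriched" if (not np.isnan(odds) and odds > 1) else "depleted"
    return EnrichmentResult(
        track=track, category_group=category_group,
        dar_hit=dar_hit, dar_miss=dar_miss, car_hit=car_hit, car_miss=car_miss,
        odds_ratio=odds, test_used=test_used, p=p,
        direction=direction, degenerate=degenerate, contrast=contrast,
    )


def adjust_across_categories(results: list[EnrichmentResult],
                             alpha: float = 0.05) -> list[EnrichmentResult]:
    """Bonferroni within each (contrast, category_group): p_adj = min(1, p*m)."""
    groups: dict[tuple, list[EnrichmentResult]] = {}
    for r in results:
        groups.setdefault((r.contrast, r.category_group), []).append(r)
    for members in groups.values():
        m = len(members)
        for r in members:
            r.p_adj = min(1.0, r.p * m)
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "treatment": r.contrast[0] if r.contrast else "",
        "time": r.contrast[1] if len(r.contrast) > 1 else "",
        "track": r.track,
        "category_group": r.category_group,
        "dar_hit": r.dar_hit, "dar_miss": r.dar_miss,
        "car_hit": r.car_hit, "car_miss": r.car_miss,
        "odds_ratio": r.odds_ratio, "test_used": r.test_used,
        "p": r.p, "p_adj": r.p_adj, "direction": r.direction,
        "degenerate": r.degenerate,
    } for r in results])


def deg_proximity_enrichment(
    dar_linked: pd.DataFrame,
    car_linked: pd.DataFrame,
    deg_genes: set[str],
    contrast: tuple = (),
    window: int = 0,
) -> EnrichmentResult:
    """Are DARs enriched near differentially expressed genes?

    ``dar_linked``/``car_linked`` are region->gene link tables (one row per
    linked region, column ``gene_id``); the universe is the linked regions.
    Fisher's exact test on (DAR/CAR) x (linked gene is DEG / not).
    """
    if not len(dar_linked) and not len(car_linked):
        raise ValidationError("empty link universe: no regions within the window")
    a = int(dar_linked["gene_id"].isin(deg_genes).sum())
    b = len(dar_linked) - a
    c = int(car_linked["gene_id"].isin(deg_genes).sum())
    d = len(car_linked) - c
    odds, degenerate = _odds_ratio(a, b, c, d)
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        p = 1.0
    else:
        _, p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(
        track=f"DEG_within_{window}bp", category_group="deg_proximity",
        dar_hit=a, dar_miss=b, car_hit=c, car_miss=d,
        odds_ratio=odds, test_used="fisher", p=float(p),
        direction="enriched" if odds > 1 else "depleted",
        degenerate=degenerate, contrast=contrast,
    )
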