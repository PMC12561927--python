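"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates the drug-response ATAC-seq design it is built for:
48 samples (4 individuals x 6 treatments x 2 timepoints), negative-binomial
fragment counts with a per-(region, individual) random effect on the log2
scale, treatment effects shared across the anthracyclines (DOX/EPI/DNR), a
partial response for MTX, and no effect for TRZ or the vehicle. Responsive
regions are preferentially placed on a designated feature track and SNPs are
planted nearer responsive regions, so downstream recovery of enrichment and
distance statistics is a testable property with known ground truth.

Everything is driven by a single integer seed; fixed seed implies bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .enrichment import FeatureTrack
from .intervals import RegionSet, TssTable, closest_tss
from .quant_qc import CountExperiment
from .snp_tad import TadSet
from . import io as cio


@dataclass
class SimulationDesign:
    n_individuals: int = 4
    treatments: tuple[str, ...] = ("DOX", "EPI", "DNR", "MTX", "TRZ", "VEH")
    anthracyclines: tuple[str, ...] = ("DOX", "EPI", "DNR")
    mtx_label: str = "MTX"
    null_treatments: tuple[str, ...] = ("TRZ",)
    vehicle: str = "VEH"
    timepoints: tuple[int, ...] = (3, 24)
    n_regions: int = 2000
    n_decoy_regions: int = 150
    n_blacklist_regions: int = 20
    frac_dar: float = 0.10
    effect_log2fc: float = 1.5
    shared_across_acs: float = 0.9
    mtx_subset: float = 0.5
    individual_sd: float = 0.3
    nb_dispersion: float = 0.1
    lib_size_range: tuple[float, float] = (5e5, 2e6)
    n_chroms: int = 3
    chrom_size: int = 10_000_000
    region_width: tuple[int, int] = (300, 800)
    peak_presence_prob: float = 0.95
    peak_jitter_bp: int = 50
    feature_relative_risk: float = 3.0
    feature_base_rate: float = 0.10
    tad_length: int = 500_000
    tad_gap: int = 50_000
    n_snps_per_trait: dict = field(default_factory=lambda: {
        "ACT": 60, "AF": 100, "HF": 60, "CAD": 100, "IHD": 7,
    })
    snp_near_dar_frac: float = 0.5
    snp_in_region_frac: float = 0.15
    expression_kappa: float = 0.5
    expression_noise_sd: float = 0.5
    histone_kappa: float = 0.7
    histone_noise_sd: float = 0.4
    gene_link_frac: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_dar <= 1.0):
            raise ValidationError("frac_dar must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if self.vehicle not in self.treatments:
            raise ValidationError("treatments must contain the vehicle")

    @property
    def individuals(self) -> list[str]:
        return [chr(ord("A") + i) for i in range(self.n_individuals)]

    @property
    def chroms(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-region effects and feature/gene links."""

    regions: pd.DataFrame        # region_id, planted, true_log2fc, on_feature, linked_gene
    effects: pd.DataFrame        # region_id, treatment, time, beta (nonzero rows only)
    snps: pd.DataFrame           # rsid, trait, planted_near_dar

    def is_dar(self, treatment: str, time) -> np.ndarray:
        e = self.effects
        hit_ids = set(e[(e["treatment"] == treatment)
                        & (e["time"].astype(str) == str(time))]["region_id"])
        return self.regions["region_id"].isin(hit_ids).to_numpy()


@dataclass
class Annotation:
    chrom_sizes: dict[str, int]
    tss: TssTable
    tracks: dict[str, FeatureTrack]
    blacklist: RegionSet
    tads: TadSet
    snps: list[cio.SNPRecord]
    expressed_genes: set[str]
    reference_peaks: RegionSet
    plan: "SimulationPlan"


@dataclass
class SimulationPlan:
    """Deterministic layout shared by annotation and count simulation."""

    regions: RegionSet           # the true accessible regions (n_regions)
    decoys: RegionSet            # low-support peaks, removed by the consensus rule
    blacklisted: RegionSet       # peaks that fall in blacklist intervals
    planted: np.ndarray          # bool per region
    beta: np.ndarray             # n_regions x n_treatments x n_timepoints (log2)
    true_log2fc: np.ndarray      # signed planted magnitude (0 for unplanted)
    on_feature: np.ndarray       # bool per region: overlaps the linked track
    base_abundance: np.ndarray


def _place_regions(design: SimulationDesign, rng: np.random.Generator,
                   n: int, margin: int = 2000) -> pd.DataFrame:
    """Place n non-overlapping regions on an even grid with jitter."""
    per_chrom = np.full(design.n_chroms, n // design.n_chroms)
    per_chrom[: n % design.n_chroms] += 1
    rows = []
    for chrom, m in zip(design.chroms, per_chrom):
        if m == 0:
            continue
        spacing = (design.chrom_size - 2 * margin) // m
        lo_w, hi_w = design.region_width
        if spacing <= hi_w + 2 * design.peak_jitter_bp:
            raise ValidationError("requested region density infeasible")
        anchors = margin + spacing * np.arange(m)
        widths = rng.integers(lo_w, hi_w + 1, size=m)
        jitter = rng.integers(0, spacing - hi_w - 2 * design.peak_jitter_bp, size=m)
        starts = anchors + design.peak_jitter_bp + jitter
        for s, w in zip(starts, widths):
            rows.append((chrom, int(s), int(s + w)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def plan_simulation(design: SimulationDesign) -> SimulationPlan:
    rng = np.random.default_rng(design.seed)
    n_total = design.n_regions + design.n_decoy_regions + design.n_blacklist_regions
    all_df = _place_regions(design, rng, n_total)
    idx = rng.permutation(n_total)
    region_rows = np.sort(idx[: design.n_regions])
    decoy_rows = np.sort(idx[design.n_regions: design.n_regions + design.n_decoy_regions])
    bl_rows = np.sort(idx[design.n_regions + design.n_decoy_regions:])
    regions = RegionSet(all_df.iloc[region_rows], name="true_regions")
    decoys = RegionSet(all_df.iloc[decoy_rows], name="decoys")
    blacklisted = RegionSet(all_df.iloc[bl_rows], name="blacklisted")

    R = len(regions)
    n_planted = int(round(design.frac_dar * R))
    planted_idx = rng.choice(R, size=n_planted, replace=False)
    planted = np.zeros(R, dtype=bool)
    planted[planted_idx] = True

    # feature linkage: planted regions carry the feature at relative risk x base
    p_feat = np.where(
        planted,
        min(1.0, design.feature_relative_risk * design.feature_base_rate),
        design.feature_base_rate,
    )
    on_feature = rng.random(R) < p_feat

    treatments = list(design.treatments)
    timepoints = [str(t) for t in design.timepoints]
    beta = np.zeros((R, len(treatments), len(timepoints)))
    sign = rng.choice([-1.0, 1.0], size=R)
    true_fc = np.where(planted, sign * design.effect_log2fc, 0.0)
    shared = rng.random(R) < design.shared_across_acs
    n_acs = max(1, len(design.anthracyclines))
    solo_ac = rng.integers(0, n_acs, size=R)
    mtx_resp = rng.random(R) < design.mtx_subset
    for r in np.flatnonzero(planted):
        if not design.anthracyclines:
            responders = []
        else:
            responders = (
                list(design.anthracyclines) if shared[r]
                else [design.anthracyclines[solo_ac[r]]]
            )
        if mtx_resp[r] and design.mtx_label in treatments:
            responders.append(design.mtx_label)
        for trt in responders:
            beta[r, treatments.index(trt), :] = true_fc[r]

    base = np.exp(rng.normal(0.0, 1.0, size=R))
    return SimulationPlan(
        regions=regions, decoys=decoys, blacklisted=blacklisted,
        planted=planted, beta=beta, true_log2fc=true_fc,
        on_feature=on_feature, base_abundance=base,
    )


def _interval_track(rng: np.random.Generator, design: SimulationDesign,
                    density: float, width: tuple[int, int]) -> RegionSet:
    """Random background intervals, ~density per 100 kb, per chromosome."""
    rows = []
    for chrom in design.chroms:
        n = rng.poisson(density * design.chrom_size / 1e5)
        if n == 0:
            continue
        starts = np.sort(rng.integers(0, design.chrom_size - width[1], size=n))
        widths = rng.integers(width[0], width[1] + 1, size=n)
        for s, w in zip(starts, widths):
            rows.append((chrom, int(s), int(s + w)))
    if not rows:
        return RegionSet()
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def simulate_annotation(design: SimulationDesign) -> Annotation:
    """Genome layout, TSS, feature tracks, TADs, SNPs and the blacklist."""
    plan = plan_simulation(design)
    rng = np.random.default_rng(np.random.SeedSequence((design.seed, 1)))
    chrom_sizes = {c: design.chrom_size for c in design.chroms}
    regions_df = plan.regions.df

    # --- TSS: a fraction of regions get a gene TSS near their start ---------
    rows = []
    gene_no = 0
    linked = rng.random(len(regions_df)) < design.gene_link_frac
    for i, row in enumerate(regions_df.itertuples(index=False)):
        if linked[i]:
            offset = int(rng.integers(-1500, 1501))
            pos = max(0, row.start + offset)
            rows.append((f"G{gene_no:05d}", row.chrom, pos,
                         "+" if rng.random() < 0.5 else "-"))
            gene_no += 1
    n_background = max(10, len(regions_df) // 4)
    for _ in range(n_background):
        chrom = design.chroms[int(rng.integers(0, design.n_chroms))]
        rows.append((f"G{gene_no:05d}", chrom, int(rng.integers(0, design.chrom_size)),
                     "+" if rng.random() < 0.5 else "-"))
        gene_no += 1
    tss = TssTable(pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"]))
    expressed = {g for g in tss.df["gene_id"]}

    # --- feature tracks -----------------------------------------------------
    tracks: dict[str, FeatureTrack] = {}

    def _on_region_track(mask: np.ndarray, pad: int) -> RegionSet:
        sub = regions_df.loc[mask, ["chrom", "start", "end"]].copy()
        sub["start"] = np.maximum(0, sub["start"] - pad)
        sub["end"] = sub["end"] + pad
        return RegionSet(sub)

    # linked track: intervals sitting on (mostly planted) regions
    tracks["TOP2B"] = FeatureTrack("TOP2B", _on_region_track(plan.on_feature, 0),
                                   category_group="top2b")
    te_classes = ["SINE", "LINE", "LTR", "DNA", "SVA"]
    te_frames = []
    for name, dens in zip(te_classes, (4.0, 3.0, 2.0, 1.5, 0.3)):
        t = _interval_track(rng, design, dens, (150, 400))
        tracks[name] = FeatureTrack(name, t, category_group="te_classes")
        if len(t):
            te_frames.append(t.df[["chrom", "start", "end"]])
    tracks["TE"] = FeatureTrack(
        "TE", RegionSet(pd.concat(te_frames, ignore_index=True)) if te_frames else RegionSet(),
        category_group="te_classes",
    )
    tracks["CpG"] = FeatureTrack(
        "CpG", _interval_track(rng, design, 1.0, (200, 600)), category_group="other_features")
    tss_points = tss.df.copy()
    tss_points["start"] = np.maximum(0, tss_points["tss"] - 1)
    tss_points["end"] = tss_points["tss"] + 1
    tracks["TSS"] = FeatureTrack(
        "TSS", RegionSet(tss_points[["chrom", "start", "end"]]),
        category_group="other_features")
    for name, dens in (("PLS", 0.6), ("pELS", 1.2), ("dELS", 1.8), ("CTCF", 0.8)):
        tracks[name] = FeatureTrack(
            name, _interval_track(rng, design, dens, (150, 350)), category_group="cre")

    # --- blacklist: intervals covering the designated blacklisted peaks -----
    bl = plan.blacklisted.df.copy()
    bl["start"] = np.maximum(0, bl["start"] - 100)
    bl["end"] = bl["end"] + 100
    blacklist = RegionSet(bl[["chrom", "start", "end"]])

    # --- TADs tile each chromosome with gaps --------------------------------
    rows = []
    step = design.tad_length + design.tad_gap
    for chrom in design.chroms:
        for s in range(0, design.chrom_size - design.tad_length + 1, step):
            rows.append((chrom, s, s + design.tad_length))
    tads = TadSet(RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end"])))

    # --- SNPs ----------------------------------------------------------------
    snps: list[cio.SNPRecord] = []
    planted_rows = regions_df.loc[plan.planted]
    unplanted_rows = regions_df.loc[~plan.planted]
    counter = 0
    for trait, n in sorted(design.n_snps_per_trait.items()):
        for _ in range(n):
            near_dar = bool(rng.random() < design.snp_near_dar_frac) and len(planted_rows)
            pool = planted_rows if near_dar else unplanted_rows
            row = pool.iloc[int(rng.integers(0, len(pool)))]
            if rng.random() < design.snp_in_region_frac:
                pos0 = int(rng.integers(row["start"], row["end"]))
            else:
                offset = (int(rng.integers(200, 3000)) if near_dar
                          else int(rng.integers(5000, 40000)))
                pos0 = max(0, int(row["start"]) - offset)
            snps.append(cio.SNPRecord(rsid=f"rs{counter:06d}", chrom=row["chrom"],
                                      pos0=pos0, trait=trait))
            counter += 1

    # --- an external reference peak set (heart-tissue-like) -----------------
    take = rng.random(len(regions_df)) < 0.5
    ref = regions_df.loc[take, ["chrom", "start", "end"]].copy()
    shift = rng.integers(-100, 101, size=len(ref))
    ref["start"] = np.maximum(0, ref["start"] + shift)
    ref["end"] = ref["end"] + shift
    extra = _interval_track(rng, design, 1.0, (300, 800))
    ref_set = RegionSet(pd.concat([ref, extra.df[["chrom", "start", "end"]]],
                                  ignore_index=True) if len(extra) else ref)

    return Annotation(
        chrom_sizes=chrom_sizes, tss=tss, tracks=tracks, blacklist=blacklist,
        tads=tads, snps=snps, expressed_genes=expressed,
        reference_peaks=ref_set, plan=plan,
    )


def sample_metadata(design: SimulationDesign) -> pd.DataFrame:
    rows = []
    for ind in design.individuals:
        for trt in design.treatments:
            for tm in design.timepoints:
                rows.append({
                    "sample_id": f"{ind}_{trt}_{tm}h",
                    "individual": ind,
                    "treatment": trt,
                    "time": str(tm),
                })
    return pd.DataFrame(rows)


def simulate_counts(
    design: SimulationDesign,
    annotation: Annotation,
) -> tuple[CountExperiment, dict[str, RegionSet], SyntheticTruth]:
    """Negative-binomial counts, per-sample peak sets and the truth table.

    count ~ NB(mean = lib_s * q_r * 2^(b_{r,ind} + beta_{r,trt,time}),
    dispersion = nb_dispersion) with b ~ Normal(0, individual_sd) per
    (region, individual).
    """
    plan = annotation.plan
    rng = np.random.default_rng(np.random.SeedSequence((design.seed, 2)))
    meta = sample_metadata(design)
    R, S = len(plan.regions), len(meta)
    treatments = list(design.treatments)
    timepoints = [str(t) for t in design.timepoints]

    libs = rng.uniform(*design.lib_size_range, size=S)
    q = plan.base_abundance / plan.base_abundance.sum()
    b = rng.normal(0.0, design.individual_sd, size=(R, design.n_individuals))
    ind_index = {ind: i for i, ind in enumerate(design.individuals)}

    mu = np.empty((R, S))
    for j, row in enumerate(meta.itertuples(index=False)):
        ti = treatments.index(row.treatment)
        pi = timepoints.index(row.time)
        log2_eff = b[:, ind_index[row.individual]] + plan.beta[:, ti, pi]
        mu[:, j] = libs[j] * q * np.exp2(log2_eff)
    n_nb = 1.0 / design.nb_dispersion
    counts = rng.negative_binomial(n_nb, n_nb / (n_nb + mu))

    # per-sample peak sets: true regions (mostly present), decoys (rare),
    # blacklisted peaks (always present), with jittered edges
    peaks: dict[str, RegionSet] = {}
    decoy_presence = np.zeros((len(plan.decoys), S), dtype=bool)
    for d in range(len(plan.decoys)):
        k = int(rng.integers(1, 5))  # below the default consensus threshold
        decoy_presence[d, rng.choice(S, size=k, replace=False)] = True
    for j, sample_id in enumerate(meta["sample_id"]):
        present = rng.random(R) < design.peak_presence_prob
        frames = []
        for source, mask in (
            (plan.regions.df, present),
            (plan.decoys.df, decoy_presence[:, j]),
            (plan.blacklisted.df, np.ones(len(plan.blacklisted), dtype=bool)),
        ):
            sub = source.loc[np.asarray(mask)] if len(source) else source
            if not len(sub):
                continue
            jit_s = rng.integers(-design.peak_jitter_bp, design.peak_jitter_bp + 1,
                                 size=len(sub))
            jit_e = rng.integers(-design.peak_jitter_bp, design.peak_jitter_bp + 1,
                                 size=len(sub))
            f = sub[["chrom", "start", "end"]].copy()
            f["start"] = np.maximum(0, f["start"] + jit_s)
            f["end"] = np.maximum(f["start"] + 50, f["end"] + jit_e)
            frames.append(f)
        peaks[sample_id] = RegionSet(pd.concat(frames, ignore_index=True),
                                     name=sample_id)

    gene_link = closest_tss(plan.regions, annotation.tss)
    linked_gene = np.where(
        np.abs(gene_link["distance"].to_numpy()) <= 2000,
        gene_link["gene_id"].to_numpy(object), None,
    )
    ids = plan.regions.region_ids.to_numpy()
    region_truth = pd.DataFrame({
        "region_id": ids,
        "planted": plan.planted,
        "true_log2fc": plan.true_log2fc,
        "on_feature": plan.on_feature,
        "linked_gene": linked_gene,
    })
    eff_rows = []
    for r, ti, pi in zip(*np.nonzero(plan.beta)):
        eff_rows.append({
            "region_id": ids[r], "treatment": treatments[ti],
            "time": timepoints[pi], "beta": plan.beta[r, ti, pi],
        })
    effects = pd.DataFrame(eff_rows, columns=["region_id", "treatment", "time", "beta"])
    snp_truth = pd.DataFrame({
        "rsid": [s.rsid for s in annotation.snps],
        "trait": [s.trait for s in annotation.snps],
    })
    truth = SyntheticTruth(regions=region_truth, effects=effects, snps=snp_truth)
    experiment = CountExperiment(regions=plan.regions, counts=counts, samples=meta)
    return experiment, peaks, truth


def simulate_fragments(
    design: SimulationDesign,
    experiment: CountExperiment,
    n_fragments: int = 3000,
    background_frac: float = 0.2,
    seed_stream: int = 3,
) -> dict[str, RegionSet]:
    """Down-sampled per-sample fragment intervals consistent with the counts.

    Fragments inside regions are drawn proportionally to that sample's counts;
    a background fraction lands uniformly on the genome. Intended for the
    FRiP/TSSE QC path, not for re-deriving the count matrix.
    """
    rng = np.random.default_rng(np.random.SeedSequence((design.seed, seed_stream)))
    regions = experiment.regions.df
    out = {}
    chrom_size = design.chrom_size
    for j, sample_id in enumerate(experiment.samples["sample_id"]):
        w = experiment.counts[:, j].astype(float)
        w = w / w.sum() if w.sum() > 0 else np.full(len(w), 1.0 / len(w))
        n_in = int(n_fragments * (1 - background_frac))
        picks = rng.choice(len(regions), size=n_in, p=w)
        starts = regions["start"].to_numpy()[picks]
        ends = regions["end"].to_numpy()[picks]
        frag_len = rng.integers(80, 301, size=n_in)
        centers = rng.integers(starts, ends)
        fs = np.maximum(0, centers - frag_len // 2)
        rows = pd.DataFrame({
            "chrom": regions["chrom"].to_numpy()[picks],
            "start": fs,
            "end": fs + frag_len,
        })
        n_bg = n_fragments - n_in
        bg_chrom = rng.choice(design.chroms, size=n_bg)
        bg_len = rng.integers(80, 301, size=n_bg)
        bg_start = rng.integers(0, chrom_size - 301, size=n_bg)
        bg = pd.DataFrame({"chrom": bg_chrom, "start": bg_start,
                           "end": bg_start + bg_len})
        out[sample_id] = RegionSet(pd.concat([rows, bg], ignore_index=True),
                                   name=sample_id)
    return out


def simulate_expression(
    design: SimulationDesign,
    annotation: Annotation,
    truth: SyntheticTruth,
) -> pd.DataFrame:
    """Per-(gene, treatment, time) expression response coupled to planted regions.

    Genes linked to a planted region responding to (treatment, time) get
    log2FC = kappa * beta + noise; all other genes noise only. DEG flag:
    |log2FC| above twice the noise SD.
    """
    rng = np.random.default_rng(np.random.SeedSequence((design.seed, 4)))
    genes = sorted(annotation.expressed_genes)
    gene_effect: dict[tuple[str, str, str], float] = {}
    linked = truth.regions.dropna(subset=["linked_gene"])
    merged = linked.merge(truth.effects, on="region_id", how="inner")
    for row in merged.itertuples(index=False):
        key = (row.linked_gene, row.treatment, str(row.time))
        gene_effect[key] = design.expression_kappa * row.beta
    rows = []
    contrast_treatments = [t for t in design.treatments if t != design.vehicle]
    for trt in contrast_treatments:
        for tm in design.timepoints:
            noise = rng.normal(0.0, design.expression_noise_sd, size=len(genes))
            for g, eps in zip(genes, noise):
                fc = gene_effect.get((g, trt, str(tm)), 0.0) + eps
                rows.append({
                    "gene_id": g, "treatment": trt, "time": str(tm),
                    "log2fc": fc,
                    "is_deg": bool(abs(fc) > 2.0 * design.expression_noise_sd),
                })
    return pd.DataFrame(rows)


def simulate_histone_response(
    design: SimulationDesign,
    annotation: Annotation,
    truth: SyntheticTruth,
) -> tuple[RegionSet, pd.DataFrame]:
    """Histone-mark regions (a subset of accessible regions, padded) and their
    per-(region, treatment, time) response coupled to the planted effects."""
    rng = np.random.default_rng(np.random.SeedSequence((design.seed, 5)))
    regions = annotation.plan.regions
    take = rng.random(len(regions)) < 0.3
    sub = regions.df.loc[take, ["chrom", "start", "end"]].copy()
    pad = rng.integers(0, 200, size=len(sub))
    sub["start"] = np.maximum(0, sub["start"] - pad)
    sub["end"] = sub["end"] + pad
    # a few histone-only regions so the overlap fraction is high but < 1
    n_extra = max(1, len(sub) // 50)
    extra = pd.DataFrame({
        "chrom": rng.choice(design.chroms, size=n_extra),
        "start": rng.integers(0, design.chrom_size - 2000, size=n_extra),
    })
    extra["end"] = extra["start"] + rng.integers(300, 1200, size=n_extra)
    histone_regions = RegionSet(pd.concat([sub, extra], ignore_index=True),
                                name="h3k27ac")
    ids = regions.region_ids.to_numpy()[take]
    beta = annotation.plan.beta[take]
    treatments = list(design.treatments)
    rows = []
    for trt in [t for t in design.treatments if t != design.vehicle]:
        ti = treatments.index(trt)
        for pi, tm in enumerate(design.timepoints):
            noise = rng.normal(0.0, design.histone_noise_sd, size=len(ids))
            fc = design.histone_kappa * beta[:, ti, pi] + noise
            for rid, v in zip(ids, fc):
                rows.append({"region_id": rid, "treatment": trt,
                             "time": str(tm), "log2fc": float(v)})
    return histone_regions, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dataset writer
# ---------------------------------------------------------------------------

def write_dataset(design: SimulationDesign, out_dir: str | Path,
                  with_fragments: bool = True) -> Path:
    """Materialize a complete synthetic input directory plus manifest.yaml."""
    out = Path(out_dir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    (out / "tracks").mkdir(exist_ok=True)
    annotation = simulate_annotation(design)
    experiment, peaks, truth = simulate_counts(design, annotation)
    deg = simulate_expression(design, annotation, truth)
    histone_regions, histone_response = simulate_histone_response(design, annotation, truth)

    cio.write_chrom_sizes(annotation.chrom_sizes, out / "chrom_sizes.tsv")
    experiment.samples.to_csv(out / "metadata.tsv", sep="\t", index=False)
    manifest: dict = {
        "chrom_sizes": "chrom_sizes.tsv",
        "metadata": "metadata.tsv",
        "counts": "counts.tsv",
        "blacklist": "blacklist.bed",
        "tss": "tss.tsv",
        "snps": "snps.tsv",
        "tads": "tads.bed",
        "deg": "deg.tsv",
        "expressed_genes": "expressed_genes.txt",
        "histone_regions": "histone_regions.bed",
        "histone_response": "histone_response.tsv",
        "reference_peaks": "reference_peaks.bed",
        "sample_peaks": {},
        "tracks": {},
    }
    cio.write_count_matrix(experiment, out / "counts.tsv")
    for sample_id, pk in peaks.items():
        rel = f"peaks/{sample_id}.bed"
        cio.write_bed(pk, out / rel)
        manifest["sample_peaks"][sample_id] = rel
    if with_fragments:
        (out / "fragments").mkdir(exist_ok=True)
        manifest["fragments"] = {}
        fragments = simulate_fragments(design, experiment)
        for sample_id, fr in fragments.items():
            rel = f"fragments/{sample_id}.bed"
            cio.write_bed(fr, out / rel)
            manifest["fragments"][sample_id] = rel
    cio.write_bed(annotation.blacklist, out / "blacklist.bed")
    cio.write_tss_table(annotation.tss, out / "tss.tsv")
    for name, track in annotation.tracks.items():
        rel = f"tracks/{name}.bed"
        cio.write_bed(track.regions, out / rel)
        manifest["tracks"][name] = {
            "path": rel, "category_group": track.category_group,
            "min_frac": track.min_frac,
        }
    cio.write_snp_table(annotation.snps, out / "snps.tsv")
    cio.write_bed(annotation.tads.regions, out / "tads.bed")
    deg.to_csv(out / "deg.tsv", sep="\t", index=False)
    with open(out / "expressed_genes.txt", "w") as fh:
        fh.write("\n".join(sorted(annotation.expressed_genes)) + "\n")
    cio.write_bed(histone_regions, out / "histone_regions.bed")
    histone_response.to_csv(out / "histone_response.tsv", sep="\t", index=False)
    cio.write_bed(annotation.reference_peaks, out / "reference_peaks.bed")
    truth.regions.to_csv(out / "truth_regions.tsv", sep="\t", index=False)
    truth.effects.to_csv(out / "truth_effects.tsv", sep="\t", index=False)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out / "manifest.yaml"
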