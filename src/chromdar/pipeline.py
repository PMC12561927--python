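"""Staged pipeline: consensus -> quantify/qc -> dar -> enrich -> snp -> link.

A manifest (YAML, paths relative to its own directory) names every input; each
stage writes TSV/BED artifacts into the output directory and logs one
structured line with input/output record counts. Identical config + inputs +
seed produce byte-identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .config import PipelineConfig
from .diffacc import differential_accessibility
from .enrichment import (FeatureTrack, adjust_across_categories,
                         deg_proximity_enrichment, enrichment_test, results_frame)
from .errors import MissingInputError, ValidationError
from .intervals import RegionSet, consensus_filter, merge_regions, subtract_overlapping
from .linkage import (cross_phenotype_correlation, link_regions_to_genes,
                      median_response, region_set_overlap_fraction)
from .quant_qc import (count_fragments, filter_low_accessibility, frip, log2_cpm,
                       pca_factor_association, sample_correlation, tss_enrichment)
from .snp_tad import (TadSet, effectsize_comparison, permutation_overlap_test,
                      snp_enrichment, snp_region_overlap, tad_distance_test)

log = logging.getLogger("chromdar")

STAGES = ("consensus", "quantify", "qc", "dar", "enrich", "snp", "link")

_REQUIRES = {
    "consensus": ["metadata", "sample_peaks"],
    "quantify": ["metadata"],
    "qc": ["metadata"],
    "dar": ["metadata"],
    "enrich": ["tracks"],
    "snp": ["snps", "tads"],
    "link": ["tss"],
}


class Manifest:
    def __init__(self, path: str | Path):
        self.path = Path(path)
        with open(self.path) as fh:
            self.data = yaml.safe_load(fh) or {}
        self.root = self.path.parent

    def has(self, key: str) -> bool:
        return key in self.data and self.data[key] is not None

    def resolve(self, rel: str) -> Path:
        return self.root / rel

    def require(self, key: str, stage: str) -> object:
        if not self.has(key):
            raise MissingInputError(
                f"stage {stage!r} requested but manifest is missing input {key!r}"
            )
        return self.data[key]


def _check_inputs(manifest: Manifest, stages: list[str]) -> None:
    for stage in stages:
        for key in _REQUIRES[stage]:
            manifest.require(key, stage)
    if "quantify" in stages and not (manifest.has("counts") or manifest.has("fragments")):
        raise MissingInputError(
            "stage 'quantify' needs either 'counts' or 'fragments' in the manifest"
        )


def _stage_log(stage: str, **counts) -> None:
    fields = " ".join(f"{k}={v}" for k, v in counts.items())
    log.info("stage=%s %s", stage, fields)


def run_pipeline(
    config: PipelineConfig,
    manifest_path: str | Path,
    out_dir: str | Path,
    stages: list[str] | None = None,
) -> dict:
    """Run the requested stages in order; returns in-memory stage products.

    Missing inputs for any requested stage raise before any computation.
    """
    manifest = Manifest(manifest_path)
    stages = [s for s in STAGES if s in (stages or STAGES)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValidationError(f"unknown stages: {sorted(unknown)}")
    _check_inputs(manifest, stages)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ctx: dict = {"config": config}

    meta = cio.read_metadata(manifest.resolve(manifest.data["metadata"])) \
        if manifest.has("metadata") else None
    ctx["meta"] = meta

    if "consensus" in stages:
        _run_consensus(config, manifest, meta, out, ctx)
    if "quantify" in stages:
        _run_quantify(config, manifest, meta, out, ctx)
    if "qc" in stages:
        _run_qc(config, manifest, meta, out, ctx)
    if "dar" in stages:
        _run_dar(config, manifest, out, ctx)
    if "enrich" in stages:
        _run_enrich(config, manifest, out, ctx)
    if "snp" in stages:
        _run_snp(config, manifest, out, ctx)
    if "link" in stages:
        _run_link(config, manifest, out, ctx)
    return ctx


# ---------------------------------------------------------------------------

def _load_peaks(manifest: Manifest, meta: pd.DataFrame) -> dict[str, RegionSet]:
    spec = manifest.data["sample_peaks"]
    missing = [s for s in meta["sample_id"] if s not in spec]
    if missing:
        raise MissingInputError(f"sample_peaks missing for samples {missing}")
    return {s: cio.read_bed(manifest.resolve(spec[s]), dialect="bed3")
            for s in meta["sample_id"]}


def _run_consensus(config, manifest, meta, out, ctx) -> None:
    peaks = _load_peaks(manifest, meta)
    sets = list(peaks.values())
    master = merge_regions(*sets)
    consensus = consensus_filter(master, sets, k=config.min_samples_for_consensus)
    n_before_bl = len(consensus)
    if manifest.has("blacklist"):
        blacklist = cio.read_bed(manifest.resolve(manifest.data["blacklist"]))
        consensus = subtract_overlapping(consensus, blacklist)
    if config.contig_allowlist:
        keep = consensus.df["chrom"].isin(set(config.contig_allowlist)).to_numpy()
        consensus = consensus.subset(np.flatnonzero(keep))
    cio.write_bed(consensus, out / "consensus_regions.bed")
    _stage_log("consensus", n_peak_sets=len(sets), n_master=len(master),
               n_supported=n_before_bl, n_out=len(consensus))
    ctx["consensus"] = consensus
    ctx["peaks"] = peaks


def _run_quantify(config, manifest, meta, out, ctx) -> None:
    if manifest.has("counts"):
        experiment = cio.read_count_matrix(manifest.resolve(manifest.data["counts"]), meta)
        if "consensus" in ctx:
            # keep only counted regions that survived the consensus stage
            keep = ctx["consensus"]
            from .intervals import overlaps_any
            mask = overlaps_any(experiment.regions, keep)
            experiment = experiment.subset_regions(mask)
    else:
        frag_spec = manifest.require("fragments", "quantify")
        fragments = {s: cio.read_bed(manifest.resolve(p)) for s, p in frag_spec.items()}
        regions = ctx.get("consensus")
        if regions is None:
            raise MissingInputError("'quantify' from fragments needs the consensus stage")
        regions = RegionSet(regions.df[["chrom", "start", "end"]])
        experiment = count_fragments(fragments, regions, meta)
    filtered, report = filter_low_accessibility(
        experiment, drop_chroms=config.drop_chroms, prior=config.cpm_prior)
    cio.write_count_matrix(filtered, out / "filtered_counts.tsv")
    cio.write_bed(filtered.regions, out / "filtered_regions.bed")
    _stage_log("quantify", n_in=report["n_input"],
               n_low=report["n_low_accessibility"],
               n_chrom_dropped=report["n_dropped_chrom"], n_out=report["n_kept"])
    ctx["experiment"] = filtered


def _run_qc(config, manifest, meta, out, ctx) -> None:
    experiment = ctx.get("experiment")
    if experiment is None:
        raise MissingInputError("'qc' needs the quantify stage")
    lcpm = log2_cpm(experiment, prior=config.cpm_prior)
    corr = sample_correlation(lcpm, experiment.samples["sample_id"])
    corr.to_csv(out / "sample_correlation.tsv", sep="\t")
    pca = pca_factor_association(lcpm, experiment.samples, n_pcs=config.n_pcs)
    pca.to_csv(out / "pca_factor_association.tsv", sep="\t", index=False)
    qc_rows = None
    if manifest.has("fragments") and manifest.has("tss"):
        frag_spec = manifest.data["fragments"]
        tss = cio.read_tss_table(manifest.resolve(manifest.data["tss"]))
        fragments = {s: cio.read_bed(manifest.resolve(p)) for s, p in frag_spec.items()}
        regions = RegionSet(experiment.regions.df[["chrom", "start", "end"]])
        frag_exp = count_fragments(fragments, regions, meta)
        frip_df = frip(frag_exp, floor=config.frip_floor)
        tsse = [tss_enrichment(fragments[s], tss, flank=config.tss_flank_bp,
                               window=config.tss_window_bp)
                for s in meta["sample_id"]]
        qc_rows = frip_df.assign(tsse=tsse)
        qc_rows.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    _stage_log("qc", n_samples=len(meta),
               n_flagged=int(qc_rows["below_floor"].sum()) if qc_rows is not None else 0)
    ctx["qc"] = qc_rows
    ctx["log2cpm"] = lcpm


def _run_dar(config, manifest, out, ctx) -> None:
    experiment = ctx.get("experiment")
    if experiment is None:
        raise MissingInputError("'dar' needs the quantify stage")
    result = differential_accessibility(
        experiment, vehicle=config.vehicle_label, alpha=config.dar_alpha)
    cols = ["region_id", "treatment", "time", "log2fc", "t", "p", "p_adj",
            "label", "direction"]
    result.table[cols].to_csv(out / "dar_results.tsv", sep="\t", index=False,
                              float_format="%.6g")
    result.summary().to_csv(out / "dar_summary.tsv", sep="\t", index=False)
    _stage_log("dar", n_regions=experiment.n_regions,
               n_contrasts=len(result.cells) - len(set(ctx["meta"]["time"])),
               rho_consensus=round(result.correlation.rho_consensus, 4))
    ctx["dar"] = result


def _tracks_from_manifest(manifest: Manifest) -> dict[str, FeatureTrack]:
    tracks = {}
    for name, spec in manifest.data["tracks"].items():
        tracks[name] = FeatureTrack(
            name=name,
            regions=cio.read_bed(manifest.resolve(spec["path"])),
            category_group=spec.get("category_group", "features"),
            min_frac=float(spec.get("min_frac", 0.0)),
        )
    return tracks


def _dar_car_sets(result, experiment, treatment, time):
    t = result.contrast_table(treatment, time)
    is_dar = (t["label"] == "DAR").to_numpy()
    idx = t["region_index"].to_numpy()
    dar = experiment.regions.subset(idx[is_dar])
    car = experiment.regions.subset(idx[~is_dar])
    return dar, car, t


def _run_enrich(config, manifest, out, ctx) -> None:
    result, experiment = ctx.get("dar"), ctx.get("experiment")
    if result is None:
        raise MissingInputError("'enrich' needs the dar stage")
    tracks = _tracks_from_manifest(manifest)
    results = []
    contrasts = result.table[["treatment", "time"]].drop_duplicates()
    for trt, tm in contrasts.itertuples(index=False, name=None):
        dar, car, _ = _dar_car_sets(result, experiment, trt, tm)
        if not len(dar) or not len(car):
            log.warning("enrich: skipping %s/%s (empty DAR or CAR set)", trt, tm)
            continue
        for track in tracks.values():
            results.append(enrichment_test(
                dar, car, track, fisher_switch=config.fisher_switch_count,
                contrast=(trt, tm)))
    adjust_across_categories(results, alpha=config.dar_alpha)
    frame = results_frame(results)
    frame.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    deg_frame = None
    if manifest.has("deg") and manifest.has("tss"):
        deg = cio.read_deg_table(manifest.resolve(manifest.data["deg"]))
        tss = cio.read_tss_table(manifest.resolve(manifest.data["tss"]))
        deg_results = []
        for trt, tm in contrasts.itertuples(index=False, name=None):
            dar, car, _ = _dar_car_sets(result, experiment, trt, tm)
            if not len(dar) or not len(car):
                continue
            dsub = deg[(deg["treatment"] == trt) & (deg["time"].astype(str) == str(tm))]
            deg_genes = set(dsub.loc[dsub["is_deg"], "gene_id"])
            for w in config.link_windows_bp:
                dl = link_regions_to_genes(dar, tss, None, w)
                cl = link_regions_to_genes(car, tss, None, w)
                if not len(dl) or not len(cl):
                    continue
                deg_results.append(deg_proximity_enrichment(
                    dl, cl, deg_genes, contrast=(trt, tm), window=w))
        deg_frame = results_frame(deg_results)
        deg_frame.to_csv(out / "deg_enrichment.tsv", sep="\t", index=False,
                         float_format="%.6g")
    _stage_log("enrich", n_tracks=len(tracks), n_tests=len(results),
               n_deg_tests=0 if deg_frame is None else len(deg_frame))
    ctx["enrichment"] = frame


def _run_snp(config, manifest, out, ctx) -> None:
    result, experiment = ctx.get("dar"), ctx.get("experiment")
    if result is None:
        raise MissingInputError("'snp' needs the dar stage")
    snps = cio.read_snp_table(manifest.resolve(manifest.data["snps"]))
    trait_counts = pd.Series([s.trait for s in snps]).value_counts()
    for trait, n in trait_counts.items():
        log.info("snp: trait=%s n_unique=%d", trait, n)
    tads = TadSet(cio.read_bed(manifest.resolve(manifest.data["tads"])))
    regions = experiment.regions
    overlaps = snp_region_overlap(snps, regions)
    overlaps.to_csv(out / "snp_overlaps.tsv", sep="\t", index=False)

    enr_rows, dist_rows = [], []
    contrasts = result.table[["treatment", "time"]].drop_duplicates()
    for trt, tm in contrasts.itertuples(index=False, name=None):
        dar, car, table = _dar_car_sets(result, experiment, trt, tm)
        if not len(dar) or not len(car):
            continue
        for trait, res in snp_enrichment(
                dar, car, snps, fisher_switch=config.fisher_switch_count,
                contrast=(trt, tm)).items():
            enr_rows.append(res)
        labels = table.sort_values("region_index")["label"].to_numpy()
        try:
            cmp_ = tad_distance_test(snps, regions, labels, tads)
            dist_rows.append({
                "treatment": trt, "time": tm,
                "n_dar_pairs": len(cmp_.dar_distances),
                "n_car_pairs": len(cmp_.car_distances),
                "median_dar": float(np.median(cmp_.dar_distances)),
                "median_car": float(np.median(cmp_.car_distances)),
                "w": cmp_.statistic, "p": cmp_.p, "method": cmp_.method,
            })
        except ValidationError as exc:
            log.warning("snp: TAD distance test skipped for %s/%s: %s", trt, tm, exc)
    results_frame(enr_rows).to_csv(out / "snp_enrichment.tsv", sep="\t",
                                   index=False, float_format="%.6g")
    pd.DataFrame(dist_rows).to_csv(out / "tad_distance.tsv", sep="\t",
                                   index=False, float_format="%.6g")

    # effect sizes at SNP-overlapping regions, each drug vs the reference
    eff_frame = pd.DataFrame()
    snp_region_idx = sorted(set(overlaps["region_index"]))
    ref_trt = next((t for t in ("TRZ",) if (result.table["treatment"] == t).any()), None)
    if snp_region_idx and ref_trt:
        rows = []
        for tm in sorted(set(map(str, contrasts["time"]))):
            sub = result.table[result.table["time"].astype(str) == tm]
            wide = sub.pivot_table(index="region_index", columns="treatment",
                                   values="log2fc")
            wide = wide.loc[wide.index.intersection(snp_region_idx)]
            if len(wide) < 3:
                continue
            cmp_df = effectsize_comparison(wide, reference=ref_trt)
            cmp_df["time"] = tm
            rows.append(cmp_df)
        if rows:
            eff_frame = pd.concat(rows, ignore_index=True)
    eff_frame.to_csv(out / "effectsize_comparison.tsv", sep="\t", index=False,
                     float_format="%.6g")

    perm_row = {}
    if manifest.has("reference_peaks") and manifest.has("chrom_sizes"):
        reference = cio.read_bed(manifest.resolve(manifest.data["reference_peaks"]))
        sizes = cio.read_chrom_sizes(manifest.resolve(manifest.data["chrom_sizes"]))
        obs, perm, p = permutation_overlap_test(
            regions, reference, sizes, b=config.permutations, seed=config.rng_seed)
        perm_row = {"observed": obs, "n_query": len(regions),
                    "fraction": obs / len(regions),
                    "perm_mean": float(perm.mean()), "p": p}
        pd.DataFrame([perm_row]).to_csv(out / "reference_overlap.tsv", sep="\t",
                                        index=False, float_format="%.6g")
    _stage_log("snp", n_snps=len(snps), n_overlapping=len(overlaps),
               n_enrichment_tests=len(enr_rows))
    ctx["snp_overlaps"] = overlaps
    ctx["reference_overlap"] = perm_row


def _run_link(config, manifest, out, ctx) -> None:
    result, experiment = ctx.get("dar"), ctx.get("experiment")
    if result is None:
        raise MissingInputError("'link' needs the dar stage")
    tss = cio.read_tss_table(manifest.resolve(manifest.data["tss"]))
    expressed = (cio.read_gene_list(manifest.resolve(manifest.data["expressed_genes"]))
                 if manifest.has("expressed_genes") else None)
    regions = experiment.regions
    links = link_regions_to_genes(regions, tss, expressed, config.link_windows_bp[0])
    links.to_csv(out / "region_gene_links.tsv", sep="\t", index=False)

    rows = []
    overlap_row = {}
    if manifest.has("histone_regions"):
        histone = cio.read_bed(manifest.resolve(manifest.data["histone_regions"]))
        if len(histone):
            n, frac = region_set_overlap_fraction(histone, regions)
            overlap_row = {"n_histone": len(histone), "n_overlapping": n,
                           "fraction": frac}
            pd.DataFrame([overlap_row]).to_csv(out / "histone_overlap.tsv", sep="\t",
                                               index=False, float_format="%.6g")
    ac_treatments = [t for t in ("DOX", "EPI", "DNR", "MTX")
                     if (result.table["treatment"] == t).any()]
    region_to_gene = dict(zip(links["region_id"], links["gene_id"]))
    times = sorted(set(result.table["time"].astype(str)))
    deg = (cio.read_deg_table(manifest.resolve(manifest.data["deg"]))
           if manifest.has("deg") else None)
    histone_response = (pd.read_csv(manifest.resolve(manifest.data["histone_response"]), sep="\t")
                        if manifest.has("histone_response") else None)
    for tm in times:
        if not ac_treatments:
            break
        med_acc = median_response(result.table, tm, ac_treatments)
        med_acc = med_acc[med_acc.index.isin(region_to_gene)]
        if histone_response is not None:
            med_his = median_response(histone_response, tm,
                                      [t for t in ac_treatments
                                       if (histone_response["treatment"] == t).any()])
            shared = med_acc.index.intersection(med_his.index)
            if len(shared) >= 3:
                rep = cross_phenotype_correlation(
                    med_acc.loc[shared], med_his.loc[shared],
                    phenotypes=("accessibility", "histone"), time=tm,
                    method=config.correlation_method)
                rows.append(rep)
        if deg is not None:
            med_expr = median_response(
                deg.rename(columns={"gene_id": "region_id"}), tm,
                [t for t in ac_treatments if (deg["treatment"] == t).any()])
            gene_fc = med_acc.rename(index=region_to_gene)
            gene_fc = gene_fc.groupby(level=0).median()
            shared = gene_fc.index.intersection(med_expr.index)
            if len(shared) >= 3:
                rep = cross_phenotype_correlation(
                    gene_fc.loc[shared], med_expr.loc[shared],
                    phenotypes=("accessibility", "expression"), time=tm,
                    method=config.correlation_method)
                rows.append(rep)
    corr_frame = pd.DataFrame([{
        "phenotype_a": r.phenotypes[0], "phenotype_b": r.phenotypes[1],
        "time": r.time, "rho": r.rho, "p": r.p, "n": r.n, "method": r.method,
    } for r in rows])
    corr_frame.to_csv(out / "cross_phenotype_correlation.tsv", sep="\t",
                      index=False, float_format="%.6g")
    _stage_log("link", n_links=len(links), n_correlations=len(corr_frame))
    ctx["links"] = links
    ctx["correlations"] = corr_frame
    ctx["histone_overlap"] = overlap_row
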