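"""Readers and writers for the external formats the pipeline touches.

BED and narrowPeak coordinates are 0-based half-open on disk and in memory.
SNP tables are 1-based on disk (VCF-style) and converted to 0-based point
intervals on read. Region identifiers are ``chrom:start-end`` with 0-based
half-open coordinates, so they round-trip exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, ValidationError
from .intervals import RegionSet, TssTable

_BED_DIALECTS = {
    "bed3": ["chrom", "start", "end"],
    "bed6": ["chrom", "start", "end", "name", "score", "strand"],
    "narrowPeak": [
        "chrom", "start", "end", "name", "score", "strand",
        "signalValue", "pValue", "qValue", "peak",
    ],
}

_REGION_ID_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


@dataclass(frozen=True)
class SNPRecord:
    """A GWAS SNP: 0-based point position plus its associated trait."""

    rsid: str
    chrom: str
    pos0: int
    trait: str

    def __post_init__(self) -> None:
        if self.pos0 < 0:
            raise ValidationError(f"SNP {self.rsid}: position must be >= 1 (1-based)")


# ---------------------------------------------------------------------------
# BED / narrowPeak
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, dialect: str = "bed3") -> RegionSet:
    """Read a BED3/BED6/narrowPeak file into a RegionSet.

    Extra columns beyond the dialect's are preserved as opaque ``attr_N``
    columns for bed3; bed6 and narrowPeak require at least/exactly their
    standard column counts.
    """
    if dialect not in _BED_DIALECTS:
        raise ConfigurationError(
            f"unknown BED dialect {dialect!r}; expected one of {sorted(_BED_DIALECTS)}"
        )
    cols = _BED_DIALECTS[dialect]
    records: list[list] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 tab-separated fields")
            if dialect == "narrowPeak" and len(fields) != 10:
                raise ParseError(
                    f"{path}:{lineno}: narrowPeak requires 10 columns, got {len(fields)}"
                )
            if dialect == "bed6" and len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: bed6 requires >= 6 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: interval must satisfy start < end "
                    f"([{start}, {end}))"
                )
            records.append([fields[0], start, end] + fields[3:])
    if not records:
        return RegionSet(name=str(path))
    width = max(len(r) for r in records)
    names = list(cols[:width]) + [f"attr_{i}" for i in range(len(cols), width)]
    df = pd.DataFrame([r + [None] * (width - len(r)) for r in records], columns=names)
    for numeric in ("score", "signalValue", "pValue", "qValue"):
        if numeric in df.columns:
            df[numeric] = pd.to_numeric(df[numeric], errors="coerce")
    if "peak" in df.columns:
        df["peak"] = pd.to_numeric(df["peak"], errors="coerce").astype("Int64")
    return RegionSet(df, name=str(path))


def write_bed(regions: RegionSet, path: str | Path) -> None:
    """Write a RegionSet with all attribute columns, tab-separated, no header."""
    regions.df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "individual", "treatment", "time"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ParseError(f"{path}: metadata missing columns {missing}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"{path}: duplicate sample ids {dups}")
    return meta.reset_index(drop=True)


def parse_region_id(region_id: str) -> tuple[str, int, int]:
    m = _REGION_ID_RE.match(region_id)
    if not m:
        raise ParseError(f"malformed region id {region_id!r} (want chrom:start-end)")
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    if start >= end:
        raise ValidationError(f"region id {region_id!r} has start >= end")
    return chrom, start, end


def read_count_matrix(path: str | Path, meta: pd.DataFrame):
    """Read a region x sample TSV count matrix into a CountExperiment.

    The first column holds region ids ``chrom:start-end``; the header row holds
    sample ids. Columns are reordered to metadata order; region order on disk
    is preserved (the RegionSet re-sorts coordinates, and counts follow).
    """
    from .quant_qc import CountExperiment  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", index_col=0)
    unknown = [s for s in df.columns if s not in set(meta["sample_id"])]
    if unknown:
        raise ValidationError(f"{path}: samples missing from metadata: {unknown}")
    absent = [s for s in meta["sample_id"] if s not in set(df.columns)]
    if absent:
        raise ValidationError(f"{path}: metadata samples absent from matrix: {absent}")
    df = df[meta["sample_id"].tolist()]
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.all(np.equal(np.mod(values, 1), 0)):
            raise ValidationError(f"{path}: counts must be integers")
        values = values.astype(np.int64)
    if (values < 0).any():
        raise ValidationError(f"{path}: negative counts")
    parsed = [parse_region_id(r) for r in df.index]
    regions_df = pd.DataFrame(parsed, columns=["chrom", "start", "end"])
    order = regions_df.sort_values(["chrom", "start", "end"], kind="mergesort").index.to_numpy()
    regions = RegionSet(regions_df.iloc[order], name=str(path))
    return CountExperiment(regions=regions, counts=values[order], samples=meta.copy())


def write_count_matrix(experiment, path: str | Path) -> None:
    df = pd.DataFrame(
        experiment.counts,
        index=experiment.regions.region_ids.to_numpy(),
        columns=experiment.samples["sample_id"].tolist(),
    )
    df.index.name = "region"
    df.to_csv(path, sep="\t")


def read_snp_table(path: str | Path) -> list[SNPRecord]:
    """Read a TSV of (rsID, chrom, pos [1-based], trait) into SNP records.

    Positions become 0-based points; duplicate (rsID, trait) rows collapse to
    one record.
    """
    df = pd.read_csv(path, sep="\t", dtype={"rsID": str, "chrom": str, "trait": str})
    missing = [c for c in ("rsID", "chrom", "pos", "trait") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: SNP table missing columns {missing}")
    if (df["pos"] < 1).any():
        bad = df.loc[df["pos"] < 1, "rsID"].tolist()
        raise ValidationError(f"{path}: 1-based positions must be >= 1 (SNPs {bad})")
    df = df.drop_duplicates(subset=["rsID", "trait"], keep="first")
    return [
        SNPRecord(rsid=r.rsID, chrom=r.chrom, pos0=int(r.pos) - 1, trait=r.trait)
        for r in df.itertuples(index=False)
    ]


def write_snp_table(snps: list[SNPRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.rsid, s.chrom, s.pos0 + 1, s.trait) for s in snps],
        columns=["rsID", "chrom", "pos", "trait"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_tss_table(path: str | Path) -> TssTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    missing = [c for c in ("gene_id", "chrom", "tss", "strand") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: TSS table missing columns {missing}")
    return TssTable(df)


def write_tss_table(tss: TssTable, path: str | Path) -> None:
    tss.df.to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    if (df["size"] <= 0).any():
        raise ValidationError(f"{path}: chromosome sizes must be positive")
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    pd.DataFrame(sorted(sizes.items()), columns=["chrom", "size"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_deg_table(path: str | Path) -> pd.DataFrame:
    """Per-(gene, treatment, time) expression response: log2fc + DEG flag."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "treatment": str})
    missing = [c for c in ("gene_id", "treatment", "time", "log2fc", "is_deg")
               if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: DEG table missing columns {missing}")
    df["is_deg"] = df["is_deg"].astype(bool)
    return df


def read_gene_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
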