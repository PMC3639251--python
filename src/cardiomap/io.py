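"""File formats and run manifests.

Conventions (stated in every file header this module writes): VCF positions
are 1-based; BED intervals are 0-based half-open; TSV site/profile tables are
1-based inclusive. Genotypes are encoded against the yw parent as REF and the
WE70 parent as ALT, so GT 0/0 = yw, 1/1 = WE70.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import MarkerMap
from .rilscan import GenotypeMatrix, MISSING
from .simulate import SiteCounts

logger = logging.getLogger("cardiomap")

_GT = {1: "1/1", 0: "0/0", MISSING: "./."}


# ---------------------------------------------------------------------------
# Marker maps and pileups (TSV)
# ---------------------------------------------------------------------------


def write_marker_map(marker_map: MarkerMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("# marker map; positions 1-based inclusive\n")
        fh.write(f"# crossover_rate_per_arm={marker_map.crossover_rate}\n")
        for name, length in marker_map.chromosomes:
            fh.write(f"##chrom\t{name}\t{length}\n")
        fh.write("chrom\tpos\n")
        marker_map.site_table().to_csv(fh, sep="\t", header=False, index=False)


def read_marker_map(path) -> MarkerMap:
    chroms = []
    rate = 1.0
    with open(path) as fh:
        for line in fh:
            if line.startswith("# crossover_rate_per_arm="):
                rate = float(line.split("=", 1)[1])
            elif line.startswith("##chrom\t"):
                _, name, length = line.rstrip("\n").split("\t")
                chroms.append((name, int(length)))
            elif not line.startswith("#"):
                break
    table = pd.read_csv(path, sep="\t", comment="#", skiprows=2 + len(chroms))
    positions = {name: table.loc[table["chrom"] == name, "pos"].to_numpy(np.int64)
                 for name, _ in chroms}
    return MarkerMap(tuple(chroms), positions, rate)


def write_pileup(counts: SiteCounts, path) -> None:
    with open(path, "w") as fh:
        fh.write("# pileup counts; pos 1-based\n")
        df = counts.sites.assign(count_w=counts.count_w, count_y=counts.count_y,
                                 n_error=counts.n_error)
        df.to_csv(fh, sep="\t", index=False)


def read_pileup(path) -> SiteCounts:
    df = pd.read_csv(path, sep="\t", comment="#")
    return SiteCounts(sites=df[["chrom", "pos"]].copy(),
                      count_w=df["count_w"].to_numpy(),
                      count_y=df["count_y"].to_numpy(),
                      n_error=df["n_error"].to_numpy() if "n_error" in df else
                      np.zeros(len(df), dtype=int))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(gm: GenotypeMatrix, marker_map: MarkerMap, path) -> None:
    """Uncompressed VCF 4.2, one sample per line; REF=A encodes the yw allele,
    ALT=T the WE70 allele."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cardiomap\n")
        fh.write('##INFO=<ID=.,Number=0,Type=Flag,Description="none">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for name, length in marker_map.chromosomes:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
                  "FORMAT", *gm.line_ids]
        fh.write("\t".join(header) + "\n")
        chroms = gm.sites["chrom"].to_numpy()
        pos = gm.sites["pos"].to_numpy()
        for j in range(len(gm.sites)):
            gts = "\t".join(_GT[int(g)] for g in gm.calls[:, j])
            fh.write(f"{chroms[j]}\t{pos[j]}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path, classes: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read a (cardiomap-convention) VCF back into a GenotypeMatrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    line_ids = list(vcf.samples)
    chroms, positions, columns = [], [], []
    for variant in vcf:
        chroms.append(variant.CHROM)
        positions.append(variant.POS)
        gt = variant.gt_types  # 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        col = np.full(len(line_ids), MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 2] = 1
        columns.append(col)
    vcf.close()
    calls = np.stack(columns, axis=1) if columns else np.empty((len(line_ids), 0), np.int8)
    sites = pd.DataFrame({"chrom": chroms, "pos": np.asarray(positions, np.int64)})
    return GenotypeMatrix(line_ids, sites, calls, dict(classes or {}))


# ---------------------------------------------------------------------------
# BED and profiles
# ---------------------------------------------------------------------------


def write_bed(regions: pd.DataFrame, path) -> None:
    """BED3+ (0-based half-open). Input regions use 1-based inclusive
    coordinates (columns chrom, start, end, + extras); unsorted input is
    sorted with a warning."""
    regions = regions.copy()
    if len(regions):
        sorted_ok = regions.sort_values(["chrom", "start"]).index.equals(regions.index)
        if not sorted_ok:
            logger.warning("BED regions were unsorted; sorting before write")
            regions = regions.sort_values(["chrom", "start"]).reset_index(drop=True)
    with open(path, "w") as fh:
        fh.write("# BED: 0-based half-open\n")
        if len(regions):
            out = regions.copy()
            out["start"] = out["start"].astype(np.int64) - 1
            out.to_csv(fh, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    """Inverse of :func:`write_bed`: returns 1-based inclusive regions."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    df["start"] = df["start"].astype(np.int64) + 1
    return df


def write_profile(profile, path) -> None:
    """Window profile as TSV with the thresholds, if any, in the header."""
    with open(path, "w") as fh:
        fh.write("# window profile; start/end 1-based inclusive\n")
        fh.write(f"# window={profile.window} step={profile.step}\n")
        if profile.thresholds is not None:
            low, high = profile.thresholds
            fh.write(f"# threshold_low={low} threshold_high={high}\n")
        profile.windows.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phenotype tables
# ---------------------------------------------------------------------------

DEFAULT_PHENOTYPE_COLUMNS = {"line": "line", "fly": "fly", "sd": "sd",
                             "dd": "dd", "ai": "ai"}


def _coerce_phenotypes(df: pd.DataFrame, column_map: dict[str, str]) -> pd.DataFrame:
    missing = [src for src in column_map.values() if src not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {missing}")
    out = pd.DataFrame({dst: df[src] for dst, src in column_map.items()})
    numeric = [c for c in ("sd", "dd", "ai") if c in out]
    out[numeric] = out[numeric].apply(pd.to_numeric, errors="coerce")
    bad = out[numeric].isna().any(axis=1)
    if bad.any():
        logger.info("dropped %d row(s) with unparseable numerics", int(bad.sum()))
    return out.loc[~bad].reset_index(drop=True)


def read_phenotype_xlsx(path, column_map: dict[str, str] | None = None,
                        sheet=0) -> pd.DataFrame:
    """Phenotype table from an XLSX workbook (per-fly or per-line layouts).

    ``column_map`` maps canonical names (line, fly, sd, dd, ai) to the
    workbook's column headers; rows with unparseable numerics are dropped
    (count logged)."""
    df = pd.read_excel(path, sheet_name=sheet, engine="openpyxl")
    return _coerce_phenotypes(df, column_map or DEFAULT_PHENOTYPE_COLUMNS)


def read_phenotype_tsv(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return _coerce_phenotypes(df, column_map or DEFAULT_PHENOTYPE_COLUMNS)


def write_phenotype_tsv(table: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# per-fly heart phenotypes; SD/DD in um, AI dimensionless\n")
        table.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Flat config and run manifests
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    """Flat ``key = value`` configuration text; '#' starts a comment.

    Values are parsed as int, then float, then left as strings."""
    config: dict = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            for caster in (int, float):
                try:
                    config[key] = caster(value)
                    break
                except ValueError:
                    continue
            else:
                config[key] = value
    return config


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_manifest(path, config: dict, seed, timings: dict[str, float] | None = None) -> None:
    """Machine-readable run sidecar. Stage timings are logged to stderr (not
    stored) so outputs stay byte-identical across repeated seeded runs."""
    from . import __version__

    if timings:
        for stage, dt in timings.items():
            logger.info("stage %s: %.2fs", stage, dt)
    manifest = {
        "package": "cardiomap",
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


class StageTimer:
    """Stage-granularity wall-clock logging to stderr plus a timing dict."""

    def __init__(self) -> None:
        self.timings: dict[str, float] = {}

    def __call__(self, stage: str):
        timer = self

        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                dt = time.perf_counter() - self.t0
                timer.timings[stage] = dt
                logger.info("stage %s: %.2fs", stage, dt)
                return False

        return _Ctx()
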