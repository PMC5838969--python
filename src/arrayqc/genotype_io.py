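"""Readers and writers for the tabular formats the QC pipeline touches.

The pipeline exchanges five plain-text formats:

* a **Final-Report dialect** — tab-delimited with a ``[Header]``/``[Data]``
  block, one row per (sample, probe) call, carrying the genotype in A/B
  coding, the GenCall-style confidence score, raw intensities, Log R Ratio
  and B allele frequency;
* a **locus manifest** (CSV) describing each probe: assayed locus,
  chromosome, 1-based position, A/B alleles, local GC fraction and CpG
  density;
* a **sample sheet** (TSV) describing the cohort design: individual,
  input type (gDNA / wgaDNA), source material, plate/chip placement and
  reported sex;
* **STR profiles** (TSV): one row per (sample, marker), alleles
  comma-joined, empty = marker failure;
* BED3+ for windowed per-chromosome failure maps.

Genotypes are stored internally as A/B-relative classes so that
concordance comparisons are strand-free: ``0=AA, 1=AB, 2=BB, -1=NC``.
Coordinates are 1-based inclusive everywhere inside the package; the BED
writer converts to 0-based half-open on output.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Constants: genotype coding and dialect
# ---------------------------------------------------------------------------

NC = -1
AA, AB, BB = 0, 1, 2

GENOTYPE_LABELS = {AA: "AA", AB: "AB", BB: "BB", NC: "NC"}
LABEL_TO_CODE = {v: k for k, v in GENOTYPE_LABELS.items()}

#: calls with a GenCall-style confidence score below this are no-calls
DEFAULT_GC_THRESHOLD = 0.25

#: allele pair written for a no-call in the Final-Report dialect
_NC_ALLELE = "--"

_GENOTYPE_TO_ALLELES = {AA: ("A", "A"), AB: ("A", "B"), BB: ("B", "B"),
                        NC: (_NC_ALLELE, _NC_ALLELE)}

FINAL_REPORT_COLUMNS = [
    "Sample ID", "SNP Name", "Allele1 - AB", "Allele2 - AB",
    "GC Score", "X", "Y", "Log R Ratio", "B Allele Freq",
]

MANIFEST_COLUMNS = [
    "probe_id", "locus_id", "chromosome", "position",
    "allele_a", "allele_b", "gc_fraction", "cpg_density",
]

SAMPLE_SHEET_COLUMNS = [
    "sample_id", "individual_id", "input_type", "source_material",
    "plate_id", "chip_id", "chip_position", "reported_sex",
]

INPUT_TYPES = ("gDNA", "wgaDNA")
SOURCE_MATERIALS = ("blood", "buccal", "oragene")

CALL_COLUMNS = ["sample_id", "probe_id", "genotype", "gc_score",
                "x_raw", "y_raw", "lrr", "baf"]


class FormatError(ValueError):
    """A file violates the declared dialect or a type invariant."""


# ---------------------------------------------------------------------------
# Final-Report dialect
# ---------------------------------------------------------------------------

def _alleles_to_genotype(a1: pd.Series, a2: pd.Series) -> np.ndarray:
    """Map A/B-coded allele pairs to genotype class codes."""
    g = np.full(len(a1), NC, dtype=np.int8)
    a1 = a1.to_numpy(dtype=object)
    a2 = a2.to_numpy(dtype=object)
    is_a1_a = a1 == "A"
    is_a1_b = a1 == "B"
    is_a2_a = a2 == "A"
    is_a2_b = a2 == "B"
    g[is_a1_a & is_a2_a] = AA
    g[is_a1_b & is_a2_b] = BB
    g[(is_a1_a & is_a2_b) | (is_a1_b & is_a2_a)] = AB
    return g


def read_final_report(path, gc_threshold: float = DEFAULT_GC_THRESHOLD):
    """Read a Final-Report dialect file into a call table.

    Calls whose score falls below ``gc_threshold`` are mapped to NC on
    read, mirroring the no-call rule applied at clustering time. Rows
    with a non-numeric score are collected and reported (with 1-based
    line numbers) rather than aborting the read; a missing mandatory
    column is fatal.

    Returns
    -------
    (calls, bad_rows)
        ``calls`` is a DataFrame with columns :data:`CALL_COLUMNS`;
        ``bad_rows`` a list of ``(line_number, reason)`` tuples.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        data_at = next(i for i, ln in enumerate(lines) if ln.strip() == "[Data]")
    except StopIteration:
        raise FormatError(f"{path}: no [Data] block") from None
    if not lines or lines[0].strip() != "[Header]":
        raise FormatError(f"{path}: missing [Header] block")

    header_line = data_at + 1
    if header_line >= len(lines):
        raise FormatError(f"{path}: [Data] block has no column header")
    columns = lines[header_line].rstrip("\n").split("\t")
    missing = [c for c in FINAL_REPORT_COLUMNS if c not in columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")

    body = "\n".join(lines[header_line:])
    raw = pd.read_csv(io.StringIO(body), sep="\t", dtype=str)

    bad_rows: list[tuple[int, str]] = []
    numeric = {}
    for col in ("GC Score", "X", "Y", "Log R Ratio", "B Allele Freq"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        for idx in np.flatnonzero(bad.to_numpy()):
            # +2: 1-based, plus the column-header line of the [Data] block
            bad_rows.append((header_line + 2 + idx, f"non-numeric {col!r}"))
        numeric[col] = vals

    genotype = _alleles_to_genotype(raw["Allele1 - AB"], raw["Allele2 - AB"])
    gc = numeric["GC Score"].to_numpy()
    genotype = np.where(np.nan_to_num(gc, nan=0.0) < gc_threshold, NC, genotype)

    calls = pd.DataFrame({
        "sample_id": raw["Sample ID"],
        "probe_id": raw["SNP Name"],
        "genotype": genotype.astype(np.int8),
        "gc_score": numeric["GC Score"].astype(np.float64),
        "x_raw": numeric["X"].astype(np.float64),
        "y_raw": numeric["Y"].astype(np.float64),
        "lrr": numeric["Log R Ratio"].astype(np.float64),
        "baf": numeric["B Allele Freq"].astype(np.float64),
    })
    return calls, bad_rows


def write_final_report(calls: pd.DataFrame, path) -> None:
    """Write a call table in the Final-Report dialect.

    Column order and float formatting are fixed (scores and BAF to 4
    decimals, intensities to 3, LRR to 4) so that identical tables
    produce byte-identical files.
    """
    calls = calls.reset_index(drop=True)
    n_snps = calls["probe_id"].nunique()
    n_samples = calls["sample_id"].nunique()
    g = calls["genotype"].to_numpy()
    a1 = np.empty(len(calls), dtype=object)
    a2 = np.empty(len(calls), dtype=object)
    for code, (x, y) in _GENOTYPE_TO_ALLELES.items():
        m = g == code
        a1[m] = x
        a2[m] = y

    def fmt(series, nd):
        v = series.to_numpy(dtype=float)
        out = np.array([f"{x:.{nd}f}" for x in v], dtype=object)
        out[np.isnan(v)] = ""
        return out

    with open(path, "w") as fh:
        fh.write("[Header]\n")
        fh.write("GSGT Version\tarrayqc dialect 1.0\n")
        fh.write(f"Num SNPs\t{n_snps}\n")
        fh.write(f"Total SNPs\t{n_snps}\n")
        fh.write(f"Num Samples\t{n_samples}\n")
        fh.write(f"Total Samples\t{n_samples}\n")
        fh.write("[Data]\n")
        fh.write("\t".join(FINAL_REPORT_COLUMNS) + "\n")
        cols = [
            calls["sample_id"].astype(str).to_numpy(dtype=object),
            calls["probe_id"].astype(str).to_numpy(dtype=object),
            a1, a2,
            fmt(calls["gc_score"], 4),
            fmt(calls["x_raw"], 3),
            fmt(calls["y_raw"], 3),
            fmt(calls["lrr"], 4),
            fmt(calls["baf"], 4),
        ]
        for row in zip(*cols):
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Manifest and sample sheet
# ---------------------------------------------------------------------------

def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise FormatError(f"manifest missing columns {missing}")
    if manifest["probe_id"].duplicated().any():
        dups = manifest.loc[manifest["probe_id"].duplicated(), "probe_id"]
        raise FormatError(f"duplicate probe_id values: {sorted(set(dups))[:5]}")
    if (manifest["position"] < 1).any():
        raise FormatError("positions must be 1-based (>= 1)")
    if (manifest["allele_a"] == manifest["allele_b"]).any():
        raise FormatError("allele_a must differ from allele_b")
    # probes sharing a locus must agree on placement and alleles
    key_cols = ["chromosome", "position", "allele_a", "allele_b"]
    per_locus = manifest.groupby("locus_id")[key_cols].nunique()
    bad = per_locus[(per_locus > 1).any(axis=1)]
    if len(bad):
        raise FormatError(
            f"probes sharing locus_id disagree on {key_cols}: "
            f"{list(bad.index[:5])}")
    return manifest


def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(path, dtype={"chromosome": str})
    return validate_manifest(manifest)


def write_manifest(manifest: pd.DataFrame, path) -> None:
    validate_manifest(manifest)
    out = manifest.copy()
    out["gc_fraction"] = out["gc_fraction"].map(lambda v: f"{v:.4f}")
    out["cpg_density"] = out["cpg_density"].map(lambda v: f"{v:.6f}")
    out[MANIFEST_COLUMNS].to_csv(path, index=False)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns {missing}")
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"]
        raise FormatError(f"duplicate sample_id values: {sorted(set(dups))[:5]}")
    bad_type = set(sheet["input_type"]) - set(INPUT_TYPES)
    if bad_type:
        raise FormatError(f"unknown input_type values: {bad_type}")
    bad_src = set(sheet["source_material"]) - set(SOURCE_MATERIALS)
    if bad_src:
        raise FormatError(f"unknown source_material values: {bad_src}")
    per_chip = sheet.groupby("chip_id").size()
    if (per_chip > 4).any():
        raise FormatError(
            f"chips with more than 4 samples: {list(per_chip[per_chip > 4].index[:5])}")
    return sheet


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    sheet["chip_position"] = sheet["chip_position"].astype(int)
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    validate_sample_sheet(sheet)
    sheet[SAMPLE_SHEET_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# STR profiles
# ---------------------------------------------------------------------------

def write_str_profiles(profiles: pd.DataFrame, path) -> None:
    """Write STR profiles: columns sample_id, marker, alleles (comma-joined)."""
    out = profiles.copy()
    out["alleles"] = out["alleles"].map(
        lambda s: ",".join(str(a) for a in sorted(s, key=str)))
    out[["sample_id", "marker", "alleles"]].to_csv(path, sep="\t", index=False)


def read_str_profiles(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    raw["alleles"] = raw["alleles"].map(
        lambda s: frozenset(s.split(",")) if s else frozenset())
    return raw


# ---------------------------------------------------------------------------
# BED output for window maps
# ---------------------------------------------------------------------------

def write_windows_bed(windows: pd.DataFrame, path, score_column="n_failed_wga_only",
                      window_size: int = 50_000) -> None:
    """Write window failure counts as BED3+score.

    Internal windows are 1-based half-open ``[start, start+size)``; BED is
    0-based half-open, so start becomes ``window_start - 1``.
    """
    with open(path, "w") as fh:
        for row in windows.itertuples(index=False):
            start0 = int(row.window_start) - 1
            fh.write(f"{row.chromosome}\t{start0}\t{start0 + window_size}"
                     f"\t{getattr(row, score_column)}\n")
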