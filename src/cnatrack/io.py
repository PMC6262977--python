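"""Readers and writers for the cohort table formats.

All tables are plain text. Coordinates are 1-based inclusive on disk and
in memory; chromosome labels are accepted with or without a ``chr`` prefix
and normalized to the bare label. The gene annotation is the only
BED-like (0-based half-open) table and is converted on read.

Files of a cohort directory
---------------------------
``segments.tsv``   sample_id, chrom, start, end, n_probes, total_cn,
                   minor_cn, state2_total, state2_minor, frac_state1
``samples.tsv``    sample_id, patient_id, timepoint_weeks, ploidy, acf,
                   quality, pathologist_pct
``clinical.csv``   patient_id, arm, size_dx, size_surgery, pcr
``expression.tsv`` gene, then one column per sample
``genes.tsv``      chrom, start, end, gene  (BED-like)
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import SampleProfile, normalize_chrom

SEGMENT_FILE_COLUMNS = [
    "sample_id", "chrom", "start", "end", "n_probes",
    "total_cn", "minor_cn", "state2_total", "state2_minor", "frac_state1",
]
SAMPLE_FILE_COLUMNS = [
    "sample_id", "patient_id", "timepoint_weeks", "ploidy", "acf",
    "quality", "pathologist_pct",
]
CLINICAL_FILE_COLUMNS = ["patient_id", "arm", "size_dx", "size_surgery", "pcr"]

_FLOAT_FMT = "%.6g"


def read_segments(path, samples: pd.DataFrame | None = None) -> list[SampleProfile]:
    """Read a segment table into :class:`SampleProfile` objects.

    ``samples`` (from :func:`read_samples`) supplies patient, time point,
    ploidy, ACF and quality; without it, neutral defaults are used.
    Malformed rows (start > end, negative copy number, overlapping
    segments) raise a ValueError naming the offending file line.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SEGMENT_FILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["_line"] = np.arange(2, len(df) + 2)  # header is line 1
    df["chrom"] = df["chrom"].map(normalize_chrom)
    bad = df["start"] > df["end"]
    if bad.any():
        raise ValueError(f"{path}: start > end at line {int(df.loc[bad, '_line'].iloc[0])}")
    bad = df["total_cn"] < 0
    if bad.any():
        raise ValueError(
            f"{path}: negative total_cn at line {int(df.loc[bad, '_line'].iloc[0])}")
    bad = df["n_probes"] < 1
    if bad.any():
        raise ValueError(
            f"{path}: n_probes < 1 at line {int(df.loc[bad, '_line'].iloc[0])}")
    for (sample, chrom), grp in df.groupby(["sample_id", "chrom"], sort=False):
        grp = grp.sort_values("start")
        overlap = grp["start"].to_numpy()[1:] <= grp["end"].to_numpy()[:-1]
        if overlap.any():
            line = int(grp["_line"].to_numpy()[1:][overlap][0])
            raise ValueError(
                f"{path}: overlapping segments for {sample} chr{chrom} at line {line}")

    meta = {}
    if samples is not None:
        meta = {row["sample_id"]: row for _, row in samples.iterrows()}
    profiles = []
    for sample_id, seg in df.groupby("sample_id", sort=False):
        info = meta.get(sample_id)
        kwargs = dict(patient_id=str(sample_id), timepoint_weeks=0,
                      ploidy=2.0, acf=float("nan"), quality="good",
                      pathologist_pct=None)
        if info is not None:
            pct = info.get("pathologist_pct")
            kwargs = dict(
                patient_id=str(info["patient_id"]),
                timepoint_weeks=int(info["timepoint_weeks"]),
                ploidy=float(info["ploidy"]),
                acf=float(info["acf"]) if pd.notna(info["acf"]) else float("nan"),
                quality=str(info["quality"]),
                pathologist_pct=float(pct) if pd.notna(pct) else None,
            )
        profiles.append(SampleProfile(
            sample_id=str(sample_id),
            segments=seg.drop(columns=["sample_id", "_line"]).reset_index(drop=True),
            **kwargs))
    return profiles


def write_segments(profiles, path) -> None:
    """Write profiles (or a prepared segment DataFrame) as a segment TSV."""
    if isinstance(profiles, pd.DataFrame):
        df = profiles
    else:
        chunks = []
        for p in profiles:
            seg = p.segments.copy()
            seg.insert(0, "sample_id", p.sample_id)
            chunks.append(seg)
        df = pd.concat(chunks, ignore_index=True)
    df[SEGMENT_FILE_COLUMNS].to_csv(path, sep="\t", index=False,
                                    float_format=_FLOAT_FMT)


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_FILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_samples(df: pd.DataFrame, path) -> None:
    df[SAMPLE_FILE_COLUMNS].to_csv(path, sep="\t", index=False,
                                   float_format=_FLOAT_FMT)


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_FILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["pcr"] = df["pcr"].astype(bool)
    return df


def write_clinical(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["pcr"] = out["pcr"].astype(bool)
    cols = [c for c in out.columns if c in CLINICAL_FILE_COLUMNS or c in ("rr", "response_group")]
    out[cols].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_expression(path) -> pd.DataFrame:
    """Genes x samples matrix; first column holds gene symbols."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene", float_format=_FLOAT_FMT)


def read_annotation(path) -> pd.DataFrame:
    """BED-like gene table (chrom, start, end, gene), 0-based half-open on
    disk, returned 1-based inclusive."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("chrom", "start", "end", "gene") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = df.copy()
    out["chrom"] = out["chrom"].map(normalize_chrom)
    out["start"] = out["start"].astype(np.int64) + 1
    out["end"] = out["end"].astype(np.int64)
    return out[["gene", "chrom", "start", "end"]]


def write_annotation(df: pd.DataFrame, path) -> None:
    """Write a 1-based inclusive annotation back to BED-like coordinates."""
    out = df.copy()
    out["start"] = out["start"].astype(np.int64) - 1
    out[["chrom", "start", "end", "gene"]].to_csv(path, sep="\t", index=False)


@dataclass
class CohortData:
    """All inputs of one cohort, loaded."""

    profiles: list
    samples: pd.DataFrame
    clinical: pd.DataFrame
    expression: pd.DataFrame
    annotation: pd.DataFrame


def load_cohort(directory) -> CohortData:
    d = Path(directory)
    samples = read_samples(d / "samples.tsv")
    return CohortData(
        profiles=read_segments(d / "segments.tsv", samples),
        samples=samples,
        clinical=read_clinical(d / "clinical.csv"),
        expression=read_expression(d / "expression.tsv"),
        annotation=read_annotation(d / "genes.tsv"),
    )


def file_checksum(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
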