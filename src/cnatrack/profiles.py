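"""Sample-level containers for segmented copy-number profiles.

A :class:`SampleProfile` is one biopsy's segmented, purity/ploidy-annotated
copy-number genome at one time point, as emitted by allele-specific
copy-number callers. Segments are held in a pandas DataFrame with 1-based
inclusive coordinates.

Column semantics of the segment table
-------------------------------------
``total_cn`` / ``minor_cn`` carry the tumor-adjusted average total and
minor-allele copy number for samples with a good profile (``quality ==
"good"``); for samples whose purity/subclonality fit failed they carry the
raw bulk values, since no adjustment was possible. Subclonal segments
additionally carry an integer state pair: ``(state2_total, state2_minor)``
and the mixing fraction ``frac_state1`` of the first state; the first
state's copies are recovered from the mixture identity
``state1 = (total_cn - (1 - frac1) * state2) / frac1`` (rounded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEGMENT_COLUMNS = [
    "chrom", "start", "end", "n_probes", "total_cn", "minor_cn",
    "state1_total", "state1_minor", "state2_total", "state2_minor",
    "frac_state1",
]

QUALITIES = ("good", "poor", "non_aberrant")
TIMEPOINTS = (0, 12, 25)


def normalize_chrom(label) -> str:
    """Strip any 'chr' prefix and return the bare chromosome label."""
    s = str(label)
    return s[3:] if s.lower().startswith("chr") else s


def derive_state1(df: pd.DataFrame) -> pd.DataFrame:
    """Recover the first copy-number state from the mixture identity.

    For subclonal rows ``total = f1*s1 + (1-f1)*s2`` gives
    ``s1 = (total - (1-f1)*s2) / f1`` (likewise for the minor allele);
    clonal rows round the stored averages. Rows that already carry
    ``state1_total`` are left untouched.
    """
    out = df.copy()
    if "state1_total" not in out.columns:
        out["state1_total"] = np.nan
    if "state1_minor" not in out.columns:
        out["state1_minor"] = np.nan
    todo = out["state1_total"].isna().to_numpy()
    if not todo.any():
        return out
    f1 = out["frac_state1"].to_numpy(float)
    s2t = out["state2_total"].to_numpy(float)
    s2m = out["state2_minor"].to_numpy(float)
    total = out["total_cn"].to_numpy(float)
    minor = out["minor_cn"].to_numpy(float)
    sub = todo & ~np.isnan(f1) & ~np.isnan(s2t) & (f1 > 0) & (f1 < 1)
    clon = todo & ~sub
    s1t = out["state1_total"].to_numpy(float)
    s1m = out["state1_minor"].to_numpy(float)
    s1t[clon] = np.round(total[clon])
    s1m[clon] = np.round(minor[clon])
    with np.errstate(invalid="ignore"):
        s1t[sub] = np.round((total[sub] - (1 - f1[sub]) * s2t[sub]) / f1[sub])
        s1m[sub] = np.round((minor[sub] - (1 - f1[sub]) * s2m[sub]) / f1[sub])
    out["state1_total"] = np.maximum(s1t, 0)
    out["state1_minor"] = np.maximum(s1m, 0)
    return out


def validate_segments(segments: pd.DataFrame) -> pd.DataFrame:
    """Sort, type-check and overlap-check a segment table (one sample);
    derives the first copy-number state when the table lacks it."""
    seg = derive_state1(segments)
    for col in SEGMENT_COLUMNS:
        if col not in seg.columns:
            seg[col] = np.nan
    chrom = np.asarray([normalize_chrom(c) for c in seg["chrom"].to_numpy()])
    seg = seg[SEGMENT_COLUMNS].copy()
    seg["chrom"] = chrom
    start = seg["start"].to_numpy(np.int64)
    end = seg["end"].to_numpy(np.int64)
    n_probes = seg["n_probes"].to_numpy(np.int64)
    seg["start"], seg["end"], seg["n_probes"] = start, end, n_probes
    # order chromosomes by first appearance, positions within
    _, codes = np.unique(chrom, return_inverse=True)
    first_seen = {}
    rank = np.empty(len(chrom), dtype=np.int64)
    for i, c in enumerate(chrom):
        rank[i] = first_seen.setdefault(c, len(first_seen))
    order = np.lexsort((start, rank))
    if not np.array_equal(order, np.arange(len(seg))):
        seg = seg.iloc[order].reset_index(drop=True)
        chrom, start, end = chrom[order], start[order], end[order]
        rank = rank[order]
    else:
        seg = seg.reset_index(drop=True)
    if np.any(start > end):
        raise ValueError(f"segment start > end at row {int(np.argmax(start > end))}")
    if np.any(n_probes < 1):
        raise ValueError("every segment needs n_probes >= 1")
    total = seg["total_cn"].to_numpy(float)
    minor = seg["minor_cn"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        if np.any(total < 0):
            raise ValueError("negative total copy number")
        if np.any(minor > total + 1e-9):
            raise ValueError("minor_cn exceeds total_cn")
    same_chrom = rank[1:] == rank[:-1]
    if np.any(same_chrom & (start[1:] <= end[:-1])):
        bad = int(np.argmax(same_chrom & (start[1:] <= end[:-1]))) + 1
        raise ValueError(f"overlapping segments on chromosome {chrom[bad]}")
    return seg


@dataclass
class SampleProfile:
    """One biopsy's copy-number profile at one time point."""

    sample_id: str
    patient_id: str
    timepoint_weeks: int
    ploidy: float
    acf: float  # aberrant cell fraction (purity); NaN when unknown
    quality: str
    segments: pd.DataFrame = field(repr=False)
    pathologist_pct: float | None = None

    def __post_init__(self) -> None:
        if self.timepoint_weeks not in TIMEPOINTS:
            raise ValueError(f"timepoint_weeks must be one of {TIMEPOINTS}")
        if self.quality not in QUALITIES:
            raise ValueError(f"quality must be one of {QUALITIES}")
        if not np.isnan(self.ploidy) and self.ploidy <= 0:
            raise ValueError("ploidy must be positive")
        self.segments = validate_segments(self.segments)

    @property
    def acf_known(self) -> bool:
        return not np.isnan(self.acf)

    def bulk_total_cn(self) -> np.ndarray:
        """Observed bulk total copy number per segment.

        Good profiles store purity-adjusted values; this undoes the
        adjustment (bulk = 2(1-ACF) + ACF * adjusted). Profiles without a
        usable adjustment already store bulk values.
        """
        adj = self.segments["total_cn"].to_numpy(float)
        if self.quality == "good" and self.acf_known:
            return 2.0 * (1.0 - self.acf) + self.acf * adj
        return adj

    def bulk_minor_cn(self) -> np.ndarray:
        """Observed bulk minor-allele copy number per segment (normal = 1)."""
        adj = self.segments["minor_cn"].to_numpy(float)
        if self.quality == "good" and self.acf_known:
            return 1.0 * (1.0 - self.acf) + self.acf * adj
        return adj


def interval_lookup(segments: pd.DataFrame, chroms, positions) -> np.ndarray:
    """Map genomic positions to covering segment row indices (-1 if none).

    Segments are 1-based inclusive and non-overlapping per chromosome.
    """
    chroms = np.asarray([normalize_chrom(c) for c in np.atleast_1d(chroms)])
    positions = np.atleast_1d(np.asarray(positions, dtype=np.int64))
    out = np.full(positions.shape, -1, dtype=np.int64)
    seg_chrom = segments["chrom"].to_numpy()
    seg_start = segments["start"].to_numpy()
    seg_end = segments["end"].to_numpy()
    row_idx = np.arange(len(segments))
    for chrom in np.unique(chroms):
        seg_mask = seg_chrom == chrom
        if not seg_mask.any():
            continue
        starts = seg_start[seg_mask]
        ends = seg_end[seg_mask]
        rows = row_idx[seg_mask]
        qmask = chroms == chrom
        pos = positions[qmask]
        k = np.searchsorted(starts, pos, side="right") - 1
        hit = (k >= 0) & (pos <= ends[np.clip(k, 0, None)])
        res = np.where(hit, rows[np.clip(k, 0, None)], -1)
        out[qmask] = res
    return out


def make_bins(genome, bin_size: int) -> pd.DataFrame:
    """Tile a genome with fixed-width bins (1-based inclusive coordinates).

    Returns a DataFrame with columns ``chrom, start, end, midpoint`` and a
    global ``bin_index``.
    """
    rows = []
    for chrom, length in genome:
        start = 1
        while start <= length:
            end = min(start + bin_size - 1, length)
            rows.append((normalize_chrom(chrom), start, end))
            start = end + 1
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    bins["midpoint"] = (bins["start"] + bins["end"]) // 2
    bins.index.name = "bin_index"
    return bins
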