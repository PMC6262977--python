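"""Segment-level copy-number arithmetic.

Aberration scoring against sample ploidy, the genomic instability index
(GII), purity/ploidy-adjusted logR, fixed-grid genome binning, cross-sample
gain/loss frequency profiles, and gene-level logR assignment.

Scores use a symmetric margin around the sample's (possibly non-integer)
ploidy: a segment is a gain when its total copy number exceeds
``ploidy + margin`` (strictly) and a deletion when it falls below
``ploidy - margin`` (strictly); gains and amplifications count as one
event. The GII is the fraction of probes sitting on aberrant segments.
Adjusted logR is ``gamma * log2(total_cn / ploidy)`` with the array-noise
factor gamma compressing the ratio the way array intensities do.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .profiles import SampleProfile, interval_lookup, make_bins, normalize_chrom

__all__ = [
    "aberration_score", "genomic_instability_index", "adjusted_logr",
    "bin_profile", "aberration_frequencies", "gene_logr", "gii_table",
    "make_bins",
]

log = logging.getLogger(__name__)


def aberration_score(total_cn, ploidy, margin: float = 0.6):
    """Score copy number against ploidy: +1 gain, -1 deletion, 0 neutral.

    Strict inequalities on both sides: ``total_cn`` exactly at
    ``ploidy + margin`` (or ``ploidy - margin``) is neutral.
    Accepts scalars or arrays; NaN propagates as NaN.
    """
    cn = np.asarray(total_cn, dtype=float)
    pl = np.asarray(ploidy, dtype=float)
    if np.any(cn[~np.isnan(cn)] < 0):
        raise ValueError("total_cn must be non-negative")
    if np.any(pl[~np.isnan(pl)] <= 0):
        raise ValueError("ploidy must be positive")
    score = np.where(cn > pl + margin, 1.0, np.where(cn < pl - margin, -1.0, 0.0))
    score = np.where(np.isnan(cn) | np.isnan(pl), np.nan, score)
    if score.ndim == 0:
        s = float(score)
        return int(s) if not np.isnan(s) else np.nan
    return score


def genomic_instability_index(profile: SampleProfile, margin: float = 0.6) -> float:
    """Fraction of probes on segments whose copy number deviates from ploidy."""
    seg = profile.segments
    if len(seg) == 0:
        raise ValueError("profile has no segments")
    scores = aberration_score(seg["total_cn"].to_numpy(), profile.ploidy, margin)
    probes = seg["n_probes"].to_numpy(float)
    valid = ~np.isnan(scores)
    total = probes[valid].sum()
    if total == 0:
        raise ValueError("profile has no scorable probes")
    return float(probes[valid][scores[valid] != 0].sum() / total)


def gii_table(profiles, margin: float = 0.6) -> pd.DataFrame:
    """GII for every profile, one row per sample."""
    rows = [
        {
            "sample_id": p.sample_id,
            "patient_id": p.patient_id,
            "timepoint_weeks": p.timepoint_weeks,
            "gii": genomic_instability_index(p, margin),
        }
        for p in profiles
    ]
    return pd.DataFrame(rows)


def adjusted_logr(total_cn, ploidy, gamma: float = 0.55, cn_floor: float = 0.05):
    """Purity/ploidy-adjusted logR: ``gamma * log2(total_cn / ploidy)``.

    Zero copy numbers are floored at ``cn_floor`` before the log so the
    value stays finite; a warning flags how many values were floored.
    """
    cn = np.asarray(total_cn, dtype=float)
    scalar = cn.ndim == 0
    cn = np.atleast_1d(cn).copy()
    if np.any(cn[~np.isnan(cn)] < 0):
        raise ValueError("total_cn must be non-negative")
    if np.any(np.asarray(ploidy, dtype=float) <= 0):
        raise ValueError("ploidy must be positive")
    floored = cn == 0
    if floored.any():
        warnings.warn(
            f"{int(floored.sum())} zero copy-number value(s) floored at {cn_floor} "
            "before log transform", stacklevel=2)
        cn[floored] = cn_floor
    out = gamma * np.log2(cn / ploidy)
    return float(out[0]) if scalar else out


def bin_profile(profile: SampleProfile, bins: pd.DataFrame,
                margin: float = 0.6) -> np.ndarray:
    """Per-bin aberration score; a bin takes the score of the segment
    covering its midpoint, NaN when no segment covers it."""
    idx = interval_lookup(profile.segments, bins["chrom"].to_numpy(),
                          bins["midpoint"].to_numpy())
    out = np.full(len(bins), np.nan)
    hit = idx >= 0
    if hit.any():
        cn = profile.segments["total_cn"].to_numpy()[idx[hit]]
        out[hit] = aberration_score(cn, profile.ploidy, margin)
    return out


def aberration_frequencies(profiles, bins: pd.DataFrame,
                           margin: float = 0.6) -> pd.DataFrame:
    """Percentage of profiles gained / lost per bin, among informative ones.

    Returns ``chrom, start, end, gain_pct, loss_pct, n_informative``.
    """
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    scores = np.vstack([bin_profile(p, bins, margin) for p in profiles])
    informative = ~np.isnan(scores)
    n_inf = informative.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        gain = 100.0 * np.nansum(scores == 1, axis=0) / n_inf
        loss = 100.0 * np.nansum(scores == -1, axis=0) / n_inf
    out = bins[["chrom", "start", "end"]].copy()
    out["gain_pct"] = np.where(n_inf > 0, gain, 0.0)
    out["loss_pct"] = np.where(n_inf > 0, loss, 0.0)
    out["n_informative"] = n_inf
    return out


def gene_logr(profile: SampleProfile, annotation: pd.DataFrame,
              gamma: float = 0.55, cn_floor: float = 0.05) -> pd.Series:
    """Adjusted logR per gene (segment covering the gene's midpoint).

    ``annotation`` needs columns ``gene, chrom, start, end`` (1-based
    inclusive). Genes on chromosomes absent from the profile draw a
    warning and come back NaN, as do genes in uncovered gaps.
    """
    ann = annotation.copy()
    ann["chrom"] = ann["chrom"].map(normalize_chrom)
    known = set(profile.segments["chrom"].unique())
    unknown = sorted(set(ann["chrom"]) - known)
    if unknown:
        log.warning("annotation chromosomes absent from profile %s: %s",
                    profile.sample_id, ", ".join(unknown))
    mid = (ann["start"].to_numpy(np.int64) + ann["end"].to_numpy(np.int64)) // 2
    idx = interval_lookup(profile.segments, ann["chrom"].to_numpy(), mid)
    values = np.full(len(ann), np.nan)
    hit = idx >= 0
    if hit.any():
        cn = profile.segments["total_cn"].to_numpy()[idx[hit]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            values[hit] = adjusted_logr(cn, profile.ploidy, gamma, cn_floor)
    return pd.Series(values, index=ann["gene"].to_numpy(), name=profile.sample_id)


def gene_logr_matrix(profiles, annotation: pd.DataFrame,
                     gamma: float = 0.55, cn_floor: float = 0.05) -> pd.DataFrame:
    """Genes x samples matrix of adjusted logR across profiles."""
    cols = {p.sample_id: gene_logr(p, annotation, gamma, cn_floor) for p in profiles}
    return pd.DataFrame(cols)
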