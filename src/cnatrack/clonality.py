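"""Clonal and subclonal dynamics across serial biopsies.

For each patient a reference sample is chosen (diagnosis if its profile is
good, else week 12, else the patient is excluded). On diploid references
(ploidy < 3) every segment with exactly one aberrant copy-number state —
clonal aberrant, or a subclonal mixture of one aberrant and one normal
state — becomes a tracked CNA, classed as gain, loss, or copy-neutral LOH
and flagged clonal or subclonal.

Assuming the per-cell aberrant state stays the same over time, the bulk
signal at a tracked segment is a three-way mixture of normal cells, tumor
cells without the CNA, and tumor cells carrying it:

    bulk_total = 2 (1 - ACF) + ACF * (2 + f * (state - 2))
    bulk_minor = 1 (1 - ACF) + ACF * (1 - f)          (LOH, total state 2)

which is solved for the carrier fraction ``f`` at each time point. Sample
ACF comes from the caller's estimate when the profile is good, otherwise
from the main peak of the kernel density of per-segment implied ACFs at
reference-clonal segments. Increases and decreases of ``f`` relative to
the reference (beyond a dead zone ``delta``) are summed across patients
per genome bin; under no selection increases and decreases are equally
likely, so the goodness-of-fit statistic (I - D)^2 / (I + D) is tested
against a chi-squared with one degree of freedom, with Benjamini-Hochberg
correction within each aberration class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clinical import resolve_nonaberrant_cellularity
from .config import AnalysisConfig
from .profiles import SampleProfile, interval_lookup
from .stats import benjamini_hochberg

log = logging.getLogger(__name__)

CNA_CLASSES = ("gain", "loss", "LOH")

TRACKED_COLUMNS = [
    "patient_id", "chrom", "start", "end", "cna_class",
    "state_total", "state_minor", "clonality", "f_ref",
]


def select_reference(profiles) -> SampleProfile | None:
    """Pick the patient's reference sample: week 0 if good, else week 12;
    None when neither yields a usable profile."""
    by_week = {p.timepoint_weeks: p for p in profiles}
    for week in (0, 12):
        p = by_week.get(week)
        if p is not None and p.quality == "good":
            return p
    return None


def implied_acf(observed_bulk_cn, aberrant_state):
    """Aberrant cell fraction implied by a clonal aberration's bulk signal:
    ``(bulk - 2) / (state - 2)``, clamped to [0, 1]."""
    state = np.asarray(aberrant_state, dtype=float)
    if np.any(state == 2):
        raise ValueError("aberrant state 2 carries no total-copy-number signal")
    bulk = np.asarray(observed_bulk_cn, dtype=float)
    rho = np.clip((bulk - 2.0) / (state - 2.0), 0.0, 1.0)
    return float(rho) if rho.ndim == 0 else rho


def estimate_sample_acf(profile: SampleProfile, reference_tracked: pd.DataFrame,
                        min_segments: int = 3, grid_step: float = 0.01,
                        peak_window: float = 0.02) -> float:
    """ACF of a sample: the caller's value for good profiles, otherwise the
    main density peak of per-segment implied ACFs.

    The density route evaluates a Gaussian KDE (Silverman bandwidth) of the
    ACFs implied by segments that were clonal gains/losses in the reference,
    on a fixed grid 0.01..1.00, and returns the median of the implied values
    within a small window of the peak (exact when the values are degenerate).
    Returns NaN when fewer than ``min_segments`` informative segments match.
    """
    if profile.quality == "good" and profile.acf_known:
        return float(profile.acf)
    informative = reference_tracked[
        (reference_tracked["clonality"] == "clonal")
        & (reference_tracked["state_total"] != 2)
    ]
    if len(informative) == 0:
        return float("nan")
    mid = (informative["start"].to_numpy(np.int64)
           + informative["end"].to_numpy(np.int64)) // 2
    idx = interval_lookup(profile.segments, informative["chrom"].to_numpy(), mid)
    hit = idx >= 0
    if hit.sum() < min_segments:
        log.info("sample %s: only %d informative segments for ACF estimation",
                 profile.sample_id, int(hit.sum()))
        return float("nan")
    bulk = profile.bulk_total_cn()[idx[hit]]
    values = implied_acf(bulk, informative["state_total"].to_numpy(float)[hit])
    if np.std(values) < 1e-9:
        return float(np.mean(values))
    grid = np.arange(grid_step, 1.0 + grid_step / 2, grid_step)
    kde = sps.gaussian_kde(values, bw_method="silverman")
    peak = float(grid[np.argmax(kde(grid))])
    near = values[np.abs(values - peak) <= max(peak_window, grid_step)]
    return float(np.median(near)) if near.size else peak


def categorize_segments(reference: SampleProfile,
                        diploid_ploidy_cut: float = 3.0) -> pd.DataFrame:
    """Tracked CNAs of a diploid reference profile.

    Keeps segments with exactly one aberrant copy-number state; the
    tracked aberration inherits that state, its class, and its reference
    carrier fraction (1 for clonal segments, the mixture fraction for
    subclonal ones).
    """
    if not np.isnan(reference.ploidy) and reference.ploidy >= diploid_ploidy_cut:
        raise ValueError(
            f"reference ploidy {reference.ploidy:.2f} >= {diploid_ploidy_cut}: "
            "patient not eligible for clonality tracking")
    seg = reference.segments
    s1t = np.round(seg["state1_total"].to_numpy(float))
    s1m = seg["state1_minor"].to_numpy(float)
    s1m = np.round(np.where(np.isnan(s1m), 1.0, s1m))  # unknown minor: not LOH
    s2t = seg["state2_total"].to_numpy(float)
    s2m = seg["state2_minor"].to_numpy(float)
    f1 = seg["frac_state1"].to_numpy(float)
    has1 = ~np.isnan(s1t)
    sub = has1 & ~np.isnan(s2t) & ~np.isnan(f1) & (f1 > 0) & (f1 < 1)
    s2m = np.where(np.isnan(s2m), 1.0, np.round(s2m))
    s2t = np.round(np.where(np.isnan(s2t), 2.0, s2t))

    def _aberrant(t, m):
        return (t != 2) | (m == 0)

    ab1 = has1 & _aberrant(s1t, s1m)
    ab2 = sub & _aberrant(s2t, s2m)
    # clonal rows: keep when the single state is aberrant; subclonal rows:
    # keep when exactly one of the two states is
    keep = np.where(sub, ab1 ^ ab2, ab1)
    if not keep.any():
        return pd.DataFrame(columns=TRACKED_COLUMNS)
    use1 = np.where(sub, ab1, True)[keep]
    tot = np.where(use1, s1t[keep], s2t[keep]).astype(int)
    minr = np.where(use1, s1m[keep], s2m[keep]).astype(int)
    frac = np.where(sub[keep],
                    np.where(use1, f1[keep], 1.0 - f1[keep]), 1.0)
    cls = np.where(tot > 2, "gain", np.where(tot < 2, "loss", "LOH"))
    return pd.DataFrame({
        "patient_id": reference.patient_id,
        "chrom": seg["chrom"].to_numpy()[keep],
        "start": seg["start"].to_numpy()[keep],
        "end": seg["end"].to_numpy()[keep],
        "cna_class": cls,
        "state_total": tot, "state_minor": minr,
        "clonality": np.where(sub[keep], "subclonal", "clonal"),
        "f_ref": frac,
    })


def track_cna_fraction(tracked: pd.DataFrame, profile: SampleProfile,
                       acf_t: float, min_acf: float = 0.01) -> np.ndarray:
    """Carrier fraction of each tracked CNA in ``profile``, clamped to [0,1].

    NaN when the tumor is effectively absent (``acf_t`` unknown or below
    ``min_acf``) or when no segment covers the tracked interval.
    """
    n = len(tracked)
    if np.isnan(acf_t) or acf_t < min_acf:
        return np.full(n, np.nan)
    mid = (tracked["start"].to_numpy(np.int64) + tracked["end"].to_numpy(np.int64)) // 2
    idx = interval_lookup(profile.segments, tracked["chrom"].to_numpy(), mid)
    out = np.full(n, np.nan)
    hit = idx >= 0
    if not hit.any():
        return out
    bulk_total = profile.bulk_total_cn()[idx[hit]]
    bulk_minor = profile.bulk_minor_cn()[idx[hit]]
    state = tracked["state_total"].to_numpy(float)[hit]
    is_loh = tracked["cna_class"].to_numpy()[hit] == "LOH"
    f = np.full(hit.sum(), np.nan)
    gl = ~is_loh
    with np.errstate(invalid="ignore", divide="ignore"):
        f[gl] = (bulk_total[gl] - 2.0) / (acf_t * (state[gl] - 2.0))
        f[is_loh] = (1.0 - bulk_minor[is_loh]) / acf_t
    out[hit] = np.clip(f, 0.0, 1.0)
    return out


def call_change(f_ref: float, f_t: float, delta: float = 0.05) -> str:
    """"increase" / "decrease" / "unchanged" of a carrier fraction relative
    to the reference; missing values are unchanged (excluded from counts)."""
    if np.isnan(f_ref) or np.isnan(f_t):
        return "unchanged"
    if f_t - f_ref > delta:
        return "increase"
    if f_ref - f_t > delta:
        return "decrease"
    return "unchanged"


def call_changes(f_ref: np.ndarray, f_t: np.ndarray,
                 delta: float = 0.05) -> np.ndarray:
    """Vectorized :func:`call_change`."""
    diff = np.asarray(f_t, float) - np.asarray(f_ref, float)
    out = np.full(diff.shape, "unchanged", dtype=object)
    with np.errstate(invalid="ignore"):
        out[diff > delta] = "increase"
        out[-diff > delta] = "decrease"
    return out


@dataclass
class ClonalityResult:
    """Everything the time-course engine produces for a cohort."""

    tracked: pd.DataFrame        # per tracked CNA, wide: f_ref + f/acf per week
    changes: pd.DataFrame        # long: one row per tracked CNA x follow-up
    selection: pd.DataFrame      # per bin x class: I, D, chi2, p, q, direction
    exclusions: list = field(default_factory=list)
    acf_estimates: pd.DataFrame | None = None


def track_patient(profiles, config: AnalysisConfig | None = None):
    """Track every eligible CNA of one patient across time points.

    Returns ``(tracked, changes, exclusion)`` where ``exclusion`` is None
    for analyzed patients or a dict with a reason code.
    """
    cfg = config or AnalysisConfig()
    profiles = list(profiles)
    patient_id = profiles[0].patient_id
    reference = select_reference(profiles)
    if reference is None:
        return None, None, {"patient_id": patient_id, "reason": "no_good_reference"}
    if not np.isnan(reference.ploidy) and reference.ploidy >= cfg.diploid_ploidy_cut:
        return None, None, {"patient_id": patient_id, "reason": "aneuploid_reference"}
    tracked = categorize_segments(reference, cfg.diploid_ploidy_cut)
    if len(tracked) == 0:
        return None, None, {"patient_id": patient_id, "reason": "no_trackable_cna"}
    tracked = tracked.copy()
    tracked["reference_week"] = reference.timepoint_weeks

    change_rows = []
    for p in profiles:
        if p.timepoint_weeks <= reference.timepoint_weeks:
            continue
        if p.quality == "non_aberrant":
            acf_t = resolve_nonaberrant_cellularity(
                p, p.pathologist_pct, profiles, cfg.aberration_margin)
            if acf_t == 0.0:
                # tumor gone: carrier fractions undefined, nothing to count
                acf_t = float("nan")
        else:
            acf_t = estimate_sample_acf(p, tracked)
        f_t = track_cna_fraction(tracked, p, acf_t, cfg.min_acf)
        tracked[f"f_wk{p.timepoint_weeks}"] = f_t
        tracked[f"acf_wk{p.timepoint_weeks}"] = acf_t
        calls = call_changes(tracked["f_ref"].to_numpy(), f_t, cfg.change_delta)
        chunk = tracked[["patient_id", "chrom", "start", "end",
                         "cna_class", "f_ref"]].copy()
        chunk["timepoint_weeks"] = p.timepoint_weeks
        chunk["acf_t"] = acf_t
        chunk["f_t"] = f_t
        chunk["change"] = calls
        change_rows.append(chunk)
    changes = (pd.concat(change_rows, ignore_index=True)
               if change_rows else pd.DataFrame())
    return tracked, changes, None


def _bins_spanned(bins: pd.DataFrame, chroms, starts, ends) -> list[np.ndarray]:
    """Global bin indices whose midpoints lie within each interval."""
    by_chrom = {
        c: (g["midpoint"].to_numpy(), g.index.to_numpy())
        for c, g in bins.groupby("chrom", sort=False)
    }
    out = []
    for chrom, start, end in zip(chroms, starts, ends):
        mids, idx = by_chrom.get(chrom, (np.array([]), np.array([], dtype=int)))
        lo = np.searchsorted(mids, start, side="left")
        hi = np.searchsorted(mids, end, side="right")
        out.append(idx[lo:hi])
    return out


def selection_scan(changes: pd.DataFrame, bins: pd.DataFrame,
                   cna_class: str, alpha: float = 0.05) -> pd.DataFrame:
    """Genome scan for bins under positive or negative selection.

    ``changes`` is the long table from :func:`track_patient` concatenated
    over patients. Increases (I) and decreases (D) of one aberration class
    are summed per bin over all patient/follow-up comparisons; each bin is
    tested with (I - D)^2 / (I + D) against chi-squared (1 df), and BH
    correction runs across the informative (I + D >= 1) bins of the class.
    """
    if cna_class not in CNA_CLASSES:
        raise ValueError(f"cna_class must be one of {CNA_CLASSES}")
    out = bins[["chrom", "start", "end"]].copy()
    out["cna_class"] = cna_class
    n_bins = len(bins)
    inc = np.zeros(n_bins, dtype=np.int64)
    dec = np.zeros(n_bins, dtype=np.int64)
    sub = changes[(changes["cna_class"] == cna_class)
                  & (changes["change"] != "unchanged")] if len(changes) else changes
    if len(sub):
        spans = _bins_spanned(bins, sub["chrom"].to_numpy(),
                              sub["start"].to_numpy(), sub["end"].to_numpy())
        is_inc = (sub["change"] == "increase").to_numpy()
        for span, up in zip(spans, is_inc):
            if up:
                inc[span] += 1
            else:
                dec[span] += 1
    out["n_increase"] = inc
    out["n_decrease"] = dec
    total = inc + dec
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(total > 0, (inc - dec) ** 2 / np.maximum(total, 1), np.nan)
    p = np.where(total > 0, sps.chi2.sf(chi2, df=1), np.nan)
    q = np.full(n_bins, np.nan)
    informative = total > 0
    if informative.any():
        q[informative] = benjamini_hochberg(np.clip(p[informative], 1e-300, 1.0))
    out["chi2"] = chi2
    out["p"] = p
    out["q"] = q
    direction = np.full(n_bins, "none", dtype=object)
    sig = informative & (q < alpha)
    direction[sig & (inc > dec)] = "positive"
    direction[sig & (dec > inc)] = "negative"
    out["direction"] = direction
    return out


def run_clonality(profiles, bins: pd.DataFrame,
                  config: AnalysisConfig | None = None) -> ClonalityResult:
    """Full time-course analysis of a cohort of profiles.

    ``profiles`` is a flat iterable of :class:`SampleProfile`; they are
    grouped by patient, tracked, and scanned per aberration class.
    """
    cfg = config or AnalysisConfig()
    by_patient: dict[str, list[SampleProfile]] = {}
    for p in profiles:
        by_patient.setdefault(p.patient_id, []).append(p)
    tracked_all, changes_all, exclusions = [], [], []
    for patient_id in sorted(by_patient):
        tracked, changes, excl = track_patient(by_patient[patient_id], cfg)
        if excl is not None:
            exclusions.append(excl)
            continue
        tracked_all.append(tracked)
        if len(changes):
            changes_all.append(changes)
    tracked_df = (pd.concat(tracked_all, ignore_index=True)
                  if tracked_all else pd.DataFrame(columns=TRACKED_COLUMNS))
    changes_df = (pd.concat(changes_all, ignore_index=True)
                  if changes_all else pd.DataFrame(
                      columns=["patient_id", "chrom", "start", "end", "cna_class",
                               "f_ref", "timepoint_weeks", "acf_t", "f_t", "change"]))
    selection = pd.concat(
        [selection_scan(changes_df, bins, cls, cfg.fdr_alpha)
         for cls in CNA_CLASSES],
        ignore_index=True)
    acfs = None
    if len(changes_df):
        acfs = (changes_df.groupby(["patient_id", "timepoint_weeks"])["acf_t"]
                .first().reset_index())
    return ClonalityResult(tracked=tracked_df, changes=changes_df,
                           selection=selection, exclusions=exclusions,
                           acf_estimates=acfs)
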