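"""Clinical derivations for the neoadjuvant time-course design.

Response ratio (tumor size at surgery over size at diagnosis), the
three-group response classification (GR / IR / NR by > 90% / 10-90% /
< 10% shrinkage), the manual-cellularity rule for samples whose
copy-number profile is non-aberrant, and the 11-gene proliferation score.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import AnalysisConfig, PAM50_PROLIFERATION_GENES
from .cna import aberration_score
from .profiles import SampleProfile

log = logging.getLogger(__name__)

RESPONSE_GROUPS = ("GR", "IR", "NR")


def response_ratio(size_dx: float, size_surgery: float) -> float:
    """Tumor size at surgery divided by tumor size at diagnosis."""
    if size_dx <= 0:
        raise ValueError("size at diagnosis must be positive")
    if size_surgery < 0:
        raise ValueError("size at surgery must be non-negative")
    return size_surgery / size_dx


def classify_response(rr: float, gr_cut: float = 0.10, nr_cut: float = 0.90) -> str:
    """GR when RR < ``gr_cut`` (> 90% shrinkage), NR when RR > ``nr_cut``
    (< 10% shrinkage), IR otherwise. Values exactly on a cut are IR: the
    extreme groups are defined by strict shrinkage bounds."""
    if rr < 0:
        raise ValueError("response ratio must be non-negative")
    if rr < gr_cut:
        return "GR"
    if rr > nr_cut:
        return "NR"
    return "IR"


def annotate_clinical(clinical: pd.DataFrame,
                      config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Add ``rr`` and ``response_group`` columns to a clinical table with
    ``size_dx`` and ``size_surgery`` columns."""
    cfg = config or AnalysisConfig()
    out = clinical.copy()
    out["rr"] = [
        response_ratio(dx, sx) for dx, sx in zip(out["size_dx"], out["size_surgery"])
    ]
    out["response_group"] = [
        classify_response(r, cfg.rr_gr_cut, cfg.rr_nr_cut) for r in out["rr"]
    ]
    return out


def _is_flat(profile: SampleProfile, margin: float = 0.6) -> bool:
    scores = aberration_score(
        profile.segments["total_cn"].to_numpy(), profile.ploidy, margin)
    return bool(np.all(scores[~np.isnan(scores)] == 0))


def resolve_nonaberrant_cellularity(profile: SampleProfile,
                                    pathologist_pct: float | None,
                                    sibling_profiles,
                                    margin: float = 0.6) -> float:
    """Manual tumor-cell-fraction call for a non-aberrant profile.

    Purity estimation needs aberrations to lock onto; when a profile is
    called non-aberrant the fraction is set manually: zero when the profile
    is flat and the pathologist saw 0% tumor cells; unknown (NaN) when the
    non-aberrant profile is at week 0 or 12 while other time points of the
    same patient are aberrant; otherwise unknown.
    """
    if profile.quality != "non_aberrant":
        raise ValueError("profile is not non-aberrant; nothing to resolve")
    if (pathologist_pct is not None and pathologist_pct == 0
            and _is_flat(profile, margin)):
        return 0.0
    if profile.timepoint_weeks in (0, 12):
        others_aberrant = any(
            p.quality != "non_aberrant" for p in sibling_profiles
            if p.timepoint_weeks != profile.timepoint_weeks)
        if others_aberrant:
            return float("nan")
    return float("nan")


def proliferation_score(expression: pd.DataFrame,
                        genes=PAM50_PROLIFERATION_GENES) -> pd.Series:
    """Mean normalized expression of the proliferation signature genes.

    ``expression`` is genes x samples. Genes missing from the matrix are
    skipped with a warning; if none are present this is an error.
    """
    genes = list(genes)
    present = [g for g in genes if g in expression.index]
    missing = [g for g in genes if g not in expression.index]
    if not present:
        raise ValueError("none of the proliferation genes are in the matrix")
    if missing:
        log.warning("proliferation genes missing from matrix: %s", ", ".join(missing))
    score = expression.loc[present].mean(axis=0)
    score.name = "proliferation_score"
    return score
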