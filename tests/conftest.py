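"""Shared fixtures: small synthetic cohorts and profile builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cnatrack as ct


def make_profile(segment_rows, sample_id="S1", patient_id="P1", week=0,
                 ploidy=2.0, acf=float("nan"), quality="good",
                 pathologist_pct=None) -> ct.SampleProfile:
    """Build a profile from (chrom, start, end, n_probes, total_cn[, minor_cn,
    state2_total, state2_minor, frac_state1]) tuples."""
    cols = ["chrom", "start", "end", "n_probes", "total_cn", "minor_cn",
            "state2_total", "state2_minor", "frac_state1"]
    rows = [list(r) + [np.nan] * (len(cols) - len(r)) for r in segment_rows]
    seg = pd.DataFrame(rows, columns=cols)
    return ct.SampleProfile(sample_id=sample_id, patient_id=patient_id,
                            timepoint_weeks=week, ploidy=ploidy, acf=acf,
                            quality=quality, segments=seg,
                            pathologist_pct=pathologist_pct)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """20-patient cohort with no observation noise: exact recovery regime."""
    cfg = ct.SimulationConfig(seed=11, n_patients=20,
                              noise_sd=0.0, minor_noise_sd=0.0)
    cohort, truth = ct.simulate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def default_cohort():
    """Default noisy 40-patient cohort."""
    cfg = ct.SimulationConfig(seed=13, n_patients=40)
    cohort, truth = ct.simulate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def default_bins(default_cohort):
    cfg, _, _ = default_cohort
    return ct.make_bins(cfg.genome, cfg.bin_size)
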