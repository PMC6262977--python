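"""Synthetic serial-biopsy cohort generator.

Emulates the upstream outputs of allele-specific copy-number callers for a
neoadjuvant time-course design: per-sample segment profiles that mix
normal and tumor cells, subclones whose carrier fractions change between
biopsies, optional planted loci under positive or negative selection,
response-dependent tumor-cellularity trajectories, an expression matrix
with a configurable fraction of genes coupled to gene-level logR, and a
clinical table — plus ground-truth tables for parameter-recovery tests.

Generative model
----------------
Each patient draws a treatment arm, a response group (GR/IR/NR), a
response ratio inside that group's range, and an aberrant-cell-fraction
(ACF) trajectory over weeks 0/12/25 whose mean depends on the response
group (good responders' tumor content collapses by surgery). Copy-number
aberrations are placed as contiguous bin runs on a diploid (or, for a
minority of patients, tetraploid) background; each is clonal or subclonal
with carrier fraction ``f``. The observed bulk copy number of a segment is
the mixture

    bulk = 2 (1 - ACF) + ACF * (base + f * (state - base)) + noise,

with Gaussian segment-level noise. Samples with a good profile store
purity-adjusted values plus the Battenberg-style subclonal state pair;
samples whose fit "failed" (poor quality) store raw bulk values.

Subclonal carrier fractions evolve between time points by bounded additive
steps; planted selection loci move by a fixed amount per interval instead.
The null generator (:func:`simulate_null_cohort`) draws each follow-up
sample's deviation independently and symmetrically around the reference
fraction, so increase and decrease calls are independent fair coin flips —
the regime the selection scan's chi-squared test assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig, SimulationConfig, PAM50_PROLIFERATION_GENES, save_config
from .profiles import SampleProfile, make_bins
from . import io as cio

WEEKS = (0, 12, 25)

_RR_RANGES = {"GR": (0.0, 0.0976), "IR": (0.106, 0.83), "NR": (0.903, 2.35)}

#: ACF below which the caller would have labelled the profile non-aberrant.
NON_ABERRANT_ACF = 0.02


@dataclass
class GroundTruth:
    """True parameters behind a simulated cohort."""

    patients: pd.DataFrame   # patient_id, arm, response_group, rr, ploidy
    samples: pd.DataFrame    # sample_id, patient_id, timepoint_weeks, true_acf
    tracked: pd.DataFrame    # per CNA: class, state, clonal, f per week
    genes: pd.DataFrame      # gene, coupled, slope, true_r
    selection: pd.DataFrame  # planted loci: bin_index, direction, change

    def write(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(d / "truth_patients.tsv", sep="\t", index=False)
        self.samples.to_csv(d / "truth_samples.tsv", sep="\t", index=False)
        self.tracked.to_csv(d / "truth_tracked.tsv", sep="\t", index=False)
        self.genes.to_csv(d / "truth_genes.tsv", sep="\t", index=False)
        self.selection.to_csv(d / "truth_selection.tsv", sep="\t", index=False)


@dataclass
class Cohort:
    """A simulated cohort in memory, in the pipeline's table formats."""

    segments: pd.DataFrame
    samples: pd.DataFrame
    clinical: pd.DataFrame
    expression: pd.DataFrame
    annotation: pd.DataFrame   # 1-based inclusive
    config: SimulationConfig

    def profiles(self) -> list[SampleProfile]:
        meta = {r["sample_id"]: r for _, r in self.samples.iterrows()}
        out = []
        for sample_id, seg in self.segments.groupby("sample_id", sort=False):
            m = meta[sample_id]
            out.append(SampleProfile(
                sample_id=sample_id,
                patient_id=m["patient_id"],
                timepoint_weeks=int(m["timepoint_weeks"]),
                ploidy=float(m["ploidy"]),
                acf=float(m["acf"]) if pd.notna(m["acf"]) else float("nan"),
                quality=m["quality"],
                pathologist_pct=(float(m["pathologist_pct"])
                                 if pd.notna(m["pathologist_pct"]) else None),
                segments=seg.drop(columns="sample_id").reset_index(drop=True),
            ))
        return out

    def write(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        cio.write_segments(self.segments, d / "segments.tsv")
        cio.write_samples(self.samples, d / "samples.tsv")
        cio.write_clinical(self.clinical, d / "clinical.csv")
        cio.write_expression(self.expression, d / "expression.tsv")
        cio.write_annotation(self.annotation, d / "genes.tsv")
        save_config(d / "config.yaml", simulation=self.config)


def _place_cnas(rng, cfg: SimulationConfig, bins: pd.DataFrame,
                diploid: bool) -> list[dict]:
    """Draw non-overlapping CNAs as bin runs for one patient."""
    n_bins = len(bins)
    chrom_of = bins["chrom"].to_numpy()
    occupied = np.zeros(n_bins, dtype=bool)
    cnas = []

    def try_add(b0, b1, **kw):
        if occupied[b0:b1 + 1].any():
            return False
        occupied[b0:b1 + 1] = True
        cnas.append(dict(bin_first=b0, bin_last=b1, **kw))
        return True

    if cfg.dense_subclonal_coverage:
        for b in range(n_bins):
            try_add(b, b, cna_class="gain", state_total=3, state_minor=1,
                    clonal=False, f0=rng.uniform(0.2, 0.8), planted=None)
        return cnas

    base = 2 if diploid else 4
    for bin_idx, direction, change in cfg.selection_loci:
        if rng.random() >= cfg.selection_patient_fraction:
            continue
        f0 = rng.uniform(0.2, 0.35) if direction == "positive" else rng.uniform(0.65, 0.8)
        try_add(bin_idx, bin_idx, cna_class="gain", state_total=base + 1,
                state_minor=1 if diploid else 2, clonal=False, f0=f0,
                planted=(direction, abs(change)))

    n_cnas = rng.poisson(cfg.cna_rate)
    for _ in range(n_cnas):
        for _attempt in range(20):
            b0 = int(rng.integers(0, n_bins))
            length = min(int(rng.geometric(0.5)) - 1, cfg.max_cna_bins - 1)
            b1 = b0
            while b1 < n_bins - 1 and b1 - b0 < length and chrom_of[b1 + 1] == chrom_of[b0]:
                b1 += 1
            cls = rng.choice(["gain", "loss", "LOH"], p=cfg.class_probs)
            if cls == "LOH" and not diploid:
                cls = "gain"
            if cls == "gain":
                s_tot = base + (2 if rng.random() < 0.2 else 1)
                s_min = 1 if diploid else 2
            elif cls == "loss":
                s_tot = base - 1
                s_min = 0 if diploid else 1
            else:
                s_tot, s_min = 2, 0
            clonal = rng.random() < cfg.clonal_fraction
            f0 = 1.0 if clonal else float(rng.uniform(0.2, 0.8))
            if try_add(b0, b1, cna_class=cls, state_total=int(s_tot),
                       state_minor=int(s_min), clonal=clonal, f0=f0, planted=None):
                break
    return cnas


def _evolve_fractions(rng, cfg: SimulationConfig, cnas: list[dict]) -> None:
    """Fill f at weeks 0/12/25 for every CNA, in place."""
    for cna in cnas:
        f0 = cna["f0"]
        if cna["planted"] is not None:
            direction, change = cna["planted"]
            sign = 1.0 if direction == "positive" else -1.0
            fs = [np.clip(f0 + sign * change * k, 0.0, 1.0) for k in range(3)]
        elif cna["clonal"]:
            fs = [1.0, 1.0, 1.0]
        elif cfg.null_model:
            # independent symmetric deviation of each follow-up around f0
            fs = [f0] + [float(np.clip(f0 + rng.normal(0.0, cfg.drift_sd), 0.0, 1.0))
                         for _ in range(2)]
        else:
            fs = [f0]
            for _ in range(2):
                fs.append(float(np.clip(fs[-1] + rng.normal(0.0, cfg.drift_sd), 0.0, 1.0)))
        cna["f"] = dict(zip(WEEKS, fs))


def _sample_segment_table(rng, cfg: SimulationConfig, bins: pd.DataFrame,
                          cnas: list[dict], week: int, rho: float,
                          base_total: int, base_minor: int, quality: str):
    """Build one sample's segment rows plus its true per-bin tumor CN."""
    n_bins = len(bins)
    avg_tot = np.full(n_bins, float(base_total))
    avg_min = np.full(n_bins, float(base_minor))
    cna_id = np.full(n_bins, -1)
    for k, cna in enumerate(cnas):
        f = cna["f"][week]
        sl = slice(cna["bin_first"], cna["bin_last"] + 1)
        cna_id[sl] = k
        avg_tot[sl] = base_total + f * (cna["state_total"] - base_total)
        avg_min[sl] = base_minor + f * (cna["state_minor"] - base_minor)

    bulk_tot = 2.0 * (1.0 - rho) + rho * avg_tot
    bulk_min = 1.0 * (1.0 - rho) + rho * avg_min

    # segment = run of bins with the same CNA identity on one chromosome
    chrom = bins["chrom"].to_numpy()
    new_seg = np.ones(n_bins, dtype=bool)
    new_seg[1:] = (cna_id[1:] != cna_id[:-1]) | (chrom[1:] != chrom[:-1])
    seg_start_bins = np.flatnonzero(new_seg)
    seg_end_bins = np.append(seg_start_bins[1:] - 1, n_bins - 1)

    n_seg = len(seg_start_bins)
    eps_t = rng.normal(0.0, cfg.noise_sd, n_seg) if cfg.noise_sd > 0 else np.zeros(n_seg)
    eps_m = (rng.normal(0.0, cfg.minor_noise_sd, n_seg)
             if cfg.minor_noise_sd > 0 else np.zeros(n_seg))
    bt = np.maximum(bulk_tot[seg_start_bins] + eps_t, 0.0)
    bm = np.clip(bulk_min[seg_start_bins] + eps_m, 0.0, bt)
    seg_cna = cna_id[seg_start_bins]
    f_of = np.array([c["f"][week] for c in cnas]) if cnas else np.empty(0)
    if quality == "good" and rho >= NON_ABERRANT_ACF:
        tot = np.maximum((bt - 2.0 * (1.0 - rho)) / rho, 0.0)
        minr = np.clip((bm - (1.0 - rho)) / rho, 0.0, tot)
        f_seg = (np.where(seg_cna >= 0, f_of[np.maximum(seg_cna, 0)], np.nan)
                 if len(f_of) else np.full(n_seg, np.nan))
        is_sub = (seg_cna >= 0) & (f_seg > 0.0) & (f_seg < 1.0)
        s2t = np.where(is_sub, float(base_total), np.nan)
        s2m = np.where(is_sub, float(base_minor), np.nan)
        f1 = np.where(is_sub, f_seg, np.nan)
    else:  # poor or non_aberrant: raw bulk, no state fit
        tot, minr = bt, bm
        s2t = s2m = f1 = np.full(n_seg, np.nan)
    seg = pd.DataFrame({
        "chrom": chrom[seg_start_bins],
        "start": bins["start"].to_numpy()[seg_start_bins],
        "end": bins["end"].to_numpy()[seg_end_bins],
        "n_probes": cfg.probes_per_bin * (seg_end_bins - seg_start_bins + 1),
        "total_cn": tot, "minor_cn": minr,
        "state2_total": s2t, "state2_minor": s2m, "frac_state1": f1,
    })
    return seg, avg_tot


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a full cohort and its ground truth. Deterministic in
    ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    bins = make_bins(cfg.genome, cfg.bin_size)
    n_bins = len(bins)
    for bin_idx, direction, _ in cfg.selection_loci:
        if not 0 <= bin_idx < n_bins:
            raise ValueError(f"selection locus bin {bin_idx} outside genome")
        if direction not in ("positive", "negative"):
            raise ValueError("selection direction must be positive or negative")

    annotation = _make_annotation(rng, cfg, bins)

    seg_chunks, sample_rows, clin_rows = [], [], []
    truth_samples, truth_tracked, truth_patients = [], [], []
    expr_cols = {}
    true_logr_cols = {}  # noise-free per-gene logR, for ground-truth r
    gii_true = {}

    for i in range(cfg.n_patients):
        pid = f"P{i + 1:03d}"
        arm = "combination" if rng.random() < cfg.arm_fraction else "chemotherapy"
        group = str(rng.choice(["GR", "IR", "NR"], p=cfg.response_mix))
        lo, hi = _RR_RANGES[group]
        rr = float(rng.uniform(lo, hi))
        size_dx = float(cfg.size_dx_median * np.exp(rng.normal(0.0, cfg.size_dx_sigma)))
        size_surgery = rr * size_dx
        pcr = bool(group == "GR" and rng.random() < cfg.pcr_given_gr)
        diploid = not (rng.random() < cfg.aneuploid_fraction
                       and not cfg.dense_subclonal_coverage)
        base_total, base_minor = (2, 1) if diploid else (4, 2)

        means = cfg.purity_trajectory[group]
        rho = {w: float(np.clip(rng.normal(means[k], cfg.purity_spread), 0.0, 0.95))
               for k, w in enumerate(WEEKS)}

        cnas = _place_cnas(rng, cfg, bins, diploid)
        _evolve_fractions(rng, cfg, cnas)

        # Battenberg-style profile quality per time point
        u = rng.random()
        if u < cfg.both_poor_prob:
            qual = {0: "poor", 12: "poor"}
        elif u < cfg.both_poor_prob + cfg.ref_week0_poor_prob:
            qual = {0: "poor", 12: "good"}
        else:
            qual = {0: "good",
                    12: "good" if rng.random() < cfg.followup_good_prob else "poor"}
        qual[25] = "good" if rng.random() < cfg.followup_good_prob else "poor"

        present = {w: not (w > 0 and rng.random() < cfg.missing_followup_prob)
                   for w in WEEKS}

        for week in WEEKS:
            if not present[week]:
                continue
            quality = qual[week]
            if rho[week] < NON_ABERRANT_ACF:
                quality = "non_aberrant"
            seg, avg_tot = _sample_segment_table(
                rng, cfg, bins, cnas, week, rho[week], base_total, base_minor, quality)
            sample_id = f"{pid}_wk{week}"
            seg.insert(0, "sample_id", sample_id)
            seg_chunks.append(seg)
            # sample ploidy as a caller would report it: probe-weighted mean
            # of the stored copy numbers (tumor-level for good profiles,
            # bulk-level when the fit failed)
            ploidy = float(np.average(seg["total_cn"], weights=seg["n_probes"]))
            tumor_ploidy = float(np.mean(avg_tot))
            dev = np.abs(avg_tot - tumor_ploidy) > 0.6
            gii_true[sample_id] = float(np.mean(dev))
            pct = 0.0 if rho[week] < 0.005 else round(100 * rho[week])
            sample_rows.append({
                "sample_id": sample_id, "patient_id": pid,
                "timepoint_weeks": week, "ploidy": ploidy,
                "acf": rho[week] if quality == "good" else np.nan,
                "quality": quality,
                "pathologist_pct": pct if quality == "non_aberrant" else np.nan,
            })
            truth_samples.append({
                "sample_id": sample_id, "patient_id": pid,
                "timepoint_weeks": week, "true_acf": rho[week],
            })
            expr, logr_true = _expression_column(
                rng, cfg, annotation, avg_tot, ploidy, gii_true[sample_id])
            expr_cols[sample_id] = expr
            if week == 0:
                true_logr_cols[sample_id] = logr_true

        clin_rows.append({
            "patient_id": pid, "arm": arm, "size_dx": size_dx,
            "size_surgery": size_surgery, "pcr": pcr,
        })
        truth_patients.append({
            "patient_id": pid, "arm": arm, "response_group": group, "rr": rr,
            "ploidy": float(base_total), "diploid": diploid,
        })
        for cna in cnas:
            truth_tracked.append({
                "patient_id": pid,
                "chrom": bins["chrom"].iloc[cna["bin_first"]],
                "start": int(bins["start"].iloc[cna["bin_first"]]),
                "end": int(bins["end"].iloc[cna["bin_last"]]),
                "bin_first": cna["bin_first"], "bin_last": cna["bin_last"],
                "cna_class": cna["cna_class"], "state_total": cna["state_total"],
                "state_minor": cna["state_minor"], "clonal": cna["clonal"],
                "planted": cna["planted"][0] if cna["planted"] else "",
                "f_wk0": cna["f"][0], "f_wk12": cna["f"][12], "f_wk25": cna["f"][25],
            })

    segments = pd.concat(seg_chunks, ignore_index=True)
    samples = pd.DataFrame(sample_rows)
    clinical = pd.DataFrame(clin_rows)
    expression = pd.DataFrame(expr_cols, index=annotation["gene"])
    truth_genes = annotation[["gene", "coupled", "slope"]].copy()
    truth_genes["true_r"] = _true_r(cfg, truth_genes, true_logr_cols)

    cohort = Cohort(segments=segments, samples=samples, clinical=clinical,
                    expression=expression,
                    annotation=annotation[["gene", "chrom", "start", "end"]],
                    config=cfg)
    truth = GroundTruth(
        patients=pd.DataFrame(truth_patients),
        samples=pd.DataFrame(truth_samples),
        tracked=pd.DataFrame(truth_tracked),
        genes=truth_genes,
        selection=pd.DataFrame(
            [{"bin_index": b, "direction": d, "change": c}
             for b, d, c in cfg.selection_loci],
            columns=["bin_index", "direction", "change"]),
    )
    return cohort, truth


def _make_annotation(rng, cfg: SimulationConfig, bins: pd.DataFrame) -> pd.DataFrame:
    """Random gene placement: regular genes plus the proliferation panel."""
    n_bins = len(bins)
    names = [f"G{k:04d}" for k in range(cfg.n_genes)] + list(PAM50_PROLIFERATION_GENES)
    rows = []
    coupled_cut = int(round(cfg.expr_coupling_fraction * cfg.n_genes))
    for k, name in enumerate(names):
        b = int(rng.integers(0, n_bins))
        mid = int(bins["midpoint"].iloc[b])
        is_prolif = k >= cfg.n_genes
        coupled = (k < coupled_cut) and not is_prolif
        rows.append({
            "gene": name, "chrom": bins["chrom"].iloc[b],
            "start": max(mid - 5000, 1), "end": mid + 5000,
            "bin_index": b, "coupled": coupled,
            "slope": cfg.expr_slope if coupled else 0.0,
            "proliferation": is_prolif,
        })
    return pd.DataFrame(rows)


def _expression_column(rng, cfg: SimulationConfig, annotation: pd.DataFrame,
                       avg_tot: np.ndarray, ploidy: float, gii: float):
    """One sample's expression vector, coupled to true tumor-dosage logR.

    Returns ``(expression, true_logr)``; proliferation-panel genes track
    the sample's true genomic instability instead of local dosage.
    """
    logr = 0.55 * np.log2(np.maximum(avg_tot[annotation["bin_index"]], 0.05) / ploidy)
    base = 2.0 + annotation["slope"].to_numpy() * logr
    prolif = annotation["proliferation"].to_numpy()
    base[prolif] = 1.0 + 3.0 * gii
    return base + rng.normal(0.0, cfg.expr_noise_sd, len(base)), logr


def _true_r(cfg: SimulationConfig, truth_genes: pd.DataFrame,
            true_logr_cols: dict) -> np.ndarray:
    """Population Pearson r between expression and logR per gene, given
    the realized noise-free logR spread across the diagnosis samples:
    ``r = s * sd(x) / sqrt(s^2 var(x) + sigma^2)``; zero for uncoupled or
    dosage-invariant genes."""
    if not true_logr_cols:
        return np.zeros(len(truth_genes))
    x = np.column_stack(list(true_logr_cols.values()))
    sd = x.std(axis=1)
    s = truth_genes["slope"].to_numpy()
    denom = np.sqrt(s ** 2 * sd ** 2 + cfg.expr_noise_sd ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where((sd > 0) & (denom > 0), s * sd / denom, 0.0)
    return r


def simulate_null_cohort(config: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """Same generative process, but no locus is under selection: follow-up
    carrier fractions deviate independently and symmetrically around the
    reference fraction."""
    cfg = replace(config, null_model=True, selection_loci=())
    return simulate_cohort(cfg)


def calibration_config(seed: int, n_patients: int = 40) -> SimulationConfig:
    """Study conditions for null calibration of the selection scan:
    a 100-bin genome with one subclonal gain per bin per patient, good
    profiles throughout (the chain under test is counting + chi-squared +
    BH), default observation noise."""
    return SimulationConfig(
        seed=seed, n_patients=n_patients,
        genome=tuple((str(c), 10_000_000) for c in range(1, 11)),
        dense_subclonal_coverage=True, null_model=True,
        aneuploid_fraction=0.0, ref_week0_poor_prob=0.0, both_poor_prob=0.0,
        followup_good_prob=1.0, missing_followup_prob=0.0,
    )


def selection_power_config(seed: int, change: float = 0.3,
                           n_patients: int = 40,
                           patient_fraction: float = 0.8) -> SimulationConfig:
    """Study conditions for the selection-scan power check: one planted
    positively selected bin and one mirrored negatively selected bin, on
    the default genome with the default mixed-quality cohort."""
    return SimulationConfig(
        seed=seed, n_patients=n_patients,
        selection_loci=((43, "positive", change), (150, "negative", change)),
        selection_patient_fraction=patient_fraction,
    )
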