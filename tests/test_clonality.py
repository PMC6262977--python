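"""Time-course engine: reference choice, ACF estimation, tracking, scan."""

import numpy as np
import pandas as pd
import pytest

import cnatrack as ct
from cnatrack.clonality import call_changes

from conftest import make_profile


def _patient(qualities):
    """Profiles for one patient with given quality by week."""
    return [make_profile([("1", 1, 1_000_000, 100, 3.0)], sample_id=f"P_wk{w}",
                         week=w, acf=0.5, quality=q)
            for w, q in qualities.items()]


class TestSelectReference:
    def test_good_week0_wins(self):
        ref = ct.select_reference(_patient({0: "good", 12: "good"}))
        assert ref.timepoint_weeks == 0

    def test_poor_week0_falls_back_to_week12(self):
        ref = ct.select_reference(_patient({0: "poor", 12: "good"}))
        assert ref.timepoint_weeks == 12

    def test_both_poor_excluded(self):
        assert ct.select_reference(_patient({0: "poor", 12: "poor"})) is None


class TestImpliedAcf:
    @pytest.mark.parametrize("bulk,state,expected", [
        (2.6, 3, 0.6),
        (2.0, 3, 0.0),
        (1.4, 1, 0.6),
    ])
    def test_mixture_identity(self, bulk, state, expected):
        assert ct.implied_acf(bulk, state) == pytest.approx(expected)

    def test_neutral_state_rejected(self):
        with pytest.raises(ValueError):
            ct.implied_acf(2.0, 2)


def _reference_with_clonal_gains(n_segments, state=3):
    rows = [("1", 1 + i * 1_000_000, (i + 1) * 1_000_000, 100, float(state))
            for i in range(n_segments)]
    ref = make_profile(rows, week=0, acf=0.7, quality="good")
    return ref, ct.categorize_segments(ref)


def _bulk_profile(tracked, rho, f=1.0, noise=0.0, rng=None, week=12):
    """Follow-up profile storing raw bulk values (poor quality)."""
    rows = []
    for _, t in tracked.iterrows():
        bulk = 2 * (1 - rho) + rho * (2 + f * (t["state_total"] - 2))
        if rng is not None and noise > 0:
            bulk += rng.normal(0, noise)
        rows.append(("1", t["start"], t["end"], 100, bulk))
    return make_profile(rows, week=week, quality="poor")


class TestEstimateSampleAcf:
    def test_noise_free_recovers_exactly(self):
        _, tracked = _reference_with_clonal_gains(10)
        sample = _bulk_profile(tracked, rho=0.4)
        assert ct.estimate_sample_acf(sample, tracked) == pytest.approx(0.4, abs=1e-9)

    def test_good_profile_passthrough(self):
        ref, tracked = _reference_with_clonal_gains(10)
        assert ct.estimate_sample_acf(ref, tracked) == 0.7

    def test_too_few_segments_unknown(self):
        _, tracked = _reference_with_clonal_gains(2)
        sample = _bulk_profile(tracked, rho=0.4)
        assert np.isnan(ct.estimate_sample_acf(sample, tracked))

    def test_noisy_mode_within_tolerance(self):
        # density main peak lands within 0.05 of truth in >= 95% of samples
        rng = np.random.default_rng(21)
        _, tracked = _reference_with_clonal_gains(30)
        hits = 0
        for _ in range(100):
            sample = _bulk_profile(tracked, rho=0.4, noise=0.05, rng=rng)
            est = ct.estimate_sample_acf(sample, tracked)
            hits += abs(est - 0.4) <= 0.05
        assert hits >= 95


class TestCategorizeSegments:
    def test_clonal_gain(self):
        ref = make_profile([("1", 1, 1_000_000, 100, 3.0, 1.0)])
        tracked = ct.categorize_segments(ref)
        row = tracked.iloc[0]
        assert (row["cna_class"], row["clonality"], row["f_ref"]) == \
            ("gain", "clonal", 1.0)

    def test_subclonal_loss_mixture(self):
        # 40% of tumor cells at state 1 (minor 0), 60% at normal 2
        ref = make_profile([
            ("1", 1, 1_000_000, 100, 1.6, 0.6, 2.0, 1.0, 0.4)])
        row = ct.categorize_segments(ref).iloc[0]
        assert (row["cna_class"], row["clonality"]) == ("loss", "subclonal")
        assert row["f_ref"] == pytest.approx(0.4)

    def test_clonal_loh(self):
        ref = make_profile([("1", 1, 1_000_000, 100, 2.0, 0.0)])
        row = ct.categorize_segments(ref).iloc[0]
        assert (row["cna_class"], row["clonality"]) == ("LOH", "clonal")

    def test_normal_segment_not_tracked(self):
        ref = make_profile([("1", 1, 1_000_000, 100, 2.0, 1.0)])
        assert len(ct.categorize_segments(ref)) == 0

    def test_aneuploid_reference_rejected(self):
        ref = make_profile([("1", 1, 1_000_000, 100, 4.0, 2.0)], ploidy=4.0)
        with pytest.raises(ValueError):
            ct.categorize_segments(ref)


class TestTrackFraction:
    tracked = pd.DataFrame([{
        "patient_id": "P", "chrom": "1", "start": 1, "end": 1_000_000,
        "cna_class": "gain", "state_total": 3, "state_minor": 1,
        "clonality": "subclonal", "f_ref": 0.3}])

    def test_gain_mixture_identity(self):
        p = make_profile([("1", 1, 1_000_000, 100, 2.25)], quality="poor", week=12)
        f = ct.track_cna_fraction(self.tracked, p, acf_t=0.5)
        assert f[0] == pytest.approx(0.5)

    def test_neutral_bulk_gives_zero(self):
        p = make_profile([("1", 1, 1_000_000, 100, 2.0)], quality="poor", week=12)
        assert ct.track_cna_fraction(self.tracked, p, acf_t=0.5)[0] == 0.0

    def test_loh_solved_on_minor_allele(self):
        loh = self.tracked.assign(cna_class="LOH", state_total=2, state_minor=0)
        # bulk minor = 1 - acf*f = 1 - 0.5*0.6 = 0.7
        p = make_profile([("1", 1, 1_000_000, 100, 2.0, 0.7)],
                         quality="poor", week=12)
        assert ct.track_cna_fraction(loh, p, acf_t=0.5)[0] == pytest.approx(0.6)

    def test_absent_tumor_missing(self):
        p = make_profile([("1", 1, 1_000_000, 100, 2.25)], quality="poor", week=12)
        assert np.isnan(ct.track_cna_fraction(self.tracked, p, acf_t=0.0)[0])
        assert np.isnan(ct.track_cna_fraction(self.tracked, p,
                                              acf_t=float("nan"))[0])

    def test_good_profile_adjusted_values_roundtrip(self):
        # adjusted CN 2.5 at ACF 0.5 is bulk 2.25: same carrier fraction
        p = make_profile([("1", 1, 1_000_000, 100, 2.5)], acf=0.5,
                         quality="good", week=12)
        assert ct.track_cna_fraction(self.tracked, p, 0.5)[0] == pytest.approx(0.5)


class TestCallChange:
    @pytest.mark.parametrize("f_ref,f_t,expected", [
        (0.3, 0.6, "increase"),
        (0.6, 0.3, "decrease"),
        (0.50, 0.52, "unchanged"),
        (float("nan"), 0.5, "unchanged"),
    ])
    def test_dead_zone(self, f_ref, f_t, expected):
        assert ct.call_change(f_ref, f_t, 0.05) == expected

    def test_vectorized_matches_scalar(self):
        fr = np.array([0.3, 0.6, 0.5, np.nan])
        ft = np.array([0.6, 0.3, 0.52, 0.5])
        expected = [ct.call_change(a, b, 0.05) for a, b in zip(fr, ft)]
        assert list(call_changes(fr, ft, 0.05)) == expected


def _changes_frame(n_inc, n_dec, cna_class="gain"):
    rows = []
    for i in range(n_inc + n_dec):
        rows.append({
            "patient_id": f"P{i}", "chrom": "1", "start": 1, "end": 1_000_000,
            "cna_class": cna_class, "f_ref": 0.3, "timepoint_weeks": 12,
            "acf_t": 0.5, "f_t": 0.6 if i < n_inc else 0.1,
            "change": "increase" if i < n_inc else "decrease"})
    return pd.DataFrame(rows)


class TestSelectionScan:
    bins = ct.make_bins([("1", 2_000_000)], 1_000_000)

    def test_thirteen_increases_no_decreases(self):
        res = ct.selection_scan(_changes_frame(13, 0), self.bins, "gain")
        row = res.iloc[0]
        assert row["chi2"] == pytest.approx(13.0)
        # independent upper-tail evaluation through the complementary error
        # function: P(chi2_1 > x) = erfc(sqrt(x/2))
        from scipy.special import erfc
        assert row["p"] == pytest.approx(erfc(np.sqrt(13 / 2)), rel=1e-10)
        assert row["p"] == pytest.approx(3.11e-4, rel=0.01)
        assert row["direction"] == "positive"

    def test_balanced_counts_not_selected(self):
        res = ct.selection_scan(_changes_frame(7, 7), self.bins, "gain")
        row = res.iloc[0]
        assert row["chi2"] == 0.0
        assert row["p"] == pytest.approx(1.0)
        assert row["direction"] == "none"

    def test_swapping_labels_flips_directions(self):
        fwd = ct.selection_scan(_changes_frame(13, 2), self.bins, "gain")
        rev_changes = _changes_frame(13, 2)
        rev_changes["change"] = rev_changes["change"].map(
            {"increase": "decrease", "decrease": "increase"})
        rev = ct.selection_scan(rev_changes, self.bins, "gain")
        assert np.allclose(fwd["p"].dropna(), rev["p"].dropna())
        assert fwd.iloc[0]["direction"] == "positive"
        assert rev.iloc[0]["direction"] == "negative"

    def test_uninformative_bins_excluded_from_bh(self):
        res = ct.selection_scan(_changes_frame(13, 0), self.bins, "gain")
        assert np.isnan(res.iloc[1]["p"]) and np.isnan(res.iloc[1]["q"])

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            ct.selection_scan(_changes_frame(1, 0), self.bins, "amplification")


class TestCohortTracking:
    def test_noise_free_round_trip(self, noiseless_cohort):
        cfg, cohort, truth = noiseless_cohort
        bins = ct.make_bins(cfg.genome, cfg.bin_size)
        res = ct.run_clonality(cohort.profiles(), bins)
        merged = truth.tracked.merge(
            res.tracked, on=["patient_id", "chrom", "start", "end"],
            suffixes=("_true", ""))
        assert len(merged) == len(res.tracked) > 50
        for wk in (12, 25):
            col = f"f_wk{wk}"
            if col not in merged:
                continue
            sub = merged.dropna(subset=[col])
            assert len(sub) > 20
            assert np.abs(sub[col] - sub[f"{col}_true"]).max() < 1e-6
        acf = res.acf_estimates.merge(truth.samples,
                                      on=["patient_id", "timepoint_weeks"])
        acf = acf.dropna(subset=["acf_t"])
        assert len(acf) > 10
        assert np.abs(acf["acf_t"] - acf["true_acf"]).max() < 1e-6

    def test_at_most_two_counts_per_patient_per_bin(self, default_cohort,
                                                    default_bins):
        cfg, cohort, _ = default_cohort
        res = ct.run_clonality(cohort.profiles(), default_bins)
        counted = res.changes[res.changes["change"] != "unchanged"]
        per = counted.groupby(
            ["patient_id", "cna_class", "chrom", "start", "end"]).size()
        assert per.max() <= 2

    def test_recovery_rmse_monotone_in_noise(self):
        def rmse(noise_sd, seed):
            cfg = ct.SimulationConfig(seed=seed, n_patients=15,
                                      noise_sd=noise_sd,
                                      minor_noise_sd=noise_sd / 2)
            cohort, truth = ct.simulate_cohort(cfg)
            bins = ct.make_bins(cfg.genome, cfg.bin_size)
            res = ct.run_clonality(cohort.profiles(), bins)
            merged = truth.tracked.merge(
                res.tracked, on=["patient_id", "chrom", "start", "end"],
                suffixes=("_true", ""))
            errs = []
            for wk in (12, 25):
                col = f"f_wk{wk}"
                if col in merged:
                    sub = merged.dropna(subset=[col])
                    errs.extend((sub[col] - sub[f"{col}_true"]).to_numpy())
            return float(np.sqrt(np.mean(np.square(errs))))

        levels = [0.0, 0.02, 0.05, 0.1]
        means = [np.mean([rmse(s, seed) for seed in (31, 32, 33)])
                 for s in levels]
        assert means[0] < 1e-9
        assert all(b >= a - 0.005 for a, b in zip(means, means[1:]))
        assert means[-1] > means[0]
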