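"""End-to-end orchestration: cohort files in, result tables out.

Stage order: response classification -> GII and aberration frequencies ->
proliferation score and GII group comparisons -> expression-correlation
filter -> differential logR (GR vs NR) -> clonality dynamics -> selection
scan. Every run writes a manifest with the config snapshot, input
checksums, per-stage row counts and every exclusion with a reason code.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import __version__
from . import io as cio
from .clinical import annotate_clinical, proliferation_score
from .clonality import run_clonality
from .cna import aberration_frequencies, gene_logr_matrix, gii_table
from .config import AnalysisConfig
from .profiles import make_bins
from .stats import (compare_gii_groups, differential_logr,
                    expression_correlation_filter, merge_significant_regions,
                    pearson_correlation)

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _genome_from_profiles(profiles) -> list[tuple[str, int]]:
    """Infer chromosome extents from the union of all segment tables."""
    ends: dict[str, int] = {}
    for p in profiles:
        for chrom, grp in p.segments.groupby("chrom", sort=False):
            ends[chrom] = max(ends.get(chrom, 0), int(grp["end"].max()))
    return list(ends.items())


def run_pipeline(input_dir, out_dir, config: AnalysisConfig | None = None,
                 seed: int = 0, make_plots: bool = True) -> Path:
    """Run every stage on a cohort directory; returns the result directory."""
    cfg = config or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": dataclasses.asdict(cfg),
        "inputs": {},
        "stages": {},
        "exclusions": [],
    }
    input_dir = Path(input_dir)
    for name in ("segments.tsv", "samples.tsv", "clinical.csv",
                 "expression.tsv", "genes.tsv"):
        path = input_dir / name
        if path.exists():
            manifest["inputs"][name] = cio.file_checksum(path)

    def stage(name):
        def deco(fn):
            def run(*a, **k):
                try:
                    result = fn(*a, **k)
                except Exception as exc:
                    manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                    _write_manifest(out, manifest)
                    raise StageError(name, exc) from exc
                return result
            return run
        return deco

    cohort = stage("load")(cio.load_cohort)(input_dir)
    profiles = cohort.profiles
    manifest["stages"]["load"] = {
        "status": "ok", "n_samples": len(profiles), "n_patients":
        len(cohort.clinical),
    }

    @stage("clinical")
    def _clinical():
        clin = annotate_clinical(cohort.clinical, cfg)
        cio.write_clinical(clin, out / "clinical_results.csv")
        return clin

    clinical = _clinical()
    manifest["stages"]["clinical"] = {
        "status": "ok",
        "group_sizes": clinical["response_group"].value_counts().to_dict(),
    }

    @stage("gii_frequencies")
    def _score():
        gii = gii_table(profiles, cfg.aberration_margin)
        gii.to_csv(out / "gii.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        genome = _genome_from_profiles(profiles)
        bins = make_bins(genome, cfg.bin_size)
        freq_chunks = []
        for week in (0, 12, 25):
            subset = [p for p in profiles if p.timepoint_weeks == week]
            if not subset:
                continue
            freq = aberration_frequencies(subset, bins, cfg.aberration_margin)
            freq.insert(0, "timepoint_weeks", week)
            freq_chunks.append(freq)
        freqs = pd.concat(freq_chunks, ignore_index=True)
        freqs.to_csv(out / "frequencies.tsv", sep="\t", index=False,
                     float_format=_FLOAT_FMT)
        return gii, bins, freqs

    gii, bins, freqs = _score()
    manifest["stages"]["gii_frequencies"] = {"status": "ok", "n_bins": len(bins)}

    @stage("proliferation_comparisons")
    def _comparisons():
        wk0 = gii[gii["timepoint_weeks"] == 0].merge(
            clinical[["patient_id", "response_group", "pcr"]], on="patient_id")
        score = proliferation_score(cohort.expression, cfg.proliferation_genes)
        score.to_frame().to_csv(out / "proliferation.tsv", sep="\t",
                                index_label="sample_id", float_format=_FLOAT_FMT)
        comp = {}
        try:
            t = compare_gii_groups(wk0["gii"], np.where(wk0["pcr"], "pCR", "non-pCR"),
                                   equal_var=not cfg.welch)
            comp["gii_pcr_ttest"] = dataclasses.asdict(t)
        except ValueError as exc:
            comp["gii_pcr_ttest"] = {"error": str(exc)}
        try:
            a = compare_gii_groups(wk0["gii"], wk0["response_group"])
            comp["gii_response_anova"] = dataclasses.asdict(a)
        except ValueError as exc:
            comp["gii_response_anova"] = {"error": str(exc)}
        paired = wk0.set_index("sample_id").join(score, how="inner").dropna(
            subset=["gii", "proliferation_score"])
        if len(paired) >= 3 and paired["gii"].std() > 0 \
                and paired["proliferation_score"].std() > 0:
            r, p = pearson_correlation(paired["gii"], paired["proliferation_score"])
            comp["gii_proliferation_pearson"] = {"r": r, "p": p, "n": len(paired)}
        with open(out / "comparisons.json", "w") as fh:
            json.dump(comp, fh, indent=2, default=float)
        return comp

    _comparisons()
    manifest["stages"]["proliferation_comparisons"] = {"status": "ok"}

    @stage("differential")
    def _differential():
        week = cfg.filter_timepoint_weeks
        subset = [p for p in profiles
                  if p.timepoint_weeks == week and p.quality == "good"]
        skipped = [p.sample_id for p in profiles
                   if p.timepoint_weeks == week and p.quality != "good"]
        for sid in skipped:
            manifest["exclusions"].append(
                {"sample_id": sid, "stage": "differential",
                 "reason": "profile_not_adjustable"})
        logr = gene_logr_matrix(subset, cohort.annotation, cfg.gamma, cfg.cn_floor)
        filt = expression_correlation_filter(
            logr, cohort.expression, cfg.expr_corr_threshold)
        filt.to_csv(out / "expression_filter.tsv", sep="\t",
                    float_format=_FLOAT_FMT)
        kept = filt.index[filt["kept"]]
        group_of = clinical.set_index("patient_id")["response_group"]
        labels = pd.Series({
            p.sample_id: group_of.get(p.patient_id) for p in subset})
        empty = pd.DataFrame(columns=[
            "mean_logR_GR", "mean_logR_NR", "n_GR", "n_NR", "t_stat", "p",
            "direction", "q", "significant", "expr_corr",
            "chrom", "start", "end"])
        empty.index.name = "gene"
        try:
            results = differential_logr(logr.loc[kept], labels,
                                        equal_var=not cfg.welch,
                                        alpha=cfg.fdr_alpha)
        except ValueError as exc:
            # an extreme response group can be empty in small cohorts: the
            # comparison is undefined, not a failure
            log.warning("differential test skipped: %s", exc)
            empty.to_csv(out / "differential.tsv", sep="\t")
            empty.iloc[:0, :4].to_csv(out / "regions.tsv", sep="\t", index=False)
            return empty, empty.iloc[:0, :4], str(exc)
        results = results.join(filt["r"].rename("expr_corr"))
        ann = cohort.annotation.set_index("gene")
        results = results.join(ann[["chrom", "start", "end"]])
        results.to_csv(out / "differential.tsv", sep="\t", index_label="gene",
                       float_format=_FLOAT_FMT)
        regions = merge_significant_regions(results, cohort.annotation, bins)
        regions.to_csv(out / "regions.tsv", sep="\t", index=False)
        return results, regions, None

    diff_results, regions, diff_skip = _differential()
    manifest["stages"]["differential"] = {
        "status": "ok", "n_tested": len(diff_results),
        "n_significant": int(diff_results["significant"].sum())
        if "significant" in diff_results and len(diff_results) else 0,
        "n_regions": len(regions),
        **({"skipped": diff_skip} if diff_skip else {}),
    }

    @stage("clonality")
    def _clonality():
        res = run_clonality(profiles, bins, cfg)
        res.tracked.to_csv(out / "tracked_cna.tsv", sep="\t", index=False,
                           float_format=_FLOAT_FMT)
        res.changes.to_csv(out / "changes.tsv", sep="\t", index=False,
                           float_format=_FLOAT_FMT)
        res.selection.to_csv(out / "selection.tsv", sep="\t", index=False,
                             float_format=_FLOAT_FMT)
        if res.acf_estimates is not None:
            res.acf_estimates.to_csv(out / "acf_estimates.tsv", sep="\t",
                                     index=False, float_format=_FLOAT_FMT)
        return res

    clonality = _clonality()
    for excl in clonality.exclusions:
        manifest["exclusions"].append({**excl, "stage": "clonality"})
    manifest["stages"]["clonality"] = {
        "status": "ok",
        "n_patients_analyzed": clonality.tracked["patient_id"].nunique()
        if len(clonality.tracked) else 0,
        "n_patients_excluded": len(clonality.exclusions),
        "n_tracked_cna": len(clonality.tracked),
    }

    if make_plots:
        @stage("plots")
        def _plots():
            _plot_frequencies(freqs, out / "frequencies.png")
            _plot_selection(clonality.selection, out / "selection.png")

        _plots()
        manifest["stages"]["plots"] = {"status": "ok"}

    _write_manifest(out, manifest)
    return out


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _plot_frequencies(freqs: pd.DataFrame, path: Path) -> None:
    weeks = sorted(freqs["timepoint_weeks"].unique())
    fig, axes = plt.subplots(len(weeks), 1, figsize=(10, 2.2 * len(weeks)),
                             sharex=True, squeeze=False)
    for ax, week in zip(axes[:, 0], weeks):
        sub = freqs[freqs["timepoint_weeks"] == week].reset_index(drop=True)
        ax.bar(sub.index, sub["gain_pct"], color="firebrick", width=1.0)
        ax.bar(sub.index, -sub["loss_pct"], color="seagreen", width=1.0)
        ax.set_ylabel(f"wk {week}\n% gain / loss")
        ax.set_ylim(-100, 100)
    axes[-1, 0].set_xlabel("genome bin")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_selection(selection: pd.DataFrame, path: Path) -> None:
    classes = [c for c in ("gain", "loss", "LOH")
               if (selection["cna_class"] == c).any()]
    fig, axes = plt.subplots(len(classes), 1, figsize=(10, 2.2 * len(classes)),
                             sharex=True, squeeze=False)
    for ax, cls in zip(axes[:, 0], classes):
        sub = selection[selection["cna_class"] == cls].reset_index(drop=True)
        net = sub["n_increase"] - sub["n_decrease"]
        ax.bar(sub.index, net, color="grey", width=1.0)
        sig = sub["direction"] != "none"
        if sig.any():
            ax.scatter(sub.index[sig], net[sig], color="red", s=12, zorder=3)
        ax.set_ylabel(f"{cls}\nI - D")
    axes[-1, 0].set_xlabel("genome bin")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def report(result_dir) -> str:
    """Plain-text summary of a completed run (idempotent)."""
    d = Path(result_dir)
    if not (d / "manifest.json").exists():
        raise FileNotFoundError(f"{d} does not contain a completed run")
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    failed = [k for k, v in manifest["stages"].items()
              if v.get("status") != "ok"]
    if failed:
        raise RuntimeError(f"run incomplete: failed stages {failed}")
    lines = ["# cnatrack run report", ""]
    clin = pd.read_csv(d / "clinical_results.csv")
    counts = clin["response_group"].value_counts()
    lines.append("Response groups: " + ", ".join(
        f"{g}={counts.get(g, 0)}" for g in ("GR", "IR", "NR")))
    gii = pd.read_csv(d / "gii.tsv", sep="\t")
    wk0 = gii[gii["timepoint_weeks"] == 0].merge(
        clin[["patient_id", "response_group"]], on="patient_id")
    lines.append("Mean GII at diagnosis by group: " + ", ".join(
        f"{g}={m:.3f}" for g, m in
        wk0.groupby("response_group")["gii"].mean().items()))
    if (d / "comparisons.json").exists():
        with open(d / "comparisons.json") as fh:
            comp = json.load(fh)
        anova = comp.get("gii_response_anova", {})
        if "p" in anova:
            lines.append(f"GII ~ response group ANOVA: F={anova['statistic']:.3f}, "
                         f"p={anova['p']:.4g}")
        pear = comp.get("gii_proliferation_pearson", {})
        if "r" in pear:
            lines.append(f"GII vs proliferation: r={pear['r']:.3f}, "
                         f"p={pear['p']:.4g} (n={pear['n']})")
    diff = pd.read_csv(d / "differential.tsv", sep="\t")
    if len(diff) == 0:
        lines.append("Differential genes: no testable genes")
    else:
        sig = diff[diff["significant"]]
        lines.append(
            f"Differential genes (q < alpha): {len(sig)} of {len(diff)} tested")
        top = diff.nsmallest(10, "q")[["gene", "t_stat", "p", "q", "direction"]]
        lines.append("Top differential genes:")
        lines.extend("  " + "  ".join(f"{v:.4g}" if isinstance(v, float) else str(v)
                                      for v in row)
                     for row in top.itertuples(index=False))
    sel = pd.read_csv(d / "selection.tsv", sep="\t")
    informative = sel[(sel["n_increase"] + sel["n_decrease"]) > 0]
    if len(informative) == 0:
        lines.append("Selection scan: no bins tested")
    else:
        hits = informative[informative["direction"] != "none"]
        lines.append(f"Selection scan: {len(informative)} informative bins, "
                     f"{len(hits)} under selection (q < alpha)")
        for row in hits.sort_values("q").head(10).itertuples(index=False):
            lines.append(
                f"  {row.cna_class} chr{row.chrom}:{row.start}-{row.end} "
                f"I={row.n_increase} D={row.n_decrease} chi2={row.chi2:.2f} "
                f"q={row.q:.3g} {row.direction}")
    text = "\n".join(lines) + "\n"
    with open(d / "report.txt", "w") as fh:
        fh.write(text)
    return text
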