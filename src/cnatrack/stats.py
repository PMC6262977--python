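"""Statistics layer: expression-correlation filtering, differential
adjusted-logR testing between extreme response groups, GII group
comparisons, and Benjamini-Hochberg correction.

The per-gene differential test is the classic pooled-variance two-sample
t-test (Welch available via ``equal_var=False``), with BH step-up
correction across the tested genes. The expression filter keeps genes
whose adjusted logR correlates with mRNA expression (pairwise-complete
Pearson r at or above the threshold); it doubles as a germline-CNV screen,
since copy-number polymorphisms with little expression effect fail it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up q-values, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def expression_correlation_filter(gene_logr: pd.DataFrame,
                                  expression: pd.DataFrame,
                                  threshold: float = 0.5,
                                  min_pairs: int = 3) -> pd.DataFrame:
    """Correlate each gene's adjusted logR with its expression and filter.

    Both matrices are genes x samples; only shared genes and samples are
    used, and pairs with a missing value on either side are dropped per
    gene. Genes with fewer than ``min_pairs`` complete pairs, or zero
    variance on either side, are dropped (r undefined).

    Returns a DataFrame indexed by gene with columns ``r, n_pairs, kept``.
    """
    shared_samples = gene_logr.columns.intersection(expression.columns)
    shared_genes = gene_logr.index.intersection(expression.index)
    if len(shared_samples) < min_pairs:
        raise ValueError("need at least %d shared samples" % min_pairs)
    lr = gene_logr.loc[shared_genes, shared_samples].to_numpy(float)
    ex = expression.loc[shared_genes, shared_samples].to_numpy(float)
    rows = []
    for g, gene in enumerate(shared_genes):
        ok = ~np.isnan(lr[g]) & ~np.isnan(ex[g])
        n = int(ok.sum())
        if n < min_pairs:
            log.warning("gene %s dropped: only %d complete pairs", gene, n)
            rows.append((gene, np.nan, n, False))
            continue
        x, y = lr[g, ok], ex[g, ok]
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((gene, np.nan, n, False))
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append((gene, r, n, r >= threshold))
    out = pd.DataFrame(rows, columns=["gene", "r", "n_pairs", "kept"])
    return out.set_index("gene")


def differential_logr(gene_logr: pd.DataFrame, labels: pd.Series,
                      equal_var: bool = True, alpha: float = 0.05) -> pd.DataFrame:
    """Two-sided t-test of mean adjusted logR, GR versus NR, per gene.

    ``labels`` maps sample id -> "GR" / "NR" (other labels are ignored).
    Genes with fewer than two non-missing values in either group are
    skipped. Returns a DataFrame indexed by gene with group means, t, p,
    BH q, a significance flag at ``alpha``, and the direction of the
    difference (``gain_in_GR`` when mean logR is higher in GR).
    """
    labels = labels.reindex(gene_logr.columns)
    gr_cols = labels[labels == "GR"].index
    nr_cols = labels[labels == "NR"].index
    if len(gr_cols) < 2 or len(nr_cols) < 2:
        raise ValueError("need at least 2 samples per extreme group")
    rows = []
    for gene, values in gene_logr.iterrows():
        a = values[gr_cols].dropna().to_numpy(float)
        b = values[nr_cols].dropna().to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            log.info("gene %s skipped: group too small after missing removal", gene)
            continue
        if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(a, b, equal_var=equal_var)
        rows.append({
            "gene": gene,
            "mean_logR_GR": a.mean(), "mean_logR_NR": b.mean(),
            "n_GR": len(a), "n_NR": len(b),
            "t_stat": float(t), "p": float(min(max(p, np.nextafter(0, 1)), 1.0)),
            "direction": "gain_in_GR" if a.mean() >= b.mean() else "loss_in_GR",
        })
    if not rows:
        raise ValueError("no testable genes")
    out = pd.DataFrame(rows).set_index("gene")
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out


def merge_significant_regions(results: pd.DataFrame, annotation: pd.DataFrame,
                              bins: pd.DataFrame) -> pd.DataFrame:
    """Collapse significant genes into unique genomic regions.

    Genes whose midpoints fall in the same or adjacent bins merge into one
    region; returns one row per region with its gene list and span.
    """
    from .profiles import interval_lookup  # local import to avoid cycle

    sig = results[results["significant"]]
    if len(sig) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_genes", "genes"])
    ann = annotation.set_index("gene").loc[sig.index.intersection(annotation["gene"])]
    mid = ((ann["start"] + ann["end"]) // 2).to_numpy(np.int64)
    bin_idx = interval_lookup(bins, ann["chrom"].to_numpy(), mid)
    ann = ann.assign(bin_index=bin_idx).loc[lambda d: d["bin_index"] >= 0]
    ann = ann.sort_values("bin_index")
    regions = []
    current = None
    for gene, row in ann.iterrows():
        if current is not None and row["bin_index"] <= current["last_bin"] + 1 \
                and row["chrom"] == current["chrom"]:
            current["last_bin"] = row["bin_index"]
            current["end"] = max(current["end"], int(row["end"]))
            current["genes"].append(gene)
        else:
            if current is not None:
                regions.append(current)
            current = {"chrom": row["chrom"], "start": int(row["start"]),
                       "end": int(row["end"]), "last_bin": row["bin_index"],
                       "genes": [gene]}
    regions.append(current)
    out = pd.DataFrame([
        {"chrom": r["chrom"], "start": r["start"], "end": r["end"],
         "n_genes": len(r["genes"]), "genes": ",".join(map(str, r["genes"]))}
        for r in regions
    ])
    return out


@dataclass
class GroupComparison:
    """A t-test (two groups) or one-way ANOVA (three or more)."""

    kind: str  # "t" or "anova"
    statistic: float
    p: float
    group_means: dict
    group_sizes: dict


def compare_gii_groups(values, labels, equal_var: bool = True) -> GroupComparison:
    """Compare mean GII across groups: pooled t-test for two groups,
    one-way ANOVA for three or more."""
    df = pd.DataFrame({"value": np.asarray(values, float),
                       "label": np.asarray(labels)}).dropna()
    groups = {k: g["value"].to_numpy() for k, g in df.groupby("label")}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 members each")
    arrays = list(groups.values())
    if len(groups) == 2:
        if all(np.var(a) == 0 for a in arrays) and arrays[0].mean() == arrays[1].mean():
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.ttest_ind(*arrays, equal_var=equal_var)
        kind = "t"
    else:
        if all(np.var(a) == 0 for a in arrays) and len({a.mean() for a in arrays}) == 1:
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.f_oneway(*arrays)
        kind = "anova"
    return GroupComparison(
        kind=kind, statistic=float(stat), p=float(p),
        group_means={k: float(v.mean()) for k, v in groups.items()},
        group_sizes={k: int(len(v)) for k, v in groups.items()},
    )
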