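"""Configuration objects for the analysis pipeline and the cohort simulator.

Two dataclasses hold every tunable: :class:`AnalysisConfig` for the analysis
stages (aberration margin, array-noise factor gamma, correlation and FDR
thresholds, response-ratio cuts) and :class:`SimulationConfig` for the
synthetic-cohort generator. Both round-trip through YAML so a single config
file can drive a full run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

#: The 11 proliferation genes of the PAM50 signature ("NUF" in some listings
#: is the historical alias of NUF2, the NDC80-complex partner).
PAM50_PROLIFERATION_GENES = (
    "CCNB1", "UBE2C", "BIRC5", "NDC80", "CDC20", "PTTG1",
    "RRM2", "MKI67", "TYMS", "CEP55", "NUF2",
)

#: Default desk-scale genome: 22 autosome-like chromosomes of 10 Mb each.
DEFAULT_GENOME: tuple[tuple[str, int], ...] = tuple(
    (str(c), 10_000_000) for c in range(1, 23)
)


@dataclass
class AnalysisConfig:
    """Thresholds and constants used across the analysis stages.

    Attributes
    ----------
    aberration_margin:
        Distance from sample ploidy beyond which a segment's total copy
        number is called a gain (above) or a deletion (below). Default 0.6.
    gamma:
        Array-noise attenuation factor applied to log2 copy-number ratios
        when computing adjusted logR. Default 0.55.
    expr_corr_threshold:
        Minimum Pearson correlation between a gene's adjusted logR and its
        mRNA expression for the gene to pass the expression filter.
    change_delta:
        Minimum absolute change in carrier fraction (relative to the
        reference sample) to call an increase or decrease; smaller moves are
        "unchanged" and excluded from selection-scan counts.
    rr_gr_cut, rr_nr_cut:
        Response-ratio cuts: RR < ``rr_gr_cut`` is a good response (GR,
        > 90% shrinkage), RR > ``rr_nr_cut`` no response (NR, < 10%
        shrinkage); everything else (boundaries included) is intermediate.
    diploid_ploidy_cut:
        Reference samples with ploidy below this value are treated as
        diploid and enter the clonal-dynamics analysis.
    fdr_alpha:
        Benjamini-Hochberg q-value cut for significance.
    cn_floor:
        Copy-number floor substituted for zero before the log transform.
    min_acf:
        Aberrant cell fractions below this are treated as "tumor absent"
        when back-solving carrier fractions (the division is ill-posed).
    welch:
        If True use Welch's t-test instead of classic pooled-variance.
    filter_timepoint_weeks:
        Time point (weeks) whose samples are used for the expression
        correlation filter and the differential test; the untreated
        (diagnosis) samples by default.
    """

    aberration_margin: float = 0.6
    gamma: float = 0.55
    expr_corr_threshold: float = 0.5
    change_delta: float = 0.05
    rr_gr_cut: float = 0.10
    rr_nr_cut: float = 0.90
    diploid_ploidy_cut: float = 3.0
    fdr_alpha: float = 0.05
    bin_size: int = 1_000_000
    cn_floor: float = 0.05
    min_acf: float = 0.01
    welch: bool = False
    filter_timepoint_weeks: int = 0
    proliferation_genes: tuple[str, ...] = PAM50_PROLIFERATION_GENES

    def __post_init__(self) -> None:
        if not 0 < self.aberration_margin < 1:
            raise ValueError("aberration_margin must be in (0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not 0 < self.expr_corr_threshold < 1:
            raise ValueError("expr_corr_threshold must be in (0, 1)")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if isinstance(self.proliferation_genes, list):
            self.proliferation_genes = tuple(self.proliferation_genes)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic serial-biopsy cohort generator.

    The generator emulates the outputs of allele-specific copy-number
    callers (purity/ploidy-annotated segment profiles, subclonal state
    mixtures) for a neoadjuvant time-course design with biopsies at weeks
    0, 12 and 25, together with a coupled expression matrix and a clinical
    table. See :mod:`cnatrack.simulate`.
    """

    seed: int = 0
    n_patients: int = 40
    genome: tuple[tuple[str, int], ...] = DEFAULT_GENOME
    bin_size: int = 1_000_000
    probes_per_bin: int = 100
    arm_fraction: float = 0.5
    # GR/IR/NR mix matching the trial's 33/68/22 split.
    response_mix: tuple[float, float, float] = (33 / 123, 68 / 123, 22 / 123)
    # Per-group mean ACF at weeks 0/12/25; good responders' tumor content
    # collapses by surgery, non-responders keep theirs.
    purity_trajectory: dict = field(default_factory=lambda: {
        "GR": (0.65, 0.25, 0.0),
        "IR": (0.60, 0.45, 0.35),
        "NR": (0.60, 0.55, 0.50),
    })
    purity_spread: float = 0.08
    aneuploid_fraction: float = 0.15
    n_subclones_per_tumor: tuple[int, int] = (1, 3)
    cna_rate: float = 10.0
    clonal_fraction: float = 0.6
    max_cna_bins: int = 5
    class_probs: tuple[float, float, float] = (0.45, 0.45, 0.10)  # gain/loss/LOH
    drift_sd: float = 0.15
    selection_loci: tuple = ()  # (bin_index, direction, change per interval)
    selection_patient_fraction: float = 1.0
    noise_sd: float = 0.05
    minor_noise_sd: float = 0.025
    expr_coupling_fraction: float = 0.3
    expr_slope: float = 2.0
    expr_noise_sd: float = 0.2
    n_genes: int = 200
    ref_week0_poor_prob: float = 0.10
    both_poor_prob: float = 0.05
    followup_good_prob: float = 0.5
    missing_followup_prob: float = 0.05
    pcr_given_gr: float = 2 / 3
    size_dx_median: float = 40.0
    size_dx_sigma: float = 0.3
    dense_subclonal_coverage: bool = False
    null_model: bool = False

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if abs(sum(self.response_mix) - 1.0) > 1e-9:
            raise ValueError("response_mix must sum to 1")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.bin_size < self.probes_per_bin:
            raise ValueError("bins smaller than one probe are not meaningful")
        if self.noise_sd < 0 or self.expr_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        for frac in (self.arm_fraction, self.clonal_fraction,
                     self.expr_coupling_fraction, self.selection_patient_fraction,
                     self.aneuploid_fraction, self.followup_good_prob):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        self.genome = tuple((str(c), int(n)) for c, n in self.genome)
        self.selection_loci = tuple(
            (int(b), str(d), float(c)) for b, d, c in self.selection_loci
        )


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(path, analysis: AnalysisConfig | None = None,
                simulation: SimulationConfig | None = None) -> None:
    """Write one YAML file with ``analysis`` and/or ``simulation`` sections."""
    doc = {}
    if analysis is not None:
        doc["analysis"] = _to_plain(asdict(analysis))
    if simulation is not None:
        doc["simulation"] = _to_plain(asdict(simulation))
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> tuple[AnalysisConfig, SimulationConfig]:
    """Read a YAML config; missing sections fall back to defaults."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    analysis = AnalysisConfig(**doc.get("analysis", {}))
    sim_kwargs = dict(doc.get("simulation", {}))
    simulation = SimulationConfig(**sim_kwargs)
    return analysis, simulation
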