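"""Generate a synthetic serial-biopsy cohort and inspect its files.

The generator emulates the outputs of allele-specific copy-number callers
for a neoadjuvant time-course: segment profiles at weeks 0/12/25 mixing
normal and tumor cells, subclones whose carrier fractions drift between
biopsies, response-dependent tumor-cellularity trajectories, an expression
matrix coupled to gene dosage, and a clinical table — plus ground truth.
"""

import cnatrack as ct

cfg = ct.SimulationConfig(seed=1, n_patients=12)
cohort, truth = ct.simulate_cohort(cfg)

cohort.write("scratch_example_cohort")
truth.write("scratch_example_cohort/truth")

print(f"patients: {cfg.n_patients}, samples: {len(cohort.samples)}")
print(f"segment rows: {len(cohort.segments)}, genes: {len(cohort.annotation)}")
print("\nsample metadata (first biopsies):")
print(cohort.samples.head(6).to_string(index=False))
print("\nground-truth tracked CNAs of one patient:")
cols = ["chrom", "start", "end", "cna_class", "state_total", "clonal",
        "f_wk0", "f_wk12", "f_wk25"]
print(truth.tracked.query("patient_id == 'P001'")[cols].to_string(index=False))

# Each tracked CNA's carrier fraction (f_wk*) is the fraction of tumor
# cells bearing it at each time point; the analysis layer tries to recover
# exactly these numbers from the observed bulk copy-number tables.
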