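"""Full pipeline run: eligibility -> episodes -> scores -> models.

Writes every analysis artifact (baseline table, stratified ratio panels,
model table, patient-by-pathogen matrix, provenance) as CSV/JSON into
./pipeline_out, then prints the biomarker rows of the baseline table.
"""

from burncohort import generate_cohort, run_full

patients, infections = generate_cohort(seed=3)
res = run_full(patients, infections, "pipeline_out", seed=3, n_boot=2000)

baseline = res["baseline"]
row = baseline.set_index("variable").loc["tnf-alpha/il-10 ratio"]
print(f"TNF-alpha/IL-10 ratio: non-case {row['noncase']}, "
      f"case {row['case']}, t-test p = {row['p']:.4f}")
print(f"artifacts: {sorted(res.keys())} -> ./pipeline_out/")
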