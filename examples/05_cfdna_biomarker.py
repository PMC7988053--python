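"""The cfDNA biomarker: hyper:hypo DMR overlap ratio vs time to progression.

Simulates a 20-patient cohort whose circulating-DNA DMRs carry a graded
amount of neuroendocrine methylation signal, counts DMRs containing
called hypermethylated DMPs, correlates the per-patient hyper:hypo hit
ratio with time to clinical progression, and checks one patient's
overlap against a probe-resampling null.
"""

import methylstage as ms

manifest = ms.generate_manifest(n_probes=20000, n_genes=800, seed=7)
design = ms.default_study_design(n_planted=800)
matrix, truth = ms.generate_beta_matrix(manifest, design, seed=11)
filtered, _ = ms.filter_probes(matrix, manifest)
comparison = design.comparisons[-1]
dmps = ms.call_dmps(filtered, comparison)
query = dmps.loc[dmps["direction"] == "hyper"]
print(f"query set: {len(query)} hypermethylated {comparison.name} DMPs")

patients, outcomes, truth = ms.generate_cohort(truth, manifest, 20, seed=5)
ratios = ms.cohort_ratios(query, patients, manifest)
table = ratios.merge(outcomes, on="patient_id")
print(table[["patient_id", "n_hyper_hit", "n_hypo_hit", "ratio", "ttp_days"]]
      .round(2).to_string(index=False))

res = ms.correlate_ttp(ratios, outcomes)
print(f"\nSpearman rho(ratio, TTP) = {res['rho']:.3f}, p = {res['p']:.2g}, "
      f"n = {res['n']}")
print("-> patients whose cfDNA is enriched for hypermethylated DMRs at "
      "the query CpGs progress faster (negative correlation).")

strong = patients[-1]  # highest planted signal fraction
null = ms.resampling_null(query, manifest, strong, n_iter=10000, seed=1)
print(f"\nresampling null for {strong.patient_id}: "
      f"p_obs={null.p_obs:.4f}, p0={null.p0:.4f}, z={null.z:.2f}, "
      f"p={null.p_value:.2g} ({null.n_iter} resamples of {null.n} probes)")
print("-> the observed DMP-in-DMR fraction far exceeds random probe sets: "
      "the overlap is not chance.")
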