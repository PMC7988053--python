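"""Set algebra across the staged comparisons.

Which probes change methylation at *every* disease transition, and how
often does the direction of change switch between the emergence of
castration resistance and the neuroendocrine transition?
"""

import methylstage as ms

manifest = ms.generate_manifest(n_probes=20000, n_genes=800, seed=7)
design = ms.default_study_design(n_planted=800)
matrix, truth = ms.generate_beta_matrix(manifest, design, seed=11)
filtered, _ = ms.filter_probes(matrix, manifest)

by_name = {c.name: ms.call_dmps(filtered, c) for c in design.comparisons}
for name, dmps in by_name.items():
    print(f"{name}: {len(dmps)} DMPs")

vs_ln = [by_name[n] for n in ("CRPC_vs_LN", "ADENO_vs_LN", "NE1_vs_LN", "NE2_vs_LN")]
common = ms.common_dmps(vs_ln, mode="same_direction")
print(f"\nDMPs shared by all vs-LN comparisons (same direction): "
      f"{common.n} ({common.n_hyper} hyper / {common.n_hypo} hypo)")
print("-> probes consistently altered with the development of castration "
      "resistance across every derived line.")

switches = ms.direction_switches(by_name["CRPC_vs_LN"], by_name["NE1_vs_CRPC"])
print(f"\nprobes significant in both CRPC_vs_LN and NE1_vs_CRPC: {switches.total}")
for (a, b), n in switches.counts.items():
    print(f"  {a} then {b}: {n}")
print("-> off-diagonal cells are probes whose methylation reversed "
      "direction at the neuroendocrine transition.")

conc = ms.delta_concordance(by_name["NE1_vs_LN"], by_name["NE1_vs_CRPC"])
print(f"\ndelta-beta concordance of shared DMPs: r={conc['r']:.3f} "
      f"(n={conc['n']}, p={conc['p']:.2g})")
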