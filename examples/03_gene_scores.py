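"""Gene-level aggregation, the net hyper:hypo methylation score, and
overlap with an external direction-labelled region set.
"""

import pandas as pd

import methylstage as ms

manifest = ms.generate_manifest(n_probes=20000, n_genes=800, seed=7)
design = ms.default_study_design(n_planted=800)
matrix, truth = ms.generate_beta_matrix(manifest, design, seed=11)
filtered, _ = ms.filter_probes(matrix, manifest)
comparison = design.comparisons[-1]
dmps = ms.call_dmps(filtered, comparison)

annotated = ms.annotate_dmps(dmps, manifest)
composition = ms.region_composition(annotated)["feature"]
print("DMP composition by genomic feature:")
print(composition.to_string(index=False))
print("-> counts are probe-unique; fractions sum to 1.\n")

summaries = ms.gene_dmp_summary(annotated)
scores = ms.net_methylation_score(summaries, min_dmps=6)
print(f"genes with >= 6 DMPs: {len(scores)}")
print(scores.head(5)[["gene", "n_hyper", "n_hypo", "score", "net_class"]]
      .to_string(index=False))
print("-> score = log2((n_hyper+0.5)/(n_hypo+0.5)); strongly positive "
      "genes gained methylation at the neuroendocrine transition.\n")

# external DMC-style region set built around some called hyper DMPs
hyper = annotated.loc[annotated["direction"] == "hyper"].head(50)
pos = manifest.loc[hyper["probe_id"], ["chrom", "pos"]]
regions = pd.DataFrame(
    {
        "chrom": pos["chrom"].to_numpy(),
        "start": pos["pos"].to_numpy() - 101,
        "end": pos["pos"].to_numpy() + 100,
        "direction": "hyper",
        "source": "external_DMCs",
    }
)
overlap = ms.overlap_with_regions(annotated, regions, manifest, direction_match=True)
print("overlap with external regions (same methylation trend required):")
print(overlap.to_string(index=False))
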