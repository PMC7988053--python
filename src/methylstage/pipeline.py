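"""End-to-end orchestration of the staged methylation analysis.

``run_pipeline`` drives filter → per-comparison DMP calling → comparison
set algebra → annotation → gene scoring → differential expression +
scenario classification → cfDNA biomarker, writing every table to a run
directory together with a machine-readable run manifest (seeds,
thresholds, input hashes).  Stages whose inputs are absent are skipped
with a logged notice rather than failing; outputs are write-once per
run directory.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .annotation import annotate_dmps, region_composition
from .cfdna import cohort_ratios, cohort_resampling, correlate_ttp
from .clustering import cluster_samples, top_dmp_heatmap_order
from .dmp import call_dmps, filter_probes
from .expression import call_degs, classify_scenarios
from .genes import gene_dmp_summary, net_methylation_score, overlap_with_regions
from .sets import common_dmps, direction_switches
from .synthetic import (
    default_study_design,
    generate_beta_matrix,
    generate_cohort,
    generate_expression,
    generate_manifest,
    split_seed,
)
from .types import Comparison, StudyDesign

log = logging.getLogger("methylstage")


@dataclass
class RunConfig:
    """Inputs, thresholds and seeds for one pipeline run."""

    out_dir: str
    simulate: bool = False
    seed: int = 0
    # file inputs (ignored when simulating)
    beta: str | None = None
    samples: str | None = None
    manifest: str | None = None
    expr: str | None = None
    dmrs: str | None = None
    outcomes: str | None = None
    regions: str | None = None
    # thresholds
    fdr: float = 0.01
    delta: float = 0.2
    expr_fdr: float = 0.05
    min_dmps: int = 6
    n_iter: int = 10000
    # simulation sizes
    n_probes: int = 50000
    n_genes: int = 2000
    n_patients: int = 20
    n_planted: int | None = None  # per comparison; default n_probes // 25
    comparisons: list[dict] = field(default_factory=list)

    def comparison_objects(self, design: StudyDesign | None) -> list[Comparison]:
        if self.comparisons:
            return [Comparison(c["name"], c["case"], c["ref"]) for c in self.comparisons]
        if design is not None:
            return design.comparisons
        raise ValueError("config must list comparisons when not simulating")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_entry: dict = {"config": asdict(config), "inputs": {}, "stages": []}
    design = None

    if config.simulate:
        n_planted = config.n_planted or max(10, config.n_probes // 25)
        design = default_study_design(n_planted=n_planted)
        seeds = {s: split_seed(config.seed, s) for s in ("manifest", "beta", "expr", "cohort")}
        manifest_entry["seeds"] = seeds
        probe_manifest = generate_manifest(config.n_probes, config.n_genes, seeds["manifest"])
        matrix, truth = generate_beta_matrix(probe_manifest, design, seeds["beta"])
        expr, truth = generate_expression(truth, probe_manifest, design, seeds["expr"])
        patients, outcomes, truth = generate_cohort(
            truth, probe_manifest, config.n_patients, seeds["cohort"]
        )
        io.write_manifest(probe_manifest, out / "manifest.tsv")
        io.write_beta_matrix(matrix, out / "beta.tsv", out / "samples.tsv")
        io.write_expression(expr, out / "expression.tsv")
        io.write_patient_dmrs(patients, out / "patient_dmrs.tsv")
        io.write_outcomes(outcomes, out / "outcomes.tsv")
        io.write_json(
            {
                "planted_dmps": {k: sorted(map(list, v)) for k, v in truth.planted_dmps.items()},
                "planted_degs": {k: sorted(map(list, v)) for k, v in truth.planted_degs.items()},
                "scenario_labels": truth.scenario_labels,
                "patient_signal": truth.patient_signal,
                "seeds": truth.seeds,
            },
            out / "truth.json",
        )
        regions = None
    else:
        if not (config.beta and config.samples and config.manifest):
            raise FileNotFoundError("beta, samples and manifest paths are required")
        for key in ("beta", "samples", "manifest", "expr", "dmrs", "outcomes", "regions"):
            path = getattr(config, key)
            if path:
                if not Path(path).exists():
                    raise FileNotFoundError(f"input {key} not found: {path}")
                manifest_entry["inputs"][key] = _sha256(Path(path))
        probe_manifest = io.read_manifest(config.manifest)
        matrix = io.read_beta_matrix(config.beta, config.samples)
        expr = io.read_expression(config.expr, config.samples) if config.expr else None
        patients = io.read_patient_dmrs(config.dmrs) if config.dmrs else None
        outcomes = io.read_outcomes(config.outcomes) if config.outcomes else None
        regions = io.read_regions(config.regions) if config.regions else None

    comparisons = config.comparison_objects(design)

    # --- filtering and DMP calling -------------------------------------
    filtered, removal_log = filter_probes(matrix, probe_manifest)
    manifest_entry["stages"].append({"filter": removal_log, "n_kept": len(filtered.probe_ids)})
    dmp_sets = {}
    for cmp in comparisons:
        dmps = call_dmps(filtered, cmp, fdr_cut=config.fdr, delta_cut=config.delta)
        dmp_sets[cmp.name] = dmps
        io.write_dmps(dmps, out / f"dmps_{cmp.name}.tsv")
    manifest_entry["stages"].append({"dmps": {k: len(v) for k, v in dmp_sets.items()}})

    # --- clustering + heatmap order ------------------------------------
    clus = cluster_samples(filtered)
    pd.DataFrame({"sample_id": clus.sample_ids, "cluster": clus.labels.to_numpy()}).to_csv(
        out / "clusters.tsv", sep="\t", index=False
    )
    nonempty = [d for d in dmp_sets.values() if len(d)]
    if nonempty:
        order = top_dmp_heatmap_order(nonempty, n=1000)
        filtered.values.loc[order].to_csv(
            out / "heatmap_top_dmps.tsv", sep="\t", index_label="probe_id",
            float_format="%.4f",
        )

    # --- comparison set algebra ----------------------------------------
    if len(dmp_sets) >= 2:
        names = list(dmp_sets)
        common = common_dmps(list(dmp_sets.values()), mode="same_direction")
        io.write_json(
            {"comparisons": common.comparisons, "n": common.n,
             "n_hyper": common.n_hyper, "n_hypo": common.n_hypo},
            out / "common_dmps.json",
        )
        sw = direction_switches(dmp_sets[names[0]], dmp_sets[names[-1]])
        io.write_json(
            {"total": sw.total,
             "counts": {f"{a}/{b}": n for (a, b), n in sw.counts.items()}},
            out / "direction_switches.json",
        )

    # --- annotation, composition, gene scores --------------------------
    summaries_by_cmp = {}
    for name, dmps in dmp_sets.items():
        if not len(dmps):
            summaries_by_cmp[name] = pd.DataFrame(
                columns=["gene", "comparison", "n_tss_hyper", "n_tss_hypo",
                         "n_body_hyper", "n_body_hypo", "n_hyper", "n_hypo", "n_total"]
            )
            continue
        ann = annotate_dmps(dmps, probe_manifest)
        comp = region_composition(ann)
        comp["feature"].to_csv(out / f"region_composition_{name}.tsv", sep="\t", index=False)
        summaries = gene_dmp_summary(ann)
        summaries_by_cmp[name] = summaries
        scores = net_methylation_score(summaries, min_dmps=config.min_dmps)
        scores.to_csv(out / f"gene_scores_{name}.tsv", sep="\t", index=False, float_format="%.4f")
        if regions is not None:
            overlap = overlap_with_regions(ann, regions, probe_manifest, direction_match=True)
            overlap.to_csv(out / f"region_overlap_{name}.tsv", sep="\t", index=False)

    # --- expression + scenarios ----------------------------------------
    if expr is not None:
        for cmp in comparisons:
            if not expr.group_samples(cmp.case_group) or not expr.group_samples(cmp.ref_group):
                log.info("expression missing for %s; scenario stage skipped", cmp.name)
                continue
            degs = call_degs(expr, cmp, fdr_cut=config.expr_fdr)
            io.write_degs(degs, out / f"degs_{cmp.name}.tsv")
            scen = classify_scenarios(degs, summaries_by_cmp[cmp.name])
            scen.to_csv(out / f"scenarios_{cmp.name}.tsv", sep="\t", index=False)
    else:
        log.info("no expression input; scenario stage skipped")

    # --- cfDNA biomarker -------------------------------------------------
    if patients and outcomes is not None and nonempty:
        query_name = comparisons[-1].name
        query = dmp_sets[query_name]
        query_hyper = query.loc[query["direction"] == "hyper"]
        if len(query_hyper):
            ratios = cohort_ratios(query_hyper, patients, probe_manifest)
            resamp = cohort_resampling(
                query_hyper, probe_manifest, patients,
                n_iter=config.n_iter, seed=split_seed(config.seed, "resample"),
            )
            result = ratios.merge(resamp, on="patient_id")
            result.to_csv(out / "cfdna_biomarker.tsv", sep="\t", index=False, float_format="%.6g")
            rho = correlate_ttp(ratios, outcomes)
            io.write_json({"query_comparison": query_name, **rho}, out / "cfdna_ttp.json")
    else:
        log.info("cfDNA inputs incomplete; biomarker stage skipped")

    io.write_json(manifest_entry, out / "run_manifest.json")
    return manifest_entry
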