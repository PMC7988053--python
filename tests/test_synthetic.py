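"""Invariants and determinism of the synthetic-data generator."""

import numpy as np
import pandas as pd
import pytest

import methylstage as ms
from methylstage.synthetic import split_seed


class TestManifest:
    def test_minimal_case(self):
        man = ms.generate_manifest(1, 1, seed=1)
        assert len(man) == 1
        assert man["feature"].iloc[0] in ms.types.FEATURE_CLASSES
        assert man["cgi_context"].iloc[0] in ms.types.CGI_CONTEXTS

    def test_full_scan_invariants(self, small_manifest):
        man = small_manifest
        # unique 1-based positions per chromosome
        for _, sub in man.groupby("chrom"):
            assert sub["pos"].is_unique
            assert (sub["pos"] >= 1).all()
        # every annotated gene exists; IGR probes carry no gene
        assert (man.loc[man["feature"] == "IGR", "genes"] == "").all()
        assert (man.loc[man["feature"] != "IGR", "genes"] != "").all()
        assert set(man["feature"]) <= set(ms.types.FEATURE_CLASSES)
        assert set(man["cgi_context"]) <= set(ms.types.CGI_CONTEXTS)
        # ~3% exclusion flags
        assert 0.01 < (man["flags"] != "").mean() < 0.06

    def test_probe_count_skew(self, small_manifest):
        counts = {}
        for gl in small_manifest["genes"]:
            for g in filter(None, gl.split(";")):
                counts[g] = counts.get(g, 0) + 1
        vals = np.array(list(counts.values()))
        assert 0.3 <= np.mean(vals <= 2) <= 0.6  # about half thinly covered

    def test_determinism(self):
        a = ms.generate_manifest(500, 40, seed=9)
        b = ms.generate_manifest(500, 40, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_bad_args(self):
        with pytest.raises(ValueError):
            ms.generate_manifest(0, 1, seed=1)
        with pytest.raises(ValueError):
            ms.generate_manifest(5, 10, seed=1)


class TestBetaMatrix:
    def test_values_in_open_unit_interval(self, small_study):
        matrix, _ = small_study
        vals = matrix.values.to_numpy()
        assert vals.min() > 0 and vals.max() < 1

    def test_null_design_has_no_group_difference(self, small_manifest):
        design = ms.StudyDesign(
            groups=["A", "B"],
            n_replicates=3,
            plants=[ms.PlantSpec(ms.Comparison("B_vs_A", "B", "A"), 0)],
        )
        matrix, truth = ms.generate_beta_matrix(small_manifest, design, seed=2)
        assert truth.planted_dmps["B_vs_A"] == set()
        a = matrix.values[matrix.group_samples("A")].mean(axis=1)
        b = matrix.values[matrix.group_samples("B")].mean(axis=1)
        assert abs((b - a).mean()) < 0.005
        dmps = ms.call_dmps(matrix, ms.Comparison("B_vs_A", "B", "A"))
        assert len(dmps) / len(small_manifest) <= 0.01

    def test_truth_covers_shared_case_groups(self, small_design, small_study):
        """A shift planted on either member group shows up in the truth of
        every comparison between those groups (plants use disjoint probes)."""
        _, truth = small_study
        ne1_crpc = truth.planted_probes("NE1_vs_CRPC")
        assert truth.planted_probes("NE1_vs_LN") <= ne1_crpc
        assert truth.planted_probes("CRPC_vs_LN") <= ne1_crpc

    def test_planted_directions_valid(self, small_study):
        _, truth = small_study
        for pairs in truth.planted_dmps.values():
            assert {d for _, d in pairs} <= {"hyper", "hypo"}

    def test_determinism(self, small_manifest):
        design = ms.default_study_design(n_planted=50)
        m1, _ = ms.generate_beta_matrix(small_manifest, design, seed=4)
        m2, _ = ms.generate_beta_matrix(small_manifest, design, seed=4)
        pd.testing.assert_frame_equal(m1.values, m2.values)

    def test_bad_designs_rejected(self, small_manifest):
        with pytest.raises(ValueError):
            ms.PlantSpec(ms.Comparison("x", "A", "B"), 10, delta=0.0)
        with pytest.raises(ValueError):
            ms.StudyDesign(groups=["A", "B"], n_replicates=1)


class TestExpression:
    def test_counts_nonnegative_integers(self, small_manifest, small_design, small_study):
        _, truth = small_study
        expr, _ = ms.generate_expression(truth, small_manifest, small_design, seed=3,
                                         n_per_scenario=20)
        arr = expr.counts.to_numpy()
        assert (arr >= 0).all() and np.issubdtype(arr.dtype, np.integer)

    def test_null_has_no_planted_degs(self, small_manifest, small_design, small_study):
        _, truth = small_study
        t = ms.SyntheticTruth(planted_dmps=dict(truth.planted_dmps))
        expr, t = ms.generate_expression(t, small_manifest, small_design, seed=5,
                                         n_per_scenario=0)
        cmp_name = small_design.comparisons[-1].name
        assert t.planted_degs[cmp_name] == set()
        cmp = small_design.comparisons[-1]
        degs = ms.call_degs(expr, cmp)
        assert len(degs) / len(expr.counts) <= 0.05 + 0.02

    def test_scenario_fraction_validation(self, small_manifest, small_design, small_study):
        _, truth = small_study
        with pytest.raises(ValueError):
            ms.generate_expression(
                truth, small_manifest, small_design, seed=1,
                scenario_fractions={"a": 0.6, "b": 0.6},
            )

    def test_scenario_labels_respect_planted_methylation(
        self, small_manifest, small_design, small_study
    ):
        _, truth = small_study
        t = ms.SyntheticTruth(planted_dmps=dict(truth.planted_dmps))
        expr, t = ms.generate_expression(t, small_manifest, small_design, seed=3,
                                         n_per_scenario=20)
        cmp_name = small_design.comparisons[-1].name
        planted = dict(t.planted_dmps[cmp_name])
        by_gene: dict[str, list] = {}
        for probe, direction in t.planted_dmps[cmp_name]:
            feat = small_manifest.at[probe, "feature"]
            for g in filter(None, small_manifest.at[probe, "genes"].split(";")):
                by_gene.setdefault(g, []).append((feat, direction))
        need = {"a": ("TSS", "hyper"), "b": ("Body", "hyper"),
                "c": ("Body", "hypo"), "d": ("TSS", "hypo")}
        for gene, scen in t.scenario_labels[cmp_name].items():
            assert need[scen] in by_gene[gene]


class TestCohort:
    def test_zero_noise_ttp_is_exact_monotone_in_signal_ratio(
        self, small_manifest, small_study
    ):
        _, truth = small_study
        patients, outcomes, truth = ms.generate_cohort(
            truth, small_manifest, 10, seed=5, noise_sd=0.0
        )
        from scipy.stats import spearmanr

        exp_ratio = [truth.patient_expected_ratio[p] for p in outcomes["patient_id"]]
        rho, _ = spearmanr(exp_ratio, outcomes["ttp_days"])
        assert rho == pytest.approx(-1.0)

    def test_null_cohort_uninformative(self, small_manifest, small_study):
        _, truth = small_study
        patients, outcomes, truth = ms.generate_cohort(
            truth, small_manifest, 12, seed=6, signal_fractions=np.zeros(12)
        )
        assert all(truth.patient_signal[p.patient_id] == 0 for p in patients)
        # expected ratios are all ~1: TTP carries no overlap signal
        vals = [truth.patient_expected_ratio[p.patient_id] for p in patients]
        assert max(vals) - min(vals) < 0.05

    def test_dmr_geometry(self, small_manifest, small_study):
        _, truth = small_study
        patients, _, _ = ms.generate_cohort(
            truth, small_manifest, 5, seed=7, n_dmr_range=(100, 300),
            width_range=(100, 2000),
        )
        for p in patients:
            iv = p.intervals
            assert (iv["start"] < iv["end"]).all()
            widths = iv["end"] - iv["start"]
            assert widths.between(100, 2000).all()
            assert set(iv["direction"]) <= {"hyper", "hypo"}
            assert 100 <= len(iv) <= 300 + 1

    def test_too_few_patients_rejected(self, small_manifest, small_study):
        _, truth = small_study
        with pytest.raises(ValueError):
            ms.generate_cohort(truth, small_manifest, 2, seed=1)


def test_split_seed_is_stable_and_stage_dependent():
    assert split_seed(42, "beta") == split_seed(42, "beta")
    assert split_seed(42, "beta") != split_seed(42, "cohort")
    assert 0 <= split_seed(123, "x") < 2**31
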