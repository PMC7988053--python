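"""Beta values, probe filtering, BH adjustment and the moderated t caller."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import methylstage as ms
from methylstage.dmp import squeeze_variances, trigamma_inverse

from conftest import make_beta


class TestBetaFromIntensities:
    @pytest.mark.parametrize(
        "m,u,expected",
        [(0, 0, 0.0), (100, 0, 0.5), (900, 0, 0.9), (50, 50, 0.25)],
    )
    def test_formula(self, m, u, expected):
        assert ms.beta_from_intensities(m, u) == pytest.approx(expected, abs=1e-12)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            ms.beta_from_intensities(-1, 10)

    @given(
        m=st.floats(0, 1e6, allow_nan=False),
        u=st.floats(0, 1e6, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_range(self, m, u):
        b = ms.beta_from_intensities(m, u)
        assert 0.0 <= b < 1.0


class TestBHAdjust:
    def test_worked_step_up_example(self):
        # hand computation: q4=0.5; q3=min(0.5, 4*0.03/3)=0.04;
        # q2=min(0.04, 4*0.02/2)=0.04; q1=min(0.04, 4*0.001)=0.004
        q = ms.bh_adjust([0.001, 0.02, 0.03, 0.5])
        assert np.allclose(q, [0.004, 0.04, 0.04, 0.5], atol=1e-12)

    def test_equal_ps_unchanged(self):
        assert np.allclose(ms.bh_adjust([0.3, 0.3, 0.3]), 0.3)

    def test_single_p(self):
        assert ms.bh_adjust([0.07])[0] == pytest.approx(0.07)

    def test_empty(self):
        assert len(ms.bh_adjust([])) == 0

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(max_examples=100, deadline=None)
    def test_properties(self, ps):
        q = ms.bh_adjust(ps)
        p = np.asarray(ps)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1 + 1e-12)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)  # monotone in sorted p


class TestFilterProbes:
    def _matrix(self, manifest, n=10):
        ids = manifest.index[:n]
        vals = pd.DataFrame(
            0.5, index=ids, columns=["A_r1", "A_r2", "B_r1", "B_r2"]
        )
        samples = pd.DataFrame(
            {
                "sample_id": vals.columns,
                "group": ["A", "A", "B", "B"],
                "replicate": [1, 2, 1, 2],
            }
        )
        return ms.BetaMatrix(vals, samples)

    def test_no_flags_identity(self):
        manifest = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": range(1, 11),
                "strand": "+",
                "genes": "",
                "feature": "IGR",
                "cgi_context": "open_sea",
                "flags": "",
            },
            index=[f"p{i}" for i in range(10)],
        )
        matrix = self._matrix(manifest)
        out, log = ms.filter_probes(matrix, manifest)
        assert list(out.probe_ids) == list(matrix.probe_ids)
        assert all(v == 0 for v in log.values())

    def test_flagged_and_detection_counts(self):
        flags = ["snp", "snp", "snp"] + [""] * 7
        manifest = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": range(1, 11),
                "strand": "+",
                "genes": "",
                "feature": "IGR",
                "cgi_context": "open_sea",
                "flags": flags,
            },
            index=[f"p{i}" for i in range(10)],
        )
        matrix = self._matrix(manifest)
        det = pd.DataFrame(0.0001, index=matrix.probe_ids, columns=matrix.values.columns)
        det.loc["p3", "A_r1"] = 0.5  # one failing sample removes the probe
        det.loc["p4", "B_r2"] = 0.5
        out, log = ms.filter_probes(matrix, manifest, detection_p=det)
        assert len(out.probe_ids) == 5
        assert log["snp"] == 3 and log["low_detection"] == 2

    def test_double_flag_counted_once_in_output_twice_in_log(self):
        manifest = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": range(1, 11),
                "strand": "+",
                "genes": "",
                "feature": "IGR",
                "cgi_context": "open_sea",
                "flags": ["snp;cross_reactive"] + [""] * 9,
            },
            index=[f"p{i}" for i in range(10)],
        )
        matrix = self._matrix(manifest)
        out, log = ms.filter_probes(matrix, manifest)
        assert len(out.probe_ids) == 9
        assert log["snp"] == 1 and log["cross_reactive"] == 1


class TestModeratedT:
    def _two_group(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        sd = rng.uniform(0.02, 0.2, size=n)
        mu = rng.uniform(0.2, 0.8, size=n)
        vals = np.clip(mu[:, None] + rng.normal(0, 1, (n, 6)) * sd[:, None], 1e-3, 1 - 1e-3)
        return make_beta(vals, ["A", "A", "A", "B", "B", "B"])

    def test_prior_df_zero_equals_pooled_t(self):
        bm = self._two_group()
        cmp = ms.Comparison("B_vs_A", "B", "A")
        mine = ms.dmp_statistics(bm, cmp, prior_df=0)
        from scipy import stats as ss

        ref = ss.ttest_ind(
            bm.values.iloc[:, 3:], bm.values.iloc[:, :3], axis=1, equal_var=True
        )
        assert np.allclose(mine["t"], ref.statistic, atol=1e-10)
        assert np.allclose(mine["p"], ref.pvalue, atol=1e-10)

    def test_infinite_prior_df_shares_one_variance(self):
        bm = self._two_group()
        cmp = ms.Comparison("B_vs_A", "B", "A")
        mine = ms.dmp_statistics(bm, cmp, prior_df=np.inf)
        delta = mine["delta_beta"].to_numpy()
        t = mine["t"].to_numpy()
        # t / delta constant => a single pooled variance is in use
        ratio = t[np.abs(delta) > 1e-8] / delta[np.abs(delta) > 1e-8]
        assert np.allclose(ratio, ratio[0], rtol=1e-9)

    def test_matches_limma_reference(self, tmp_path):
        """Dual route: empirical-Bayes t and p agree with R limma."""
        bm = self._two_group(seed=3, n=250)
        cmp = ms.Comparison("B_vs_A", "B", "A")
        mine = ms.dmp_statistics(bm, cmp).set_index("probe_id")
        beta_path = tmp_path / "beta.tsv"
        bm.values.to_csv(beta_path, sep="\t")
        script = tmp_path / "limma.R"
        out_path = tmp_path / "limma.tsv"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f'x <- as.matrix(read.delim("{beta_path}", row.names=1))\n'
            "design <- cbind(Intercept=1, B=c(0,0,0,1,1,1))\n"
            "fit <- eBayes(lmFit(x, design))\n"
            "out <- data.frame(probe=rownames(x), lt=fit$t[,2], lp=fit$p.value[,2])\n"
            f'write.table(out, "{out_path}", sep="\\t", row.names=FALSE, quote=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(out_path, sep="\t", index_col=0)
        assert np.allclose(mine["t"], ref["lt"], atol=1e-8)
        assert np.allclose(mine["p"], ref["lp"], atol=1e-8)

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma

        for y in [0.01, 0.5, 2.0, 10.0]:
            x = float(polygamma(1, y))
            assert trigamma_inverse(x) == pytest.approx(y, rel=1e-6)

    def test_squeeze_handles_zero_variances(self):
        s2 = np.array([0.0, 0.0, 0.01, 0.02, 0.05])
        post, d0, s02 = squeeze_variances(s2, 4)
        assert np.all(post > 0)


class TestCallDMPs:
    def test_identical_groups_empty(self):
        vals = np.tile(np.linspace(0.1, 0.9, 20)[:, None], (1, 6))
        bm = make_beta(vals, ["A", "A", "A", "B", "B", "B"])
        dmps = ms.call_dmps(bm, ms.Comparison("B_vs_A", "B", "A"))
        assert len(dmps) == 0

    def test_delta_threshold_is_inclusive_lower_bound(self):
        # strong but sub-threshold shift (0.19 < 0.2) must be excluded
        rng = np.random.default_rng(5)
        base = np.full((50, 6), 0.4) + rng.normal(0, 0.002, (50, 6))
        base[0, 3:] += 0.19
        base[1, 3:] += 0.30
        bm = make_beta(np.clip(base, 0, 1), ["A", "A", "A", "B", "B", "B"])
        dmps = ms.call_dmps(bm, ms.Comparison("B_vs_A", "B", "A"))
        assert "p0" not in set(dmps["probe_id"])
        assert "p1" in set(dmps["probe_id"])

    def test_case_ref_swap_negates_delta_and_flips_direction(self, small_study, small_manifest):
        matrix, _ = small_study
        sub = matrix.subset_probes(matrix.probe_ids[:2000])
        fwd = ms.dmp_statistics(sub, ms.Comparison("f", "NE1", "CRPC"))
        rev = ms.dmp_statistics(sub, ms.Comparison("r", "CRPC", "NE1"))
        assert np.allclose(fwd["delta_beta"], -rev["delta_beta"], atol=1e-12)
        assert np.allclose(fwd["p"], rev["p"], atol=1e-12)
        flip = {"hyper": "hypo", "hypo": "hyper"}
        assert all(
            flip[d] == r for d, r in zip(fwd["direction"], rev["direction"])
        )

    def test_fewer_than_two_replicates_rejected(self):
        vals = np.full((5, 3), 0.5)
        bm = make_beta(vals, ["A", "A", "B"])
        with pytest.raises(ValueError):
            ms.call_dmps(bm, ms.Comparison("B_vs_A", "B", "A"))

    def test_planted_effects_recovered(self, small_manifest, small_design, small_study, small_dmps):
        _, truth = small_study
        cmp = small_design.comparisons[0]
        called = set(small_dmps[cmp.name]["probe_id"])
        planted = truth.planted_probes(cmp.name)
        sens = len(called & planted) / len(planted)
        emp_fdr = len(called - planted) / max(len(called), 1)
        assert sens >= 0.9
        assert emp_fdr <= 0.05


class TestClustering:
    def test_separable_groups_recovered(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0.2, 0.8, size=100)
        vals = np.clip(
            np.column_stack(
                [base + rng.normal(0, 0.01, 100) for _ in range(3)]
                + [base + 0.15 + rng.normal(0, 0.01, 100) for _ in range(3)]
            ),
            0,
            1,
        )
        bm = make_beta(vals, ["A", "A", "A", "B", "B", "B"])
        res = ms.cluster_samples(bm)
        labels = res.labels
        groups = bm.samples.set_index("sample_id")["group"]
        # same flat cluster iff same group (up to label permutation)
        mapping = {}
        for sid in labels.index:
            mapping.setdefault(labels[sid], set()).add(groups[sid])
        assert all(len(v) == 1 for v in mapping.values())
        assert len(mapping) == 2

    def test_replicate_triples_monophyletic(self, small_study):
        matrix, _ = small_study
        res = ms.cluster_samples(matrix)
        from scipy.cluster import hierarchy

        groups = matrix.samples.set_index("sample_id")["group"]
        tree = hierarchy.to_tree(res.linkage)

        def leafsets(node, acc):
            if node.is_leaf():
                return {node.id}
            s = leafsets(node.left, acc) | leafsets(node.right, acc)
            acc.append(s)
            return s

        acc: list[set] = []
        leafsets(tree, acc)
        ids = {i: res.sample_ids[i] for i in range(len(res.sample_ids))}
        for g in groups.unique():
            want = {i for i, sid in ids.items() if groups[sid] == g}
            assert want in acc or want == set(ids)  # each triple is a clade

    def test_duplicate_samples_merge_at_zero(self):
        vals = np.tile(np.linspace(0.1, 0.9, 10)[:, None], (1, 4))
        bm = make_beta(vals, ["A", "A", "B", "B"])
        res = ms.cluster_samples(bm)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_probe_subset_rejected(self, small_study):
        matrix, _ = small_study
        with pytest.raises(ValueError):
            ms.cluster_samples(matrix, probe_subset={"not_a_probe"})


class TestHeatmapOrder:
    def test_small_pool_returned_whole(self):
        from conftest import make_dmp_table

        t = make_dmp_table([("a", "hyper"), ("b", "hypo"), ("c", "hyper")])
        assert len(ms.top_dmp_heatmap_order([t], n=1000)) == 3

    def test_best_q_wins(self):
        from conftest import make_dmp_table

        t = make_dmp_table([("a", "hyper", 0.3, 1e-3), ("b", "hyper", 0.3, 1e-8)])
        assert ms.top_dmp_heatmap_order([t], n=1)[0] == "b"

    def test_q_tie_broken_by_abs_delta_then_id(self):
        from conftest import make_dmp_table

        t = make_dmp_table(
            [("a", "hyper", 0.25, 1e-6), ("b", "hypo", -0.4, 1e-6), ("c", "hyper", 0.4, 1e-6)]
        )
        assert ms.top_dmp_heatmap_order([t], n=3) == ["b", "c", "a"]

    def test_nonpositive_n_rejected(self):
        from conftest import make_dmp_table

        with pytest.raises(ValueError):
            ms.top_dmp_heatmap_order([make_dmp_table([("a", "hyper")])], n=0)
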