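"""Differential expression and methylation–expression scenario calls.

Expression changes are tested per gene with a 2x2 chi-squared count
test: reads in the gene vs reads in the rest of the library, case vs
reference (replicates pooled per group), with expectations proportional
to library size.  An unpooled Welch t on log-CPM is available as an
alternative backend for data with strong biological dispersion.

Scenario classification links expression direction to the promoter/body
location of methylation changes:

* ``a`` — downregulated, promoter (TSS) hypermethylation, no body
  hypermethylation;
* ``b`` — upregulated, body hypermethylation, no promoter
  hypermethylation;
* ``c`` — downregulated, body hypomethylation, no promoter
  hypomethylation;
* ``d`` — upregulated, promoter hypomethylation, no body
  hypomethylation.

``a``/``b`` and ``c``/``d`` are mutually exclusive per gene (opposite
expression directions); ``a`` with ``c`` or ``b`` with ``d`` can
co-occur and both letters are reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .dmp import bh_adjust
from .types import DEG_COLUMNS, Comparison, ExpressionMatrix

SCENARIOS = ("a", "b", "c", "d")


def chi2_count_test(x_case: float, n_case: float, x_ref: float, n_ref: float):
    """Uncorrected Pearson chi-squared on the 2x2 gene-vs-rest table."""
    table = np.array(
        [[x_case, x_ref], [n_case - x_case, n_ref - x_ref]], dtype=float
    )
    if table.min() < 0:
        raise ValueError("counts exceed library sizes")
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def call_degs(
    expr: ExpressionMatrix,
    cmp: Comparison,
    fdr_cut: float = 0.05,
    method: str = "chi2",
) -> pd.DataFrame:
    """Differentially expressed genes for one comparison.

    Returns records with ``q < fdr_cut``; ``log2fc`` is the ratio of
    group-mean CPM with a 0.5 pseudocount and ``direction`` follows its
    sign.  Genes with zero counts in every sample are skipped.
    """
    case_ids = expr.group_samples(cmp.case_group)
    ref_ids = expr.group_samples(cmp.ref_group)
    if not case_ids or not ref_ids:
        raise ValueError(f"comparison {cmp.name!r}: both groups need >= 1 sample")
    counts = expr.counts
    lib = counts.sum(axis=0)
    cpm = counts / lib * 1e6
    mean_case = cpm[case_ids].mean(axis=1)
    mean_ref = cpm[ref_ids].mean(axis=1)
    log2fc = np.log2((mean_case + 0.5) / (mean_ref + 0.5))

    expressed = (counts[case_ids + ref_ids].sum(axis=1) > 0).to_numpy()
    genes = counts.index[expressed]
    if method == "chi2":
        x_case = counts.loc[genes, case_ids].sum(axis=1).to_numpy(dtype=float)
        x_ref = counts.loc[genes, ref_ids].sum(axis=1).to_numpy(dtype=float)
        n_case = float(lib[case_ids].sum())
        n_ref = float(lib[ref_ids].sum())
        stat_p = [chi2_count_test(xc, n_case, xr, n_ref) for xc, xr in zip(x_case, x_ref)]
        chi2_stat = np.array([s for s, _ in stat_p])
        p = np.array([pv for _, pv in stat_p])
    elif method == "welch":
        if len(case_ids) < 2 or len(ref_ids) < 2:
            raise ValueError("welch backend needs >= 2 samples per group")
        logc = np.log2(cpm.loc[genes] + 0.5)
        res = stats.ttest_ind(
            logc[case_ids], logc[ref_ids], axis=1, equal_var=False
        )
        chi2_stat = np.nan_to_num(res.statistic, nan=0.0) ** 2
        p = np.nan_to_num(res.pvalue, nan=1.0)
    else:
        raise ValueError(f"unknown method {method!r}")

    table = pd.DataFrame(
        {
            "gene": genes,
            "comparison": cmp.name,
            "log2fc": log2fc.loc[genes].to_numpy(),
            "chi2_stat": chi2_stat,
            "p": p,
            "q": bh_adjust(p),
        }
    )
    table["direction"] = np.where(table["log2fc"] > 0, "up", "down")
    degs = table.loc[(table["q"] < fdr_cut) & (table["log2fc"] != 0), DEG_COLUMNS]
    return degs.sort_values(["q", "gene"], kind="mergesort").reset_index(drop=True)


def classify_scenarios(
    degs: pd.DataFrame,
    summaries: pd.DataFrame,
    min_tss: int = 1,
    min_body: int = 1,
) -> pd.DataFrame:
    """Assign promoter/body methylation–expression scenarios to DEGs.

    ``summaries`` is a gene-level DMP count table for the same
    comparison.  Genes without any DMP summary receive no scenario.
    "No opposite-region methylation" is read as zero called DMPs of the
    relevant direction in that region.
    """
    if len(degs) and "comparison" in summaries.columns:
        summaries = summaries.loc[
            summaries["comparison"].isin(set(degs["comparison"]))
        ]
    if summaries["gene"].duplicated().any():
        raise ValueError("gene summaries must be for a single comparison")
    summ = summaries.set_index("gene")
    rows = []
    for rec in degs.itertuples():
        letters = []
        if rec.gene in summ.index:
            s = summ.loc[rec.gene]
            if rec.direction == "down":
                if s["n_tss_hyper"] >= min_tss and s["n_body_hyper"] == 0:
                    letters.append("a")
                if s["n_body_hypo"] >= min_body and s["n_tss_hypo"] == 0:
                    letters.append("c")
            else:
                if s["n_body_hyper"] >= min_body and s["n_tss_hyper"] == 0:
                    letters.append("b")
                if s["n_tss_hypo"] >= min_tss and s["n_body_hypo"] == 0:
                    letters.append("d")
        rows.append(
            {
                "gene": rec.gene,
                "comparison": rec.comparison,
                "scenarios": ",".join(letters),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "comparison", "scenarios"])
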