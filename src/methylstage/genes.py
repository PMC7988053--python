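"""Gene-level DMP aggregation, net methylation scoring and region overlap.

The net methylation score summarises, for genes carrying enough DMPs,
whether the balance of probe-level changes is towards gain or loss of
methylation: ``score = log2((n_hyper + 0.5) / (n_hypo + 0.5))`` over all
DMPs in or near the gene.  The 0.5 pseudocount keeps genes with no
hypomethylated probes finite and rankable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .dmp import bh_adjust
from .intervals import points_in_any, validate_intervals


def gene_dmp_summary(annotated: pd.DataFrame) -> pd.DataFrame:
    """Per-(gene, comparison) DMP counts by region class and direction.

    Input is an annotated DMP table (one record per probe-gene pair);
    intergenic records (empty gene) are ignored.  ``n_total`` counts the
    unique probes annotated to the gene; the region-direction cells
    count TSS and Body probes only, so 5'UTR/1stExon/3'UTR probes appear
    in ``n_total`` but in none of the cells.
    """
    gene_rows = annotated.loc[annotated["gene"] != ""]
    records = []
    for (gene, comparison), sub in gene_rows.groupby(["gene", "comparison"], sort=True):
        sub = sub.drop_duplicates("probe_id")
        tss = sub["feature"] == "TSS"
        body = sub["feature"] == "Body"
        hyper = sub["direction"] == "hyper"
        records.append(
            {
                "gene": gene,
                "comparison": comparison,
                "n_tss_hyper": int((tss & hyper).sum()),
                "n_tss_hypo": int((tss & ~hyper).sum()),
                "n_body_hyper": int((body & hyper).sum()),
                "n_body_hypo": int((body & ~hyper).sum()),
                "n_hyper": int(hyper.sum()),
                "n_hypo": int((~hyper).sum()),
                "n_total": len(sub),
            }
        )
    cols = [
        "gene", "comparison", "n_tss_hyper", "n_tss_hypo",
        "n_body_hyper", "n_body_hypo", "n_hyper", "n_hypo", "n_total",
    ]
    return pd.DataFrame(records, columns=cols)


def filter_gene_summaries(
    summaries: pd.DataFrame, min_tss: int = 0, min_body: int = 0
) -> pd.DataFrame:
    """Genes meeting minimum TSS / body DMP counts (either direction)."""
    tss = summaries["n_tss_hyper"] + summaries["n_tss_hypo"]
    body = summaries["n_body_hyper"] + summaries["n_body_hypo"]
    return summaries.loc[(tss >= min_tss) & (body >= min_body)].reset_index(drop=True)


def net_methylation_score(
    summaries: pd.DataFrame, min_dmps: int = 6, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Net hyper:hypo score for genes with at least ``min_dmps`` DMPs.

    The default of 6 reads a "more than 5 DMPs" refinement literally;
    pass ``min_dmps=5`` for the inclusive variant.  ``net_class`` is
    decided on raw counts (pseudocount-free), so it is exactly
    ``net_hyper`` iff more hyper- than hypomethylated probes.
    """
    if min_dmps < 1:
        raise ValueError("min_dmps must be >= 1")
    kept = summaries.loc[summaries["n_total"] >= min_dmps].copy()
    h = kept["n_hyper"].to_numpy(dtype=float)
    l = kept["n_hypo"].to_numpy(dtype=float)
    kept["score"] = np.log2((h + pseudocount) / (l + pseudocount))
    kept["net_class"] = np.select(
        [h > l, l > h], ["net_hyper", "net_hypo"], default="balanced"
    )
    kept = kept.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    return kept.reset_index(drop=True)


def overlap_with_regions(
    annotated: pd.DataFrame,
    regions: pd.DataFrame,
    manifest: pd.DataFrame,
    direction_match: bool = False,
) -> pd.DataFrame:
    """Count DMPs falling inside external interval sets, by direction.

    ``regions`` is a BED-style table (chrom, 0-based half-open
    start/end) with optional ``direction`` and ``source`` columns.  With
    ``direction_match`` a probe only counts as a hit inside regions
    whose direction equals its own ("same methylation trend").  Counts
    are probe-unique and reported per source.
    """
    validate_intervals(regions)
    regions = regions.copy()
    if "source" not in regions.columns:
        regions["source"] = "regions"
    if "direction" not in regions.columns:
        regions["direction"] = "none"
    unique = annotated.drop_duplicates("probe_id")
    pos = manifest.loc[unique["probe_id"], "pos"].to_numpy() - 1
    chrom = manifest.loc[unique["probe_id"], "chrom"].to_numpy()
    direction = unique["direction"].to_numpy()

    rows = []
    for source, sub in regions.groupby("source", sort=True):
        for dmp_dir in ("hyper", "hypo"):
            mask = direction == dmp_dir
            target = sub if not direction_match else sub.loc[sub["direction"] == dmp_dir]
            hits = points_in_any(chrom[mask], pos[mask], target)
            rows.append(
                {
                    "source": source,
                    "dmp_direction": dmp_dir,
                    "n_dmps": int(mask.sum()),
                    "n_hits": int(hits.sum()),
                }
            )
    return pd.DataFrame(rows)


def gene_set_enrichment(
    query_genes: set,
    universe: set,
    gene_sets: dict[str, set],
    weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of user-supplied gene sets.

    Plumbing only: no probe-count bias correction is applied.  Genes on
    arrays are unevenly covered by CpG probes, which biases DMP-derived
    gene lists towards heavily probed genes; the optional ``weights``
    hook (per-gene sampling weights) is exposed for callers who want to
    build a bias-aware null themselves, but is not used by the default
    test.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    query = set(query_genes)
    if not query <= set(universe):
        raise ValueError("query genes must be a subset of the universe")
    del weights  # reserved for caller-supplied bias correction
    M, n = len(universe), len(query)
    rows = []
    for name, members in gene_sets.items():
        in_universe = set(members) & set(universe)
        k = len(in_universe & query)
        K = len(in_universe)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append(
            {"gene_set": name, "set_size": K, "overlap": k, "p": min(p, 1.0)}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"])
        out = out.sort_values(["p", "gene_set"], kind="mergesort").reset_index(drop=True)
    return out
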