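"""Genomic-feature and CGI-context annotation of DMP sets."""

from __future__ import annotations

import pandas as pd

from .types import CGI_CONTEXTS, FEATURE_CLASSES


def annotate_dmps(dmps: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Attach gene, feature-class and CGI-context columns to DMP records.

    Probes annotated to several genes expand to one record per gene (the
    ``gene`` column; empty string for intergenic probes).  Unique-probe
    statistics downstream must therefore deduplicate on ``probe_id``.
    """
    unknown = set(dmps["probe_id"]) - set(manifest.index)
    if unknown:
        raise ValueError(f"probes absent from manifest: {sorted(unknown)[:10]}")
    ann = dmps.merge(
        manifest[["genes", "feature", "cgi_context"]],
        left_on="probe_id",
        right_index=True,
        how="left",
    )
    ann["gene"] = ann["genes"].fillna("").str.split(";")
    ann = ann.explode("gene").drop(columns=["genes"])
    ann["gene"] = ann["gene"].fillna("")
    return ann.reset_index(drop=True)


def _composition(unique: pd.DataFrame, column: str, classes) -> pd.DataFrame:
    rows = []
    total = len(unique)
    for cls in classes:
        sub = unique.loc[unique[column] == cls]
        rows.append(
            {
                "region": cls,
                "n": len(sub),
                "n_hyper": int((sub["direction"] == "hyper").sum()),
                "n_hypo": int((sub["direction"] == "hypo").sum()),
                "fraction": len(sub) / total if total else 0.0,
            }
        )
    return pd.DataFrame(rows)


def region_composition(annotated: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-region DMP counts and hyper/hypo split.

    Counting is probe-unique: a probe annotated to several genes still
    contributes once to its feature class and CGI context.  Returns one
    table for feature classes and one for CGI contexts; each table's
    fractions sum to 1 over occupied classes.  A coarser grouping that
    pools 5'UTR and 1stExon into a single UTR-proximal class is included
    under the key ``"feature_grouped"``.
    """
    unique = annotated.drop_duplicates("probe_id")
    feature = _composition(unique, "feature", FEATURE_CLASSES)
    cgi = _composition(unique, "cgi_context", CGI_CONTEXTS)
    grouped = unique.assign(
        feature=unique["feature"].replace({"5'UTR": "UTR_proximal", "1stExon": "UTR_proximal"})
    )
    feature_grouped = _composition(
        grouped, "feature", ("TSS", "UTR_proximal", "Body", "3'UTR", "IGR")
    )
    return {"feature": feature, "cgi_context": cgi, "feature_grouped": feature_grouped}
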