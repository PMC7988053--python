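"""TSV/GMT/JSON readers and writers with fixed column orders.

Every table the pipeline writes can be read back by the functions here
(round-trip property).  Coordinates follow the package convention:
manifests carry 1-based CpG positions, interval files are BED-style
0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .types import DEG_COLUMNS, DMP_COLUMNS, BetaMatrix, ExpressionMatrix, PatientDMRSet

MANIFEST_COLUMNS = ["chrom", "pos", "strand", "genes", "feature", "cgi_context", "flags"]
DMR_COLUMNS = ["chrom", "start", "end", "direction", "patient_id", "visit_pair"]


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str}, keep_default_na=False)
    df = df.set_index("probe_id")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    df["pos"] = df["pos"].astype(int)
    return df[MANIFEST_COLUMNS]


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest[MANIFEST_COLUMNS].to_csv(path, sep="\t", index_label="probe_id")


def read_beta_matrix(beta_path, samples_path) -> BetaMatrix:
    values = pd.read_csv(beta_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str})
    return BetaMatrix(values, samples)


def write_beta_matrix(matrix: BetaMatrix, beta_path, samples_path) -> None:
    matrix.values.to_csv(beta_path, sep="\t", index_label="probe_id", float_format="%.6g")
    matrix.samples[["sample_id", "group", "replicate"]].to_csv(
        samples_path, sep="\t", index=False
    )


def read_expression(expr_path, samples_path, mode: str = "counts") -> ExpressionMatrix:
    counts = pd.read_csv(expr_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str})
    return ExpressionMatrix(counts, samples, mode=mode)


def write_expression(expr: ExpressionMatrix, expr_path, samples_path=None) -> None:
    expr.counts.to_csv(expr_path, sep="\t", index_label="gene")
    if samples_path is not None:
        expr.samples[["sample_id", "group", "replicate"]].to_csv(
            samples_path, sep="\t", index=False
        )


def read_dmps(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    return df[[c for c in DMP_COLUMNS if c in df.columns] +
              [c for c in df.columns if c not in DMP_COLUMNS]]


def write_dmps(dmps: pd.DataFrame, path) -> None:
    lead = [c for c in DMP_COLUMNS if c in dmps.columns]
    rest = [c for c in dmps.columns if c not in lead]
    dmps[lead + rest].to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_degs(degs: pd.DataFrame, path) -> None:
    degs[DEG_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_degs(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")[DEG_COLUMNS]


def read_regions(path) -> pd.DataFrame:
    """BED-like TSV: chrom, start, end, optional direction/source columns."""
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "start", "end"} <= set(df.columns):
        df = pd.read_csv(path, sep="\t", header=None)
        names = ["chrom", "start", "end", "direction", "source"][: df.shape[1]]
        df.columns = names
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def read_patient_dmrs(path) -> list[PatientDMRSet]:
    """Cohort DMR TSV (chrom, start, end, direction, patient_id, visit_pair)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(DMR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"patient DMR table lacks columns: {sorted(missing)}")
    out = []
    for (pid, pair), sub in df.groupby(["patient_id", "visit_pair"], sort=True):
        out.append(
            PatientDMRSet(str(pid), str(pair), sub[["chrom", "start", "end", "direction"]]
                          .reset_index(drop=True))
        )
    return out


def write_patient_dmrs(patients: list[PatientDMRSet], path) -> None:
    frames = []
    for p in patients:
        sub = p.intervals.copy()
        sub["patient_id"] = p.patient_id
        sub["visit_pair"] = p.visit_pair
        frames.append(sub)
    pd.concat(frames, ignore_index=True)[DMR_COLUMNS].to_csv(path, sep="\t", index=False)


def read_outcomes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    if not {"patient_id", "ttp_days"} <= set(df.columns):
        raise ValueError("outcome table needs patient_id and ttp_days columns")
    if (df["ttp_days"] <= 0).any():
        raise ValueError("ttp_days must be positive")
    return df


def write_outcomes(outcomes: pd.DataFrame, path) -> None:
    outcomes[["patient_id", "ttp_days"]].to_csv(
        path, sep="\t", index=False, float_format="%.4f"
    )


def read_gmt(path) -> dict[str, set]:
    """GMT gene-set file: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, set] = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) >= 3:
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
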