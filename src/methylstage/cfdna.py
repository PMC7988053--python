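"""cfDNA DMR-overlap biomarker: hit counts, ratio, TTP correlation and
a probe-resampling null.

Two overlap granularities are deliberately distinct and share one
interval engine:

* the *ratio statistic* counts DMRs — a patient DMR is a hit if it
  contains at least one query DMP, tallied by the DMR's direction — and
  forms ``(n_hyper_hit + pc) / (n_hypo_hit + pc)``;
* the *resampling null* counts probes — the observed fraction of query
  DMPs lying inside any patient DMR is compared against the mean
  fraction over repeated uniform draws (without replacement) of equally
  many probes from the filtered manifest, via a one-proportion z-test.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .dmp import bh_adjust
from .intervals import intervals_containing_any, points_in_any
from .types import PatientDMRSet, RatioStat, ResamplingResult


def _query_points(dmps: pd.DataFrame, manifest: pd.DataFrame):
    probe_ids = pd.Index(dmps["probe_id"].unique())
    missing = probe_ids.difference(manifest.index)
    if len(missing):
        raise ValueError(f"query probes absent from manifest: {list(missing[:5])}")
    sub = manifest.loc[probe_ids]
    return sub["chrom"].to_numpy(), sub["pos"].to_numpy() - 1


def overlap_dmps_dmrs(
    dmps: pd.DataFrame, patient: PatientDMRSet, manifest: pd.DataFrame
) -> RatioStat:
    """Count patient DMRs containing >= 1 query DMP, by DMR direction.

    Each DMR is counted at most once regardless of how many probes fall
    inside it; duplicated query probes are collapsed first.
    """
    iv = patient.intervals
    if len(iv) == 0:
        return RatioStat(patient.patient_id, 0, 0)
    chrom, pts = _query_points(dmps, manifest)
    hits = intervals_containing_any(iv, chrom, pts)
    direction = iv["direction"].to_numpy()
    return RatioStat(
        patient_id=patient.patient_id,
        n_hyper_hit=int(hits[direction == "hyper"].sum()),
        n_hypo_hit=int(hits[direction == "hypo"].sum()),
    )


def ratio_statistic(counts: RatioStat, pseudocount: float = 0.5) -> float:
    """Hyper:hypo DMR hit ratio with a definedness pseudocount.

    With ``pseudocount=0`` and no hypomethylated hits the ratio is
    undefined and a ``ValueError`` is raised (use the default, or the
    strict mode of :func:`cohort_ratios`, instead).
    """
    if counts.n_hyper_hit < 0 or counts.n_hypo_hit < 0:
        raise ValueError("hit counts must be non-negative")
    denom = counts.n_hypo_hit + pseudocount
    if denom == 0:
        raise ValueError("zero hypomethylated hits with pseudocount=0")
    return (counts.n_hyper_hit + pseudocount) / denom


def cohort_ratios(
    dmps: pd.DataFrame,
    patients: list[PatientDMRSet],
    manifest: pd.DataFrame,
    pseudocount: float = 0.5,
    strict: bool = False,
) -> pd.DataFrame:
    """Per-patient hit counts and ratios for a cohort.

    ``strict=True`` drops (rather than pseudocounts) patients with zero
    hypomethylated hits; dropped patients are flagged in the ``kept``
    column either way.
    """
    rows = []
    for patient in patients:
        c = overlap_dmps_dmrs(dmps, patient, manifest)
        defined = c.n_hypo_hit > 0 or (not strict and pseudocount > 0)
        rows.append(
            {
                "patient_id": c.patient_id,
                "n_hyper_hit": c.n_hyper_hit,
                "n_hypo_hit": c.n_hypo_hit,
                "ratio": ratio_statistic(c, 0.0 if strict else pseudocount)
                if defined
                else np.nan,
                "kept": defined,
            }
        )
    return pd.DataFrame(rows)


def correlate_ttp(ratios: pd.DataFrame, outcomes: pd.DataFrame) -> dict:
    """Spearman correlation between the hyper:hypo ratio and TTP.

    Patients missing either value are excluded; average ranks are used
    for ties and the p value comes from the t approximation (two-sided).
    """
    merged = ratios.merge(outcomes, on="patient_id", how="inner").dropna(
        subset=["ratio", "ttp_days"]
    )
    if "kept" in merged.columns:
        merged = merged.loc[merged["kept"]]
    if len(merged) < 3:
        raise ValueError(f"need >= 3 patients with ratio and TTP, got {len(merged)}")
    rho, p = stats.spearmanr(merged["ratio"], merged["ttp_days"])
    return {"rho": float(rho), "p": float(p), "n": int(len(merged))}


def one_proportion_z(p_obs: float, p0: float, n: int) -> float:
    """z = (p_obs - p0) / sqrt(p0 (1 - p0) / n)."""
    if not 0 < p0 < 1:
        if p_obs == p0:
            return 0.0
        return math.copysign(math.inf, p_obs - p0)
    return (p_obs - p0) / math.sqrt(p0 * (1.0 - p0) / n)


def resampling_null(
    query_dmps: pd.DataFrame,
    manifest: pd.DataFrame,
    patient: PatientDMRSet,
    n_iter: int = 10000,
    seed: int | None = None,
) -> ResamplingResult:
    """Probe-resampling null for the DMP-in-DMR overlap proportion.

    ``p_obs`` is the fraction of the k unique query probes inside any of
    the patient's DMRs.  Each iteration draws k probes uniformly without
    replacement from the manifest and records its in-DMR fraction; with
    the in-DMR status of every manifest probe precomputed, the count of
    in-DMR probes in such a draw is an exact hypergeometric variate, so
    the resample is drawn directly from that distribution.  ``p0`` is
    the mean over ``n_iter`` iterations and the z statistic compares
    ``p_obs`` with ``p0`` as a one-proportion z-test (two-sided normal p).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    query_ids = pd.Index(query_dmps["probe_id"].unique())
    k = len(query_ids)
    if k < 1:
        raise ValueError("query DMP set is empty")
    N = len(manifest)
    if k > N:
        raise ValueError(f"query size {k} exceeds manifest size {N}")

    member = points_in_any(
        manifest["chrom"].to_numpy(), manifest["pos"].to_numpy() - 1, patient.intervals
    )
    in_dmr = pd.Series(member, index=manifest.index)
    missing = query_ids.difference(manifest.index)
    if len(missing):
        raise ValueError(f"query probes absent from manifest: {list(missing[:5])}")
    p_obs = float(in_dmr.loc[query_ids].mean())

    K = int(member.sum())
    rng = np.random.default_rng(seed)
    draws = rng.hypergeometric(K, N - K, k, size=n_iter) / k
    p0 = float(draws.mean())
    z = one_proportion_z(p_obs, p0, k)
    p_value = float(2.0 * stats.norm.sf(abs(z))) if math.isfinite(z) else 0.0
    if z == 0.0:
        p_value = 1.0
    return ResamplingResult(p_obs=p_obs, p0=p0, n=k, n_iter=n_iter, z=z, p_value=p_value)


def cohort_resampling(
    query_dmps: pd.DataFrame,
    manifest: pd.DataFrame,
    patients: list[PatientDMRSet],
    n_iter: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-patient resampling z-tests with a BH column across patients.

    Per-patient p values are primary (reported as-is); the adjusted
    column is provided for transparency only.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for patient in patients:
        res = resampling_null(
            query_dmps, manifest, patient, n_iter=n_iter,
            seed=int(rng.integers(2**31)),
        )
        rows.append(
            {
                "patient_id": patient.patient_id,
                "p_obs": res.p_obs,
                "p0": res.p0,
                "n": res.n,
                "z": res.z,
                "p": res.p_value,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"])
    return out
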