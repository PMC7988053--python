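"""Core containers shared across the pipeline.

Conventions used throughout the package:

* probe manifests are :class:`pandas.DataFrame` objects indexed by
  ``probe_id`` with columns ``chrom``, ``pos`` (1-based CpG coordinate),
  ``strand``, ``genes`` (semicolon-joined, possibly empty), ``feature``
  (``TSS``/``5'UTR``/``1stExon``/``Body``/``3'UTR``/``IGR``),
  ``cgi_context`` (``island``/``shore``/``shelf``/``open_sea``) and
  ``flags`` (semicolon-joined subset of ``snp``/``cross_reactive``/
  ``multi_hit``);
* interval tables (external DMC sets, patient cfDNA DMRs) are BED-style:
  0-based half-open ``start``/``end`` with a ``direction`` column;
* DMP and DEG tables are plain DataFrames with fixed column orders
  (see :mod:`methylstage.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURE_CLASSES = ("TSS", "5'UTR", "1stExon", "Body", "3'UTR", "IGR")
CGI_CONTEXTS = ("island", "shore", "shelf", "open_sea")
EXCLUSION_FLAGS = ("snp", "cross_reactive", "multi_hit")

DMP_COLUMNS = ["probe_id", "comparison", "delta_beta", "t", "p", "q", "direction"]
DEG_COLUMNS = ["gene", "comparison", "log2fc", "chi2_stat", "p", "q", "direction"]


@dataclass(frozen=True)
class Comparison:
    """A named case-vs-reference contrast between two sample groups."""

    name: str
    case_group: str
    ref_group: str

    def __post_init__(self) -> None:
        if self.case_group == self.ref_group:
            raise ValueError("case_group and ref_group must differ")

    def swapped(self) -> "Comparison":
        return Comparison(self.name + "_swapped", self.ref_group, self.case_group)


@dataclass
class BetaMatrix:
    """Probes x samples beta values in [0, 1] plus a sample sheet.

    ``values`` is indexed by probe_id with sample ids as columns;
    ``samples`` holds one row per sample with ``sample_id``, ``group``
    and ``replicate`` columns.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        missing = set(self.values.columns) - set(self.samples["sample_id"])
        if missing:
            raise ValueError(f"samples sheet is missing ids: {sorted(missing)}")
        vals = self.values.to_numpy()
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    def group_samples(self, group: str) -> list[str]:
        ids = self.samples.loc[self.samples["group"] == group, "sample_id"]
        return [s for s in ids if s in self.values.columns]

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probe_ids)], self.samples.copy())


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values (raw counts by default)."""

    counts: pd.DataFrame
    samples: pd.DataFrame
    mode: str = "counts"

    def group_samples(self, group: str) -> list[str]:
        ids = self.samples.loc[self.samples["group"] == group, "sample_id"]
        return [s for s in ids if s in self.counts.columns]


@dataclass
class PlantSpec:
    """How many probes to shift, and how, for one comparison."""

    comparison: Comparison
    n_probes: int
    delta: float = 0.3
    hyper_frac: float = 0.6

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("planted effect size delta must be > 0")
        if not 0 <= self.hyper_frac <= 1:
            raise ValueError("hyper_frac must lie in [0, 1]")


@dataclass
class StudyDesign:
    """Groups, replication and planted effects for a synthetic study."""

    groups: list[str]
    n_replicates: int
    plants: list[PlantSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("a study design needs at least 2 groups")
        if self.n_replicates < 2:
            raise ValueError("each group needs at least 2 replicates")

    @property
    def comparisons(self) -> list[Comparison]:
        return [p.comparison for p in self.plants]

    def sample_sheet(self) -> pd.DataFrame:
        rows = [
            {"sample_id": f"{g}_r{r + 1}", "group": g, "replicate": r + 1}
            for g in self.groups
            for r in range(self.n_replicates)
        ]
        return pd.DataFrame(rows)


@dataclass
class SyntheticTruth:
    """Planted ground truth attached to a synthetic data set."""

    planted_dmps: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    planted_degs: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    scenario_labels: dict[str, dict[str, str]] = field(default_factory=dict)
    patient_signal: dict[str, float] = field(default_factory=dict)
    patient_expected_ratio: dict[str, float] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)

    def planted_probes(self, comparison: str, direction: str | None = None) -> set[str]:
        pairs = self.planted_dmps.get(comparison, set())
        if direction is None:
            return {p for p, _ in pairs}
        return {p for p, d in pairs if d == direction}


@dataclass
class PatientDMRSet:
    """Direction-labelled cfDNA DMR intervals for one patient visit pair."""

    patient_id: str
    visit_pair: str
    intervals: pd.DataFrame  # chrom, start, end, direction

    def __post_init__(self) -> None:
        iv = self.intervals
        if len(iv) and not (iv["start"] < iv["end"]).all():
            raise ValueError("intervals must satisfy start < end")


@dataclass
class RatioStat:
    """Per-patient DMR hit counts and the hyper:hypo ratio."""

    patient_id: str
    n_hyper_hit: int
    n_hypo_hit: int
    ratio: float = float("nan")


@dataclass
class ResamplingResult:
    """Observed vs resampled in-DMR probe proportion with a z-test."""

    p_obs: float
    p0: float
    n: int
    n_iter: int
    z: float
    p_value: float


@dataclass
class CommonDMPSet:
    """Probes shared by several comparisons, with per-comparison directions."""

    comparisons: list[str]
    probes: pd.DataFrame  # probe_id index, one direction column per comparison
    mode: str  # same_direction | any

    @property
    def n(self) -> int:
        return len(self.probes)

    @property
    def n_hyper(self) -> int:
        return int((self.resolved_directions() == "hyper").sum())

    @property
    def n_hypo(self) -> int:
        return int((self.resolved_directions() == "hypo").sum())

    def resolved_directions(self) -> pd.Series:
        """Per-probe direction where all comparisons agree; NaN otherwise."""
        dirs = self.probes[self.comparisons]
        agree = dirs.eq(dirs.iloc[:, 0], axis=0).all(axis=1)
        out = dirs.iloc[:, 0].where(agree)
        out.name = "direction"
        return out


@dataclass
class DirectionSwitchTable:
    """2x2 quadrant counts for probes shared by two DMP collections."""

    counts: dict[tuple[str, str], int]
    total: int

    def __getitem__(self, key: tuple[str, str]) -> int:
        return self.counts.get(key, 0)
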