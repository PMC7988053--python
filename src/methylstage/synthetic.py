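"""Synthetic manifests, beta matrices, expression and patient cohorts.

The generator emulates the study design the pipeline is built for: a
methylation array over a castration-sensitive line, a castration-
resistant derivative, and enzalutamide-resistant derivatives (one
adenocarcinoma-like, two treatment-induced neuroendocrine), profiled in
triplicate, with expression data coupled to promoter/body methylation
and a metastatic patient cohort whose cfDNA methylation shift predicts
time to progression.  Every planted effect is recorded in a
:class:`~methylstage.types.SyntheticTruth` so downstream callers have an
exact oracle.

Probes are laid on a toy genome of three ~10 Mb chromosomes.  Replicate
noise is drawn on the logit scale (keeps beta in (0, 1)); planted
effects are applied on the beta scale, where the calling threshold on
delta beta lives.  Hypermethylation is only planted on probes with
baseline beta <= 0.65 and hypomethylation on probes with baseline >=
0.35, so a planted shift of 0.3 always survives as a recoverable group
difference rather than being flattened against the [0, 1] boundary.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .intervals import merge_intervals

from .types import (
    BetaMatrix,
    Comparison,
    ExpressionMatrix,
    PatientDMRSet,
    PlantSpec,
    StudyDesign,
    SyntheticTruth,
)

CHROMS = ("chr1", "chr2", "chr3")
CHROM_SIZE = 10_000_000
TSS_WINDOW = 1500  # bp upstream counted as promoter/TSS
SHORE_BP = 2000
SHELF_BP = 4000

# cell-line style default design: castration-sensitive parental (LN),
# vehicle-control castration-resistant (CRPC), and three enzalutamide-
# resistant derivatives (ADENO = AR-driven, NE1/NE2 = neuroendocrine)
DEFAULT_GROUPS = ["LN", "CRPC", "ADENO", "NE1", "NE2"]


def split_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31) from one root seed."""
    tag = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence([int(root_seed), int(tag)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def default_study_design(
    n_planted: int = 2000, delta: float = 0.3, hyper_frac: float = 0.6
) -> StudyDesign:
    """Five groups x 3 replicates with planted effects per comparison."""
    ln, crpc, adeno, ne1, ne2 = DEFAULT_GROUPS
    plants = [
        PlantSpec(Comparison("CRPC_vs_LN", crpc, ln), n_planted, delta, hyper_frac),
        PlantSpec(Comparison("ADENO_vs_LN", adeno, ln), n_planted, delta, hyper_frac),
        PlantSpec(Comparison("NE1_vs_LN", ne1, ln), n_planted, delta, hyper_frac),
        PlantSpec(Comparison("NE2_vs_LN", ne2, ln), n_planted, delta, hyper_frac),
        PlantSpec(Comparison("NE1_vs_CRPC", ne1, crpc), n_planted, delta, 0.5),
    ]
    return StudyDesign(groups=list(DEFAULT_GROUPS), n_replicates=3, plants=plants)


# ---------------------------------------------------------------------------
# manifest


def _unique_positions(rng: np.random.Generator, positions: np.ndarray, size: int) -> np.ndarray:
    """Bump duplicated positions until all are unique (1-based)."""
    positions = positions.copy()
    for _ in range(100):
        _, first = np.unique(positions, return_index=True)
        dup = np.ones(len(positions), dtype=bool)
        dup[first] = False
        if not dup.any():
            return positions
        positions[dup] += rng.integers(1, 10, size=int(dup.sum()))
        positions = np.clip(positions, 1, size)
    raise RuntimeError("could not deduplicate probe positions")


def _lay_genes(rng: np.random.Generator, n_genes: int, chrom_size: int) -> pd.DataFrame:
    """Gene coordinates per chromosome with occasional near-adjacency."""
    rows = []
    per_chrom = np.array_split(np.arange(n_genes), len(CHROMS))
    for chrom, idx in zip(CHROMS, per_chrom):
        n = len(idx)
        if n == 0:
            continue
        lengths = rng.integers(2000, 20001, size=n)
        margin = TSS_WINDOW + 500
        free = chrom_size - 2 * margin - int(lengths.sum())
        if free < n:  # genome too small for requested genes: shrink genes
            lengths = np.maximum(2000, (chrom_size // (2 * n)) * np.ones(n, dtype=int))
            free = max(n, chrom_size - 2 * margin - int(lengths.sum()))
        gap_w = rng.exponential(1.0, size=n)
        gaps = np.maximum(1, (free * gap_w / gap_w.sum()).astype(int))
        # a few tiny gaps so neighbouring TSS windows overlap gene ends,
        # producing multi-gene probes
        tiny = rng.random(n) < 0.05
        gaps[tiny] = rng.integers(100, 1200, size=int(tiny.sum()))
        cursor = margin
        for gi, L, gap in zip(idx, lengths, gaps):
            tss = cursor + gap
            if tss + L + margin > chrom_size:
                tss = int(rng.integers(margin, chrom_size - margin - L))
            rows.append(
                {
                    "gene": f"G{gi + 1:05d}",
                    "chrom": chrom,
                    "tss": int(tss),
                    "end": int(tss + L),
                    "strand": "+",
                }
            )
            cursor = tss + L
    return pd.DataFrame(rows)


def _gene_feature_windows(gene: pd.Series) -> list[tuple[int, int, str]]:
    """0-based half-open sub-windows of one gene, 5' to 3'."""
    t, e = gene["tss"], gene["end"]
    return [
        (t - TSS_WINDOW, t, "TSS"),
        (t, t + 200, "5'UTR"),
        (t + 200, t + 500, "1stExon"),
        (t + 500, max(t + 500, e - 200), "Body"),
        (max(t + 500, e - 200), e, "3'UTR"),
    ]


_FEATURE_PRIORITY = {"TSS": 0, "5'UTR": 1, "1stExon": 2, "3'UTR": 3, "Body": 4}


def generate_manifest(
    n_probes: int,
    n_genes: int,
    seed: int,
    chrom_size: int = CHROM_SIZE,
    igr_fraction: float = 0.25,
    flag_fraction: float = 0.03,
) -> pd.DataFrame:
    """Toy probe manifest with gene, feature-class and CGI annotation.

    Per-gene probe counts are strongly skewed: roughly half of annotated
    genes carry only 1–2 probes while a minority are densely covered,
    mimicking the uneven CpG coverage of genes on real arrays.
    """
    if n_probes < 1 or n_genes < 1:
        raise ValueError("n_probes and n_genes must be positive")
    if n_probes < n_genes:
        raise ValueError("need n_probes >= n_genes")
    rng = np.random.default_rng(seed)
    genes = _lay_genes(rng, n_genes, chrom_size)

    # probe budget: one probe per gene, extras skewed, remainder intergenic
    n_igr = min(int(round(n_probes * igr_fraction)), n_probes - n_genes)
    gene_budget = n_probes - n_igr
    weights = np.where(rng.random(n_genes) < 0.5, 0.03, rng.gamma(2.0, 1.0, n_genes) + 0.2)
    extra = rng.multinomial(gene_budget - n_genes, weights / weights.sum())
    counts = 1 + extra

    chroms: list[str] = []
    points: list[int] = []  # 0-based
    for (_, g), c in zip(genes.iterrows(), counts):
        lo, hi = g["tss"] - TSS_WINDOW, g["end"]
        pts = rng.integers(lo, hi, size=int(c))
        points.extend(int(p) for p in pts)
        chroms.extend([g["chrom"]] * int(c))
    # intergenic probes: uniform draws rejected out of gene windows
    gene_by_chrom = {c: s for c, s in genes.groupby("chrom")}
    need = n_igr
    while need > 0:
        cand_chrom = rng.choice(CHROMS, size=need)
        cand_pos = rng.integers(0, chrom_size, size=need)
        keep = np.ones(need, dtype=bool)
        for c, sub in gene_by_chrom.items():
            mask = cand_chrom == c
            if not mask.any():
                continue
            lo = (sub["tss"] - TSS_WINDOW).to_numpy()
            hi = sub["end"].to_numpy()
            pos = cand_pos[mask]
            inside = ((pos[:, None] >= lo[None, :]) & (pos[:, None] < hi[None, :])).any(axis=1) \
                if len(sub) <= 512 else _in_windows(pos, lo, hi)
            keep[np.flatnonzero(mask)[inside]] = False
        chroms.extend(cand_chrom[keep])
        points.extend(int(p) for p in cand_pos[keep])
        need -= int(keep.sum())

    probes = pd.DataFrame({"chrom": chroms, "point": points})
    # unique 1-based positions per chromosome
    pos = np.zeros(len(probes), dtype=np.int64)
    for c in CHROMS:
        mask = (probes["chrom"] == c).to_numpy()
        pos[mask] = _unique_positions(rng, probes.loc[mask, "point"].to_numpy() + 1, chrom_size)
    probes["pos"] = pos
    probes = probes.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    probes.index = [f"cg{i + 1:08d}" for i in range(len(probes))]
    probes.index.name = "probe_id"

    # gene + feature annotation (multi-gene probes keep every gene; the
    # feature label follows a fixed priority, promoter first)
    gene_lists = [[] for _ in range(len(probes))]
    features = np.full(len(probes), "IGR", dtype=object)
    prio = np.full(len(probes), 99)
    for c in CHROMS:
        mask = (probes["chrom"] == c).to_numpy()
        idx = np.flatnonzero(mask)
        pts = probes.loc[mask, "pos"].to_numpy() - 1
        order = np.argsort(pts)
        pts_sorted = pts[order]
        for _, g in gene_by_chrom.get(c, pd.DataFrame()).iterrows():
            for lo, hi, feat in _gene_feature_windows(g):
                if hi <= lo:
                    continue
                a = np.searchsorted(pts_sorted, lo, side="left")
                b = np.searchsorted(pts_sorted, hi, side="left")
                for j in idx[order[a:b]]:
                    if g["gene"] not in gene_lists[j]:
                        gene_lists[j].append(g["gene"])
                    if _FEATURE_PRIORITY[feat] < prio[j]:
                        prio[j] = _FEATURE_PRIORITY[feat]
                        features[j] = feat

    # CGI contexts from islands placed at ~60% of TSSs plus random ones
    islands = []
    for _, g in genes.iterrows():
        if rng.random() < 0.6:
            w = int(rng.integers(400, 1500))
            islands.append((g["chrom"], max(0, g["tss"] - w // 2), g["tss"] + w // 2))
    for _ in range(max(1, n_genes // 4)):
        c = str(rng.choice(CHROMS))
        s = int(rng.integers(0, chrom_size - 1500))
        islands.append((c, s, s + int(rng.integers(400, 1500))))
    isl = pd.DataFrame(islands, columns=["chrom", "start", "end"])
    context = np.full(len(probes), "open_sea", dtype=object)
    for c in CHROMS:
        mask = (probes["chrom"] == c).to_numpy()
        sub = isl.loc[isl["chrom"] == c]
        if not mask.any() or not len(sub):
            continue
        pts = probes.loc[mask, "pos"].to_numpy() - 1
        starts, ends = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
        dist = _distance_to_intervals(pts, starts, ends)
        ctx = np.where(
            dist == 0, "island",
            np.where(dist <= SHORE_BP, "shore", np.where(dist <= SHELF_BP, "shelf", "open_sea")),
        )
        context[mask] = ctx

    flagged = rng.random(len(probes)) < flag_fraction
    flag_choices = np.array(["snp", "cross_reactive", "multi_hit"])
    flags = np.full(len(probes), "", dtype=object)
    for j in np.flatnonzero(flagged):
        picked = rng.choice(flag_choices, size=int(rng.integers(1, 3)), replace=False)
        flags[j] = ";".join(sorted(picked))

    manifest = pd.DataFrame(
        {
            "chrom": probes["chrom"],
            "pos": probes["pos"],
            "strand": rng.choice(["+", "-"], size=len(probes)),
            "genes": [";".join(gl) for gl in gene_lists],
            "feature": features,
            "cgi_context": context,
            "flags": flags,
        },
        index=probes.index,
    )
    return manifest


def _in_windows(pos: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    order = np.argsort(lo)
    lo, hi = lo[order], hi[order]
    idx = np.searchsorted(lo, pos, side="right") - 1
    return (idx >= 0) & (pos < hi[np.clip(idx, 0, len(hi) - 1)])


def _distance_to_intervals(pts: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """bp distance from each point to the nearest interval (0 if inside)."""
    idx = np.searchsorted(starts, pts, side="right") - 1
    inside = (idx >= 0) & (pts < ends[np.clip(idx, 0, len(ends) - 1)])
    d_prev = np.where(idx >= 0, pts - ends[np.clip(idx, 0, len(ends) - 1)] + 1, np.iinfo(np.int64).max)
    nxt = np.clip(idx + 1, 0, len(starts) - 1)
    d_next = np.where(idx + 1 < len(starts), starts[nxt] - pts, np.iinfo(np.int64).max)
    dist = np.minimum(np.maximum(d_prev, 0), np.maximum(d_next, 0))
    return np.where(inside, 0, dist)


# ---------------------------------------------------------------------------
# beta matrix


def _baseline_beta(rng: np.random.Generator, manifest: pd.DataFrame) -> np.ndarray:
    """Bimodal baselines conditioned on CGI context (islands low)."""
    ctx = manifest["cgi_context"].to_numpy()
    base = np.empty(len(manifest))
    params = {
        "island": (1.0, 8.0),
        "shore": (2.0, 5.0),
        "shelf": (5.0, 2.0),
        "open_sea": (8.0, 1.0),
    }
    for name, (a, b) in params.items():
        mask = ctx == name
        base[mask] = rng.beta(a, b, size=int(mask.sum()))
    return np.clip(base, 0.02, 0.98)


def generate_beta_matrix(
    manifest: pd.DataFrame,
    design: StudyDesign,
    seed: int,
    noise_sd: float = 0.15,
    truth: SyntheticTruth | None = None,
) -> tuple[BetaMatrix, SyntheticTruth]:
    """Replicate beta values with planted group differences.

    A probe-by-group shift matrix is built from the design's plant
    specs (each planted probe shifted by ±delta in the plant's case
    group); the recorded truth for *every* comparison is derived from
    that shift matrix, so comparisons that share a shifted group agree
    with what the data actually contain.
    """
    rng = np.random.default_rng(seed)
    for g in design.groups:
        if design.n_replicates < 2:
            raise ValueError(f"group {g} needs >= 2 replicates")
    baseline = _baseline_beta(rng, manifest)
    n_probes, groups = len(manifest), design.groups
    shift = pd.DataFrame(np.zeros((n_probes, len(groups))), index=manifest.index, columns=groups)

    base = pd.Series(baseline, index=manifest.index)
    available = pd.Series(manifest["flags"] == "", index=manifest.index)
    for plant in design.plants:
        if plant.comparison.case_group not in groups or plant.comparison.ref_group not in groups:
            raise ValueError(f"plant groups not in design: {plant.comparison}")
        n_hyper = int(round(plant.n_probes * plant.hyper_frac))
        n_hypo = plant.n_probes - n_hyper
        elig_hyper = manifest.index[available & (base <= 1 - plant.delta - 0.05)]
        if len(elig_hyper) < n_hyper:
            raise ValueError("not enough eligible probes to plant hyper effects")
        hyper = rng.choice(elig_hyper, size=n_hyper, replace=False)
        available.loc[hyper] = False
        elig_hypo = manifest.index[available & (base >= plant.delta + 0.05)]
        if len(elig_hypo) < n_hypo:
            raise ValueError("not enough eligible probes to plant hypo effects")
        hypo = rng.choice(elig_hypo, size=n_hypo, replace=False)
        available.loc[hypo] = False
        shift.loc[hyper, plant.comparison.case_group] += plant.delta
        shift.loc[hypo, plant.comparison.case_group] -= plant.delta

    truth = truth or SyntheticTruth()
    truth.seeds["beta"] = seed
    for cmp in design.comparisons:
        diff = shift[cmp.case_group] - shift[cmp.ref_group]
        planted = {
            (probe, "hyper" if d > 0 else "hypo")
            for probe, d in diff.items()
            if d != 0
        }
        truth.planted_dmps[cmp.name] = planted

    sheet = design.sample_sheet()
    mu = np.clip(baseline[:, None] + shift.to_numpy(), 0.01, 0.99)
    cols = {}
    for gi, g in enumerate(groups):
        noise = rng.normal(0.0, noise_sd, size=(n_probes, design.n_replicates))
        vals = expit(logit(mu[:, gi])[:, None] + noise)
        for r in range(design.n_replicates):
            cols[f"{g}_r{r + 1}"] = vals[:, r]
    values = pd.DataFrame(cols, index=manifest.index).clip(1e-6, 1 - 1e-6)
    return BetaMatrix(values, sheet), truth


# ---------------------------------------------------------------------------
# expression


def _gene_plant_counts(truth: SyntheticTruth, manifest: pd.DataFrame, comparison: str) -> pd.DataFrame:
    """Planted TSS/body DMP counts per gene for one comparison."""
    planted = truth.planted_dmps.get(comparison, set())
    if not planted:
        raise ValueError(f"truth has no planted DMPs for {comparison!r}")
    rows = []
    for probe, direction in planted:
        feat = manifest.at[probe, "feature"]
        for gene in filter(None, manifest.at[probe, "genes"].split(";")):
            rows.append({"gene": gene, "feature": feat, "direction": direction})
    counts = pd.DataFrame(rows, columns=["gene", "feature", "direction"])
    out = []
    for gene, sub in counts.groupby("gene"):
        out.append(
            {
                "gene": gene,
                "tss_hyper": int(((sub["feature"] == "TSS") & (sub["direction"] == "hyper")).sum()),
                "tss_hypo": int(((sub["feature"] == "TSS") & (sub["direction"] == "hypo")).sum()),
                "body_hyper": int(((sub["feature"] == "Body") & (sub["direction"] == "hyper")).sum()),
                "body_hypo": int(((sub["feature"] == "Body") & (sub["direction"] == "hypo")).sum()),
            }
        )
    return pd.DataFrame(out).set_index("gene")


_SCENARIO_RULES = {
    # scenario: (expression direction, required planted cell, forbidden cell)
    "a": ("down", "tss_hyper", "body_hyper"),
    "b": ("up", "body_hyper", "tss_hyper"),
    "c": ("down", "body_hypo", "tss_hypo"),
    "d": ("up", "tss_hypo", "body_hypo"),
}


def generate_expression(
    truth: SyntheticTruth,
    manifest: pd.DataFrame,
    design: StudyDesign,
    seed: int,
    comparison: str | None = None,
    n_per_scenario: int = 100,
    scenario_fractions: dict[str, float] | None = None,
    fold_change: float = 4.0,
    dispersion: float = 800.0,
    mean_log_expression: float = 5.5,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Negative-binomial counts with scenario-coupled expression shifts.

    Scenario genes are drawn from genes whose *already planted* DMPs
    satisfy the scenario's methylation pattern for ``comparison``
    (default: the design's last plant), then shifted ``fold_change``-fold
    up or down in that comparison's case group.  ``dispersion`` is the
    negative-binomial size parameter; the large default keeps counts
    close to Poisson, matching the technical-replicate character of the
    emulated cell-line libraries.
    """
    rng = np.random.default_rng(seed)
    cmp = None
    comparison = comparison or design.comparisons[-1].name
    for c in design.comparisons:
        if c.name == comparison:
            cmp = c
    if cmp is None:
        raise ValueError(f"comparison {comparison!r} not in design")

    all_genes = sorted(
        {g for gl in manifest["genes"] for g in gl.split(";") if g}
    )
    if scenario_fractions is not None:
        bad = set(scenario_fractions) - set(_SCENARIO_RULES)
        if bad:
            raise ValueError(f"unknown scenarios: {sorted(bad)}")
        if sum(scenario_fractions.values()) > 1:
            raise ValueError("scenario fractions must sum to <= 1")
        targets = {
            s: int(round(f * len(all_genes))) for s, f in scenario_fractions.items()
        }
    else:
        targets = {s: n_per_scenario for s in _SCENARIO_RULES}

    labels: dict[str, str] = {}
    degs: set[tuple[str, str]] = set()
    if any(targets.values()):
        plant_counts = _gene_plant_counts(truth, manifest, comparison)
        taken: set[str] = set()
        for scenario, want in targets.items():
            if want == 0:
                continue
            expr_dir, need, forbid = _SCENARIO_RULES[scenario]
            elig = plant_counts.loc[
                (plant_counts[need] >= 1) & (plant_counts[forbid] == 0)
            ].index.difference(taken)
            chosen = list(rng.choice(sorted(elig), size=min(want, len(elig)), replace=False))
            taken |= set(chosen)
            for gene in chosen:
                labels[gene] = scenario
                degs.add((gene, expr_dir))

    base_mean = np.exp(rng.normal(mean_log_expression, 1.0, size=len(all_genes)))
    sheet = design.sample_sheet()
    gene_index = pd.Index(all_genes, name="gene")
    mu = pd.DataFrame(
        np.tile(base_mean[:, None], (1, len(sheet))), index=gene_index,
        columns=sheet["sample_id"],
    )
    case_samples = sheet.loc[sheet["group"] == cmp.case_group, "sample_id"]
    for gene, scenario in labels.items():
        factor = fold_change if _SCENARIO_RULES[scenario][0] == "up" else 1.0 / fold_change
        mu.loc[gene, case_samples] *= factor
    p = dispersion / (dispersion + mu.to_numpy())
    counts = rng.negative_binomial(dispersion, p)
    expr = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_index, columns=mu.columns), sheet
    )
    truth.planted_degs[comparison] = degs
    truth.scenario_labels[comparison] = labels
    truth.seeds["expression"] = seed
    return expr, truth


# ---------------------------------------------------------------------------
# patient cohort


def generate_cohort(
    truth: SyntheticTruth,
    manifest: pd.DataFrame,
    n_patients: int,
    seed: int,
    comparison: str | None = None,
    signal_fractions=None,
    n_dmr_range: tuple[int, int] = (200, 2000),
    width_range: tuple[int, int] = (100, 2000),
    ttp_scale: float = 365.0,
    ttp_slope: float = 1.0,
    noise_sd: float = 0.25,
) -> tuple[list[PatientDMRSet], pd.DataFrame, SyntheticTruth]:
    """Per-patient cfDNA DMR sets and a time-to-progression table.

    Each patient receives an equal number of hyper- and hypomethylated
    DMRs; a patient-specific fraction ``f`` of the hypermethylated ones
    is seeded to contain a planted hypermethylated DMP of ``comparison``
    (default: the design's last planted comparison in the truth).  TTP
    (days) decreases monotonically with the patient's *expected*
    hyper:hypo hit ratio — a deterministic function of ``f`` and the
    genome-wide background hit rate — times log-normal noise, so with no
    seeded signal TTP is independent of the realised overlap.
    """
    if n_patients < 3:
        raise ValueError("need >= 3 patients for a rank correlation")
    rng = np.random.default_rng(seed)
    comparison = comparison or list(truth.planted_dmps)[-1]
    query = sorted(truth.planted_probes(comparison, "hyper"))
    if not query:
        raise ValueError(f"no planted hypermethylated DMPs for {comparison!r}")
    qsub = manifest.loc[query]
    if signal_fractions is None:
        signal_fractions = np.linspace(0.0, 0.5, n_patients)
    signal_fractions = np.asarray(signal_fractions, dtype=float)
    if len(signal_fractions) != n_patients or np.any((signal_fractions < 0) | (signal_fractions > 1)):
        raise ValueError("signal_fractions must give one value in [0,1] per patient")

    chrom_sizes = {c: int(manifest.loc[manifest["chrom"] == c, "pos"].max()) + 1000
                   for c in manifest["chrom"].unique()}
    genome = float(sum(chrom_sizes.values()))
    density = len(query) / genome
    mean_width = 0.5 * (width_range[0] + width_range[1])
    p_bg = 1.0 - np.exp(-mean_width * density)

    patients: list[PatientDMRSet] = []
    outcome_rows = []
    for i, f in enumerate(signal_fractions):
        pid = f"P{i + 1:03d}"
        half = int(rng.integers(n_dmr_range[0] // 2, n_dmr_range[1] // 2 + 1))
        n_seed = int(round(f * half))
        n_bg = 2 * half - n_seed
        widths = rng.integers(width_range[0], width_range[1] + 1, size=2 * half)

        # seeded hypermethylated DMRs each contain one planted query DMP
        seed_idx = rng.choice(len(qsub), size=n_seed, replace=n_seed > len(qsub))
        seed_w = widths[:n_seed]
        points = qsub["pos"].to_numpy()[seed_idx] - 1
        offs = rng.integers(0, seed_w) if n_seed else np.array([], dtype=int)
        seed_start = np.maximum(0, points - offs)
        # background DMRs placed uniformly on the genome
        chrom_names = sorted(chrom_sizes)
        sizes = np.array([chrom_sizes[c] for c in chrom_names], dtype=float)
        bg_chrom_idx = rng.choice(len(chrom_names), size=n_bg, p=sizes / sizes.sum())
        bg_w = widths[n_seed:]
        bg_start = rng.integers(0, np.maximum(1, sizes[bg_chrom_idx].astype(int) - bg_w))
        direction = np.array(
            ["hyper"] * half + ["hypo"] * half, dtype=object
        )
        intervals = pd.DataFrame(
            {
                "chrom": np.concatenate(
                    [qsub["chrom"].to_numpy()[seed_idx],
                     np.array(chrom_names, dtype=object)[bg_chrom_idx]]
                ),
                "start": np.concatenate([seed_start, bg_start]).astype(int),
                "end": np.concatenate(
                    [seed_start + seed_w, bg_start + bg_w]
                ).astype(int),
                "direction": direction,
            }
        )
        patients.append(PatientDMRSet(pid, "A_vs_B", intervals))

        exp_hyper = n_seed + (half - n_seed) * p_bg
        exp_hypo = half * p_bg
        exp_ratio = (exp_hyper + 0.5) / (exp_hypo + 0.5)
        ttp = ttp_scale * exp_ratio ** (-ttp_slope) * np.exp(noise_sd * rng.normal())
        truth.patient_signal[pid] = float(f)
        truth.patient_expected_ratio[pid] = float(exp_ratio)
        outcome_rows.append({"patient_id": pid, "ttp_days": float(ttp)})

    truth.seeds["cohort"] = seed
    return patients, pd.DataFrame(outcome_rows), truth
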