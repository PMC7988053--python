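"""Set algebra over DMP sets across the staged comparison scheme.

A probe is "common" to several comparisons only if it passed the calling
thresholds in every one of them; no pooling of p values is performed.
Direction-switch tables cross-tabulate the per-comparison directions of
shared probes (e.g. probes hypermethylated on the way to castration
resistance but hypomethylated with the neuroendocrine transition).
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .types import CommonDMPSet, DirectionSwitchTable

DIRECTIONS = ("hyper", "hypo")


def _direction_map(dmps: pd.DataFrame) -> pd.Series:
    dup = dmps["probe_id"].duplicated()
    if dup.any():
        raise ValueError("DMP set contains duplicated probe ids")
    return dmps.set_index("probe_id")["direction"]


def common_dmps(sets: list[pd.DataFrame], mode: str = "same_direction") -> CommonDMPSet:
    """Probes present in every DMP set.

    ``mode='same_direction'`` additionally requires the direction to
    agree across all member comparisons; ``mode='any'`` keeps any shared
    probe and records the (possibly conflicting) per-comparison
    directions.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 DMP sets")
    if mode not in ("same_direction", "any"):
        raise ValueError(f"unknown mode {mode!r}")
    names, maps = [], []
    for s in sets:
        name = str(s["comparison"].iloc[0]) if len(s) else f"set{len(names)}"
        if name in names:
            name = f"{name}#{names.count(name) + 1}"
        names.append(name)
        maps.append(_direction_map(s).rename(name))
    probes = pd.concat(maps, axis=1, join="inner")
    if mode == "same_direction" and len(probes):
        agree = probes.eq(probes.iloc[:, 0], axis=0).all(axis=1)
        probes = probes.loc[agree]
    probes.index.name = "probe_id"
    return CommonDMPSet(comparisons=names, probes=probes.sort_index(), mode=mode)


def _resolved(obj) -> pd.Series:
    """Single direction per probe from a DMPSet frame or a CommonDMPSet."""
    if isinstance(obj, CommonDMPSet):
        res = obj.resolved_directions()
        if res.isna().any():
            raise ValueError(
                "input has conflicting per-comparison directions; build it "
                "with mode='same_direction' first"
            )
        return res
    return _direction_map(obj)


def direction_switches(a, b) -> DirectionSwitchTable:
    """2x2 table of (direction in a, direction in b) over shared probes."""
    da, db = _resolved(a), _resolved(b)
    shared = da.index.intersection(db.index)
    counts = {(x, y): 0 for x in DIRECTIONS for y in DIRECTIONS}
    for probe in shared:
        counts[(da[probe], db[probe])] += 1
    return DirectionSwitchTable(counts=counts, total=len(shared))


def delta_concordance(set_a: pd.DataFrame, set_b: pd.DataFrame):
    """Pearson correlation of delta beta over the probe intersection."""
    a = set_a.set_index("probe_id")["delta_beta"]
    b = set_b.set_index("probe_id")["delta_beta"]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared probes, got {len(shared)}")
    r, p = stats.pearsonr(a.loc[shared], b.loc[shared])
    return {"r": float(r), "p": float(p), "n": int(len(shared))}
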