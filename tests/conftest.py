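import numpy as np
import pandas as pd
import pytest

import methylstage as ms


@pytest.fixture(scope="session")
def small_manifest() -> pd.DataFrame:
    return ms.generate_manifest(n_probes=8000, n_genes=400, seed=7)


@pytest.fixture(scope="session")
def small_design() -> ms.StudyDesign:
    return ms.default_study_design(n_planted=300)


@pytest.fixture(scope="session")
def small_study(small_manifest, small_design):
    """Beta matrix + truth for the 5-group, 3-replicate toy study."""
    matrix, truth = ms.generate_beta_matrix(small_manifest, small_design, seed=11)
    return matrix, truth


@pytest.fixture(scope="session")
def small_dmps(small_manifest, small_design, small_study):
    """Called DMP tables per comparison on the filtered toy study."""
    matrix, truth = small_study
    filtered, _ = ms.filter_probes(matrix, small_manifest)
    return {
        cmp.name: ms.call_dmps(filtered, cmp) for cmp in small_design.comparisons
    }


def make_beta(values: np.ndarray, groups: list[str]) -> ms.BetaMatrix:
    """Small literal beta matrix with one sample per column."""
    n, m = values.shape
    cols = [f"s{i}" for i in range(m)]
    reps: dict[str, int] = {}
    rows = []
    for c, g in zip(cols, groups):
        reps[g] = reps.get(g, 0) + 1
        rows.append({"sample_id": c, "group": g, "replicate": reps[g]})
    return ms.BetaMatrix(
        pd.DataFrame(values, index=[f"p{i}" for i in range(n)], columns=cols),
        pd.DataFrame(rows),
    )


def make_dmp_table(records, comparison="cmp") -> pd.DataFrame:
    """DMP table from (probe_id, direction[, delta_beta[, q]]) tuples."""
    rows = []
    for rec in records:
        probe, direction = rec[0], rec[1]
        delta = rec[2] if len(rec) > 2 else (0.3 if direction == "hyper" else -0.3)
        q = rec[3] if len(rec) > 3 else 1e-4
        rows.append(
            {
                "probe_id": probe,
                "comparison": comparison,
                "delta_beta": delta,
                "t": 5.0 if delta > 0 else -5.0,
                "p": q / 2,
                "q": q,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows, columns=ms.types.DMP_COLUMNS)
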