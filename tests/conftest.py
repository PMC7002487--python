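import numpy as np
import pandas as pd
import pytest

from finsoc.simulate import SimulationConfig, simulate_pedigree, simulate_surveys


def make_sightings(rows):
    """rows: (date, group_id, individual_id[, est_group_size[, x, y]])"""
    out = []
    for r in rows:
        date, gid, ind = r[0], r[1], r[2]
        est = r[3] if len(r) > 3 else None
        x = r[4] if len(r) > 4 else 0.0
        y = r[5] if len(r) > 5 else 0.0
        out.append((date, gid, x, y, ind, est))
    df = pd.DataFrame(out, columns=["date", "group_id", "x_m", "y_m",
                                    "individual_id", "est_group_size"])
    if df["est_group_size"].isna().any():
        sizes = df.groupby(["date", "group_id"])["individual_id"].transform("size")
        df["est_group_size"] = df["est_group_size"].astype(float).fillna(sizes).astype(int)
    return df


@pytest.fixture
def toy_sightings():
    """A,B together on 2 days, each alone on 1 other day; C around."""
    return make_sightings([
        ("d1", "g1", "A"), ("d1", "g1", "B"),
        ("d2", "g2", "A"), ("d2", "g2", "B"), ("d2", "g3", "C"),
        ("d3", "g4", "A"), ("d3", "g5", "C"),
        ("d4", "g6", "B"), ("d4", "g6", "C"),
    ])


@pytest.fixture(scope="session")
def small_truth_and_surveys():
    """Small default-structure simulation shared across read-only tests."""
    cfg = SimulationConfig(n_females=25, n_clusters=3, n_days=80,
                           detect_prob=0.3, n_loci=8, alleles_per_locus=6, seed=42)
    truth = simulate_pedigree(cfg)
    surveys = simulate_surveys(truth, cfg)
    return cfg, truth, surveys


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
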