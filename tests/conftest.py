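import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import retinadev as rd

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """One seed-0 default simulation with layers, shared across tests."""
    cfg = rd.SimConfig(seed=0)
    m, meta, truth = rd.gen_timecourse(cfg)
    m.add_layer("log_cpm", rd.log_cpm(m))
    m.add_layer("qnorm_log", rd.quantile_normalize(m.layers["log_cpm"]))
    junctions, jtruth = rd.gen_junctions(cfg, meta, m)
    truth.circ_trend_effect = jtruth.circ_trend_effect
    truth.de_circ_ids = jtruth.de_circ_ids
    return cfg, m, meta, junctions, truth


@pytest.fixture(scope="session")
def staged_sim(default_sim):
    """Default simulation with pipeline-assigned windows."""
    cfg, m, meta, junctions, truth = default_sim
    tree = rd.median_linkage(rd.pairwise_distances(m.layers["qnorm_log"]))
    basis = rd.moran_eigenvectors(rd.tree_to_proximity(tree))
    rules = rd.derive_window_rules(tree, basis, 4, meta=meta)
    labels = rd.assign_windows(basis, rules)
    return cfg, m, meta.with_windows(labels), junctions, truth, tree, basis


def make_meta(stage_sizes, pcws=None):
    """Small metadata table: stage_sizes = samples per consecutive stage."""
    rows = []
    for idx, n in enumerate(stage_sizes):
        pcw = pcws[idx] if pcws is not None else float(idx + 1)
        for r in range(n):
            rows.append((f"s{idx}_{r}", f"S{idx + 1}", pcw, idx))
    return rd.SampleMeta(
        pd.DataFrame(rows, columns=["sample", "stage_label", "pcw", "stage_index"])
    )


@pytest.fixture
def toy_matrix():
    """4 genes x 6 samples toy expression with a log layer equal to values."""
    rng = np.random.default_rng(11)
    counts = pd.DataFrame(
        rng.integers(10, 1000, size=(4, 6)),
        index=[f"g{i}" for i in range(4)],
        columns=[f"s{i // 3}_{i % 3}" for i in range(6)],
    )
    m = rd.ExpressionMatrix(counts)
    m.add_layer("log_cpm", rd.log_cpm(m))
    return m
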