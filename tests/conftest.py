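import logging

import numpy as np
import pandas as pd
import pytest

import riboshift as rs
from riboshift.dte import DesignSpec
from riboshift.expression import CountTable

logging.getLogger("riboshift").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_table():
    """60-gene paired dataset with a mix of planted classes."""
    cfg = rs.SimConfig(
        n_genes=60, seed=1, depth_per_library=6e4,
        class_proportions={"none": 0.5, "exclusive": 0.25, "forwarded": 0.25})
    return rs.generate_counts(cfg)


@pytest.fixture(scope="session")
def small_dte(small_table):
    table, truth = small_table
    return rs.run_dte(table), truth


@pytest.fixture(scope="session")
def cds_model():
    return rs.make_cds_model(n_genes=20, seed=2)


@pytest.fixture()
def toy_counts():
    """Tiny hand-checkable count table: 4 genes x 4 samples (2 patients,
    2 times, both assays collapsed into a minimal valid design)."""
    genes = ["gA", "gB", "gC", "gD"]
    samples = {}
    meta_rows = []
    rng = np.random.default_rng(0)
    for p in ("P1", "P2"):
        for t in ("0", "2h"):
            for a in ("RNA", "RPF"):
                sid = f"{p}_{t}_{a}"
                samples[sid] = rng.integers(50, 200, size=4)
                meta_rows.append(
                    {"sample_id": sid, "patient": p, "time": t, "assay": a})
    counts = pd.DataFrame(samples, index=genes)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    meta["time"] = pd.Categorical(meta["time"], ["0", "2h"], ordered=True)
    cds = pd.Series([300, 900, 1500, 600], index=genes)
    return CountTable(counts, meta, cds)


@pytest.fixture()
def toy_design(toy_counts):
    return DesignSpec.from_meta(toy_counts.meta)
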