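"""Shared fixtures: a tiny handmade count table and a session-scoped
convergent synthetic dataset with its CLR/PCA derivatives."""

import numpy as np
import pandas as pd
import pytest

import phycosplit as ps


def make_table(counts: np.ndarray, meta_rows: list[dict]) -> ps.CountTable:
    """Build a CountTable from a taxa x samples array and metadata dicts."""
    sample_ids = [m["sample_id"] for m in meta_rows]
    taxa = [f"t{i + 1}" for i in range(counts.shape[0])]
    counts_df = pd.DataFrame(counts, index=taxa, columns=sample_ids)
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    return ps.CountTable(counts_df, samples)


def meta(sid, soil="A", treatment="hybrid", tau=12, rnd=2, rep=1) -> dict:
    return {
        "sample_id": sid,
        "soil": soil,
        "treatment": treatment,
        "growth_period_days": tau,
        "round": rnd,
        "replicate": rep,
    }


@pytest.fixture
def tiny_table() -> ps.CountTable:
    counts = np.array([[10, 30, 5], [10, 10, 5], [0, 0, 10]])
    rows = [
        meta("s1", rnd=2, rep=1),
        meta("s2", rnd=10, rep=1),
        meta("s3", soil="B", treatment="control", rnd=2, rep=1),
    ]
    return make_table(counts, rows)


@pytest.fixture(scope="session")
def design() -> ps.DesignSpec:
    return ps.DesignSpec(seed=1)


@pytest.fixture(scope="session")
def truth(design) -> ps.GroundTruth:
    return ps.make_ground_truth(design)


@pytest.fixture(scope="session")
def table(design, truth) -> ps.CountTable:
    return ps.simulate_counts(design, truth)


@pytest.fixture(scope="session")
def filtered(table) -> ps.CountTable:
    filt, _ = ps.remove_rare_taxa(table)
    return filt


@pytest.fixture(scope="session")
def clr(filtered) -> ps.ClrMatrix:
    return ps.clr_transform(filtered)


@pytest.fixture(scope="session")
def pca(clr) -> ps.PcaModel:
    return ps.fit_pca(clr)


def null_design(seed: int, **kw) -> tuple[ps.DesignSpec, ps.GroundTruth]:
    """Small structure-free design: no drift, no suppression, shared pools."""
    d = ps.DesignSpec(
        n_taxa=kw.pop("n_taxa", 80),
        depth=kw.pop("depth", 4000),
        growth_periods=kw.pop("growth_periods", (3, 12)),
        seed=seed,
        **kw,
    )
    t = ps.make_ground_truth(
        d, suppression_slope=0.0, drift_sd=0.0, soil_b_boost=0.0
    )
    return d, t
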