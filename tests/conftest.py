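"""Shared fixtures: hand-built tables and a default synthetic dataset."""

import numpy as np
import pytest
from hypothesis import strategies as st

from otufilter import OtuTable, ReplicateDesign, SimulationConfig, generate


def make_table(counts, otu_ids=None, sample_ids=None) -> OtuTable:
    return OtuTable(np.asarray(counts), otu_ids=otu_ids, sample_ids=sample_ids)


def make_triplicate_design(n_specimens: int) -> ReplicateDesign:
    """Design for samples named Ind<i>_r<1..3>."""
    return ReplicateDesign({
        f"Ind{i + 1:02d}_r{r + 1}": f"Ind{i + 1:02d}"
        for i in range(n_specimens) for r in range(3)
    })


def triplicate_table(rows, n_specimens: int, otu_ids=None):
    """Table + design from per-OTU rows of length 3 * n_specimens."""
    samples = [f"Ind{i + 1:02d}_r{r + 1}"
               for i in range(n_specimens) for r in range(3)]
    return (make_table(rows, otu_ids=otu_ids, sample_ids=samples),
            make_triplicate_design(n_specimens))


@st.composite
def count_tables(draw, max_otus=8, max_samples=6, max_count=50):
    """Random small integer count matrices as OtuTable."""
    n_otus = draw(st.integers(1, max_otus))
    n_samples = draw(st.integers(1, max_samples))
    counts = draw(st.lists(
        st.lists(st.integers(0, max_count), min_size=n_samples,
                 max_size=n_samples),
        min_size=n_otus, max_size=n_otus))
    return make_table(counts)


@st.composite
def triplicate_tables(draw, max_otus=8, max_specimens=3, max_count=30):
    """Random tables with complete triplicate structure."""
    n_otus = draw(st.integers(1, max_otus))
    n_spec = draw(st.integers(1, max_specimens))
    counts = draw(st.lists(
        st.lists(st.integers(0, max_count), min_size=3 * n_spec,
                 max_size=3 * n_spec),
        min_size=n_otus, max_size=n_otus))
    return triplicate_table(counts, n_spec)


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic dataset at the default (calibrated) configuration."""
    return generate(SimulationConfig(), seed=20240901)


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced dataset for fast grid-level tests."""
    cfg = SimulationConfig(
        n_specimens=4, n_core_otus=80, depth_mean=3000.0, depth_sd=600.0,
        depth_min=1500, depth_max=6000, depth_within_sd=300.0,
        spurious_rate=15.0,
        spurious_pool_size=400, individuality=200.0,
    )
    return generate(cfg, seed=7)
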