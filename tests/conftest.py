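"""Shared fixtures: synthetic bundles generated once per session."""

import numpy as np
import pytest

from cgimethpred import (
    SimulationSpec,
    extract_all,
    read_cpg_calls,
    simulate,
)
from cgimethpred.label_builder import build_dataset


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """60 islands, 4 tissues: cheap multi-tissue bundle."""
    spec = SimulationSpec(seed=3, n_islands=60, n_tissues=4)
    return simulate(spec, tmp_path_factory.mktemp("bundle_small"))


@pytest.fixture(scope="session")
def cv_bundle(tmp_path_factory):
    """120 islands, one tissue, planted histone signal: CV-scale bundle."""
    spec = SimulationSpec(seed=11, n_islands=120, n_tissues=1)
    return simulate(spec, tmp_path_factory.mktemp("bundle_cv"))


@pytest.fixture(scope="session")
def cv_data(cv_bundle):
    """(matrix, labels, intensities) for the CV-scale bundle's tissue."""
    genome = cv_bundle.load_genome()
    manifest = cv_bundle.load_manifest()
    islands = cv_bundle.load_planted_islands()
    calls = read_cpg_calls(cv_bundle.calls_tsv)
    matrix = extract_all(islands, genome, manifest)
    ds = build_dataset("CD4", islands, calls, genome)
    tr = ds.trainable.set_index("island_id")
    ids = [i for i in matrix.island_ids if i in tr.index]
    y = (tr.loc[ids, "label"] == "methylated").astype(int).to_numpy()
    intensities = tr.loc[ids, "intensity"].to_numpy()
    return matrix.subset_rows(ids), y, intensities


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
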