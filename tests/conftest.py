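import numpy as np
import pandas as pd
import pytest

from woundnet import grn, pointwise, signatures
from woundnet.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_bundle():
    """A compact but complete synthetic experiment shared across tests."""
    return simulate_experiment(SimulationConfig(n_genes=300, n_tfs=12,
                                                seed=11))


@pytest.fixture(scope="session")
def small_norm(small_bundle):
    b = small_bundle
    sf = pointwise.estimate_size_factors(b.counts)
    disp = pointwise.estimate_dispersion(b.counts, sf, b.design)
    traj = signatures.trajectory_matrix(b.counts, b.design, sf)
    return {"sf": sf, "disp": disp, "traj": traj}


@pytest.fixture(scope="session")
def default_bundle():
    """The generator at its default study-scale configuration."""
    return simulate_experiment(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_network(default_bundle):
    """Recovered binding evidence and annotated edges at default scale."""
    b = default_bundle
    hits = grn.scan_promoters(b.promoters, b.pwms)
    windows = grn.promoter_windows(b.annotation)
    peak_ev = grn.map_peaks_to_promoters(b.peaks, windows)
    matrix, evidence = grn.build_tf_target_matrix(peak_ev, hits)
    sf = pointwise.estimate_size_factors(b.counts)
    traj = signatures.trajectory_matrix(b.counts, b.design, sf)
    fpkm = pointwise.compute_fpkm(b.counts, sf, b.annotation)
    fpkm_tp = grn.tf_fpkm_by_timepoint(fpkm, b.design)
    edges = grn.annotate_edges(evidence, traj, fpkm_tp, b.annotation)
    return {"matrix": matrix, "evidence": evidence, "edges": edges,
            "traj": traj, "fpkm_tp": fpkm_tp, "sf": sf}


def nb_counts(rng, mean, alpha, size=None):
    """Draw NB counts with Var = mu + alpha mu^2."""
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + np.asarray(mean)), size=size)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
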