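"""Shared fixtures: ideal helices, toy energy model, and replica ensembles.

The heavier ensembles are session-scoped so the orientation pipeline runs
once and is reused across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from helixmodes.energetics import load_energy_model
from helixmodes.pipeline import ensemble_orientation_samples
from helixmodes.structure_io import Frame
from helixmodes.synthetic import (
    MIGM_FIRST_RESIDUE,
    MIGM_TMD_SEQUENCE,
    EnsembleSpec,
    build_ideal_helix,
    simulate_association,
)

# conditions of the headline two-mode recovery experiment: the package
# defaults plant two wells at (60, 120) and (240, 300), width 15 deg, well
# depths in 2:1 ratio
TWO_MODE_SPEC = EnsembleSpec(n_replicas=100, t_total=1000.0, seed=2026)


@pytest.fixture(scope="session")
def mu_helix():
    """Ideal 32-residue IgM heavy-chain TM helix along +z."""
    return build_ideal_helix(
        MIGM_TMD_SEQUENCE, chain_id="A", first_residue=MIGM_FIRST_RESIDUE
    )


@pytest.fixture(scope="session")
def energy_model():
    return load_energy_model()


@pytest.fixture(scope="session")
def mu_pair_frame(mu_helix):
    """Two ideal mu helices in contact at 0.95 nm axis separation."""
    frame, topo = mu_helix
    frame_b, topo_b = build_ideal_helix(
        MIGM_TMD_SEQUENCE, chain_id="B", first_residue=MIGM_FIRST_RESIDUE
    )
    coords = np.vstack([frame.coordinates, frame_b.coordinates + [0.95, 0.0, 0.0]])
    chain_index = np.concatenate([np.zeros(32, int), np.ones(32, int)])
    return Frame(coords, frame.box, chain_index), [topo, topo_b]


@pytest.fixture(scope="session")
def small_ensemble():
    """Cheap association ensemble for pipeline-level tests."""
    spec = EnsembleSpec(n_replicas=30, t_total=400.0, seed=5)
    return spec, simulate_association(spec)


@pytest.fixture(scope="session")
def two_mode_ensemble():
    """The two-well study-condition ensemble (100 replicas x 1000 ns)."""
    return TWO_MODE_SPEC, simulate_association(TWO_MODE_SPEC)


@pytest.fixture(scope="session")
def two_mode_window_samples(two_mode_ensemble, energy_model):
    """Trailing-50-ns orientation samples through the full analysis path
    (frames -> axis fits -> beta/chi; bound by the -200 kJ/mol criterion)."""
    _, result = two_mode_ensemble
    return ensemble_orientation_samples(result, energy_model, window=50.0)
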