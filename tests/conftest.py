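"""Shared fixtures: tissue stacks and a handful of session-scoped Monte
Carlo runs reused across test modules (problem sizes chosen so the whole
suite runs in a few minutes on one core)."""

from __future__ import annotations

import numpy as np
import pytest

from mcfocus import (
    FluorSource,
    PencilBeam,
    QD_DEPTHS_CM,
    default_stack,
    run_emission,
    run_transport,
)
from mcfocus.tissue import LayerOpticalProperties, LayerStack


@pytest.fixture(scope="session")
def s785():
    return default_stack("excitation_785")


@pytest.fixture(scope="session")
def s1100():
    return default_stack("emission_1100")


@pytest.fixture(scope="session")
def excitation_run(s785):
    """785 nm pencil-beam run scoring all four quantum-dot planes."""
    return run_transport(
        s785, PencilBeam(), 400_000, seed=101, planes=QD_DEPTHS_CM,
        plane_bin_radius=0.005,
    )


@pytest.fixture(scope="session")
def pencil_1100_run(s1100):
    """1100 nm pencil-beam run (NIR-II fluence map comparison)."""
    return run_transport(s1100, PencilBeam(), 150_000, seed=102)


@pytest.fixture(scope="session")
def emission_runs(s1100):
    """Forward-model emission runs at three depths with preset weights."""
    from mcfocus import inherited_weight

    runs = {}
    for z, n, seed in [(0.04, 200_000, 201), (0.08, 200_000, 202),
                       (0.20, 500_000, 203)]:
        runs[z] = run_emission(
            s1100,
            FluorSource(z_qd=z, w0=inherited_weight(z), n_emit=n),
            seed=seed,
            model="forward",
        )
    return runs


@pytest.fixture(scope="session")
def emission_iso_run(s1100):
    """Physically isotropic emission run at the cortical surface."""
    return run_emission(
        s1100, FluorSource(z_qd=0.04, w0=1.0, n_emit=150_000), seed=204,
        model="isotropic",
    )


@pytest.fixture(scope="session")
def vacuum_stack():
    """Single matched-index, non-interacting slab (ballistic oracle)."""
    lay = LayerOpticalProperties("void", 1.0, 0.0, 0.0, 0.0, 1.0)
    return LayerStack("custom", (lay,), ambient_above_n=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
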