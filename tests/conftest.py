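"""Shared fixtures: phantoms and reconstructions reused across the suite.

All phantoms keep the clinical 128 x 128 in-plane matrix at 2.6 mm and vary
only the number of slices, so organ proportions and the lung-volume range
stay realistic while reconstructions remain fast.
"""

from __future__ import annotations

import pytest

from petmrac.grid import GridSpec
from petmrac.phantom import PhantomConfig, generate_phantom
from petmrac.simulate import ReconProtocol, forward_project, labels_to_mu, reconstruct_osem


@pytest.fixture(scope="session")
def protocol():
    return ReconProtocol()


@pytest.fixture(scope="session")
def thorax16():
    """Thin-slab thorax (128 x 128 x 16) with labels, activity and mu."""
    grid = GridSpec((128, 128, 16))
    cfg = PhantomConfig.default(grid)
    labels, activity = generate_phantom(cfg, seed=5)
    return {
        "grid": grid,
        "cfg": cfg,
        "labels": labels,
        "activity": activity,
        "mu": labels_to_mu(labels),
    }


@pytest.fixture(scope="session")
def sino16(thorax16, protocol):
    return forward_project(thorax16["activity"], thorax16["mu"], protocol)


@pytest.fixture(scope="session")
def recon_ac16(sino16, thorax16, protocol):
    return reconstruct_osem(sino16, thorax16["mu"], protocol)


@pytest.fixture(scope="session")
def recon_nonac16(sino16, protocol):
    return reconstruct_osem(sino16, None, protocol)


@pytest.fixture(scope="session")
def thorax64():
    """Full-length thorax (128 x 128 x 64) plus its nonAC reconstruction,
    the working material for misalignment recovery."""
    grid = GridSpec((128, 128, 64))
    cfg = PhantomConfig.default(grid)
    labels, activity = generate_phantom(cfg, seed=9)
    mu = labels_to_mu(labels)
    protocol = ReconProtocol()
    sino = forward_project(activity, mu, protocol)
    nonac = reconstruct_osem(sino, None, protocol)
    return {
        "grid": grid,
        "cfg": cfg,
        "labels": labels,
        "activity": activity,
        "mu": mu,
        "sino": sino,
        "nonac": nonac,
    }
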