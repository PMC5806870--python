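"""Shared fixtures: tiny deterministic grids and one mini watershed bundle.

The expensive session fixtures (bundle, calibrated ensemble, strategy
curves) are shared between the unit suite and the acceptance tests so the
whole run stays well inside the CI budget.
"""

from __future__ import annotations

import numpy as np
import pytest

from sedscape import calibration, synthetic, terrain, workflow
from sedscape.raster import Raster


def plane_dem(ny=8, nx=8, dzdx=0.0, dzdy=0.0, cell=5.0, base=100.0) -> Raster:
    """Tilted plane: z = base + dzdx*x - dzdy*y(row) in grid metres."""
    rows = np.arange(ny)[:, None] * cell
    cols = np.arange(nx)[None, :] * cell
    return Raster(base + dzdx * cols + dzdy * rows, cell)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_flow_grid(seed: int, n: int | None = None, cell: float = 5.0):
    """A filled random DEM and its flow field, for oracle comparisons."""
    rng = np.random.default_rng(seed)
    if n is None:
        n = int(rng.integers(5, 16))
    dem = Raster(rng.random((n, n)) * 20.0, cell)
    filled = terrain.fill_depressions(dem)
    flow = terrain.d8_flow(filled, threshold=max(3, n))
    return filled, flow


# Truth with the highest K option: every max-K member must calibrate and
# the min-K members must be discarded (the member-dismissal structure).
REFERENCE_TRUTH = dict(
    k_option="max", forest_sre=0.65, linkage="increasing",
    pasture_c=0.20, pasture_sre=0.08,
)
REFERENCE_SEED = 7


@pytest.fixture(scope="session")
def mini_bundle():
    truth = synthetic.TruthParams(**REFERENCE_TRUTH)
    return synthetic.make_reference_watershed(
        seed=REFERENCE_SEED, size="mini", truth=truth
    )


@pytest.fixture(scope="session")
def ensemble(mini_bundle):
    members = calibration.build_members()
    results, summary = calibration.run_ensemble(
        members, mini_bundle, mini_bundle.truth.observed_se
    )
    return results, summary


@pytest.fixture(scope="session")
def strategy_comparison(mini_bundle, ensemble):
    results, _ = ensemble
    curves, baseline = workflow.strategy_curves(
        mini_bundle, results, [15.0, 25.0]
    )
    return curves, baseline
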