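"""Shared fixtures: small grids and one session-scoped synthetic landscape."""

from __future__ import annotations

import numpy as np
import pytest

import riversdm as r
from riversdm.grid import GridGeometry


@pytest.fixture
def small_geometry() -> GridGeometry:
    return GridGeometry(west=0.0, north=1.0, cellsize=0.1, nrows=10, ncols=10)


@pytest.fixture(scope="session")
def landscape():
    """Default synthetic study conditions: strong niche, 200 occurrence
    draws, 2000 background cells on the 100×100 grid."""
    geom = r.synthetic.default_geometry()
    truth = r.synthetic.default_truth(7)
    climate = r.synthetic.make_climate(geom, seed=7)
    bio = r.derive_bioclim(climate)
    stack = r.EnvStack({"bio_1": bio["bio_1"], "bio_12": bio["bio_12"]},
                       {"bio_1": "continuous", "bio_12": "continuous"}, geom)
    records = r.synthetic.sample_occurrences(stack, truth, n=200, seed=8)
    occ = r.clean_occurrences(records, stack)
    background = r.sample_background(stack, 2000, seed=9)
    return {"geometry": geom, "truth": truth, "climate": climate,
            "bioclim": bio, "stack": stack, "records": records,
            "occurrences": occ, "background": background}


@pytest.fixture(scope="session")
def fitted_model(landscape):
    """One model fitted on all presences of the session landscape."""
    stack = landscape["stack"]
    occ = landscape["occurrences"]
    bg = landscape["background"]
    feats = r.build_features(stack, occ.cells, bg)
    return r.fit(feats, occ.cells, bg, stack)
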