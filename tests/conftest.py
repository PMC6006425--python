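"""Shared fixtures.

The expensive session fixtures simulate a small cohort once and reuse it
across tests: per-subject contrast maps for the gradient analyses, a group
t map for the spatial ROC checks, and per-subject PPI outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import gradconn as g
from gradconn.volumes import Volume

CONTRASTS = {
    "colour-control": {"colour": 1, "control": -1},
    "semantic-control": {"semantic": 1, "control": -1},
    "colour-semantic": {"colour": 1, "semantic": -1},
}


@pytest.fixture(scope="session")
def geometry():
    return g.default_geometry()


@pytest.fixture(scope="session")
def main_design():
    return g.build_main_task_design(order_seed=0)


@pytest.fixture(scope="session")
def acquisition(main_design, geometry):
    return g.AcquisitionSpec.for_design(main_design, shape=geometry.shape)


@pytest.fixture(scope="session")
def roi_vectors(geometry):
    vecs = {}
    for name in ("FG", "ITG"):
        anch = g.compute_anchors(
            Volume(geometry.sectors[name].astype(float), geometry.affine), 5, name
        )
        vecs[name] = g.place_rois(g.fit_spline(anch), anch, 2, 3.0, label=name)
    vecs["ITG"], _ = g.match_vectors(vecs["FG"], vecs["ITG"])
    return vecs


@dataclass
class CohortResults:
    n_subjects: int
    beta_maps: dict            # contrast -> list of per-subject beta StatMaps
    ppi_hits: list             # per-subject: thresholded cluster overlaps target blob
    target_blob: np.ndarray


@pytest.fixture(scope="session")
def cohort(geometry) -> CohortResults:
    """Twenty simulated subjects analysed with the full chain.

    Runs are generated, analysed (GLM contrasts + IFG-seed PPI) and discarded
    one at a time to bound memory.
    """
    n_subjects = 20
    beta_maps = {c: [] for c in CONTRASTS}
    ppi_hits = []
    blob, _ = geometry.node_blob("OCC-C")
    for i in range(n_subjects):
        subj = g.simulate_subject(seed=1000 + i, geometry=geometry)
        dm = g.build_design_matrix(subj.design, subj.acquisition, rt_s=subj.rt_s)
        fit = g.fit_glm(subj.run, dm)
        for c, w in CONTRASTS.items():
            beta_maps[c].append(g.contrast_map(fit, w, kind="beta", label=c))
        seed = g.extract_seed(subj.run, geometry.node_coords["IFG"], 6.0)
        ppi = g.build_ppi_design(
            seed, subj.design, {"colour": 1, "semantic": -1}, subj.acquisition
        )
        res = g.ppi_map(subj.run, ppi)
        ppi_hits.append(bool((res.mask & blob).any()))
    return CohortResults(n_subjects, beta_maps, ppi_hits, blob)
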