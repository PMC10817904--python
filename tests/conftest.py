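"""Shared fixtures: seeded phantoms and one session-trained patch classifier.

The expensive end-to-end fixture (cohort generation + CNN training) is
session-scoped and shared by the acceptance tests, so the network is
trained exactly once per test run.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

import octskin as ok
from octskin import patchcnn, patchset, preprocess


# ---------------------------------------------------------------------------
# study conditions for the end-to-end phantom experiment
# ---------------------------------------------------------------------------
PHANTOM_BASE = ok.PhantomConfig(height=220, width=256)
COHORT_RANGES = {
    "sc_depth_mean": (70.0, 95.0),
    "et_mean": (45.0, 75.0),
    "curvature_amplitude": (4.0, 10.0),
}
COHORT_N = 34  # splits 24 / 5 / 5
TRAIN_MAX_EPOCHS = 10
PIPE = ok.PipelineConfig(step=4, depth_below=160)


def cohort_patchsets(cohort, indices, seed=0, max_per_class=None):
    """Balanced labeled patchsets pooled over the given cohort images."""
    pieces = []
    for j, i in enumerate(indices):
        scan = preprocess.normalize(cohort.scans[i])
        air = preprocess.detect_air_boundary(preprocess.despeckle(scan))
        region_scan, region = preprocess.crop_target_region(
            scan, air, depth_below=PIPE.depth_below
        )
        pieces.append(
            patchset.extract_training_patches(
                region_scan,
                region.to_region_rows(cohort.traces_sc[i]),
                region.to_region_rows(cohort.traces_dej[i]),
                seed=seed + j,
                max_per_class=max_per_class,
            )
        )
    return patchset.PatchSet(
        centers=np.concatenate([p.centers for p in pieces]),
        patches=np.concatenate([p.patches for p in pieces]),
        spec=pieces[0].spec,
        labels=np.concatenate([p.labels for p in pieces]),
    )


@pytest.fixture(scope="session")
def phantom_cohort():
    return ok.generate_cohort(COHORT_N, COHORT_RANGES, seed=11, base_config=PHANTOM_BASE)


@pytest.fixture(scope="session")
def trained_model(phantom_cohort):
    """cnn-gs-skin preset trained on the phantom cohort's train/val splits."""
    cohort = phantom_cohort
    config = replace(ok.load_preset("cnn-gs-skin"), max_epochs=TRAIN_MAX_EPOCHS, seed=7)
    train_set = cohort_patchsets(cohort, cohort.splits["train"], seed=0)
    val_set = cohort_patchsets(cohort, cohort.splits["val"], seed=100)
    assert train_set.class_counts().min() >= 5000
    model = patchcnn.build_model(config)
    report = patchcnn.train(model, train_set, val_set, config)
    return {"model": model, "report": report, "config": config}


@pytest.fixture(scope="session")
def segmented_test_phantoms(phantom_cohort, trained_model):
    """Step-4 pipeline segmentations of the 5 held-out test phantoms."""
    model = trained_model["model"]
    results = []
    for scan, sc, dej in phantom_cohort.subset("test"):
        res = ok.segment_scan(scan, model, PIPE)
        results.append({"scan": scan, "truth_sc": sc, "truth_dej": dej, "result": res})
    return results


# ---------------------------------------------------------------------------
# independent oracle: exhaustive min-cost simple path on tiny grids
# ---------------------------------------------------------------------------
_OFF = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def brute_force_min_cost(prob: np.ndarray, w_min: float = 1e-5) -> float:
    """Minimum total edge weight over all simple paths from the top-left to
    the bottom-right pixel, by depth-first enumeration with cost pruning."""
    prob = np.asarray(prob, dtype=float)
    h, w = prob.shape
    target = (h - 1, w - 1)

    def weight(a, b):
        return 2.0 - (prob[a] + prob[b]) + w_min

    # seed the bound with one known path: across the top row, down the right edge
    bound = 0.0
    cur = (0, 0)
    for c in range(1, w):
        bound += weight(cur, (0, c))
        cur = (0, c)
    for r in range(1, h):
        bound += weight(cur, (r, w - 1))
        cur = (r, w - 1)
    best = [bound if (h, w) != (1, 1) else 0.0]

    visited = np.zeros((h, w), dtype=bool)
    visited[0, 0] = True

    def dfs(node, cost):
        if node == target:
            best[0] = min(best[0], cost)
            return
        for dr, dc in _OFF:
            nb = (node[0] + dr, node[1] + dc)
            if 0 <= nb[0] < h and 0 <= nb[1] < w and not visited[nb]:
                c2 = cost + weight(node, nb)
                if c2 < best[0]:
                    visited[nb] = True
                    dfs(nb, c2)
                    visited[nb] = False

    dfs((0, 0), 0.0)
    return best[0]
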