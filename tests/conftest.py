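import numpy as np
import pytest

from granulekit import synth
from granulekit.detect import Granule, GranuleSet


@pytest.fixture(scope="session")
def reference_field():
    """The package's reference detection scenario: SNR ~= 10, planted
    diameters 0.6-1.6 um, 5 cells x 5 granules, seed 1."""
    params = synth.FieldParams(read_noise_sd=30.0, diameter_range=(0.6, 1.6))
    return synth.generate_field_image(params, seed=1)


def make_set(centroids_by_cell, image_id="img", channel="A", pixel_size=0.1):
    """Hand-built GranuleSet from centroids only (unit-pixel granules)."""
    granules = []
    gid = 0
    for cell_id, cents in centroids_by_cell.items():
        for r, c in cents:
            granules.append(
                Granule(
                    granule_id=gid,
                    cell_id=cell_id,
                    centroid=(float(r), float(c)),
                    area_px=1,
                    equivalent_diameter_um=2.0 * np.sqrt(1 / np.pi) * pixel_size,
                    mean_intensity=1.0,
                    pixel_set=np.array([[int(r), int(c)]]),
                )
            )
            gid += 1
    return GranuleSet(
        image_id=image_id,
        channel=channel,
        pixel_size=pixel_size,
        granules=granules,
        gate=(0.0, 100.0),
        threshold_used=0.0,
        cell_ids=sorted(centroids_by_cell),
    )


@pytest.fixture
def make_granule_set():
    """Factory fixture wrapping :func:`make_set`."""

    def _make(centroids_by_cell, image_id="img", channel="A", pixel_size=0.1):
        return make_set(centroids_by_cell, image_id, channel, pixel_size)

    return _make


def match_planted(gt, granule_set, tol_px=1.0):
    """Recall/precision of a detection against planted ground truth with
    nearest-centroid matching at a pixel tolerance."""
    planted = np.array([[g.row, g.col] for g in gt.granules])
    detected = np.array([g.centroid for g in granule_set.granules])
    if planted.size == 0 or detected.size == 0:
        return 0.0, 0.0
    d = np.linalg.norm(planted[:, None, :] - detected[None, :, :], axis=2)
    recall = float((d.min(axis=1) <= tol_px).mean())
    precision = float((d.min(axis=0) <= tol_px).mean())
    return recall, precision
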