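"""Bundled published reference data.

Small tables reproduced from the published sow study this pipeline
re-implements: the tape-measured vs point-cloud-extracted body widths for
seven animals (used to reproduce the reported width-error percentages) and
two 8-point excerpts of a back cloud, with and without RGB, illustrating
the exact column layouts the regressor consumes.
"""

from __future__ import annotations

import numpy as np

from .pc_io import PointCloud

__all__ = [
    "BODY_MEASUREMENT_TABLE",
    "reference_body_measurements",
    "reference_cloud_xyz",
    "reference_cloud_xyzrgb",
]

# columns: true shoulder, extracted shoulder, true abdomen, extracted
# abdomen, true hip, extracted hip (meters); one row per animal
BODY_MEASUREMENT_TABLE = np.array([
    [0.395, 0.386, 0.481, 0.492, 0.404, 0.414],
    [0.433, 0.451, 0.368, 0.357, 0.378, 0.365],
    [0.291, 0.285, 0.324, 0.304, 0.321, 0.306],
    [0.411, 0.396, 0.316, 0.325, 0.422, 0.434],
    [0.491, 0.474, 0.395, 0.417, 0.335, 0.323],
    [0.415, 0.425, 0.361, 0.373, 0.381, 0.362],
    [0.401, 0.385, 0.362, 0.350, 0.401, 0.420],
])

_XYZ8 = np.array([
    [-0.26387, 0.02476, -1.68700],
    [-0.25939, 0.02476, -1.68700],
    [-0.25431, 0.02470, -1.68300],
    [-0.24984, 0.02470, -1.68300],
    [-0.24537, 0.02470, -1.68300],
    [-0.24148, 0.02476, -1.68700],
    [-0.23770, 0.02483, -1.69200],
    [-0.23321, 0.02483, -1.69200],
])

_RGB8 = np.array([
    [137, 128, 119],
    [137, 130, 120],
    [136, 127, 122],
    [134, 119, 118],
    [125, 110, 109],
    [123, 108, 107],
    [125, 111, 105],
    [128, 109, 103],
])


def reference_body_measurements(part: str) -> tuple[np.ndarray, np.ndarray]:
    """(true, extracted) width columns for 'shoulder', 'abdomen' or 'hip'."""
    col = {"shoulder": 0, "abdomen": 2, "hip": 4}[part]
    t = BODY_MEASUREMENT_TABLE
    return t[:, col].copy(), t[:, col + 1].copy()


def reference_cloud_xyz() -> PointCloud:
    """The published 8-point coordinate-only back-cloud excerpt."""
    return PointCloud(_XYZ8.copy(), source_id="reference-xyz-8")


def reference_cloud_xyzrgb() -> PointCloud:
    """The published 8-point colored back-cloud excerpt."""
    return PointCloud(_XYZ8.copy(), _RGB8.copy(), source_id="reference-xyzrgb-8")
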