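"""Segmentation-gated false-positive removal.

Contact points can only exist where florets meet the receptacle, so any
detection whose bounding box does not overlap the receptacle mask of its
slice is discarded as a false positive.  "Overlap" means at least one
mask-true pixel centre (integer coordinates) lies inside the half-open box;
no area threshold is applied.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .detection_eval import BBox, Detection, MaskImage


def _box_overlaps_mask(box: BBox, pixels: np.ndarray) -> bool:
    w, h = pixels.shape
    h0 = max(0, math.ceil(box.x_min))
    h1 = min(w, math.ceil(box.x_max))
    v0 = max(0, math.ceil(box.y_min))
    v1 = min(h, math.ceil(box.y_max))
    if h0 >= h1 or v0 >= v1:
        return False
    return bool(pixels[h0:h1, v0:v1].any())


def filter_detections(
    dets: Sequence[Detection], mask: MaskImage
) -> tuple[list[Detection], list[Detection]]:
    """Split detections on one slice into (kept, removed) by mask overlap.

    All detections must carry the mask's ``slice_id``.  Kept and removed
    are disjoint, preserve the input order, and together contain every
    input detection.
    """
    kept: list[Detection] = []
    removed: list[Detection] = []
    for det in dets:
        if det.slice_id != mask.slice_id:
            raise ValueError(
                f"slice_id mismatch: detection {det.slice_id!r} vs mask {mask.slice_id!r}"
            )
        (kept if _box_overlaps_mask(det.box, mask.pixels) else removed).append(det)
    return kept, removed
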