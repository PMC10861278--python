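"""Connection-based tractogram scoring and length statistics.

Each streamline is classified by where its two endpoints land among the
ground-truth endpoint ROIs:

* **VC** (valid connection): the endpoints occupy the two distinct ROIs of
  one ground-truth bundle;
* **IC** (invalid connection): both endpoints are in ROIs, but the pair of
  ROIs is not a ground-truth bundle;
* **NC** (no connection): at least one endpoint is in no ROI.  A streamline
  whose endpoints sit in one and the same ROI also counts as NC — it
  connects nothing.

**VB** counts ground-truth bundles recovered by at least one VC streamline;
**IB** counts distinct non-ground-truth ROI pairs carrying at least one IC
streamline.  An endpoint is "in" an ROI when its containing voxel
(``floor(inv(affine) @ p)``) is set in the ROI mask.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .phantom import ConnectivityGroundTruth
from .tracking import Tractogram

__all__ = ["EvaluationReport", "classify_streamlines", "length_stats"]


@dataclass
class EvaluationReport:
    """Tractometer-style connection scores plus fiber length statistics.

    Percentages are over all streamlines and partition to 100; lengths are
    mm.  ``fl_min``/``fl_max``/``fl_mean`` are NaN for an empty tractogram
    (``degenerate`` is then set).
    """

    vc_percent: float
    ic_percent: float
    nc_percent: float
    vb_count: int
    ib_count: int
    fb_num: int
    fl_min: float
    fl_max: float
    fl_mean: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_frame(self) -> pd.DataFrame:
        """One-row table with the conventional column names."""
        return pd.DataFrame(
            [
                {
                    "VB": self.vb_count,
                    "VC": self.vc_percent,
                    "IC": self.ic_percent,
                    "NC": self.nc_percent,
                    "IB": self.ib_count,
                    "FB_num": self.fb_num,
                    "FL_max": self.fl_max,
                    "FL_min": self.fl_min,
                    "FL_mean": self.fl_mean,
                }
            ]
        )

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)


def length_stats(tractogram: Tractogram) -> tuple[int, float, float, float]:
    """Streamline count and (min, max, mean) polyline length in mm."""
    lengths = np.array([s.length for s in tractogram.streamlines])
    if lengths.size == 0:
        return 0, float("nan"), float("nan"), float("nan")
    return (
        int(lengths.size),
        float(lengths.min()),
        float(lengths.max()),
        float(lengths.mean()),
    )


def _roi_hits(point: np.ndarray, rois: list[np.ndarray], inv_affine: np.ndarray) -> list[int]:
    u = np.floor(inv_affine[:3, :3] @ point + inv_affine[:3, 3]).astype(int)
    shape = rois[0].shape
    if not all(0 <= u[d] < shape[d] for d in range(3)):
        return []
    return [i for i, roi in enumerate(rois) if roi[u[0], u[1], u[2]]]


def classify_streamlines(
    tractogram: Tractogram, gt: ConnectivityGroundTruth
) -> EvaluationReport:
    """Score a tractogram against ground-truth connectivity (see module docs).

    When an endpoint lies in several ROIs, any bundle whose ROI pair is
    jointly covered counts as valid; otherwise the lowest-index ROI of each
    endpoint identifies the invalid pair.
    """
    n = len(tractogram)
    fb_num, fl_min, fl_max, fl_mean = length_stats(tractogram)
    if n == 0:
        return EvaluationReport(
            0.0, 0.0, 0.0, 0, 0, 0, fl_min, fl_max, fl_mean, degenerate=True
        )
    inv_affine = np.linalg.inv(np.asarray(gt.affine, dtype=float))
    rois: list[np.ndarray] = []
    for b in gt.bundles:
        rois.extend([np.asarray(b.roi_a, dtype=bool), np.asarray(b.roi_b, dtype=bool)])
    n_vc = n_ic = n_nc = 0
    vb_hit = set()
    ib_pairs = set()
    for sl in tractogram.streamlines:
        hits0 = _roi_hits(sl.points[0], rois, inv_affine) if rois else []
        hits1 = _roi_hits(sl.points[-1], rois, inv_affine) if rois else []
        if not hits0 or not hits1:
            n_nc += 1
            continue
        valid = [
            bi
            for bi in range(len(gt.bundles))
            if (2 * bi in hits0 and 2 * bi + 1 in hits1)
            or (2 * bi + 1 in hits0 and 2 * bi in hits1)
        ]
        if valid:
            n_vc += 1
            vb_hit.update(valid)
            continue
        pairs = [(i, j) for i in hits0 for j in hits1 if i != j]
        if not pairs:  # both endpoints in the same single ROI: connects nothing
            n_nc += 1
            continue
        n_ic += 1
        ib_pairs.add(tuple(sorted(min(pairs))))
    return EvaluationReport(
        vc_percent=100.0 * n_vc / n,
        ic_percent=100.0 * n_ic / n,
        nc_percent=100.0 * n_nc / n,
        vb_count=len(vb_hit),
        ib_count=len(ib_pairs),
        fb_num=fb_num,
        fl_min=fl_min,
        fl_max=fl_max,
        fl_mean=fl_mean,
    )
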