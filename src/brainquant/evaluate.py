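"""Scoring detections against synthetic ground truth.

Matches detections to ground-truth cells one-to-one by centroid distance
and derives recall, spurious-detection rate and classification accuracy.
Used to validate the pipeline on generated sections, where the truth is
exhaustive; on real tissue the analogous reference is a manual count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .classify import CellClass
from .containers import BinaryMask
from .detect import Detections
from .synthetic import GroundTruthCell, MICROGLIA, NEGATIVE, PERICYTE

__all__ = ["MatchResult", "match_detections", "classification_accuracy"]

TRUE_TO_PREDICTED = {
    PERICYTE: CellClass.DSRED_POS.value,
    MICROGLIA: CellClass.GFP_POS.value,
    NEGATIVE: CellClass.NEGATIVE.value,
}


@dataclass
class MatchResult:
    """One-to-one assignment between ground-truth cells and detections.

    ``gt_to_det[i]`` is the detection row index matched to ground-truth
    cell ``i`` (−1 if unmatched), and vice versa for ``det_to_gt``.
    """

    gt_to_det: np.ndarray
    det_to_gt: np.ndarray
    gt_in_mask: np.ndarray

    @property
    def n_matched(self) -> int:
        return int((self.gt_to_det >= 0).sum())

    def recall_pct(self) -> float:
        """Percent of in-mask ground-truth cells with a matched detection."""
        n = int(self.gt_in_mask.sum())
        if n == 0:
            return float("nan")
        return 100.0 * float((self.gt_to_det[self.gt_in_mask] >= 0).sum()) / n

    def spurious_pct(self) -> float:
        """Percent of detections with no ground-truth counterpart."""
        if len(self.det_to_gt) == 0:
            return 0.0
        return 100.0 * float((self.det_to_gt < 0).sum()) / len(self.det_to_gt)


def match_detections(
    cells: Sequence[GroundTruthCell],
    dets: Detections,
    max_dist_um: float = 5.0,
    within: BinaryMask | None = None,
) -> MatchResult:
    """Greedily match detections to ground-truth cells by nearest centroid.

    Pairs are accepted closest-first, each side used at most once, up to
    ``max_dist_um``.  ``within`` marks which ground-truth cells are in the
    analyzed mask (used for recall; unmatched detections are counted as
    spurious regardless).
    """
    n_gt = len(cells)
    n_det = len(dets)
    gt_to_det = -np.ones(n_gt, dtype=int)
    det_to_gt = -np.ones(n_det, dtype=int)
    if within is None:
        gt_in_mask = np.ones(n_gt, dtype=bool)
    else:
        ps = within.pixel_size_um
        rows = np.clip(
            np.array([int(c.y_um / ps) for c in cells]), 0, within.shape[0] - 1
        )
        cols = np.clip(
            np.array([int(c.x_um / ps) for c in cells]), 0, within.shape[1] - 1
        )
        gt_in_mask = within.data[rows, cols] if n_gt else np.zeros(0, dtype=bool)
    if n_gt == 0 or n_det == 0:
        return MatchResult(gt_to_det, det_to_gt, gt_in_mask)

    gxy = np.array([[c.x_um, c.y_um] for c in cells])
    dxy = dets.table[["centroid_x_um", "centroid_y_um"]].to_numpy(dtype=float)
    dist, idx = cKDTree(gxy).query(dxy, distance_upper_bound=max_dist_um)
    for d in np.argsort(dist):
        if not np.isfinite(dist[d]):
            break
        g = int(idx[d])
        if gt_to_det[g] >= 0:
            # nearest truth already taken; try the next-nearest within range
            cand = cKDTree(gxy).query(dxy[d], k=4, distance_upper_bound=max_dist_um)
            for dd, gg in zip(np.atleast_1d(cand[0]), np.atleast_1d(cand[1])):
                if np.isfinite(dd) and gt_to_det[int(gg)] < 0:
                    gt_to_det[int(gg)] = d
                    det_to_gt[d] = int(gg)
                    break
            continue
        gt_to_det[g] = d
        det_to_gt[d] = g
    return MatchResult(gt_to_det, det_to_gt, gt_in_mask)


def classification_accuracy(
    cells: Sequence[GroundTruthCell], dets: Detections, match: MatchResult
) -> float:
    """Percent of matched in-mask cells whose predicted class is the true one."""
    if "cell_class" not in dets.table.columns:
        raise ValueError("detections are not classified")
    pred = dets.table["cell_class"].to_numpy()
    ok = tot = 0
    for g, d in enumerate(match.gt_to_det):
        if d < 0 or not match.gt_in_mask[g]:
            continue
        tot += 1
        ok += pred[d] == TRUE_TO_PREDICTED[cells[g].cell_class]
    return 100.0 * ok / tot if tot else float("nan")
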