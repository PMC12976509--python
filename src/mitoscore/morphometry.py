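"""Classical per-mitochondrion and network morphometry (the traditional baseline).

Two families of descriptors are computed from a segmented mitochondrial image:

* per-object shape — form factor ``FF = P^2 / (4*pi*A)`` (1 for a disc,
  growing with elongation and boundary complexity) and aspect ratio
  ``AR = major/minor`` axis of the moment-equivalent ellipse;
* network topology — branches, geodesic branch lengths and junctions of the
  1-px topological skeleton.

Fragmented (hyperfission) phenotypes show many small near-circular objects;
hyperfused phenotypes show few elongated, branched networks.  These metrics
separate hyperfission from normal robustly but hyperfusion from normal only
weakly, which is exactly the gap the learned patch classifier closes.

Perimeter is estimated by contour following (marching squares at the 0.5
level) with a 5-point moving-average smoothing of the contour polygon; the
smoothing removes the staircase inflation that would otherwise bias the form
factor of a disc by ~15%, while leaving straight edges nearly exact (disc
bias < 1% for radius >= 10 px, rectangle perimeter within 2%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology

_EIGHT = np.ones((3, 3), dtype=int)
_SMOOTH_WINDOW = 5


def perimeter_contour(binary: np.ndarray) -> float:
    """Smoothed contour-following perimeter of a binary object mask."""
    padded = np.pad(np.asarray(binary, dtype=float), 1)
    total = 0.0
    for ct in measure.find_contours(padded, 0.5):
        closed = bool(np.allclose(ct[0], ct[-1]))
        pts = ct[:-1] if closed else ct
        if len(pts) > _SMOOTH_WINDOW:
            mode = "wrap" if closed else "nearest"
            pts = np.column_stack(
                [ndimage.uniform_filter1d(pts[:, i], _SMOOTH_WINDOW, mode=mode) for i in (0, 1)]
            )
        if closed:
            pts = np.vstack([pts, pts[:1]])
        d = np.diff(pts, axis=0)
        total += float(np.hypot(d[:, 0], d[:, 1]).sum())
    return total


@dataclass(frozen=True)
class MitoObject:
    """Shape descriptors of one segmented mitochondrial object."""

    label_id: int
    area_px: int
    perimeter_px: float
    major_axis_px: float
    minor_axis_px: float
    form_factor: float
    aspect_ratio: float
    reliable: bool  # False for degenerate (e.g. 1-px-wide) objects


def segment_mitochondria(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    block_size: int = 33,
    offset: float = 0.02,
    min_area_px: int = 4,
) -> np.ndarray:
    """Label mitochondrial objects by adaptive (local-mean) thresholding.

    A pixel is foreground when it exceeds the local mean of its
    ``block_size`` neighbourhood by ``offset`` (intensities assumed
    normalized to [0, 1]); mitochondrial signal is locally contrasted, so a
    local threshold avoids merging networks the way a global one would.  A
    global floor — half the Otsu threshold of the within-mask intensities —
    is applied on top, suppressing the cell-rim artifacts a pure local-mean
    rule produces where the mask meets dark background.  Objects smaller
    than ``min_area_px`` are removed; labelling uses 8-connectivity.  An
    empty mask yields an empty labelling.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected 2D image, got shape {image.shape}")
    if block_size % 2 == 0:
        block_size += 1
    local_mean = filters.threshold_local(image, block_size=block_size, method="mean")
    binary = image > (local_mean + offset)
    if mask is not None:
        mask_arr = np.asarray(getattr(mask, "mask", mask)).astype(bool)
        binary &= mask_arr
        inside = image[mask_arr]
    else:
        inside = image.ravel()
    if inside.size and np.ptp(inside) > 0:
        binary &= image > 0.5 * filters.threshold_otsu(inside)
    if min_area_px > 1:
        binary = morphology.remove_small_objects(binary, max_size=min_area_px - 1)
    labels, _ = ndimage.label(binary, structure=_EIGHT)
    return labels


def shape_metrics(labels: np.ndarray, min_area_px: int = 4) -> list[MitoObject]:
    """Per-object form factor and aspect ratio from a labelled image.

    Objects with a degenerate moment ellipse (minor axis ~ 0, i.e. 1 px wide)
    are flagged unreliable and excluded from field summaries.
    """
    objects: list[MitoObject] = []
    for region in measure.regionprops(np.asarray(labels)):
        if region.area < min_area_px:
            continue
        perim = perimeter_contour(region.image)
        major = float(region.axis_major_length)
        minor = float(region.axis_minor_length)
        reliable = minor > 0.5 and perim > 0
        ff = perim**2 / (4.0 * math.pi * region.area) if perim > 0 else float("nan")
        ar = major / minor if minor > 0.5 else float("inf")
        objects.append(
            MitoObject(
                label_id=int(region.label),
                area_px=int(region.area),
                perimeter_px=perim,
                major_axis_px=major,
                minor_axis_px=minor,
                form_factor=ff,
                aspect_ratio=ar,
                reliable=reliable,
            )
        )
    return objects


@dataclass(frozen=True)
class SkeletonGraph:
    """Branch/junction summary of a skeletonized network.

    Junction nodes are 8-connected clusters of skeleton pixels with degree
    >= 3; endpoints have degree 1; branches are the connected components left
    after removing junction pixels, with geodesic length (1 per axial step,
    sqrt(2) per diagonal step, plus one step per junction attachment).
    Isolated cycles (rings) count as a single branch with no junction.
    """

    n_branches: int
    n_junctions: int
    n_endpoints: int
    branch_lengths: np.ndarray  # px, one entry per branch

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths.sum())

    @property
    def mean_branch_length(self) -> float:
        return float(self.branch_lengths.mean()) if self.n_branches else float("nan")


def _edge_lengths_per_label(blab: np.ndarray, skel: np.ndarray) -> np.ndarray:
    """Geodesic length of each branch component: axial steps weigh 1,
    diagonal steps sqrt(2); a diagonal step is skipped when either of its two
    corner-adjacent skeleton pixels exists (the path runs through it)."""
    n = int(blab.max())
    lengths = np.zeros(n + 1)
    # axial edges
    for dr, dc in ((0, 1), (1, 0)):
        a = blab[: blab.shape[0] - dr, : blab.shape[1] - dc]
        b = blab[dr:, dc:]
        same = (a > 0) & (a == b)
        np.add.at(lengths, a[same], 1.0)
    # diagonal edges with corner correction
    for dr, dc in ((1, 1), (1, -1)):
        if dc == 1:
            a = blab[:-1, :-1]
            b = blab[1:, 1:]
            c1 = skel[:-1, 1:]
            c2 = skel[1:, :-1]
        else:
            a = blab[:-1, 1:]
            b = blab[1:, :-1]
            c1 = skel[:-1, :-1]
            c2 = skel[1:, 1:]
        same = (a > 0) & (a == b) & ~c1 & ~c2
        np.add.at(lengths, a[same], math.sqrt(2.0))
    return lengths[1:]


def skeleton_graph(mask: np.ndarray) -> SkeletonGraph:
    """Topological skeleton analysis of a binary network mask."""
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError(f"expected 2D mask, got shape {mask.shape}")
    skel = morphology.skeletonize(mask)
    if not skel.any():
        return SkeletonGraph(0, 0, 0, np.zeros(0))
    degree = ndimage.convolve(skel.astype(int), _EIGHT, mode="constant") - 1
    degree[~skel] = 0
    junction_px = skel & (degree >= 3)
    endpoint_px = skel & (degree == 1)
    _, n_junctions = ndimage.label(junction_px, structure=_EIGHT)
    n_endpoints = int(endpoint_px.sum())

    branch_px = skel & ~junction_px
    blab, n_branches = ndimage.label(branch_px, structure=_EIGHT)
    lengths = _edge_lengths_per_label(blab, skel)

    # one extra step per (branch, junction-cluster) attachment
    jlab, _ = ndimage.label(junction_px, structure=_EIGHT)
    if n_junctions and n_branches:
        attach: set[tuple[int, int]] = set()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                shifted = np.roll(np.roll(jlab, dr, axis=0), dc, axis=1)
                # rolled-in borders are invalid; mask them out
                if dr == 1:
                    shifted[0, :] = 0
                elif dr == -1:
                    shifted[-1, :] = 0
                if dc == 1:
                    shifted[:, 0] = 0
                elif dc == -1:
                    shifted[:, -1] = 0
                both = (blab > 0) & (shifted > 0)
                for b, j in zip(blab[both].tolist(), shifted[both].tolist()):
                    attach.add((b, j))
        for b, _j in attach:
            lengths[b - 1] += 1.0
    return SkeletonGraph(
        n_branches=int(n_branches),
        n_junctions=int(n_junctions),
        n_endpoints=n_endpoints,
        branch_lengths=lengths,
    )


def field_morphometry(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    block_size: int = 33,
    offset: float = 0.02,
) -> pd.Series:
    """Per-field morphometry summary (means and medians over reliable objects
    plus skeleton network counts).  Zero objects yield NaNs with
    ``object_count = 0``."""
    labels = segment_mitochondria(image, mask, block_size=block_size, offset=offset)
    objects = [o for o in shape_metrics(labels) if o.reliable]
    graph = skeleton_graph(labels > 0)
    nan = float("nan")
    ff = np.array([o.form_factor for o in objects])
    ar = np.array([o.aspect_ratio for o in objects])
    return pd.Series(
        {
            "object_count": len(objects),
            "form_factor_mean": ff.mean() if len(objects) else nan,
            "form_factor_median": float(np.median(ff)) if len(objects) else nan,
            "aspect_ratio_mean": ar.mean() if len(objects) else nan,
            "aspect_ratio_median": float(np.median(ar)) if len(objects) else nan,
            "n_branches": graph.n_branches,
            "mean_branch_length": graph.mean_branch_length,
            "n_junctions": graph.n_junctions,
            "total_skeleton_length": graph.total_length,
        }
    )
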