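"""Segmentation accuracy scoring with the Jaccard index.

An automated object ``A`` and a manual annotation ``M`` are compared as
pixel-position sets:

    J(A, M) = |A n M| / |A u M| = |A n M| / (|A| + |M| - |A n M|)

``J = 0`` means no overlap (a missed cell, read as a false negative);
``J = 1`` means exact pixel-for-pixel overlap.  IOU is a harsh measure —
around 0.7 already indicates a good segmentation, in part because manual
outlines themselves carry drawing inaccuracy.

Matching is manual-centric: every hand-drawn cell receives a score, each
automated object is used at most once (greedy, by descending pixel
overlap), and manual cells with no partner score 0.  For 3D volumes,
orthogonal xy / zy / xz cross-sections are scored against 2D annotations
drawn on those planes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from lfseg.types import check_same_shape


class UndefinedComparisonError(ValueError):
    """Jaccard of two empty sets is undefined."""


def _as_mask(pixels, shape_hint=None) -> np.ndarray:
    """Coerce a pixel set (boolean mask, coordinate set, or coordinate array)."""
    if isinstance(pixels, np.ndarray) and pixels.dtype == bool:
        return pixels
    if isinstance(pixels, np.ndarray) and pixels.ndim >= 2 and pixels.dtype != bool:
        # treat nonzero entries of a label/intensity image as the set
        return pixels != 0
    coords = {tuple(int(c) for c in p) for p in pixels}
    if shape_hint is None:
        if not coords:
            raise ValueError("cannot infer grid shape from an empty coordinate set")
        shape_hint = tuple(max(c[i] for c in coords) + 1 for i in range(len(next(iter(coords)))))
    mask = np.zeros(shape_hint, dtype=bool)
    for c in coords:
        mask[c] = True
    return mask


def jaccard(A, M) -> float:
    """Jaccard score of two pixel sets on a common grid.

    Accepts boolean masks, label images (nonzero = member), or iterables of
    coordinate tuples.  Raises :class:`UndefinedComparisonError` if both
    sets are empty; returns 0.0 if exactly one is.
    """
    if not isinstance(A, np.ndarray) or not isinstance(M, np.ndarray):
        # coordinate-set route: pure set arithmetic
        a = {tuple(int(c) for c in p) for p in A} if not isinstance(A, np.ndarray) else None
        m = {tuple(int(c) for c in p) for p in M} if not isinstance(M, np.ndarray) else None
        if a is None or m is None:  # mixed inputs: rasterize both
            shape = _as_mask(A if a is None else M).shape
            return jaccard(_as_mask(A, shape), _as_mask(M, shape))
        if not a and not m:
            raise UndefinedComparisonError("Jaccard of two empty pixel sets is undefined")
        inter = len(a & m)
        union = len(a) + len(m) - inter
        return inter / union if union else 0.0
    a = _as_mask(A)
    m = _as_mask(M)
    check_same_shape(a, m)
    na, nm = int(a.sum()), int(m.sum())
    if na == 0 and nm == 0:
        raise UndefinedComparisonError("Jaccard of two empty pixel sets is undefined")
    inter = int(np.logical_and(a, m).sum())
    return inter / (na + nm - inter)


@dataclass(frozen=True)
class SegmentationComparison:
    """One manual annotation paired with (at most) one automated object.

    Stores the set sizes and intersection so the score is recomputable:
    ``J = intersection / (a_size + m_size - intersection)``.
    ``auto_id`` is None for an unmatched manual cell (J = 0).
    """

    manual_id: int
    auto_id: int | None
    a_size: int
    m_size: int
    intersection: int

    @property
    def j(self) -> float:
        union = self.a_size + self.m_size - self.intersection
        return self.intersection / union if union else 0.0


@dataclass
class IOUReport:
    """Per-object comparisons plus summary statistics for one evaluation."""

    comparisons: list[SegmentationComparison]
    unmatched_automated: int = 0
    plane: str | None = None
    slice_index: int | None = None

    @property
    def scores(self) -> np.ndarray:
        return np.array([c.j for c in self.comparisons], dtype=np.float64)

    @property
    def median_j(self) -> float:
        return float(np.median(self.scores)) if self.comparisons else float("nan")

    @property
    def unmatched_manual(self) -> int:
        return sum(1 for c in self.comparisons if c.auto_id is None)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "manual_id": [c.manual_id for c in self.comparisons],
                "auto_id": [c.auto_id for c in self.comparisons],
                "auto_size": [c.a_size for c in self.comparisons],
                "manual_size": [c.m_size for c in self.comparisons],
                "intersection": [c.intersection for c in self.comparisons],
                "jaccard": [c.j for c in self.comparisons],
            }
        )

    def summary(self) -> dict:
        return {
            "n_manual": len(self.comparisons),
            "median_jaccard": self.median_j,
            "unmatched_manual": self.unmatched_manual,
            "unmatched_automated": self.unmatched_automated,
            "plane": self.plane,
            "slice_index": self.slice_index,
        }


def _border_labels(labels: np.ndarray) -> set[int]:
    edge_ids: set[int] = set()
    for axis in range(labels.ndim):
        for idx in (0, -1):
            sl = [slice(None)] * labels.ndim
            sl[axis] = idx
            edge_ids.update(np.unique(labels[tuple(sl)]).tolist())
    edge_ids.discard(0)
    return edge_ids


def match_objects(
    auto: np.ndarray, manual: np.ndarray, exclude_border: bool = True
) -> IOUReport:
    """Score every manual object against a one-to-one automated partner.

    Pairs are assigned greedily by descending pixel overlap (ties broken
    toward lower ids); each automated object is used at most once; manual
    objects left without a partner are recorded with J = 0.  By default,
    manual cells clipped by the image border are excluded from scoring.
    """
    auto = np.asarray(auto)
    manual = np.asarray(manual)
    check_same_shape(auto, manual)

    excluded = _border_labels(manual) if exclude_border else set()
    manual_sizes = {
        i: int(c)
        for i, c in enumerate(np.bincount(manual.ravel()))
        if i > 0 and c > 0 and i not in excluded
    }
    auto_sizes = {
        i: int(c) for i, c in enumerate(np.bincount(auto.ravel())) if i > 0 and c > 0
    }

    # joint overlap histogram over pixels where both maps are nonzero
    both = (auto > 0) & (manual > 0)
    pairs, counts = np.unique(
        np.stack([manual[both], auto[both]]), axis=1, return_counts=True
    )
    overlaps = [
        (int(c), int(m), int(a))
        for (m, a), c in zip(pairs.T, counts)
        if m in manual_sizes
    ]
    overlaps.sort(key=lambda t: (-t[0], t[1], t[2]))

    assigned_auto: set[int] = set()
    match: dict[int, tuple[int, int]] = {}  # manual -> (auto, intersection)
    for c, m, a in overlaps:
        if m in match or a in assigned_auto:
            continue
        match[m] = (a, c)
        assigned_auto.add(a)

    comparisons = []
    for m in sorted(manual_sizes):
        if m in match:
            a, inter = match[m]
            comparisons.append(
                SegmentationComparison(m, a, auto_sizes[a], manual_sizes[m], inter)
            )
        else:
            comparisons.append(SegmentationComparison(m, None, 0, manual_sizes[m], 0))
    unmatched_auto = len(auto_sizes) - len(assigned_auto)
    return IOUReport(comparisons, unmatched_automated=unmatched_auto)


PLANE_ALIASES = {
    "xy": "xy", "yx": "xy",
    "zy": "zy", "yz": "zy",
    "xz": "xz", "zx": "xz",
}


def extract_plane(volume: np.ndarray, plane: str, index: int) -> np.ndarray:
    """Orthogonal 2D cross-section of a (z, y, x) volume.

    ``xy`` slices at a z index, ``zy`` at an x index, ``xz`` at a y index.
    """
    if volume.ndim != 3:
        raise ValueError("extract_plane expects a 3D (z, y, x) volume")
    canonical = PLANE_ALIASES.get(plane.lower())
    if canonical is None:
        raise ValueError(f"plane must be one of xy/zy/xz, got {plane!r}")
    axis = {"xy": 0, "xz": 1, "zy": 2}[canonical]
    if not 0 <= index < volume.shape[axis]:
        raise ValueError(
            f"slice index {index} out of range for axis {axis} of shape {volume.shape}"
        )
    sl = [slice(None)] * 3
    sl[axis] = index
    return volume[tuple(sl)]


def evaluate_3d_planes(
    auto3d: np.ndarray,
    annotations: list[tuple[str, int, np.ndarray]],
    exclude_border: bool = True,
) -> list[IOUReport]:
    """Score a 3D segmentation against per-plane 2D manual annotations.

    Each annotation is ``(plane, slice_index, manual_2d_label_map)``; the
    matching cross-section of the 3D label map is extracted and scored with
    :func:`match_objects`.  Returns one report per annotation.
    """
    reports = []
    for plane, index, manual2d in annotations:
        section = extract_plane(np.asarray(auto3d), plane, int(index))
        report = match_objects(section, np.asarray(manual2d), exclude_border=exclude_border)
        report.plane = PLANE_ALIASES[plane.lower()]
        report.slice_index = int(index)
        reports.append(report)
    return reports


def per_plane_medians(reports: list[IOUReport]) -> dict[str, float]:
    """Median Jaccard per plane label, pooling objects across slices."""
    pooled: dict[str, list[float]] = {}
    for r in reports:
        pooled.setdefault(r.plane or "xy", []).extend(r.scores.tolist())
    return {p: float(np.median(s)) for p, s in pooled.items() if s}
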