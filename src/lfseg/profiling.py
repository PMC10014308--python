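"""Single-cell feature extraction, gating, and nearest-neighbor analysis.

After instance segmentation, each cell object is measured on every channel:
mean and integrated intensity on the raw values, and *fluorescence area*
(2D) / *volume* (3D) — the count of suprathreshold pixels inside the cell,
obtained by integrating the binarized channel.  Channel thresholds come
from tissue-matched control images (secondary-only, FMO, or isotype),
placed so that ~95% of the control's fluorescence is removed.

Positive populations are built flow-cytometry style with sequential gates:
an intensity gate, then a gate on the fluorescence area fraction per cell.
The second gate suppresses "bystander-positive" events — cells whose
outline catches surface fluorescence spilling over from an adjacent
positive cell.  Gated populations can be split into four expression levels
(dim / low / intermediate / high) by quartiles, and nearest-cell neighbors
are found by dilating a startpoint cell's pixel set with a 3-pixel
spherical structuring element and collecting every object it touches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage

from lfseg.types import MultichannelImage, check_same_shape

EXPRESSION_BINS = ("dim", "low", "intermediate", "high")
CONTROL_SOURCES = ("secondary_only", "fmo", "isotype")


@dataclass(frozen=True)
class GateSpec:
    """A sequential intensity + fluorescence-area gate for one marker.

    ``intensity_cutoff`` usually comes from :func:`control_threshold` on the
    marker's control image; ``min_area_fraction`` is the second sequential
    gate, expressed as a fraction of the cell's area for scale invariance.
    ``statistic`` selects the per-cell intensity statistic gated on.
    """

    channel: str
    intensity_cutoff: float
    min_area_fraction: float = 0.0
    statistic: str = "mean"
    control_source: str = "secondary_only"

    def __post_init__(self) -> None:
        if self.intensity_cutoff < 0:
            raise ValueError("intensity_cutoff must be nonnegative")
        if not 0 <= self.min_area_fraction <= 1:
            raise ValueError("min_area_fraction must lie in [0, 1]")
        if self.statistic not in ("mean", "integrated"):
            raise ValueError("statistic must be 'mean' or 'integrated'")
        if self.control_source not in CONTROL_SOURCES:
            raise ValueError(f"control_source must be one of {CONTROL_SOURCES}")


def control_threshold(control_image: np.ndarray, removal_fraction: float = 0.95) -> float:
    """Intensity cutoff removing the given fraction of control fluorescence.

    Returns the quantile of the control image's fluorescence-positive
    (nonzero) pixel intensities below which ``removal_fraction`` of them
    lie (linear interpolation).  An all-zero control yields 0 with a
    warning.
    """
    control = np.asarray(control_image, dtype=np.float64)
    if control.size == 0:
        raise ValueError("control image is empty")
    if not 0 < removal_fraction < 1:
        raise ValueError("removal_fraction must lie in (0, 1)")
    positive = control[control > 0]
    if positive.size == 0:
        warnings.warn("all-zero control image: cutoff set to 0", stacklevel=2)
        return 0.0
    return float(np.percentile(positive, 100.0 * removal_fraction))


def extract_features(
    objects: np.ndarray,
    channels: MultichannelImage,
    cutoffs: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Measure every segmented cell on every channel.

    Returns one row per object with columns:

    * ``cell_id`` — instance label
    * ``centroid_0`` .. — centroid in pixel coordinates
    * ``area`` — pixel (2D) or voxel (3D) count
    * ``mean_<ch>`` / ``integrated_<ch>`` — intensity statistics on the raw
      channel values
    * ``fluor_area_<ch>`` — count of pixels inside the cell at or above the
      channel's cutoff (NaN, and listed in ``df.attrs['missing_cutoffs']``,
      for channels without a cutoff)
    """
    objects = np.asarray(objects)
    if channels.channels:
        check_same_shape(objects, next(iter(channels.channels.values())))
    cutoffs = dict(cutoffs or {})

    ids = np.unique(objects)
    ids = ids[ids > 0]
    df = pd.DataFrame({"cell_id": ids.astype(int)})
    if ids.size:
        centroids = ndimage.center_of_mass(np.ones_like(objects, dtype=np.float64), objects, ids)
        for axis in range(objects.ndim):
            df[f"centroid_{axis}"] = [c[axis] for c in centroids]
        df["area"] = ndimage.sum_labels(np.ones_like(objects, dtype=np.int64), objects, ids)
    else:
        for axis in range(objects.ndim):
            df[f"centroid_{axis}"] = pd.Series(dtype=float)
        df["area"] = pd.Series(dtype=int)

    missing: list[str] = []
    for name, channel in channels.channels.items():
        channel = np.asarray(channel, dtype=np.float64)
        if ids.size:
            df[f"mean_{name}"] = ndimage.mean(channel, objects, ids)
            df[f"integrated_{name}"] = ndimage.sum_labels(channel, objects, ids)
        else:
            df[f"mean_{name}"] = pd.Series(dtype=float)
            df[f"integrated_{name}"] = pd.Series(dtype=float)
        if name in cutoffs:
            binary = (channel >= cutoffs[name]).astype(np.int64)
            df[f"fluor_area_{name}"] = (
                ndimage.sum_labels(binary, objects, ids) if ids.size else pd.Series(dtype=float)
            )
        else:
            missing.append(name)
            df[f"fluor_area_{name}"] = np.nan
    if missing:
        warnings.warn(
            f"no cutoff given for channels {missing}: fluorescence areas set to missing",
            stacklevel=2,
        )
    df.attrs["missing_cutoffs"] = missing
    return df


def gate_cells(table: pd.DataFrame, gate: GateSpec) -> set[int]:
    """Sequential gating: intensity first, then fluorescence-area fraction.

    Returns the surviving cell-id set.  With ``min_area_fraction = 0`` the
    second gate is the identity and this reduces to a pure intensity gate.
    """
    if table.empty:
        return set()
    stat_col = f"{gate.statistic}_{gate.channel}"
    area_col = f"fluor_area_{gate.channel}"
    for col in (stat_col, area_col):
        if col not in table.columns:
            raise KeyError(f"table lacks column {col!r}; extract features for {gate.channel!r}")
    sel = table[table[stat_col] >= gate.intensity_cutoff]
    if gate.min_area_fraction > 0:
        if sel[area_col].isna().any():
            raise ValueError(
                f"fluorescence area for {gate.channel!r} is missing; provide a cutoff"
            )
        frac = sel[area_col] / sel["area"]
        sel = sel[frac >= gate.min_area_fraction]
    return set(sel["cell_id"].astype(int))


def expression_bins(
    table: pd.DataFrame,
    marker: str,
    positive_ids: set[int],
    statistic: str = "mean",
) -> dict[int, str]:
    """Quartile-split a positive population into dim/low/intermediate/high.

    Quartiles are computed on the positive cells' marker intensity; values
    tied with a quartile boundary fall into the lower bin.  Fewer than 4
    positives cannot support quartiles: all are assigned "dim" with a
    warning.
    """
    if not positive_ids:
        raise ValueError("positive set is empty")
    col = f"{statistic}_{marker}"
    sub = table[table["cell_id"].isin(positive_ids)]
    values = sub[col].to_numpy(dtype=np.float64)
    ids = sub["cell_id"].astype(int).to_numpy()
    if len(ids) < 4:
        warnings.warn("fewer than 4 positive cells: all binned as 'dim'", stacklevel=2)
        return {int(i): "dim" for i in ids}
    cuts = np.percentile(values, [25, 50, 75])
    # side='left': a value equal to a boundary stays in the lower bin
    bins = np.searchsorted(cuts, values, side="left")
    return {int(i): EXPRESSION_BINS[b] for i, b in zip(ids, bins)}


def _ball(ndim: int, radius: int) -> np.ndarray:
    grids = np.ogrid[tuple(slice(-radius, radius + 1) for _ in range(ndim))]
    return sum(g**2 for g in grids) <= radius**2


def find_neighbors(
    objects: np.ndarray,
    startpoints: set[int] | None = None,
    dilation_px: int = 3,
    full_connectivity: bool = True,
) -> nx.Graph:
    """Nearest-cell-neighbor graph by boundary dilation.

    Each startpoint cell's pixel set is dilated by a disc (2D) or ball
    (3D) of radius ``dilation_px``; every distinct object the dilated set
    touches becomes an undirected neighbor edge.  The startpoint geometry
    itself is untouched (the dilation is scratch space only).  With
    ``dilation_px = 0`` the structuring element degrades to the declared
    pixel connectivity, so only objects sharing adjacent pixels connect.
    """
    objects = np.asarray(objects)
    all_ids = {int(i) for i in np.unique(objects) if i > 0}
    if startpoints is None:
        startpoints = all_ids
    else:
        startpoints = {int(s) for s in startpoints}
        unknown = startpoints - all_ids
        if unknown:
            raise ValueError(f"unknown startpoint ids: {sorted(unknown)}")
    if dilation_px < 0:
        raise ValueError("dilation_px must be >= 0")

    structure = (
        _ball(objects.ndim, dilation_px)
        if dilation_px > 0
        else ndimage.generate_binary_structure(
            objects.ndim, objects.ndim if full_connectivity else 1
        )
    )
    graph = nx.Graph()
    graph.add_nodes_from(sorted(all_ids))

    slices = ndimage.find_objects(objects)
    pad = max(dilation_px, 1)
    for start in sorted(startpoints):
        sl = slices[start - 1]
        if sl is None:
            continue
        window = tuple(
            slice(max(0, s.start - pad), min(dim, s.stop + pad))
            for s, dim in zip(sl, objects.shape)
        )
        crop = objects[window]
        dilated = ndimage.binary_dilation(crop == start, structure=structure)
        touched = np.unique(crop[dilated])
        for other in touched:
            other = int(other)
            if other not in (0, start):
                graph.add_edge(start, other, contact=True)
    return graph


def positive_for(marker: str):
    """Predicate: the cell is in the marker's gated positive set."""

    def pred(cell_id: int, gate_sets: dict[str, set[int]]) -> bool:
        return cell_id in gate_sets[marker]

    return pred


def negative_for_all():
    """Predicate: the cell is in no marker's gated positive set."""

    def pred(cell_id: int, gate_sets: dict[str, set[int]]) -> bool:
        return all(cell_id not in s for s in gate_sets.values())

    return pred


def neighbor_pair_map(
    graph: nx.Graph,
    gate_sets: dict[str, set[int]],
    combination: tuple,
    objects: np.ndarray | None = None,
) -> tuple[list[tuple[int, int]], np.ndarray | None]:
    """Touching cell pairs satisfying a phenotype combination.

    ``combination`` is a pair of predicates ``(pred_a, pred_b)`` over
    ``(cell_id, gate_sets)`` (see :func:`positive_for`,
    :func:`negative_for_all`).  An edge qualifies if its endpoints satisfy
    (A, B) in either order; returned pairs are oriented (a_cell, b_cell).
    If ``objects`` is given, a label mask containing only the involved
    cells — the nearest-cell-neighbor map — is returned alongside.
    """
    pred_a, pred_b = combination
    pairs: list[tuple[int, int]] = []
    for u, v in graph.edges:
        if pred_a(u, gate_sets) and pred_b(v, gate_sets):
            pairs.append((u, v))
        elif pred_a(v, gate_sets) and pred_b(u, gate_sets):
            pairs.append((v, u))
    mask = None
    if objects is not None:
        objects = np.asarray(objects)
        keep = {i for pair in pairs for i in pair}
        mask = np.where(np.isin(objects, sorted(keep)), objects, 0).astype(objects.dtype)
    return pairs, mask
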